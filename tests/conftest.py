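import numpy as np
import pytest

from axispls import connmap, pls, synthgen

SMALL_SHAPE = (12, 16, 12)
SMALL_SIZES = (40, 120, 80)


def make_cohort(seed=0, n=30, T=100, **overrides):
    """A desk-scale synthetic cohort on a 12 x 16 x 12 grid."""
    kwargs = dict(
        n_subjects=n,
        shape=SMALL_SHAPE,
        n_timepoints=T,
        seed_sizes=SMALL_SIZES,
        make_tacs=False,
    )
    kwargs.update(overrides)
    return synthgen.gen_cohort(synthgen.CohortConfig(**kwargs), seed=seed)


def seed_map_stack(cohort, restrict_to_extra_seed=True):
    """Seed maps for all subjects x conditions, stacked for PLS."""
    maps = []
    for i, sub in enumerate(cohort.table["subject"]):
        for label in ("aHC", "mHC", "pHC"):
            maps.append(
                connmap.seed_map(
                    cohort.series[i], cohort.truth.seed_masks[label],
                    subject=sub, condition=label,
                )
            )
    stack = pls.ConnStack.from_seed_maps(maps)
    if not restrict_to_extra_seed:
        return stack
    strip = np.zeros(cohort.config.shape, bool)
    for m in cohort.truth.seed_masks.values():
        strip |= m
    return stack.restrict(~strip.reshape(-1))


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(seed=11)


@pytest.fixture(scope="session")
def small_stack(small_cohort):
    return seed_map_stack(small_cohort)
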