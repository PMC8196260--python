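"""Seeded synthetic cohorts for the hippocampal-axis connectivity pipeline.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale and with a machine-readable ground truth:

* Three hippocampal seed regions (anterior / middle / posterior) ordered
  along one spatial axis, whose voxels mix three latent network time
  courses: an "anterior" course A(t), a "posterior" course P(t), and a
  "shared" course S(t) common to all seeds.
* Three extra-hippocampal network voxel sets carrying A, P and S
  respectively, scaled per subject by adherence weights (w_ant, w_post,
  w_shared) -- the generative analogue of individual differences in network
  expression.
* Behavioural covariates (episodic memory, D2 receptor availability)
  linearly coupled to the adherence weights, plus nuisance variables (sex,
  mean frame-wise displacement, per-region signal-to-noise).
* Per-subject PET time--activity curve pairs following a one-tissue
  reference-tissue kinetic model with a known binding potential.

Everything is reproducible from (config, seed); the planted parameters are
returned in a :class:`TruthRecord` so recovery tests can score the pipeline
against a known answer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .kinetics import Tac

__all__ = [
    "EffectSizes",
    "CohortConfig",
    "TruthRecord",
    "SyntheticCohort",
    "gen_cohort",
    "gen_tacs",
    "gen_memory_trials",
    "default_frame_schedule",
    "default_reference_tac",
    "MEMORY_TASKS",
]

# Episodic-memory tasks: (items per trial, number of trials).  Word recall
# 16 items x 2 trials (max 32), number-word recall 8 x 2 (max 16),
# object-location recall 12 x 2 (max 24).
MEMORY_TASKS: dict[str, tuple[int, int]] = {
    "word": (16, 2),
    "numword": (8, 2),
    "objloc": (12, 2),
}


@dataclass(frozen=True)
class EffectSizes:
    """Amplitudes of the planted network signals, in units of the voxel noise SD."""

    anterior: float = 1.0
    posterior: float = 1.0
    shared: float = 0.8
    #: weight of the shared course S(t) inside every seed region's signal
    seed_shared_gain: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """Settings for :func:`gen_cohort`.

    Defaults describe the emulated study conditions: 170 subjects, 170
    volumes at TR = 2 s, a 20 x 24 x 20 voxel grid with axis-ordered seed
    masks of 82 / 283 / 157 voxels, and behaviour coupled to the shared
    network (the generative counterpart of a memory- and receptor-related
    network expressed equally along the axis).
    """

    n_subjects: int = 170
    shape: tuple[int, int, int] = (20, 24, 20)
    n_timepoints: int = 170
    tr: float = 2.0
    seed_sizes: tuple[int, int, int] = (82, 283, 157)
    effects: EffectSizes = field(default_factory=EffectSizes)
    noise_sd: float = 1.0
    baseline: float = 1000.0
    #: target mean signal-to-noise of the ROI-average signal, anterior ->
    #: posterior; sets the per-region fluctuation amplitude.
    target_snr: tuple[float, float, float] = (292.8, 428.6, 590.3)
    adherence_mean: float = 1.0
    adherence_sd: float = 0.25
    mid_mix_mean: float = 0.5
    mid_mix_sd: float = 0.15
    #: "mixture": middle-seed voxels carry a subject-specific blend of A and
    #: P; "independent": they carry their own latent course (useful when the
    #: three seed regions must be spatially separable sources).
    middle_course: str = "mixture"
    #: target correlations between each behaviour column and z-scored
    #: adherence weights; keys are behaviour names, values map weight name
    #: ("w_ant" | "w_post" | "w_shared") to a coupling coefficient.
    couplings: dict = field(
        default_factory=lambda: {
            "memory": {"w_shared": 0.5},
            "d2dr": {"w_shared": 0.4},
        }
    )
    bp_mean: float = 0.3
    bp_sd: float = 0.1
    missing_rate: float = 0.0
    smooth_sigma: float = 2.0  # temporal smoothing of latent courses, in samples
    make_tacs: bool = True

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError(f"CohortConfig.n_subjects = {self.n_subjects}: need at least 3 subjects")
        if any(s <= 0 for s in self.seed_sizes):
            raise ValueError(f"CohortConfig.seed_sizes = {self.seed_sizes}: empty seed mask requested")
        if self.noise_sd < 0:
            raise ValueError(f"CohortConfig.noise_sd = {self.noise_sd}: negative SD")
        if self.adherence_sd < 0:
            raise ValueError(f"CohortConfig.adherence_sd = {self.adherence_sd}: negative SD")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"CohortConfig.missing_rate = {self.missing_rate}: must lie in [0, 1]")
        if self.n_timepoints < 3:
            raise ValueError(f"CohortConfig.n_timepoints = {self.n_timepoints}: need >= 3 volumes")
        if self.middle_course not in ("mixture", "independent"):
            raise ValueError(f"CohortConfig.middle_course = {self.middle_course!r}: unknown option")
        total = np.prod(self.shape)
        if sum(self.seed_sizes) > total:
            raise ValueError("CohortConfig.seed_sizes exceed the voxel grid")
        for beh, cmap in self.couplings.items():
            ssq = sum(c**2 for c in cmap.values())
            if ssq > 1.0:
                raise ValueError(
                    f"CohortConfig.couplings[{beh!r}]: sum of squared couplings {ssq:.3f} exceeds 1"
                )


@dataclass
class TruthRecord:
    """Planted parameters of a synthetic cohort -- the oracle for recovery tests."""

    w_ant: np.ndarray
    w_post: np.ndarray
    w_shared: np.ndarray
    mid_mix: np.ndarray
    couplings: dict
    bp_true: np.ndarray
    seed_masks: dict[str, np.ndarray]  # label -> boolean volume
    network_masks: dict[str, np.ndarray]
    noise_sd: float
    region_scales: dict[str, float]
    behavior_latents: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name in ("w_ant", "w_post", "w_shared"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"TruthRecord.{name}: non-finite adherence weights")
        if np.any(self.bp_true < 0):
            raise ValueError("TruthRecord.bp_true: binding potential must be >= 0")
        all_masks = list(self.seed_masks.values()) + list(self.network_masks.values())
        stack = np.stack([m.ravel() for m in all_masks])
        if np.any(stack.sum(axis=0) > 1):
            raise ValueError("TruthRecord: seed/network masks overlap")

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, np.ndarray):
                if v.dtype == bool:
                    return np.flatnonzero(v.ravel()).tolist()
                return v.tolist()
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            return v

        payload = {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}
        return json.dumps(payload, indent=1)


@dataclass
class SyntheticCohort:
    """A generated cohort: one 4-D series, one TAC pair and one table row per subject."""

    config: CohortConfig
    seed: int
    series: list[np.ndarray]  # per subject, shape (*config.shape, n_timepoints), float32
    table: pd.DataFrame
    tacs: list[tuple[Tac, Tac] | None]  # (target, reference) per subject
    truth: TruthRecord

    def content_hash(self) -> str:
        """SHA-256 over all generated arrays and the cohort table -- determinism probe."""
        h = hashlib.sha256()
        for s in self.series:
            h.update(np.ascontiguousarray(s).tobytes())
        h.update(self.table.to_csv(index=False).encode())
        for pair in self.tacs:
            if pair is not None:
                for tac in pair:
                    h.update(tac.activity.tobytes())
        h.update(self.truth.to_json().encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# mask construction


def _strip_bounds(shape: tuple[int, int, int]) -> tuple[slice, slice]:
    """x- and z-extent of the hippocampal strip running along the y axis."""
    nx, _, nz = shape
    cx, cz = nx // 2, nz // 2
    hx, hz = min(4, nx // 4), min(2, nz // 4)
    return slice(cx - hx, cx + hx), slice(cz - hz, cz + hz)


def build_seed_masks(shape: tuple[int, int, int], sizes: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Three disjoint axis-ordered seed masks inside a strip along the y axis.

    Voxels fill the strip slice by slice in increasing y, so the anterior
    mask occupies the smallest y values and the posterior the largest,
    giving the configured axis ordering aHC < mHC < pHC in mean y.  The
    strip is mirror-symmetric in x so each mask spans both hemispheres.
    """
    xs, zs = _strip_bounds(shape)
    ny = shape[1]
    order = []  # (y, x, z) in fill order, alternating mirrored x pairs
    xvals = list(range(xs.start, xs.stop))
    half = len(xvals) // 2
    left, right = xvals[:half], xvals[half:][::-1]
    for y in range(1, ny - 1):
        for xl, xr in zip(left, right):
            for z in range(zs.start, zs.stop):
                order.append((xl, y, z))
                order.append((xr, y, z))
    if sum(sizes) > len(order):
        raise ValueError(
            f"seed_sizes: requested {sum(sizes)} voxels but the axis strip holds {len(order)}"
        )
    masks = {}
    pos = 0
    for label, n in zip(("aHC", "mHC", "pHC"), sizes):
        m = np.zeros(shape, dtype=bool)
        for x, y, z in order[pos : pos + n]:
            m[x, y, z] = True
        masks[label] = m
        pos += n
    return masks


def build_network_masks(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Three disjoint extra-hippocampal network voxel sets.

    Boxes are carved out of the volume left of / right of / above the
    hippocampal strip, so they never intersect the seed masks at any grid
    size: an anterior box toward small y, a posterior box toward large y,
    and a shared box at mid-axis.
    """
    nx, ny, nz = shape
    xs, zs = _strip_bounds(shape)

    def box(x0, x1, y0, y1, z0, z1):
        m = np.zeros(shape, dtype=bool)
        m[x0:x1, y0:y1, z0:z1] = True
        if not m.any():
            raise ValueError(f"network mask empty for grid {shape}; grid too small")
        return m

    # anterior and posterior boxes must have identical voxel counts: an
    # asymmetric pair biases the middle condition's brain score away from 0
    y_len = ny // 3 - 1
    x_len = min(xs.start - 1, nx - 1 - xs.stop)
    return {
        "anterior": box(xs.start - x_len, xs.start, 1, 1 + y_len, 1, zs.start),
        "posterior": box(xs.stop, xs.stop + x_len, ny - 1 - y_len, ny - 1, 1, zs.start),
        "shared": box(1, xs.start, ny // 2 - 2, ny // 2 + 2, zs.stop, nz - 1),
    }


# ---------------------------------------------------------------------------
# latent machinery


def _latent_courses(rng: np.random.Generator, n_t: int, n_courses: int, sigma: float) -> np.ndarray:
    """Smoothed, z-scored Gaussian-process-like latent time courses, (n_t, k)."""
    x = rng.standard_normal((n_t, n_courses))
    if sigma > 0:
        x = gaussian_filter1d(x, sigma=sigma, axis=0, mode="wrap")
    x -= x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return x / sd


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _coupled_column(
    rng: np.random.Generator, couplings: dict[str, float], weights_z: dict[str, np.ndarray], n: int
) -> np.ndarray:
    """A unit-variance column with the stated correlations to the weight z-scores."""
    out = np.zeros(n)
    ssq = 0.0
    for wname, rho in couplings.items():
        out += rho * weights_z[wname]
        ssq += rho**2
    resid = max(0.0, 1.0 - ssq)
    out += np.sqrt(resid) * rng.standard_normal(n)
    return out


# ---------------------------------------------------------------------------
# PET TAC simulation


def default_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """An 18-frame, 55-minute dynamic schedule (4x1, 6x2.5, 8x4.5 min)."""
    dur = np.array([1.0] * 4 + [2.5] * 6 + [4.5] * 8)
    end = np.cumsum(dur)
    return end - dur, end


def default_reference_tac(
    t: np.ndarray, amplitude: float = 10.0, alpha: float = 1.0, beta: float = 4.0
) -> np.ndarray:
    """Gamma-variate reference-region input, peaking at ``alpha * beta`` minutes."""
    peak = (alpha * beta) ** alpha * np.exp(-alpha)
    return amplitude * np.power(np.maximum(t, 0.0), alpha) * np.exp(-t / beta) / peak


def gen_tacs(
    bp_true: float,
    r1: float = 1.0,
    k2: float = 0.15,
    ref_curve: Tac | None = None,
    seed: int | None = None,
    noise_sd: float = 0.0,
    schedule: tuple[np.ndarray, np.ndarray] | None = None,
    dt: float = 0.01,
) -> tuple[Tac, Tac]:
    """Simulate a (target, reference) TAC pair from a reference-tissue model.

    The target tissue follows the one-tissue simplified reference-tissue
    kinetics

        C_t(t) = R1 C_ref(t) + (k2 - R1 k2 / (1 + BP)) *
                 [C_ref (x) exp(-k2 t / (1 + BP))](t)

    with (x) denoting convolution.  The convolution is evaluated on a fine
    grid with an exponential-integrator recursion (second-order accurate),
    and frame activities are frame means of the continuous curves, as a PET
    scanner reports them.

    Parameters
    ----------
    bp_true : float
        Planted binding potential, >= 0.
    r1 : float
        Delivery ratio K1 / K1'.
    k2 : float, per minute
        Target-tissue efflux rate constant.
    ref_curve : Tac, optional
        Reference TAC to resample; when omitted a smooth gamma-variate
        curve is used.
    noise_sd : float
        SD of additive Gaussian frame noise, as a fraction of the frame
        activity (0 = noiseless).
    """
    if bp_true < 0:
        raise ValueError(f"gen_tacs: bp_true = {bp_true} must be >= 0")
    if noise_sd < 0:
        raise ValueError(f"gen_tacs: noise_sd = {noise_sd} must be >= 0")
    if schedule is None:
        start, end = default_frame_schedule()
    else:
        start, end = (np.asarray(a, dtype=float) for a in schedule)
        if np.any(np.diff(start) <= 0) or np.any(end <= start):
            raise ValueError("gen_tacs: frame schedule must be strictly increasing")

    t = np.arange(0.0, end[-1] + dt, dt)
    if ref_curve is None:
        c_ref = default_reference_tac(t)
    else:
        c_ref = np.interp(t, np.concatenate([[0.0], ref_curve.mid]), np.concatenate([[0.0], ref_curve.activity]))

    k2a = k2 / (1.0 + bp_true)
    # y' = c_ref - k2a y  solved with an integrating-factor trapezoid step
    decay = np.exp(-k2a * dt)
    conv = np.zeros_like(t)
    for i in range(1, t.size):
        conv[i] = conv[i - 1] * decay + 0.5 * dt * (c_ref[i] + c_ref[i - 1] * decay)
    c_t = r1 * c_ref + (k2 - r1 * k2a) * conv

    def frame_means(curve: np.ndarray) -> np.ndarray:
        out = np.empty(start.size)
        for i, (s, e) in enumerate(zip(start, end)):
            sel = (t >= s - 1e-12) & (t <= e + 1e-12)
            out[i] = np.trapezoid(curve[sel], t[sel]) / (e - s)
        return out

    act_t, act_r = frame_means(c_t), frame_means(c_ref)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        act_t = np.maximum(act_t * (1.0 + noise_sd * rng.standard_normal(act_t.size)), 0.0)
        act_r = np.maximum(act_r * (1.0 + noise_sd * rng.standard_normal(act_r.size)), 0.0)
    return Tac(start, end, act_t), Tac(start, end, act_r)


# ---------------------------------------------------------------------------
# memory trials


def gen_memory_trials(
    n_subjects: int,
    seed: int | None = None,
    ability_z: np.ndarray | None = None,
    missing_rate: float = 0.0,
    tasks: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-trial episodic-memory task scores for a cohort.

    Each trial score is Binomial(items, p_s) with a subject-level success
    probability ``p_s = clip(0.65 + 0.08 * ability_z, 0, 1)``, so task sums
    respect the task maxima (32 / 16 / 24 under the default task battery)
    and an ``ability_z`` of +-inf forces the all-correct / all-wrong
    extremes.  Missing entries (NaN) are planted completely at random at
    ``missing_rate``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError(f"gen_memory_trials: missing_rate = {missing_rate} outside [0, 1]")
    tasks = MEMORY_TASKS if tasks is None else tasks
    rng = np.random.default_rng(seed)
    if ability_z is None:
        ability_z = rng.standard_normal(n_subjects)
    ability_z = np.asarray(ability_z, dtype=float)
    if ability_z.shape != (n_subjects,):
        raise ValueError("gen_memory_trials: ability_z must have one entry per subject")
    p = np.clip(0.65 + 0.08 * ability_z, 0.0, 1.0)

    data = {}
    for task, (items, n_trials) in tasks.items():
        for trial in range(1, n_trials + 1):
            col = rng.binomial(items, p).astype(float)
            if missing_rate > 0:
                col[rng.random(n_subjects) < missing_rate] = np.nan
            data[f"{task}_t{trial}"] = col
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# cohort generation


def gen_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort from (config, seed).

    Identical arguments reproduce the cohort bit-for-bit; see
    :meth:`SyntheticCohort.content_hash`.
    """
    config = CohortConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(seed)
    n, n_t = config.n_subjects, config.n_timepoints
    shape = config.shape

    seed_masks = build_seed_masks(shape, config.seed_sizes)
    network_masks = build_network_masks(shape)
    for label, m in seed_masks.items():
        for nlabel, nm in network_masks.items():
            if np.any(m & nm):
                raise ValueError(f"mask overlap between seed {label} and network {nlabel}")

    # subject-level latents
    w = {
        name: config.adherence_mean + config.adherence_sd * rng.standard_normal(n)
        for name in ("w_ant", "w_post", "w_shared")
    }
    mid_mix = np.clip(
        config.mid_mix_mean + config.mid_mix_sd * rng.standard_normal(n), 0.0, 1.0
    )
    weights_z = {k: _zscore(v) for k, v in w.items()}
    behavior_latents = {
        beh: _coupled_column(rng, cmap, weights_z, n) for beh, cmap in config.couplings.items()
    }

    # per-region fluctuation amplitude set from the target ROI-average SNR:
    # SNR ~= baseline / (scale * SD of the ROI-mean fluctuation), and the
    # ROI-mean fluctuation has SD ~ sqrt(1 + gain^2) in latent units.
    gain = config.effects.seed_shared_gain
    latent_sd = np.sqrt(1.0 + gain**2)
    region_scales = {
        label: config.baseline / (snr * latent_sd)
        for label, snr in zip(("aHC", "mHC", "pHC"), config.target_snr)
    }

    eff = config.effects
    series: list[np.ndarray] = []
    flat_seed = {k: m.reshape(-1) for k, m in seed_masks.items()}
    flat_net = {k: m.reshape(-1) for k, m in network_masks.items()}
    n_vox = int(np.prod(shape))

    for s in range(n):
        sub_rng = np.random.default_rng(rng.integers(0, 2**63 - 1))
        k_latent = 4 if config.middle_course == "independent" else 3
        courses = _latent_courses(sub_rng, n_t, k_latent, config.smooth_sigma)
        a_t, p_t, s_t = courses[:, 0], courses[:, 1], courses[:, 2]
        if config.middle_course == "independent":
            m_t = courses[:, 3]
        else:
            m_t = mid_mix[s] * a_t + (1.0 - mid_mix[s]) * p_t

        vol = np.empty((n_vox, n_t), dtype=np.float32)
        vol[:] = config.baseline
        noise = config.noise_sd * sub_rng.standard_normal((n_vox, n_t))

        def region_signal(course):
            return course + gain * s_t

        for label, course in (("aHC", a_t), ("mHC", m_t), ("pHC", p_t)):
            idx = flat_seed[label]
            scale = region_scales[label]
            vol[idx] += (scale * (region_signal(course)[None, :] + noise[idx])).astype(np.float32)

        net_courses = {
            "anterior": w["w_ant"][s] * eff.anterior * a_t,
            "posterior": w["w_post"][s] * eff.posterior * p_t,
            "shared": w["w_shared"][s] * eff.shared * s_t,
        }
        for label, course in net_courses.items():
            idx = flat_net[label]
            vol[idx] += (course[None, :] + noise[idx]).astype(np.float32)

        bg = ~(
            flat_seed["aHC"] | flat_seed["mHC"] | flat_seed["pHC"]
            | flat_net["anterior"] | flat_net["posterior"] | flat_net["shared"]
        )
        vol[bg] += noise[bg].astype(np.float32)
        series.append(vol.reshape(*shape, n_t))

    # cohort table
    sex = rng.binomial(1, 0.54, n)  # 1 = male, roughly the cohort's sex split
    fd = np.clip(0.19 + 0.09 * rng.standard_normal(n), 0.05, 0.45)
    icv = 1.5e6 + 1.5e5 * rng.standard_normal(n)
    icv_c = icv - icv.mean()
    vol_base = {"aHC": 522.0, "mHC": 2178.0, "pHC": 1228.0}
    vol_sd = {"aHC": 79.0, "mHC": 257.0, "pHC": 146.0}
    perf_mean = {"aHC": 40.31, "mHC": 42.91, "pHC": 41.84}
    d2dr_z = behavior_latents.get("d2dr", rng.standard_normal(n))
    bp_true = np.clip(config.bp_mean + config.bp_sd * d2dr_z, 0.01, None)

    table = pd.DataFrame(
        {
            "subject": [f"sub{idx:03d}" for idx in range(n)],
            "sex": sex,
            "mean_fd": fd,
            "icv": icv,
            "d2dr": bp_true,
        }
    )
    if "memory" in behavior_latents:
        table["memory"] = 50.0 + 10.0 * behavior_latents["memory"]
    for label in ("aHC", "mHC", "pHC"):
        raw = vol_base[label] + 0.3 * vol_sd[label] / icv.std() * icv_c
        raw += vol_sd[label] * np.sqrt(1 - 0.3**2) * rng.standard_normal(n)
        table[f"vol_{label}"] = raw
        table[f"perf_{label}"] = perf_mean[label] + 3.0 * rng.standard_normal(n)

    trial_seed = int(rng.integers(0, 2**31 - 1))
    ability = behavior_latents.get("memory", rng.standard_normal(n))
    trials = gen_memory_trials(
        n, seed=trial_seed, ability_z=ability, missing_rate=config.missing_rate
    )
    table = pd.concat([table, trials], axis=1)

    tacs: list[tuple[Tac, Tac] | None] = []
    if config.make_tacs:
        for s in range(n):
            tac_seed = int(rng.integers(0, 2**31 - 1))
            tacs.append(gen_tacs(float(bp_true[s]), seed=tac_seed, noise_sd=0.02))
    else:
        tacs = [None] * n

    truth = TruthRecord(
        w_ant=w["w_ant"],
        w_post=w["w_post"],
        w_shared=w["w_shared"],
        mid_mix=mid_mix,
        couplings={k: dict(v) for k, v in config.couplings.items()},
        bp_true=bp_true,
        seed_masks=seed_masks,
        network_masks=network_masks,
        noise_sd=config.noise_sd,
        region_scales=region_scales,
        behavior_latents=behavior_latents,
    )
    return SyntheticCohort(
        config=config, seed=seed, series=series, table=table, tacs=tacs, truth=truth
    )
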