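"""Data-driven parcellation of a structure along its longitudinal axis.

Group spatial ICA on temporally concatenated, variance-normalised subject
time series restricted to a structure mask yields spatially independent
component maps.  Components are matched to expected axis positions
(anterior / middle / posterior) by their axis-center coordinate -- the y of
the peak-|weight| voxel -- and assembled into three disjoint bilateral ROIs
by thresholding each component map and resolving overlaps in favour of the
larger |weight|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA

__all__ = [
    "IcaComponent",
    "AxisRoiSet",
    "group_ica",
    "select_axis_components",
    "assemble_rois",
]

AXIS_LABELS = ("anterior", "middle", "posterior")


@dataclass
class IcaComponent:
    """One spatial ICA component restricted to the structure mask.

    ``map`` holds the unit-norm voxel weights at the mask's voxel indices;
    the sign convention flips each map so its peak weight is positive.
    ``axis_center`` is the axis (y) coordinate of the peak-|weight| voxel.
    """

    map: np.ndarray  # (n_mask_voxels,)
    mask_indices: np.ndarray  # flat voxel indices into the full grid
    shape: tuple[int, int, int]
    axis_center: float
    peak_voxel: tuple[int, int, int]
    hemisphere: str | None = None  # "left" | "right" | None (bilateral run)

    def __post_init__(self) -> None:
        nrm = np.linalg.norm(self.map)
        if abs(nrm - 1.0) > 1e-8:
            raise ValueError(f"IcaComponent map norm {nrm} != 1")

    def volume(self) -> np.ndarray:
        vol = np.zeros(int(np.prod(self.shape)))
        vol[self.mask_indices] = self.map
        return vol.reshape(self.shape)


@dataclass
class AxisRoiSet:
    """Anterior / middle / posterior ROI masks plus assembly provenance."""

    anterior: np.ndarray
    middle: np.ndarray
    posterior: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in AXIS_LABELS:
            if not self.mask(label).any():
                raise ValueError(f"AxisRoiSet: empty {label} mask")
        if np.any(
            self.anterior.astype(int) + self.middle.astype(int) + self.posterior.astype(int) > 1
        ):
            raise ValueError("AxisRoiSet: masks must be mutually disjoint")

    def mask(self, label: str) -> np.ndarray:
        return getattr(self, label)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {label: self.mask(label) for label in AXIS_LABELS}


def group_ica(
    timeseries: list[np.ndarray],
    mask: np.ndarray,
    k: int,
    seed: int | None = None,
    hemisphere: str | None = None,
    max_iter: int = 2000,
) -> list[IcaComponent]:
    """Temporal-concatenation group spatial ICA within a mask.

    Each subject's masked (T, V) series is variance-normalised (divided by
    its overall SD), series are concatenated over time, and fixed-point
    negentropy ICA with PCA whitening extracts ``k`` spatially independent
    maps (voxels are the samples).  Deterministic given ``seed``.
    """
    if len(timeseries) < 2:
        raise ValueError("group_ica: need >= 2 subjects")
    mask = np.asarray(mask, dtype=bool)
    flat_mask = mask.reshape(-1)
    n_mask = int(flat_mask.sum())
    if k > n_mask:
        raise ValueError(f"group_ica: k = {k} exceeds the {n_mask} masked voxels")

    blocks = []
    for i, ts in enumerate(timeseries):
        arr = np.asarray(ts, dtype=float)
        data = arr.reshape(-1, arr.shape[-1])
        if data.shape[0] != flat_mask.size:
            raise ValueError(f"group_ica: subject {i} series does not match the mask grid")
        sub = data[flat_mask].T  # (T, V)
        sub = sub - sub.mean(axis=0, keepdims=True)
        sd = sub.std()
        if sd > 0:
            sub = sub / sd
        blocks.append(sub)
    concat = np.vstack(blocks)  # (sum T, V)

    rank = np.linalg.matrix_rank(concat)
    if rank < k:
        raise ValueError(f"group_ica: concatenated matrix has rank {rank} < k = {k}")

    # spatial PCA whitening without voxel-mean removal: the per-voxel
    # temporal mean is already zero, and keeping the spatial mean intact
    # leaves signal-free voxels at exactly zero weight in the eigenmaps,
    # so thresholded maps separate cleanly even in the noiseless limit
    _, _, wt = np.linalg.svd(concat, full_matrices=False)
    z_white = wt[:k].T * np.sqrt(n_mask)  # (V, k), unit uncentered covariance

    ica = FastICA(
        whiten=False,
        fun="logcosh",
        max_iter=max_iter,
        random_state=np.random.default_rng(seed).integers(0, 2**31 - 1) if seed is not None else 0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on degenerate fixtures
        sources = ica.fit_transform(z_white)  # (V, k): spatial maps

    shape = tuple(mask.shape)
    idx = np.flatnonzero(flat_mask)
    comps = []
    for j in range(k):
        m = sources[:, j]
        peak = np.argmax(np.abs(m))
        if m[peak] < 0:  # peak-positive sign convention
            m = -m
        m = m / np.linalg.norm(m)
        peak_xyz = tuple(int(c) for c in np.unravel_index(idx[peak], shape))
        comps.append(
            IcaComponent(
                map=m,
                mask_indices=idx,
                shape=shape,
                axis_center=float(peak_xyz[1]),
                peak_voxel=peak_xyz,
                hemisphere=hemisphere,
            )
        )
    return comps


def select_axis_components(
    components: list[IcaComponent],
    expected_centers: dict[str, list[float]],
    tol: float = 1.5,
) -> dict[str, list[IcaComponent]]:
    """Match expected axis centers to the nearest components, per label.

    ``expected_centers`` maps "anterior" / "middle" / "posterior" to the
    axis coordinates at which components are expected.  When components
    carry hemisphere labels, a matched center must be present in both
    hemispheres (within ``tol`` of the expected coordinate); components
    found in only one hemisphere are excluded with a warning.  An empty
    component list yields an empty assignment.

    Raises
    ------
    ValueError
        When two expected centers claim the same component (ambiguity).
    """
    assignment: dict[str, list[IcaComponent]] = {label: [] for label in expected_centers}
    if not components:
        return assignment

    lateralised = any(c.hemisphere is not None for c in components)
    claimed: dict[int, tuple[str, float]] = {}
    for label, centers in expected_centers.items():
        for target in centers:
            if lateralised:
                near = {
                    hemi: [c for c in components if c.hemisphere == hemi
                           and abs(c.axis_center - target) <= tol]
                    for hemi in ("left", "right")
                }
                if not (near["left"] and near["right"]):
                    present = [h for h, lst in near.items() if lst]
                    if present:
                        warnings.warn(
                            f"component near axis center {target} present only in "
                            f"{present[0]} hemisphere; excluded from assignment",
                            stacklevel=2,
                        )
                    continue
                picks = [min(near[h], key=lambda c: abs(c.axis_center - target))
                         for h in ("left", "right")]
            else:
                picks = [min(components, key=lambda c: abs(c.axis_center - target))]
            for c in picks:
                key = id(c)
                if key in claimed and claimed[key] != (label, target):
                    other = claimed[key]
                    raise ValueError(
                        f"ambiguous assignment: component at axis center {c.axis_center} "
                        f"claimed by both {other} and {(label, target)}"
                    )
                claimed[key] = (label, target)
            assignment[label].extend(picks)
    return assignment


def assemble_rois(
    assignment: dict[str, list[IcaComponent]],
    threshold_sd: float = 2.0,
) -> AxisRoiSet:
    """Threshold and merge assigned components into three disjoint ROIs.

    Each component contributes the voxels where |weight| >= ``threshold_sd``
    standard deviations of its map (``threshold_sd = 0`` keeps every mask
    voxel); left/right components of a label are merged; a voxel claimed by
    several components goes to the one with the larger |weight| there.
    """
    for label in AXIS_LABELS:
        if not assignment.get(label):
            raise ValueError(f"assemble_rois: no components assigned to {label!r}")

    any_comp = assignment[AXIS_LABELS[0]][0]
    shape = any_comp.shape
    n_vox = int(np.prod(shape))
    best_w = np.zeros(n_vox)
    owner = np.full(n_vox, -1, dtype=int)

    for li, label in enumerate(AXIS_LABELS):
        for comp in assignment[label]:
            w = np.abs(comp.map)
            cut = threshold_sd * w.std()
            keep = w >= cut
            vox = comp.mask_indices[keep]
            ww = w[keep]
            better = ww > best_w[vox]
            best_w[vox[better]] = ww[better]
            owner[vox[better]] = li

    masks = {}
    for li, label in enumerate(AXIS_LABELS):
        m = np.zeros(n_vox, dtype=bool)
        m[owner == li] = True
        if not m.any():
            raise ValueError(f"assemble_rois: {label!r} mask empty after thresholding")
        masks[label] = m.reshape(shape)

    provenance = {
        "threshold_sd": threshold_sd,
        "n_components": {label: len(assignment[label]) for label in AXIS_LABELS},
        "axis_centers": {
            label: [c.axis_center for c in assignment[label]] for label in AXIS_LABELS
        },
        "center_rule": "nearest component center; peak-voxel y as axis center",
    }
    return AxisRoiSet(
        anterior=masks["anterior"],
        middle=masks["middle"],
        posterior=masks["posterior"],
        provenance=provenance,
    )
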