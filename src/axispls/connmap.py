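"""Seed-based connectivity maps, ROI signal-to-noise, and motion screening.

A seed map assigns to every voxel the Pearson correlation between that
voxel's time series and the mean time series of a seed region, Fisher
z-transformed (atanh).  Correlations of magnitude 1, which arise in
noiseless synthetic data, are clipped to 1 - 1e-7 before the transform so
the map stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SeedMap", "RoiSnr", "seed_map", "roi_snr", "fd_filter", "FdReport"]

R_CLIP = 1.0 - 1e-7


@dataclass
class SeedMap:
    """Fisher-z connectivity of every voxel with one seed region."""

    subject: str
    condition: str
    z: np.ndarray  # flat voxel vector, finite
    shape: tuple[int, ...] | None = None
    n_zero_variance: int = 0
    seed_constant: bool = False

    def volume(self) -> np.ndarray:
        if self.shape is None:
            raise ValueError("SeedMap has no grid shape attached")
        return self.z.reshape(self.shape)


@dataclass(frozen=True)
class RoiSnr:
    """Temporal SNR of an ROI-average signal: mean over time / SD over time."""

    subject: str
    roi: str
    snr: float
    flagged: bool = False  # True when the ROI-average signal is constant


def _as_vox_by_time(series: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    arr = np.asarray(series)
    if arr.ndim < 2:
        raise ValueError("series must be at least 2-D (voxels x time)")
    spatial = arr.shape[:-1]
    return arr.reshape(-1, arr.shape[-1]).astype(np.float64), spatial


def seed_map(
    series: np.ndarray, roi: np.ndarray, subject: str = "", condition: str = ""
) -> SeedMap:
    """Whole-volume Fisher-z correlation map for one seed region.

    Parameters
    ----------
    series : ndarray, (..., T)
        Voxel time series; any spatial shape, time last.
    roi : boolean ndarray matching the spatial shape
        Seed mask.  The seed signal is the unweighted mean over ROI voxels.

    Zero-variance voxels receive z = 0 and are counted in
    ``n_zero_variance`` rather than producing NaNs; a zero-variance seed
    yields an all-zero map flagged ``seed_constant``.
    """
    data, spatial = _as_vox_by_time(series)
    mask = np.asarray(roi, dtype=bool).reshape(-1)
    if mask.size != data.shape[0]:
        raise ValueError("roi mask does not match the series' spatial grid")
    if not mask.any():
        raise ValueError("seed_map: roi mask is empty")
    if data.shape[1] < 3:
        raise ValueError("seed_map: need at least 3 time points")

    seed = data[mask].mean(axis=0)
    seed_c = seed - seed.mean()
    seed_ss = float(seed_c @ seed_c)
    if seed_ss == 0.0:
        return SeedMap(subject, condition, np.zeros(data.shape[0]), spatial, 0, True)

    vox_c = data - data.mean(axis=1, keepdims=True)
    vox_ss = np.einsum("ij,ij->i", vox_c, vox_c)
    dead = vox_ss == 0.0
    denom = np.sqrt(vox_ss * seed_ss)
    denom[dead] = 1.0
    r = (vox_c @ seed_c) / denom
    r[dead] = 0.0
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z[dead] = 0.0
    return SeedMap(subject, condition, z, spatial, int(dead.sum()), False)


def roi_snr(series: np.ndarray, roi: np.ndarray, subject: str = "", label: str = "") -> RoiSnr:
    """Temporal SNR of the ROI-average signal (mean / SD over time).

    A constant ROI-average signal has an undefined SNR; such records are
    flagged so downstream analyses can exclude them with a warning.
    """
    data, _ = _as_vox_by_time(series)
    mask = np.asarray(roi, dtype=bool).reshape(-1)
    if not mask.any():
        raise ValueError("roi_snr: roi mask is empty")
    sig = data[mask].mean(axis=0)
    sd = float(sig.std(ddof=1))
    if sd == 0.0:
        return RoiSnr(subject, label, float("inf"), flagged=True)
    return RoiSnr(subject, label, float(sig.mean()) / sd, flagged=False)


@dataclass
class FdReport:
    """Motion-exclusion report from :func:`fd_filter`."""

    threshold: float
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def fd_filter(
    cohort: pd.DataFrame, threshold: float = 0.5, fd_column: str = "mean_fd"
) -> tuple[pd.DataFrame, FdReport]:
    """Drop subjects whose mean frame-wise displacement exceeds ``threshold`` mm.

    Missing FD values are an error: motion screening must not silently pass
    a subject whose motion is unknown.
    """
    if fd_column not in cohort.columns:
        raise ValueError(f"fd_filter: column {fd_column!r} not present in cohort table")
    fd = cohort[fd_column]
    if fd.isna().any():
        bad = cohort.loc[fd.isna()].index.tolist()
        raise ValueError(f"fd_filter: missing FD values for rows {bad}")
    excl = cohort[fd > threshold]
    keep = cohort[fd <= threshold].copy()
    cols = ["subject", fd_column] if "subject" in cohort.columns else [fd_column]
    return keep, FdReport(threshold=threshold, excluded=excl[cols].copy())
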