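"""Partial least squares of connectivity maps against conditions or behaviour.

Two variants of the same singular-value machinery:

* **Mean-centered (task) PLS** contrasts the condition-mean connectivity
  maps: the condition x voxel matrix of means is centred by its grand
  column mean and decomposed by SVD.  Each latent variable (LV) pairs a
  voxel salience pattern with a condition salience pattern; the singular
  value measures the covariance they capture.
* **Behavioural PLS** decomposes the stacked condition-wise correlation
  blocks R_c = Y_c' X_c between z-scored behaviour columns and z-scored
  voxel values, yielding LVs that pair voxel saliences with behaviour
  saliences per condition.

Inference is non-parametric: LV significance by permutation of the
exchangeable unit (condition labels within subject, or behaviour rows
across subjects within condition), and voxel reliability by bootstrap
resampling of subjects with bootstrap solutions aligned to the original
decomposition by orthogonal procrustes before aggregation.  The bootstrap
ratio (salience / bootstrap SE) is thresholded at 3.3, the two-tailed
standard-normal critical value at p = 0.001, when extracting clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.linalg import orthogonal_procrustes
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ConnStack",
    "PlsResult",
    "BootstrapResult",
    "mean_centered_pls",
    "behavioral_pls",
    "permutation_test",
    "bootstrap",
    "orient_result",
    "bsr_critical_value",
    "extract_clusters",
    "Cluster",
    "ClusterTable",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ConnStack:
    """(subject x condition) x voxel matrix of Fisher-z connectivity values.

    Rows may arrive in any order; they are validated to contain every
    subject under every condition exactly once.  ``shape`` and
    ``voxel_size`` (mm) carry the voxel-space metadata needed to map
    salience vectors back onto volumes.
    """

    X: np.ndarray
    conditions: np.ndarray
    subjects: np.ndarray
    shape: tuple[int, ...] | None = None
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.conditions = np.asarray(self.conditions)
        self.subjects = np.asarray(self.subjects)
        if self.X.ndim != 2:
            raise ValueError("ConnStack.X must be 2-D (rows x voxels)")
        if not (len(self.conditions) == len(self.subjects) == self.X.shape[0]):
            raise ValueError("ConnStack: row labels must match the number of rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("ConnStack.X contains non-finite entries")
        ref = None
        for c in self.cond_order:
            subs = frozenset(self.subjects[self.conditions == c])
            n_rows = int((self.conditions == c).sum())
            if n_rows != len(subs):
                raise ValueError(f"ConnStack: duplicate subject rows in condition {c!r}")
            if ref is None:
                ref = subs
            elif subs != ref:
                raise ValueError("ConnStack: conditions must share an identical subject set")

    @property
    def cond_order(self) -> list:
        seen: dict = {}
        for c in self.conditions:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def n_subjects(self) -> int:
        return len(set(self.subjects))

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def as_cube(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (C, S, V) array plus the subject order shared by all slabs."""
        conds = self.cond_order
        sub_order = np.array(sorted(set(self.subjects)))
        cube = np.empty((len(conds), len(sub_order), self.n_voxels))
        for ci, c in enumerate(conds):
            rows = self.conditions == c
            sub_idx = {s: i for i, s in enumerate(self.subjects[rows])}
            order = [sub_idx[s] for s in sub_order]
            cube[ci] = self.X[rows][order]
        return cube, sub_order

    def restrict(self, voxel_mask: np.ndarray) -> "ConnStack":
        """Restrict the stack to the voxels where ``voxel_mask`` is True.

        Typical use: drop the seed regions themselves, whose trivial
        self-correlation would otherwise dominate a condition contrast.
        The grid shape is dropped (the restricted stack no longer tiles a
        volume)."""
        m = np.asarray(voxel_mask, dtype=bool).reshape(-1)
        if m.size != self.n_voxels:
            raise ValueError("restrict: voxel_mask does not match the stack's voxel count")
        return ConnStack(
            X=self.X[:, m],
            conditions=self.conditions.copy(),
            subjects=self.subjects.copy(),
            shape=None,
            voxel_size=self.voxel_size,
        )

    @classmethod
    def from_seed_maps(cls, maps, voxel_size=(1.5, 1.5, 1.5)) -> "ConnStack":
        """Stack :class:`~axispls.connmap.SeedMap` objects into the X block."""
        if not maps:
            raise ValueError("from_seed_maps: no maps given")
        X = np.stack([m.z for m in maps])
        return cls(
            X=X,
            conditions=np.array([m.condition for m in maps]),
            subjects=np.array([m.subject for m in maps]),
            shape=maps[0].shape,
            voxel_size=voxel_size,
        )


@dataclass
class PlsResult:
    """One PLS decomposition: saliences, singular values, scores.

    ``saliences`` has unit-norm columns (one per LV); ``row_saliences`` are
    the condition (mean-centered) or condition-x-behaviour (behavioural)
    saliences.  ``brain_scores`` projects each row of the analysed X block
    onto the voxel saliences.  Optional inference fields are attached by
    :func:`permutation_test` and :func:`bootstrap`.
    """

    mode: str
    conditions: list
    behaviors: list | None
    singular_values: np.ndarray
    saliences: np.ndarray  # (V, L)
    row_saliences: np.ndarray  # (C or C*B, L)
    brain_scores: np.ndarray  # (n_rows, L), aligned with `score_conditions`
    score_conditions: np.ndarray
    score_subjects: np.ndarray
    pct_variance: np.ndarray
    corr_scores: np.ndarray | None = None  # behavioural: (C, B, L)
    perm_p: np.ndarray | None = None
    boot: "BootstrapResult | None" = None
    shape: tuple[int, ...] | None = None
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    @property
    def n_lv(self) -> int:
        return self.singular_values.size

    def salience_volume(self, lv: int) -> np.ndarray:
        if self.shape is None:
            raise ValueError("no grid shape attached to this result")
        return self.saliences[:, lv].reshape(self.shape)


@dataclass
class BootstrapResult:
    """Bootstrap SEs, bootstrap ratios, and 95% percentile CIs."""

    n_boot: int
    salience_se: np.ndarray  # (V, L)
    bsr: np.ndarray  # (V, L)
    cond_score_mean: np.ndarray | None = None  # (C, L) observed condition means
    cond_score_ci: np.ndarray | None = None  # (C, L, 2) percentile CI
    cond_score_draws: np.ndarray | None = None  # (n_boot, C, L) bootstrap draws
    corr_score_ci: np.ndarray | None = None  # (C, B, L, 2)
    n_redraws: int = 0

    def contrast_ci(self, weights, lv: int = 0, level: float = 0.95) -> tuple[float, float]:
        """Percentile CI for a linear contrast of condition-mean brain scores."""
        if self.cond_score_draws is None:
            raise ValueError("contrast_ci: no condition-mean draws (behavioural bootstrap?)")
        w = np.asarray(weights, dtype=float)
        dist = self.cond_score_draws[:, :, lv] @ w
        a = 100 * (1 - level) / 2
        return float(np.percentile(dist, a)), float(np.percentile(dist, 100 - a))

    def bsr_volume(self, lv: int, shape) -> np.ndarray:
        return self.bsr[:, lv].reshape(shape)


# ---------------------------------------------------------------------------
# decompositions


def _svd(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    return u, s, vt.T


def mean_centered_pls(stack: ConnStack) -> PlsResult:
    """Condition-contrast (mean-centered) PLS.

    Builds the condition x voxel matrix of means, removes the grand column
    mean across conditions, and decomposes by SVD.  Percent variance of LV
    i is s_i^2 / sum s^2; brain scores project the raw rows of X onto the
    voxel saliences.
    """
    conds = stack.cond_order
    if len(conds) < 2:
        raise ValueError("mean_centered_pls: need >= 2 conditions (contrast undefined)")
    counts = [int((stack.conditions == c).sum()) for c in conds]
    if min(counts) < 3:
        raise ValueError("mean_centered_pls: need >= 3 subjects per condition")
    cube, sub_order = stack.as_cube()
    M = cube.mean(axis=1)  # (C, V)
    Mc = M - M.mean(axis=0, keepdims=True)
    u, s, v = _svd(Mc)
    pct = 100.0 * s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)
    scores = stack.X @ v
    return PlsResult(
        mode="mean_centered",
        conditions=conds,
        behaviors=None,
        singular_values=s,
        saliences=v,
        row_saliences=u,
        brain_scores=scores,
        score_conditions=stack.conditions.copy(),
        score_subjects=stack.subjects.copy(),
        pct_variance=pct,
        shape=stack.shape,
        voxel_size=stack.voxel_size,
    )


def _zscore_cols(a: np.ndarray, what: str, names=None) -> np.ndarray:
    mu = a.mean(axis=0, keepdims=True)
    sd = a.std(axis=0, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        labels = [names[b] if names is not None else str(b) for b in bad]
        raise ValueError(f"constant column(s) {labels} in {what}")
    return (a - mu) / sd


def _behavioral_R(
    cube: np.ndarray, ycube: np.ndarray, conds, behaviors
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked correlation blocks R_c = Y_c' X_c and the z-scored X cube."""
    C, S, V = cube.shape
    B = ycube.shape[2]
    R = np.empty((C * B, V))
    xz = np.empty_like(cube)
    for ci, c in enumerate(conds):
        # voxels with zero variance get a zero column instead of an error:
        # background voxels in synthetic data can be exactly constant.
        mu = cube[ci].mean(axis=0)
        sd = cube[ci].std(axis=0, ddof=1)
        dead = sd == 0
        sd = np.where(dead, 1.0, sd)
        xz[ci] = (cube[ci] - mu) / sd
        xz[ci][:, dead] = 0.0
        yz = _zscore_cols(ycube[ci], f"behaviour block, condition {c!r}", behaviors)
        R[ci * B : (ci + 1) * B] = yz.T @ xz[ci] / (S - 1)
    return R, xz


def behavioral_pls(stack: ConnStack, Y: pd.DataFrame | np.ndarray) -> PlsResult:
    """Brain-behaviour PLS on condition-wise correlation blocks.

    ``Y`` must align row-for-row with ``stack.X`` (one row per subject and
    condition).  Within each condition the columns of X and Y are z-scored
    across subjects and the correlation blocks R_c = Y_c' X_c stacked and
    decomposed by SVD.  Correlation scores give, per condition, the Pearson
    correlation between each behaviour column and the LV brain scores.
    """
    if isinstance(Y, pd.DataFrame):
        behaviors = list(Y.columns)
        Yv = Y.to_numpy(dtype=float)
    else:
        Yv = np.asarray(Y, dtype=float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        behaviors = [f"b{i}" for i in range(Yv.shape[1])]
    if Yv.shape[0] != stack.X.shape[0]:
        raise ValueError("behavioral_pls: Y rows must align with the connectivity stack")
    if not np.all(np.isfinite(Yv)):
        raise ValueError("behavioral_pls: Y contains non-finite entries")
    if Yv.shape[1] < 2:
        logger.warning("behavioral_pls: single behaviour column; LVs reduce to one profile")

    conds = stack.cond_order
    cube, sub_order = stack.as_cube()
    C, S, V = cube.shape
    B = Yv.shape[1]
    ycube = np.empty((C, S, B))
    for ci, c in enumerate(conds):
        rows = stack.conditions == c
        sub_idx = {s: i for i, s in enumerate(stack.subjects[rows])}
        order = [sub_idx[s] for s in sub_order]
        ycube[ci] = Yv[rows][order]

    R, xz = _behavioral_R(cube, ycube, conds, behaviors)
    u, s, v = _svd(R)
    pct = 100.0 * s**2 / np.sum(s**2) if np.sum(s**2) > 0 else np.zeros_like(s)

    scores = np.einsum("csv,vl->csl", xz, v)  # (C, S, L)
    L = s.size
    corr = np.empty((C, B, L))
    for ci in range(C):
        for b in range(B):
            yb = ycube[ci, :, b]
            for l in range(L):
                corr[ci, b, l] = _pearson(yb, scores[ci, :, l])

    flat_scores = scores.reshape(C * S, L)
    score_conditions = np.repeat(conds, S)
    score_subjects = np.tile(sub_order, C)
    return PlsResult(
        mode="behavioral",
        conditions=conds,
        behaviors=behaviors,
        singular_values=s,
        saliences=v,
        row_saliences=u,
        brain_scores=flat_scores,
        score_conditions=score_conditions,
        score_subjects=score_subjects,
        pct_variance=pct,
        corr_scores=corr,
        shape=stack.shape,
        voxel_size=stack.voxel_size,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac, bc = a - a.mean(), b - b.mean()
    den = np.sqrt((ac @ ac) * (bc @ bc))
    return float(ac @ bc / den) if den > 0 else 0.0


def orient_result(result: PlsResult, row: int = 0) -> PlsResult:
    """Fix the SVD sign indeterminacy: flip each LV so row ``row`` of the
    condition/behaviour saliences is non-negative.

    With the anterior condition first, positive saliences then denote the
    anterior network, the convention used when classifying subjects.
    """
    flip = np.where(result.row_saliences[row] < 0, -1.0, 1.0)
    result.row_saliences = result.row_saliences * flip
    result.saliences = result.saliences * flip
    result.brain_scores = result.brain_scores * flip
    if result.corr_scores is not None:
        result.corr_scores = result.corr_scores * flip
    return result


# ---------------------------------------------------------------------------
# permutation inference


def permutation_test(
    mode: str,
    stack: ConnStack,
    Y: pd.DataFrame | np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    permuter=None,
) -> np.ndarray:
    """Permutation p-values for each LV's singular value.

    The exchangeable unit depends on the variant: mean-centered PLS
    permutes condition labels within subject (each subject's rows are
    shuffled across conditions); behavioural PLS permutes behaviour rows
    across subjects within each condition.  p_i = (1 + #{perm s_i >=
    observed s_i}) / (1 + n_perm), so p never reaches zero.

    ``permuter`` (testing hook): callable(rng, shape) returning the index
    permutation(s) to use instead of random draws.
    """
    if n_perm < 100:
        raise ValueError(f"permutation_test: n_perm = {n_perm} below the minimum of 100")
    rng = np.random.default_rng(seed)
    cube, sub_order = stack.as_cube()
    C, S, V = cube.shape
    conds = stack.cond_order

    if mode == "mean_centered":
        obs = mean_centered_pls(stack).singular_values
        count = np.zeros_like(obs)
        for _ in range(n_perm):
            if permuter is None:
                perm = np.argsort(rng.random((S, C)), axis=1)  # row-wise permutations
            else:
                perm = permuter(rng, (S, C))
            permuted = cube[perm.T, np.arange(S)[None, :], :]
            M = permuted.mean(axis=1)
            s = np.linalg.svd(M - M.mean(axis=0, keepdims=True), compute_uv=False)
            count += s >= obs - 1e-12
        return (1.0 + count) / (1.0 + n_perm)

    if mode == "behavioral":
        if Y is None:
            raise ValueError("permutation_test: behavioural mode requires Y")
        res = behavioral_pls(stack, Y)
        obs = res.singular_values
        behaviors = res.behaviors
        Yv = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, dtype=float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        ycube = np.empty((C, S, Yv.shape[1]))
        for ci, c in enumerate(conds):
            rows = stack.conditions == c
            sub_idx = {s_: i for i, s_ in enumerate(stack.subjects[rows])}
            order = [sub_idx[s_] for s_ in sub_order]
            ycube[ci] = Yv[rows][order]
        count = np.zeros_like(obs)
        for _ in range(n_perm):
            yp = np.empty_like(ycube)
            for ci in range(C):
                idx = permuter(rng, (S,)) if permuter is not None else rng.permutation(S)
                yp[ci] = ycube[ci][idx]
            R, _ = _behavioral_R(cube, yp, conds, behaviors)
            s = np.linalg.svd(R, compute_uv=False)
            count += s >= obs - 1e-12
        return (1.0 + count) / (1.0 + n_perm)

    raise ValueError(f"permutation_test: unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# bootstrap inference


def bootstrap(
    mode: str,
    stack: ConnStack,
    Y: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    reference: PlsResult | None = None,
    alignment: str = "sign",
) -> BootstrapResult:
    """Bootstrap resampling of subjects (rows preserved across conditions).

    Every draw resamples subjects with replacement, recomputes the
    decomposition, and aligns it to the reference solution before
    aggregating.  ``alignment="sign"`` (default) flips each bootstrap LV so
    its condition/behaviour salience agrees in sign with the reference --
    this removes the SVD's sign indeterminacy while retaining genuine
    between-LV rotation variability, which keeps the percentile CIs
    honestly wide.  ``alignment="procrustes"`` additionally rotates the
    whole bootstrap basis onto the reference (useful when singular values
    are nearly degenerate and axis mixing would otherwise corrupt salience
    SEs, at the cost of absorbing real rotation variability).

    Returns per-voxel salience SEs, bootstrap ratios, and 95% percentile
    CIs for condition-mean brain scores (mean-centered) or
    behaviour-connectivity correlations (behavioural).  Draws with fewer
    than 3 distinct subjects per condition are redrawn and counted.
    """
    if alignment not in ("sign", "procrustes"):
        raise ValueError(f"bootstrap: unknown alignment {alignment!r}")
    if n_boot < 100:
        raise ValueError(f"bootstrap: n_boot = {n_boot} below the minimum of 100")
    rng = np.random.default_rng(seed)
    cube, sub_order = stack.as_cube()
    C, S, V = cube.shape
    conds = stack.cond_order

    if mode == "mean_centered":
        ref = reference if reference is not None else mean_centered_pls(stack)
    elif mode == "behavioral":
        if Y is None:
            raise ValueError("bootstrap: behavioural mode requires Y")
        ref = reference if reference is not None else behavioral_pls(stack, Y)
    else:
        raise ValueError(f"bootstrap: unknown mode {mode!r}")

    L = ref.n_lv
    behaviors = ref.behaviors
    B = len(behaviors) if behaviors else 0
    ycube = None
    if mode == "behavioral":
        Yv = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, dtype=float)
        if Yv.ndim == 1:
            Yv = Yv[:, None]
        ycube = np.empty((C, S, B))
        for ci, c in enumerate(conds):
            rows = stack.conditions == c
            sub_idx = {s_: i for i, s_ in enumerate(stack.subjects[rows])}
            order = [sub_idx[s_] for s_ in sub_order]
            ycube[ci] = Yv[rows][order]

    v_boot = np.empty((n_boot, V, L))
    cond_means = np.empty((n_boot, C, L)) if mode == "mean_centered" else None
    corr_boot = np.empty((n_boot, C, B, L)) if mode == "behavioral" else None
    n_redraws = 0

    for b in range(n_boot):
        while True:
            idx = rng.integers(0, S, S)
            if np.unique(idx).size >= 3:
                break
            n_redraws += 1
        sub = cube[:, idx, :]
        if mode == "mean_centered":
            M = sub.mean(axis=1)
            u_b, s_b, v_b = _svd(M - M.mean(axis=0, keepdims=True))
        else:
            ysub = ycube[:, idx, :]
            try:
                R, xz_b = _behavioral_R(sub, ysub, conds, behaviors)
            except ValueError:
                # behaviour column constant in the draw: redraw
                n_redraws += 1
                idx = rng.integers(0, S, S)
                ysub = ycube[:, idx, :]
                sub = cube[:, idx, :]
                R, xz_b = _behavioral_R(sub, ysub, conds, behaviors)
            u_b, s_b, v_b = _svd(R)
        if alignment == "procrustes":
            rot, _ = orthogonal_procrustes(u_b[:, :L], ref.row_saliences[:, :L])
            v_al = v_b[:, :L] @ rot
        else:
            flips = np.sum(u_b[:, :L] * ref.row_saliences[:, :L], axis=0)
            flips = np.where(flips < 0, -1.0, 1.0)
            v_al = v_b[:, :L] * flips
        v_boot[b] = v_al
        if mode == "mean_centered":
            cond_means[b] = np.einsum("csv,vl->cl", sub, v_al) / S
        else:
            sc = np.einsum("csv,vl->csl", xz_b, v_al)
            for ci in range(C):
                for bi in range(B):
                    for l in range(L):
                        corr_boot[b, ci, bi, l] = _pearson(ysub[ci, :, bi], sc[ci, :, l])

    se = v_boot.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, ref.saliences[:, :L] / se, np.sign(ref.saliences[:, :L]) * np.inf)
    bsr = np.where(np.isnan(bsr), 0.0, bsr)

    result = BootstrapResult(n_boot=n_boot, salience_se=se, bsr=bsr, n_redraws=n_redraws)
    if mode == "mean_centered":
        obs = np.empty((C, L))
        for ci, c in enumerate(conds):
            obs[ci] = ref.brain_scores[ref.score_conditions == c, :L].mean(axis=0)
        result.cond_score_mean = obs
        result.cond_score_draws = cond_means
        result.cond_score_ci = np.stack(
            [np.percentile(cond_means, 2.5, axis=0), np.percentile(cond_means, 97.5, axis=0)],
            axis=-1,
        )
    else:
        result.corr_score_ci = np.stack(
            [np.percentile(corr_boot, 2.5, axis=0), np.percentile(corr_boot, 97.5, axis=0)],
            axis=-1,
        )
    ref.boot = result
    return result


# ---------------------------------------------------------------------------
# cluster extraction


def bsr_critical_value(p: float = 0.001) -> float:
    """Two-tailed standard-normal critical value for a bootstrap-ratio cutoff."""
    return float(norm.isf(p / 2.0))


@dataclass
class Cluster:
    """One reliable cluster: its peak, voxel extent, and any sub-peaks."""

    peak: tuple[int, int, int]
    size: int
    peak_bsr: float
    sign: int
    sub_peaks: list = field(default_factory=list)  # [(xyz, bsr), ...]


@dataclass
class ClusterTable:
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        """Rows like a results table: peak rows carry the cluster size,
        sub-peak rows leave it blank."""
        rows = []
        for i, cl in enumerate(self.clusters):
            rows.append(
                {"cluster": i, "x": cl.peak[0], "y": cl.peak[1], "z": cl.peak[2],
                 "size": cl.size, "bsr": cl.peak_bsr}
            )
            for xyz, bsr in cl.sub_peaks:
                rows.append(
                    {"cluster": i, "x": xyz[0], "y": xyz[1], "z": xyz[2],
                     "size": np.nan, "bsr": bsr}
                )
        return pd.DataFrame(rows, columns=["cluster", "x", "y", "z", "size", "bsr"])


def _local_maxima(vol: np.ndarray, mask: np.ndarray) -> list[tuple[int, int, int]]:
    """Voxels >= all 26-neighbours within the mask."""
    out = []
    coords = np.argwhere(mask)
    for x, y, z in coords:
        v = vol[x, y, z]
        nb = vol[
            max(x - 1, 0) : x + 2, max(y - 1, 0) : y + 2, max(z - 1, 0) : z + 2
        ]
        nbm = mask[
            max(x - 1, 0) : x + 2, max(y - 1, 0) : y + 2, max(z - 1, 0) : z + 2
        ]
        if v >= nb[nbm].max():
            out.append((int(x), int(y), int(z)))
    return out


def extract_clusters(
    bsr_map: np.ndarray,
    threshold: float = 3.3,
    min_size: int = 10,
    min_peak_sep: float = 10.0,
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5),
) -> ClusterTable:
    """Threshold a BSR volume and tabulate reliable clusters.

    Suprathreshold voxels (|BSR| >= ``threshold``, positive and negative
    tails handled separately so oppositely-signed networks never merge) are
    grouped by 26-connectivity; components smaller than ``min_size`` are
    dropped.  Peaks closer than ``min_peak_sep`` mm to a stronger peak are
    reported as sub-peaks of the stronger cluster rather than separate
    rows; additional local maxima inside a cluster, at least
    ``min_peak_sep`` from every stronger listed peak, are reported as
    sub-peaks as well.
    """
    bsr_map = np.asarray(bsr_map, dtype=float)
    if bsr_map.ndim != 3:
        raise ValueError("extract_clusters: bsr_map must be a 3-D volume")
    if not np.all(np.isfinite(bsr_map)):
        raise ValueError("extract_clusters: bsr_map must be finite")
    vs = np.asarray(voxel_size, dtype=float)
    structure = np.ones((3, 3, 3), dtype=bool)
    absmap = np.abs(bsr_map)

    candidates = []  # (peak_abs_bsr, peak_xyz, sign, voxel_coords)
    for sign in (1, -1):
        mask = (bsr_map >= threshold) if sign == 1 else (bsr_map <= -threshold)
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            comp = labels == lab
            size = int(comp.sum())
            if size < min_size:
                continue
            flat_peak = np.argmax(np.where(comp, absmap, -np.inf))
            peak = tuple(int(i) for i in np.unravel_index(flat_peak, bsr_map.shape))
            candidates.append((absmap[peak], peak, sign, comp))

    candidates.sort(key=lambda t: -t[0])
    clusters: list[Cluster] = []
    for peak_val, peak, sign, comp in candidates:
        merged = False
        for cl in clusters:
            if cl.sign != sign:
                continue
            dist = np.linalg.norm((np.array(peak) - np.array(cl.peak)) * vs)
            if dist < min_peak_sep:
                cl.size += int(comp.sum())
                cl.sub_peaks.append((peak, float(sign * peak_val)))
                merged = True
                break
        if not merged:
            clusters.append(
                Cluster(peak=peak, size=int(comp.sum()),
                        peak_bsr=float(sign * peak_val), sign=sign)
            )
            # secondary maxima inside this component
            maxima = _local_maxima(absmap, comp)
            maxima.sort(key=lambda c: -absmap[c])
            accepted = [np.array(peak)]
            for m in maxima:
                mv = np.array(m)
                if all(np.linalg.norm((mv - a) * vs) >= min_peak_sep for a in accepted):
                    accepted.append(mv)
                    clusters[-1].sub_peaks.append((m, float(sign * absmap[m])))
    return ClusterTable(clusters)
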