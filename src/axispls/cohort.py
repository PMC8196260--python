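"""Cohort-level scoring and inference.

Memory composite construction, mean imputation, intracranial-volume
covariance adjustment, nuisance residualisation, multivariate tests,
correlation tables, the sign-based axis-group classification, and one-tailed
group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "TASK_MAXIMA",
    "composite_memory",
    "impute_missing",
    "icv_adjust",
    "residualize",
    "manova_predict",
    "correlation_table",
    "classify_axis_groups",
    "group_compare",
    "GROUP_LABELS",
]

#: maximum attainable sum score per task (items x trials)
TASK_MAXIMA = {"word": 32, "numword": 16, "objloc": 24}

GROUP_LABELS = (
    "division-mid-anterior",
    "division-mid-posterior",
    "all-anterior",
    "all-posterior",
    "excluded",
)


# ---------------------------------------------------------------------------
# memory composite


def task_sums(trials: pd.DataFrame, tasks=None) -> pd.DataFrame:
    """Sum trial columns (``<task>_t<j>``) into one column per task."""
    tasks = list(TASK_MAXIMA) if tasks is None else list(tasks)
    out = {}
    for task in tasks:
        cols = [c for c in trials.columns if c.startswith(f"{task}_t")]
        if not cols:
            raise ValueError(f"task_sums: no trial columns for task {task!r}")
        out[task] = trials[cols].sum(axis=1)
    return pd.DataFrame(out)


def composite_memory(trials: pd.DataFrame, tasks=None) -> pd.Series:
    """Composite episodic-memory score in T units (sample mean 50, SD 10).

    Trials are summed per task, each task sum z-standardised across
    subjects, the z-scores averaged, and the average linearly rescaled to
    sample mean 50 and SD 10.  Standardisation uses the sample (ddof = 1)
    SD, so the output's sample mean and SD are exactly 50 and 10.
    """
    sums = task_sums(trials, tasks)
    if len(sums) < 3:
        raise ValueError("composite_memory: need at least 3 subjects")
    if sums.isna().any().any():
        raise ValueError("composite_memory: missing trial scores; impute first")
    z = pd.DataFrame(index=sums.index)
    for task in sums.columns:
        sd = sums[task].std(ddof=1)
        if sd == 0:
            raise ValueError(f"composite_memory: task {task!r} has zero variance")
        z[task] = (sums[task] - sums[task].mean()) / sd
    avg = z.mean(axis=1)
    sd = avg.std(ddof=1)
    if sd == 0:
        raise ValueError("composite_memory: averaged z-scores have zero variance")
    return 50.0 + 10.0 * (avg - avg.mean()) / sd


def impute_missing(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing trial scores by the across-subject mean of observed values.

    Returns the completed table and an imputation log with the count and
    fraction imputed per variable.  A variable with no observed values at
    all is an error.
    """
    out = trials.copy()
    log_rows = []
    for col in trials.columns:
        n_missing = int(trials[col].isna().sum())
        if n_missing == len(trials):
            raise ValueError(f"impute_missing: column {col!r} is entirely missing")
        if n_missing:
            out[col] = trials[col].fillna(trials[col].mean())
        log_rows.append(
            {"variable": col, "n_missing": n_missing, "fraction": n_missing / len(trials)}
        )
    return out, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# volume and nuisance adjustment


def icv_adjust(raw_volume: np.ndarray, icv: np.ndarray) -> np.ndarray:
    """Covariance-adjust a regional volume for intracranial volume.

    adjusted = raw - b * (ICV - mean ICV), with b the least-squares slope
    of volume on ICV.  The adjusted volumes keep the raw sample mean and
    have exactly zero sample correlation with ICV.
    """
    raw = np.asarray(raw_volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if raw.shape != icv.shape or raw.ndim != 1:
        raise ValueError("icv_adjust: raw_volume and icv must be aligned 1-D vectors")
    if raw.size < 3:
        raise ValueError("icv_adjust: need at least 3 subjects")
    icv_c = icv - icv.mean()
    denom = float(icv_c @ icv_c)
    if denom == 0.0:
        raise ValueError("icv_adjust: ICV has zero variance")
    b = float(icv_c @ (raw - raw.mean())) / denom
    return raw - b * icv_c


def residualize(values: np.ndarray, nuisance: np.ndarray | pd.DataFrame) -> np.ndarray:
    """OLS residuals of ``values`` on [intercept, nuisance], mean re-added.

    The output is exactly uncorrelated with every nuisance column while
    keeping the original mean (so residualised brain scores stay on their
    native scale).
    """
    v = np.asarray(values, dtype=float)
    if isinstance(nuisance, pd.DataFrame):
        names = list(nuisance.columns)
        N = nuisance.to_numpy(dtype=float)
    else:
        N = np.asarray(nuisance, dtype=float)
        if N.ndim == 1:
            N = N[:, None]
        names = [f"n{i}" for i in range(N.shape[1])]
    if N.shape[0] != v.shape[0]:
        raise ValueError("residualize: values and nuisance must have aligned rows")
    design = np.column_stack([np.ones(len(v)), N])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"residualize: nuisance design rank-deficient (rank {rank} < {design.shape[1]}); "
            f"columns: {names}"
        )
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    resid = v - design @ beta
    return resid + v.mean()


# ---------------------------------------------------------------------------
# multivariate and correlation tests


@dataclass
class ManovaResult:
    """Wilks' lambda for a predictor block plus per-dependent univariate tests."""

    wilks: float
    F: float
    df_num: float
    df_den: float
    p: float
    per_dependent: pd.DataFrame
    bonferroni_alpha: float


def manova_predict(
    data: pd.DataFrame,
    dependents: list[str],
    predictors: list[str],
    covariates: list[str] | None = None,
    bonferroni_alpha: float = 0.01,
) -> ManovaResult:
    """Multivariate test of a predictor block on several dependents.

    Fits ``dependents ~ intercept + predictors + covariates`` and reports
    Wilks' lambda (with F approximation) for the joint predictor block,
    alongside per-dependent block F tests (full vs covariates-only model)
    and coefficients.  The Bonferroni-adjusted significance level used when
    flagging per-dependent results is reported back.
    """
    covariates = covariates or []
    cols = dependents + predictors + covariates
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"manova_predict: columns not in table: {missing}")
    n = len(data)
    if n <= len(predictors) + len(covariates) + 2:
        raise ValueError("manova_predict: too few subjects for the design")

    Yv = data[dependents].to_numpy(dtype=float)
    Xfull = np.column_stack(
        [np.ones(n)] + [data[c].to_numpy(dtype=float) for c in predictors + covariates]
    )
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise ValueError("manova_predict: singular design matrix")

    Xred = np.column_stack([np.ones(n)] + [data[c].to_numpy(dtype=float) for c in covariates])
    if len(dependents) > 1:
        mv = MANOVA(Yv, Xfull)
        # contrast selecting the predictor coefficient rows (after intercept)
        L = np.zeros((len(predictors), Xfull.shape[1]))
        for i in range(len(predictors)):
            L[i, 1 + i] = 1.0
        res = mv.mv_test(hypotheses=[("predictors", L, None)])
        tbl = res.results["predictors"]["stat"]
        wilks_row = tbl.loc["Wilks' lambda"]
        wilks = float(wilks_row["Value"])
        F_mv = float(wilks_row["F Value"])
        df_num = float(wilks_row["Num DF"])
        df_den = float(wilks_row["Den DF"])
        p_mv = float(wilks_row["Pr > F"])
    else:
        # with one dependent Wilks' lambda reduces to the RSS ratio and the
        # F approximation is exact (the univariate ANCOVA block F)
        y = Yv[:, 0]
        beta_f, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
        rss_f = float(np.sum((y - Xfull @ beta_f) ** 2))
        beta_r, *_ = np.linalg.lstsq(Xred, y, rcond=None)
        rss_r = float(np.sum((y - Xred @ beta_r) ** 2))
        wilks = rss_f / rss_r if rss_r > 0 else np.nan
        df_num = float(len(predictors))
        df_den = float(n - Xfull.shape[1])
        F_mv = ((rss_r - rss_f) / df_num) / (rss_f / df_den) if rss_f > 0 else np.inf
        p_mv = float(stats.f.sf(F_mv, df_num, df_den))

    # per-dependent block F: full model vs covariates-only
    rows = []
    p_full = Xfull.shape[1]
    for j, dep in enumerate(dependents):
        y = Yv[:, j]
        beta_f, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
        rss_f = float(np.sum((y - Xfull @ beta_f) ** 2))
        beta_r, *_ = np.linalg.lstsq(Xred, y, rcond=None)
        rss_r = float(np.sum((y - Xred @ beta_r) ** 2))
        df1 = len(predictors)
        df2 = n - p_full
        F = ((rss_r - rss_f) / df1) / (rss_f / df2) if rss_f > 0 else np.inf
        p = float(stats.f.sf(F, df1, df2))
        rows.append(
            {
                "dependent": dep,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": p,
                "significant_bonferroni": p < bonferroni_alpha,
                **{f"coef_{pred}": beta_f[1 + i] for i, pred in enumerate(predictors)},
            }
        )
    return ManovaResult(
        wilks=wilks,
        F=F_mv,
        df_num=df_num,
        df_den=df_den,
        p=p_mv,
        per_dependent=pd.DataFrame(rows),
        bonferroni_alpha=bonferroni_alpha,
    )


def correlation_table(
    x: pd.DataFrame, y: pd.DataFrame, alpha: float = 0.05, alpha_adjusted: float = 0.01
) -> pd.DataFrame:
    """Pearson r and two-sided p for every (x, y) column pair.

    Flags significance at the raw level and at the adjusted (Bonferroni)
    level.  Constant columns make the correlation undefined; such pairs are
    skipped with a warning.
    """
    if len(x) != len(y):
        raise ValueError("correlation_table: x and y must have aligned rows")
    if len(x) < 4:
        raise ValueError("correlation_table: need at least 4 subjects")
    rows = []
    for cx in x.columns:
        for cy in y.columns:
            a = x[cx].to_numpy(dtype=float)
            b = y[cy].to_numpy(dtype=float)
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"correlation_table: constant column in pair ({cx!r}, {cy!r}); skipped",
                    stacklevel=2,
                )
                continue
            r, p = stats.pearsonr(a, b)
            rows.append(
                {
                    "x": cx,
                    "y": cy,
                    "r": float(r),
                    "p": float(p),
                    "significant": p < alpha,
                    "significant_adjusted": p < alpha_adjusted,
                }
            )
    return pd.DataFrame(rows, columns=["x", "y", "r", "p", "significant", "significant_adjusted"])


# ---------------------------------------------------------------------------
# axis-group classification and comparison


def classify_axis_groups(
    scores: pd.DataFrame,
    anterior_positive: bool = True,
    zero_tol: float | None = None,
) -> pd.Series:
    """Classify subjects by the sign pattern of their aHC/mHC/pHC brain scores.

    With the convention that a positive score denotes adherence to the
    anterior network:

    * aHC and pHC oppositely signed (the axis division): middle region's
      sign decides "division-mid-anterior" vs "division-mid-posterior";
    * all three positive: "all-anterior"; all three negative: "all-posterior";
    * aHC and pHC same-signed with mHC opposite: "excluded".

    A score of exactly zero is an error unless ``zero_tol`` is given, in
    which case |score| <= zero_tol is nudged to the sign of the region's
    mean.
    """
    needed = ["aHC", "mHC", "pHC"]
    missing = [c for c in needed if c not in scores.columns]
    if missing:
        raise ValueError(f"classify_axis_groups: missing score columns {missing}")
    vals = scores[needed].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("classify_axis_groups: missing or non-finite brain scores")
    if not anterior_positive:
        vals = -vals
    if zero_tol is not None:
        col_sign = np.sign(vals.mean(axis=0))
        col_sign[col_sign == 0] = 1.0
        small = np.abs(vals) <= zero_tol
        vals = np.where(small, col_sign[None, :] * max(zero_tol, 1e-300), vals)
    if np.any(vals == 0):
        raise ValueError(
            "classify_axis_groups: zero brain score encountered; set zero_tol to break ties"
        )

    labels = []
    for a, m, p in np.sign(vals):
        if a > 0 and m > 0 and p > 0:
            labels.append("all-anterior")
        elif a < 0 and m < 0 and p < 0:
            labels.append("all-posterior")
        elif a * p < 0:  # axis division
            labels.append("division-mid-anterior" if m > 0 else "division-mid-posterior")
        else:  # aHC, pHC same-signed, mHC opposite
            labels.append("excluded")
    return pd.Series(labels, index=scores.index, name="axis_group")


def group_compare(
    a: np.ndarray, b: np.ndarray, direction: str = "greater"
) -> tuple[float, float]:
    """Pooled-variance two-sample t test with a one-tailed p.

    ``direction`` states the alternative for the mean of ``a`` relative to
    ``b`` ("greater" or "less").  Identical groups give t = 0, p = 0.5.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("group_compare: both groups need at least 2 observations")
    if direction not in ("greater", "less"):
        raise ValueError(f"group_compare: unknown direction {direction!r}")
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative=direction)
    return float(t), float(p)
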