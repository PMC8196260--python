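"""Logan graphical reference-tissue analysis for dynamic PET.

Converts a pair of regional time--activity curves (TAC) -- a receptor-rich
target region and a reference region devoid of specific binding (cerebellar
grey matter for [11C]-raclopride) -- into a non-displaceable binding
potential (BPnd).  The Logan reference plot regresses the normalised
cumulative target activity on the normalised cumulative reference activity;
after the tracer reaches pseudo-equilibrium the plot becomes linear and its
slope estimates the distribution volume ratio DVR, with BPnd = DVR - 1.

This is the simplified reference Logan formulation without the k2' efflux
correction term: for tracers and regions where the reference-region efflux
is fast relative to the linear window, the omitted term is absorbed by the
intercept.  The simplification is a documented limitation, not an accident.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = ["Tac", "LoganFit", "cum_integral", "logan_reference_fit", "bilateral_bp"]


@dataclass(frozen=True)
class Tac:
    """A regional time--activity curve.

    Parameters
    ----------
    frame_start, frame_end : array-like, minutes
        Start and end of each acquisition frame.  Frames must be
        non-overlapping and strictly increasing.
    activity : array-like
        Mean activity concentration per frame (kBq/mL or any consistent
        arbitrary unit).  Must be non-negative.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        for name in ("frame_start", "frame_end", "activity"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.frame_start.shape == self.frame_end.shape == self.activity.shape):
            raise ValueError("Tac: frame_start, frame_end and activity must have equal length")
        if self.frame_start.ndim != 1:
            raise ValueError("Tac: frame arrays must be one-dimensional")
        if np.any(self.frame_end <= self.frame_start):
            raise ValueError("Tac: each frame_end must exceed its frame_start")
        if np.any(np.diff(self.frame_start) <= 0) or np.any(self.frame_start[1:] < self.frame_end[:-1] - 1e-9):
            raise ValueError("Tac: frames must be strictly increasing and non-overlapping")
        if np.any(self.activity < 0):
            raise ValueError("Tac: activities must be non-negative")

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times in minutes."""
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def duration(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    def __len__(self) -> int:
        return self.activity.size

    def scaled(self, c: float) -> "Tac":
        """Return a copy with activities multiplied by ``c`` (unit change)."""
        return Tac(self.frame_start, self.frame_end, self.activity * c)


@dataclass(frozen=True)
class LoganFit:
    """Result of a Logan reference-tissue fit.

    ``slope`` is the distribution volume ratio (DVR); ``bp`` = DVR - 1 is
    the non-displaceable binding potential.  ``intercept`` carries units of
    minutes.  ``n_used`` counts the frames entering the regression
    (mid-time >= ``t_star``, non-zero target activity).
    """

    t_star: float
    slope: float
    intercept: float
    bp: float
    r_squared: float
    n_used: int


def cum_integral(tac: Tac) -> np.ndarray:
    """Cumulative trapezoidal integral of a TAC, evaluated at frame mid-times.

    The first segment is integrated from t = 0 with zero activity assumed at
    injection, so the integral through the first mid-time is
    ``0.5 * activity[0] * mid[0]``.  Exact for activities that are linear in
    time through the origin.
    """
    if len(tac) < 2:
        raise ValueError("cum_integral: need at least 2 frames")
    t = np.concatenate([[0.0], tac.mid])
    a = np.concatenate([[0.0], tac.activity])
    return cumulative_trapezoid(a, t)


def logan_reference_fit(target: Tac, reference: Tac, t_star: float = 20.0) -> LoganFit:
    """Fit the Logan reference plot and return DVR / BPnd.

    Ordinary least squares of

        y(t) = int_0^t C_target / C_target(t)   on
        x(t) = int_0^t C_ref    / C_target(t)

    restricted to frames with mid-time >= ``t_star``.  The slope is the DVR
    and BPnd = DVR - 1.  Frames where the target activity is zero are
    dropped with a warning (the normalisation is undefined there).

    Raises
    ------
    ValueError
        If the frame schedules differ, or fewer than 3 usable frames remain
        after the ``t_star`` cut.
    """
    if len(target) != len(reference) or not (
        np.allclose(target.frame_start, reference.frame_start)
        and np.allclose(target.frame_end, reference.frame_end)
    ):
        raise ValueError("logan_reference_fit: target and reference frame schedules must be aligned")

    mid = target.mid
    int_t = cum_integral(target)
    int_r = cum_integral(reference)

    use = mid >= t_star
    zero = use & (target.activity == 0)
    if np.any(zero):
        warnings.warn(
            f"logan_reference_fit: dropping {int(zero.sum())} frame(s) with zero target activity",
            stacklevel=2,
        )
        use &= ~zero
    n = int(use.sum())
    if n < 3:
        raise ValueError(f"logan_reference_fit: only {n} usable frames at t_star={t_star}; need >= 3")

    y = int_t[use] / target.activity[use]
    x = int_r[use] / target.activity[use]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return LoganFit(
        t_star=float(t_star),
        slope=float(slope),
        intercept=float(intercept),
        bp=float(slope - 1.0),
        r_squared=r2,
        n_used=n,
    )


def bilateral_bp(left: LoganFit, right: LoganFit) -> float:
    """Average left/right BPnd into one bilateral receptor-availability value."""
    for side, fit in (("left", left), ("right", right)):
        if not isinstance(fit, LoganFit):
            raise ValueError(f"bilateral_bp: {side} argument is not a LoganFit")
        if not np.isfinite(fit.bp):
            raise ValueError(f"bilateral_bp: {side} fit has non-finite BPnd")
    return 0.5 * (left.bp + right.bp)
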