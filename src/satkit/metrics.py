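"""Learning curves and the first-derivative cutoff point.

Performance at time t is ln(cumulative hits - 10 * cumulative life losses),
evaluated on a uniform grid (default 1 s).  The logarithm is undefined while
the argument is non-positive — routine early in a session, when ten times
the losses outweighs the hits — and such grid points are flagged as NaN
rather than imputed.

Training quality is summarised by the first-derivative cutoff point of the
smoothed curve: the first grid point after the slope maximum where the slope
has fallen to a set fraction (default one half) of that maximum.  Its x is
the *time to criterion*, its y the *performance at criterion*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ._exceptions import (
    InsufficientDataError,
    NoKneeError,
    ValidationError,
    ValidationWarning,
)
from .io import EventLog

#: minimum number of defined curve points find_cutoff requires
MIN_DEFINED_POINTS = 10

#: weight of a life loss relative to a hit in the performance score
LOSS_WEIGHT = 10.0


@dataclass
class LearningCurve:
    """Performance score on a uniform time grid; NaN marks undefined points."""

    t: np.ndarray
    score: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if self.t.shape != self.score.shape:
            raise ValidationError("t and score must have the same shape")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValidationError("t must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.score)


@dataclass(frozen=True)
class CutoffPoint:
    """Knee of a learning curve: (time to criterion, performance at criterion)."""

    time_to_criterion: float
    performance_at_criterion: float


def performance_score(cum_hits: int, cum_losses: int) -> float:
    """ln(cum_hits - 10*cum_losses); NaN when the argument is non-positive."""
    h, l = int(cum_hits), int(cum_losses)
    if h < 0 or l < 0:
        raise ValidationError("counts must be non-negative")
    arg = h - LOSS_WEIGHT * l
    return math.log(arg) if arg > 0 else float("nan")


def build_curve(
    events: EventLog,
    grid_seconds: float = 1.0,
    t_max: float | None = None,
) -> LearningCurve:
    """Cumulative-count learning curve on a uniform grid.

    At each grid point the score is ``performance_score`` of the events with
    time <= that point.  ``t_max`` extends (or truncates) the grid; it
    defaults to the last event time.
    """
    if grid_seconds <= 0:
        raise ValidationError("grid_seconds must be positive")
    if len(events) == 0 and t_max is None:
        warnings.warn("empty event log: all-undefined curve", ValidationWarning, stacklevel=2)
        return LearningCurve(np.array([0.0]), np.array([np.nan]))
    end = float(t_max) if t_max is not None else float(events.t[-1])
    grid = np.arange(0.0, end + 0.5 * grid_seconds, grid_seconds)
    hits = np.searchsorted(events.times_of("hit"), grid, side="right")
    losses = np.searchsorted(events.times_of("life_loss"), grid, side="right")
    arg = hits - LOSS_WEIGHT * losses
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)), np.nan)
    if not np.any(np.isfinite(score)):
        warnings.warn("learning curve undefined everywhere", ValidationWarning, stacklevel=2)
    return LearningCurve(grid, score)


def _longest_defined_run(defined: np.ndarray) -> tuple[int, int]:
    """(start, stop) of the longest contiguous True run; earliest on ties."""
    best = (0, 0)
    i = 0
    n = defined.size
    while i < n:
        if defined[i]:
            j = i
            while j < n and defined[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def find_cutoff(
    curve: LearningCurve,
    slope_fraction: float = 0.5,
    smoother_bandwidth: float = 15.0,
) -> CutoffPoint:
    """Locate the first-derivative cutoff point of a learning curve.

    The longest contiguous defined stretch of the curve is smoothed
    (Savitzky-Golay, quadratic, window ``smoother_bandwidth`` seconds — a
    plain centred moving average damps the slope at the edges of the defined
    region, where learning curves are steepest, and biases the cutoff late);
    the first derivative is taken by central finite differences; the cutoff
    is the first grid point after the slope maximum where the slope is at or
    below ``slope_fraction`` times the maximum.

    Raises
    ------
    ValidationError
        If the curve is undefined everywhere.
    InsufficientDataError
        If fewer than 10 contiguous defined points exist.
    NoKneeError
        If the slope never drops to the threshold within the curve.
    """
    if not 0 < slope_fraction <= 1:
        raise ValidationError("slope_fraction must be in (0, 1]")
    if smoother_bandwidth <= 0:
        raise ValidationError("smoother_bandwidth must be positive")
    defined = curve.defined
    if not np.any(defined):
        raise ValidationError("learning curve is undefined everywhere")
    lo, hi = _longest_defined_run(defined)
    if hi - lo < MIN_DEFINED_POINTS:
        raise InsufficientDataError(
            f"only {hi - lo} contiguous defined points; need {MIN_DEFINED_POINTS}"
        )
    t = curve.t[lo:hi]
    y = curve.score[lo:hi]
    dt = float(np.median(np.diff(t)))
    window = int(round(smoother_bandwidth / dt))
    window = max(3, min(window, y.size))
    if window % 2 == 0:
        window -= 1
    smoothed = savgol_filter(y, window_length=window, polyorder=min(2, window - 1), mode="interp")
    slope = np.gradient(smoothed, t)
    j = int(np.argmax(slope))
    threshold = slope_fraction * slope[j]
    after = np.nonzero(slope[j + 1 :] <= threshold)[0]
    if after.size == 0:
        raise NoKneeError("slope never falls below the cutoff fraction of its maximum")
    k = j + 1 + int(after[0])
    return CutoffPoint(time_to_criterion=float(t[k]), performance_at_criterion=float(smoothed[k]))


def analyze_events(
    events: EventLog,
    grid_seconds: float = 1.0,
    t_max: float | None = None,
    slope_fraction: float = 0.5,
    smoother_bandwidth: float = 15.0,
) -> dict:
    """Event log -> training-quality summary (used by the CLI)."""
    curve = build_curve(events, grid_seconds=grid_seconds, t_max=t_max)
    cutoff = find_cutoff(curve, slope_fraction=slope_fraction, smoother_bandwidth=smoother_bandwidth)
    return {
        "time_to_criterion": cutoff.time_to_criterion,
        "performance_at_criterion": cutoff.performance_at_criterion,
        "n_hits": events.n_hits,
        "n_losses": events.n_losses,
    }
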