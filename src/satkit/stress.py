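"""Streaming grip-force stress score: a moving z-score with a capped window.

The stress score of the latest grip-force sample (CGF) is

    S = (CGF - SMA) / SMSD

where SMA and SMSD are the simple moving average and simple moving standard
deviation of the grip force over a trailing window capped at 40 minutes
(48,000 samples at 20 Hz).  SMSD uses the population divisor (sum of squared
deviations over the sample count, not count - 1), and the current sample is
part of the window.  Because S is a z-score it is invariant to affine
recalibration of the force sensor.

Two routes are provided on purpose: :class:`StressEstimator` is the
streaming accumulator path the real-time controller uses, while
:func:`batch_stress` recomputes the same quantity offline through pandas
rolling windows; tests hold the two to within 1e-9 of each other.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, ValidationError, ValidationWarning
from .io import ForceSeries


@dataclass(frozen=True)
class StressConfig:
    """Parameters of the moving z-score.

    Attributes
    ----------
    rate_hz : float
        Sampling rate of the force signal (default 20 Hz).
    window_seconds : float
        Cap of the moving window (default 2400 s = 40 min, i.e. 48,000
        samples at 20 Hz).
    sd_floor : float
        Small positive guard used in place of SMSD when the window is
        (numerically) constant, so that a constant grip yields S = 0 and the
        controller keeps running instead of dividing by zero.
    warmup_seconds : float
        Minimum history before any S is emitted (default 12 s, matching the
        constant-speed initial phase that feeds the window).
    """

    rate_hz: float = 20.0
    window_seconds: float = 2400.0
    sd_floor: float = 1e-9
    warmup_seconds: float = 12.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.window_seconds <= 0:
            raise ConfigError("rate_hz and window_seconds must be positive")
        if self.sd_floor <= 0:
            raise ConfigError("sd_floor must be positive")
        if not 0 < self.warmup_seconds <= self.window_seconds:
            raise ConfigError("need 0 < warmup_seconds <= window_seconds")


def window_capacity(config: StressConfig) -> int:
    """Maximum number of samples the moving window retains.

    round(window_seconds * rate_hz); 48,000 for the defaults.
    """
    n = round(config.window_seconds * config.rate_hz)
    if n < 1:
        raise ConfigError("window shorter than one sample")
    return int(n)


def warmup_samples(config: StressConfig) -> int:
    """Number of samples that must accumulate before S is emitted."""
    return max(1, round(config.warmup_seconds * config.rate_hz))


@dataclass
class StressSeries:
    """Stress scores on the force-sample grid (post warm-up)."""

    t: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.t.shape != self.s.shape:
            raise ValidationError("t and s must have the same shape")

    def __len__(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "s": self.s})


class StressEstimator:
    """Streaming moving z-score over a ring-buffered window.

    ``update`` appends one grip-force sample, evicts the oldest sample once
    the window is full, refreshes the running sum/sum-of-squares, and returns
    the stress score — or ``None`` while warming up.  Accumulators are
    re-summed from the buffer every full window's worth of updates to keep
    floating-point drift below 1e-6 over millions of samples.
    """

    def __init__(self, config: StressConfig | None = None) -> None:
        self.config = config or StressConfig()
        self._cap = window_capacity(self.config)
        self._warmup_n = warmup_samples(self.config)
        self._buf: deque[float] = deque()
        self._sum = 0.0
        self._sumsq = 0.0
        self._since_resum = 0

    # -- state inspection ---------------------------------------------------
    @property
    def count(self) -> int:
        """Samples currently in the window."""
        return len(self._buf)

    @property
    def sma(self) -> float:
        """Simple moving average of the buffered samples."""
        if not self._buf:
            raise ValidationError("no samples yet")
        return self._sum / len(self._buf)

    @property
    def smsd(self) -> float:
        """Simple moving (population) standard deviation of the buffer."""
        m = len(self._buf)
        if not m:
            raise ValidationError("no samples yet")
        var = self._sumsq / m - (self._sum / m) ** 2
        return math.sqrt(var) if var > 0.0 else 0.0

    @property
    def warmed_up(self) -> bool:
        return len(self._buf) >= self._warmup_n

    # -- updates ------------------------------------------------------------
    def _resum(self) -> None:
        arr = np.array(self._buf, dtype=float)
        self._sum = float(arr.sum())
        self._sumsq = float((arr * arr).sum())
        self._since_resum = 0

    def update(self, cgf: float) -> float | None:
        """Consume one grip-force sample; return S or None during warm-up."""
        f = float(cgf)
        if not math.isfinite(f):
            raise ValidationError("grip-force sample must be finite")
        if len(self._buf) == self._cap:
            old = self._buf.popleft()
            self._sum -= old
            self._sumsq -= old * old
        self._buf.append(f)
        self._sum += f
        self._sumsq += f * f
        self._since_resum += 1
        if self._since_resum >= self._cap:
            self._resum()
        if not self.warmed_up:
            return None
        return (f - self.sma) / max(self.smsd, self.config.sd_floor)

    def update_many(self, values) -> np.ndarray:
        """Stream an array of samples; NaN marks warm-up positions."""
        out = np.empty(len(values), dtype=float)
        for i, v in enumerate(values):
            s = self.update(v)
            out[i] = np.nan if s is None else s
        return out


def batch_stress(series: ForceSeries, config: StressConfig | None = None) -> StressSeries:
    """Offline stress scores for a recorded force log.

    Produces exactly the values the streaming estimator emits sample by
    sample, but computes them vectorised with pandas rolling windows
    (population standard deviation, window capped at the configured size).
    A series shorter than the warm-up returns an empty result with a warning.
    """
    cfg = config or StressConfig()
    cap = window_capacity(cfg)
    warm = warmup_samples(cfg)
    if abs(series.rate_hz - cfg.rate_hz) > 1e-9:
        warnings.warn(
            f"series rate {series.rate_hz} Hz differs from config rate {cfg.rate_hz} Hz;"
            " window/warm-up sample counts follow the config",
            ValidationWarning,
            stacklevel=2,
        )
    if len(series) < warm:
        warnings.warn(
            f"series shorter than the {cfg.warmup_seconds} s warm-up; no stress emitted",
            ValidationWarning,
            stacklevel=2,
        )
        return StressSeries(np.empty(0), np.empty(0))
    x = pd.Series(series.force)
    roll = x.rolling(window=cap, min_periods=1)
    sma = roll.mean().to_numpy()
    smsd = roll.std(ddof=0).to_numpy()
    smsd = np.nan_to_num(smsd, nan=0.0)  # std of a single sample
    s = (series.force - sma) / np.maximum(smsd, cfg.sd_floor)
    return StressSeries(series.t[warm - 1 :], s[warm - 1 :])
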