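"""Reading, writing and validation of grip-force, event and heart-rate logs.

All files are plain comma-separated UTF-8 with a mandatory header row and
timestamps in session-relative seconds (t = 0 at session start).  Force is
kept in raw sensor units: the stress score is a moving z-score, so any
affine sensor calibration cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import FormatError, ValidationError, ValidationWarning

EVENT_KINDS = ("hit", "life_loss")

#: relative tolerance on the median inter-sample gap before a warning is raised
_GAP_RTOL = 0.10


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


def _check_time_axis(t: np.ndarray, rate_hz: float, what: str) -> None:
    if not np.all(np.isfinite(t)):
        raise ValidationError(f"{what}: non-finite timestamps")
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{what}: timestamps must be strictly increasing")
        med = float(np.median(dt))
        nominal = 1.0 / rate_hz
        if abs(med - nominal) > _GAP_RTOL * nominal:
            warnings.warn(
                f"{what}: median inter-sample gap {med:.6g} s deviates more than "
                f"{_GAP_RTOL:.0%} from nominal {nominal:.6g} s",
                ValidationWarning,
                stacklevel=3,
            )


@dataclass
class ForceSeries:
    """Timestamped grip-force samples at a nominal sampling rate.

    Parameters
    ----------
    t : array of float
        Seconds from session start, strictly increasing.
    force : array of float
        Grip force in sensor units, finite and non-negative.
    rate_hz : float
        Nominal sampling rate (default 20 Hz).
    n_rejected : int
        Number of rows dropped while reading (non-finite force); carried as
        metadata so that ``len(series) + n_rejected`` equals the file rows.
    """

    t: np.ndarray
    force: np.ndarray
    rate_hz: float = 20.0
    n_rejected: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.force = _as_float_array(self.force, "force")
        if self.t.size != self.force.size:
            raise ValidationError("t and force must have the same length")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        _check_time_axis(self.t, self.rate_hz, "force series")
        if not np.all(np.isfinite(self.force)):
            raise ValidationError("force values must be finite")
        if np.any(self.force < 0):
            raise ValidationError("force values must be non-negative")

    def __len__(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "force": self.force})


@dataclass
class EventLog:
    """Timestamped game events: asteroid hits and losses of life.

    Rows are kept sorted by time (stable sort, so simultaneous events keep
    their input order).
    """

    t: np.ndarray
    kind: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        kind = np.asarray(self.kind, dtype=object)
        if kind.ndim != 1 or kind.size != self.t.size:
            raise ValidationError("t and kind must be 1-d and equal length")
        bad = set(kind.tolist()) - set(EVENT_KINDS)
        if bad:
            raise FormatError(f"unknown event kind(s): {sorted(map(str, bad))}")
        if not np.all(np.isfinite(self.t)):
            raise ValidationError("event times must be finite")
        order = np.argsort(self.t, kind="stable")
        self.t = self.t[order]
        self.kind = kind[order]

    def __len__(self) -> int:
        return int(self.t.size)

    def times_of(self, kind: str) -> np.ndarray:
        if kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind: {kind!r}")
        return self.t[self.kind == kind]

    @property
    def n_hits(self) -> int:
        return int(np.sum(self.kind == "hit"))

    @property
    def n_losses(self) -> int:
        return int(np.sum(self.kind == "life_loss"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "kind": self.kind.astype(str)})


@dataclass
class HRSeries:
    """Heart-rate samples (beats per minute) used for validation analyses."""

    t: np.ndarray
    hr: np.ndarray
    rate_hz: float = 64.0

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.hr = _as_float_array(self.hr, "hr")
        if self.t.size != self.hr.size:
            raise ValidationError("t and hr must have the same length")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        _check_time_axis(self.t, self.rate_hz, "HR series")
        if not np.all(np.isfinite(self.hr)) or np.any(self.hr <= 0):
            raise ValidationError("hr values must be finite and > 0")

    def __len__(self) -> int:
        return int(self.t.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "hr": self.hr})


def _read_csv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected header {columns}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}, expected {columns}")
    return df


def read_force_series(path, rate_hz: float = 20.0) -> ForceSeries:
    """Read a ``t,force`` CSV; rows with non-finite force are rejected.

    The number of rejected rows is reported on the returned series as
    ``n_rejected`` and through a :class:`ValidationWarning`.
    """
    df = _read_csv(path, ("t", "force"))
    t = pd.to_numeric(df["t"], errors="coerce").to_numpy(dtype=float)
    force = pd.to_numeric(df["force"], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(t) & np.isfinite(force)
    n_rejected = int((~keep).sum())
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} row(s) with non-finite values",
            ValidationWarning,
            stacklevel=2,
        )
    return ForceSeries(t[keep], force[keep], rate_hz=rate_hz, n_rejected=n_rejected)


def write_force_series(series: ForceSeries, path) -> None:
    """Write a force series as CSV, lossless to 6 decimal places."""
    series.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_event_log(path) -> EventLog:
    """Read a ``t,kind`` CSV; rows come back sorted by time."""
    df = _read_csv(path, ("t", "kind"))
    t = pd.to_numeric(df["t"], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise FormatError(f"{path}: non-numeric event times")
    return EventLog(t, df["kind"].astype(str).to_numpy(dtype=object))


def write_event_log(events: EventLog, path) -> None:
    events.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_hr_series(path, rate_hz: float = 64.0) -> HRSeries:
    """Read a ``t,hr`` CSV; rows with non-finite heart rate are rejected."""
    df = _read_csv(path, ("t", "hr"))
    t = pd.to_numeric(df["t"], errors="coerce").to_numpy(dtype=float)
    hr = pd.to_numeric(df["hr"], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(t) & np.isfinite(hr)
    n_rejected = int((~keep).sum())
    if n_rejected:
        warnings.warn(
            f"{path}: rejected {n_rejected} row(s) with non-finite values",
            ValidationWarning,
            stacklevel=2,
        )
    return HRSeries(t[keep], hr[keep], rate_hz=rate_hz)


def write_hr_series(series: HRSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.6f")


def resample_to_grid(series: ForceSeries, rate_hz: float | None = None) -> ForceSeries:
    """Linearly interpolate an (irregular) force series onto its nominal grid.

    Resampling is always explicit: no other operation in the package
    interpolates silently, because the stress window assumes fixed sample
    counts per second.
    """
    if len(series) < 2:
        raise ValidationError("resampling needs at least two samples")
    rate = float(rate_hz if rate_hz is not None else series.rate_hz)
    if rate <= 0:
        raise ValidationError("rate_hz must be positive")
    dt = 1.0 / rate
    grid = np.arange(series.t[0], series.t[-1] + 0.5 * dt, dt)
    force = np.interp(grid, series.t, series.force)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ValidationWarning)
        return ForceSeries(grid, force, rate_hz=rate)


def validate_file(path, kind: str, rate_hz: float | None = None) -> dict:
    """Validate a CSV of the given kind; returns a small summary dict.

    Used by the command-line ``sat validate``; raises on hard violations and
    records soft findings (warnings) in the summary.
    """
    readers = {
        "force": lambda p: read_force_series(p, rate_hz or 20.0),
        "events": read_event_log,
        "hr": lambda p: read_hr_series(p, rate_hz or 64.0),
    }
    if kind not in readers:
        raise ValidationError(f"kind must be one of {sorted(readers)}")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ValidationWarning)
        obj = readers[kind](path)
    return {
        "kind": kind,
        "rows": len(obj),
        "rejected": getattr(obj, "n_rejected", 0),
        "warnings": [str(w.message) for w in caught],
    }
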