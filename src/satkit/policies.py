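"""Task-difficulty policies: constant, time-ramp, and stress-adaptive.

Difficulty is the asteroid velocity in pixels per second (p/s).  All three
policies share a 12-s initial phase at 6 p/s that lets the stress window
accumulate data.  Afterwards:

* ``constant`` — a fixed mid-level speed (30 p/s by default, or a yoked
  value matched to the adaptive group's realized average);
* ``time_ramp`` — +2 p/s every completed 5 s;
* ``stress_adaptive`` — every controller tick, speed drops 2 p/s when the
  stress score exceeds +0.5, rises 2 p/s when it falls below -0.5, and is
  left alone inside the dead zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._exceptions import ConfigError, ValidationError
from .stress import StressSeries

POLICIES = ("constant", "time_ramp", "stress_adaptive")

#: condition labels of the three-arm design, mapped to their policies
CONDITIONS = {
    "control_constant": "constant",
    "control_time": "time_ramp",
    "stress_adaptive": "stress_adaptive",
}


@dataclass(frozen=True)
class PolicyConfig:
    """Parameters of a difficulty policy.

    Speeds are in p/s, times in seconds.  ``adapt_interval_seconds`` is the
    controller tick: the cadence at which the adaptive rule is applied (the
    source design only says "continuously"; 1 s keeps the +/-2 p/s steps on
    the same scale as the 2 p/s-per-5-s ramp).  ``min_speed``/``max_speed``
    bound every emitted speed; thresholds are strict inequalities, so a
    stress score of exactly 0.5 does not trigger a step.
    """

    policy: str = "constant"
    initial_speed: float = 6.0
    initial_phase_seconds: float = 12.0
    constant_speed: float = 30.0
    ramp_step: float = 2.0
    ramp_interval_seconds: float = 5.0
    stress_high: float = 0.5
    stress_low: float = -0.5
    adapt_step: float = 2.0
    adapt_interval_seconds: float = 1.0
    min_speed: float = 2.0
    max_speed: float = 200.0

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ConfigError(f"policy must be one of {POLICIES}")
        if not self.stress_low < self.stress_high:
            raise ConfigError("need stress_low < stress_high")
        for name in ("initial_speed", "constant_speed", "min_speed", "max_speed"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.min_speed <= self.initial_speed:
            raise ConfigError("need min_speed <= initial_speed")
        if not self.min_speed < self.max_speed:
            raise ConfigError("need min_speed < max_speed")
        for name in (
            "initial_phase_seconds",
            "ramp_step",
            "ramp_interval_seconds",
            "adapt_step",
            "adapt_interval_seconds",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class DifficultyTrace:
    """Piecewise-constant task speed sampled at controller ticks."""

    t: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.t.shape != self.speed.shape:
            raise ValidationError("t and speed must have the same shape")

    def __len__(self) -> int:
        return int(self.t.size)

    def time_weighted_mean(self) -> float:
        """Mean speed weighting each sample by the time it was held."""
        if len(self) == 0:
            raise ValidationError("empty difficulty trace")
        if len(self) == 1:
            return float(self.speed[0])
        dt = np.diff(self.t)
        w = np.append(dt, np.median(dt))  # final sample held one typical tick
        return float(np.sum(self.speed * w) / np.sum(w))


def _check_t(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("t must be non-negative")
    return arr


def speed_constant(t, config: PolicyConfig):
    """Constant-policy speed at time ``t`` (scalar or array)."""
    arr = _check_t(t)
    out = np.where(arr < config.initial_phase_seconds, config.initial_speed, config.constant_speed)
    return float(out) if np.isscalar(t) else out


def speed_time_ramp(t, config: PolicyConfig):
    """Time-ramp speed at ``t``: +ramp_step per completed ramp interval."""
    arr = _check_t(t)
    completed = np.floor((arr - config.initial_phase_seconds) / config.ramp_interval_seconds)
    ramped = config.initial_speed + config.ramp_step * completed
    ramped = np.clip(ramped, config.min_speed, config.max_speed)
    out = np.where(arr < config.initial_phase_seconds, config.initial_speed, ramped)
    return float(out) if np.isscalar(t) else out


def adaptive_step(s: float, speed: float, config: PolicyConfig) -> float:
    """One tick of the stress-adaptive rule.

    Stress above the high threshold lowers the speed by one step; stress
    below the low threshold raises it; the dead zone in between leaves it
    unchanged.  The result is clamped to [min_speed, max_speed].
    """
    if not math.isfinite(s):
        raise ValidationError("stress score must be finite")
    new = float(speed)
    if s > config.stress_high:
        new -= config.adapt_step
    elif s < config.stress_low:
        new += config.adapt_step
    return min(max(new, config.min_speed), config.max_speed)


def run_policy(
    config: PolicyConfig,
    stress: StressSeries | None = None,
    duration: float = 600.0,
) -> DifficultyTrace:
    """Roll a policy forward for ``duration`` seconds.

    The trace is sampled at controller ticks (``adapt_interval_seconds``).
    The adaptive policy consumes the most recent stress score at or before
    each tick; while none is available (warm-up) the speed stays at
    ``initial_speed``.  ``stress`` is required iff the policy is adaptive.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    tick = config.adapt_interval_seconds
    ticks = np.arange(0.0, duration, tick)
    if config.policy == "constant":
        if stress is not None:
            pass  # ignored by design: open-loop policy
        return DifficultyTrace(ticks, speed_constant(ticks, config))
    if config.policy == "time_ramp":
        return DifficultyTrace(ticks, speed_time_ramp(ticks, config))
    # stress-adaptive
    if stress is None:
        raise ConfigError("stress stream required for the stress_adaptive policy")
    if np.any(~np.isfinite(stress.s)):
        raise ValidationError("stress stream contains non-finite scores")
    speeds = np.empty_like(ticks)
    speed = config.initial_speed
    j = -1  # index of most recent stress sample consumed
    n = len(stress)
    for i, tk in enumerate(ticks):
        while j + 1 < n and stress.t[j + 1] <= tk:
            j += 1
        if tk < config.initial_phase_seconds:
            speed = config.initial_speed
        elif j >= 0:
            speed = adaptive_step(float(stress.s[j]), speed, config)
        speeds[i] = speed
    return DifficultyTrace(ticks, speeds)


def default_policy_for(condition: str) -> PolicyConfig:
    """Default PolicyConfig for one of the three experimental conditions."""
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {sorted(CONDITIONS)}")
    return PolicyConfig(policy=CONDITIONS[condition])
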