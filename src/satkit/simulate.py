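"""Closed-loop synthetic trainee.

The generator produces, for one participant, everything the real apparatus
would record: a 20 Hz grip-force log, hit / life-loss event streams, the
task-speed trace, and (for tests only) the hidden latent stress.

Generative model
----------------
* Latent stress ``X`` follows mean-reverting (Ornstein-Uhlenbeck) dynamics
  with reversion rate ``theta``, diffusion scale ``sigma`` and equilibrium
  ``kappa * (speed - speed_ref)`` during play (0 during rest): faster
  asteroids push stress up, rest relaxes it to baseline.
* Grip force is an affine read-out of latent stress, ``g0 + g1*X`` plus
  Gaussian sensor noise (clipped at zero — a force sensor cannot go
  negative).
* Hits form an inhomogeneous Poisson stream whose rate is an inverted-U in
  stress (Gaussian bump of width ``u_width`` centred on ``s_opt``) scaled by
  a saturating learning curve ``1 - exp(-t/tau_learn)`` in cumulative task
  time.
* Life losses are Poisson with rate proportional to speed and declining with
  learning from twice to once the baseline.
* In the stress-adaptive condition the speed trace is driven by the real
  estimator + controller acting on the *simulated force* (never on latent
  stress): the full closed loop is exercised.

Event streams are realized by thinning a dominating homogeneous Poisson
process; stress diffusion, force noise, hit thinning and loss thinning use
independent RNG substreams spawned from the seed, so a given seed is
bit-reproducible.

Clocks: force and latent stress are recorded on the wall clock (rests
included, the stress window keeps filling during rest); events, speed and
estimated stress are recorded on the game clock (cumulative task time), the
axis on which learning curves are built.  ``SessionRecord.segments`` maps
between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from ._exceptions import ConfigError
from .io import EventLog, ForceSeries
from .policies import CONDITIONS, DifficultyTrace, PolicyConfig, default_policy_for
from .stress import StressConfig, StressSeries, warmup_samples, window_capacity

_POLICY_CODE = {"constant": 0, "time_ramp": 1, "stress_adaptive": 2}


@dataclass(frozen=True)
class TraineeParams:
    """Parameters of the synthetic trainee.

    Defaults are the package's stated study conditions; none claim empirical
    calibration (no public data exist to fit them to).

    Attributes
    ----------
    s_opt : float
        Latent stress at which performance peaks (inverted-U apex).
    u_width : float
        Width of the inverted-U (SD of the Gaussian bump), stress units.
    h_max : float
        Peak hit rate at optimal stress, fully learned, events/s.
    loss_base : float
        Baseline life-loss rate per second at the reference speed.
    speed_ref : float
        Reference speed (p/s) at which loss rate equals loss_base and the
        latent-stress equilibrium is zero.
    tau_learn : float
        Learning time constant (s of cumulative task time).
    theta : float
        Mean-reversion rate of latent stress, 1/s.
    sigma : float
        Diffusion scale of latent stress.
    kappa : float
        Stress sensitivity to speed, stress units per p/s above speed_ref.
    g0, g1 : float
        Grip-force intercept and slope on latent stress (sensor units).
    gnoise : float
        SD of the Gaussian force sensor noise.
    """

    s_opt: float = 0.0
    u_width: float = 1.0
    h_max: float = 1.2
    loss_base: float = 0.005
    speed_ref: float = 30.0
    tau_learn: float = 240.0
    theta: float = 0.1
    sigma: float = 0.3
    kappa: float = 0.04
    g0: float = 5.0
    g1: float = 1.5
    gnoise: float = 0.2

    def __post_init__(self) -> None:
        for name in ("u_width", "h_max", "speed_ref", "tau_learn", "theta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("loss_base", "sigma", "kappa", "gnoise", "g0"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SessionProtocol:
    """Session structure: n task sessions, each preceded by a rest period."""

    n_sessions: int = 3
    task_seconds: float = 600.0
    rest_seconds: float = 120.0
    reset_estimator_at_rest: bool = False

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if self.task_seconds <= 0 or self.rest_seconds < 0:
            raise ConfigError("need task_seconds > 0 and rest_seconds >= 0")


@dataclass
class SessionRecord:
    """Everything recorded (or hidden) for one simulated participant."""

    force: ForceSeries
    events: EventLog
    speed: DifficultyTrace
    est_stress: StressSeries
    latent_stress: np.ndarray  # wall-clock, aligned with force.t; tests only
    condition: str
    participant_id: str
    seed: int | None
    segments: list = field(default_factory=list)

    @property
    def task_duration(self) -> float:
        return float(sum(s["task_end"] - s["task_start"] for s in self.segments if s["kind"] == "task"))


@njit(cache=False)
def _segment_kernel(
    is_task,
    n_samples,
    dt,
    # trainee
    theta,
    sigma,
    kappa,
    speed_ref,
    s_opt,
    inv_2w2,
    h_max,
    loss_base,
    inv_tau,
    g0,
    g1,
    gnoise,
    # policy
    policy_code,
    initial_speed,
    phase_n,
    constant_speed,
    ramp_step,
    ramp_int_n,
    s_hi,
    s_lo,
    adapt_step_sz,
    tick_n,
    min_speed,
    max_speed,
    # estimator
    cap,
    warmup_n,
    sd_floor,
    buf,
    est_meta,
    # carried state
    x0,
    speed0,
    task_time0,
    # noise
    z_stress,
    z_force,
    hit_t,
    hit_u,
    hit_lmax,
    loss_t,
    loss_u,
    loss_lmax,
    # outputs
    force_out,
    latent_out,
    tick_t,
    tick_speed,
    tick_s,
    hit_out,
    loss_out,
):
    a = math.exp(-theta * dt)
    if theta > 0.0:
        sd = sigma * math.sqrt((1.0 - a * a) / (2.0 * theta))
    else:
        sd = sigma * math.sqrt(dt)
    count = int(est_meta[0])
    start = int(est_meta[1])
    ssum = est_meta[2]
    ssq = est_meta[3]
    x = x0
    speed = speed0
    s_cur = np.nan
    ph = 0
    pl = 0
    nh = 0
    nl = 0
    ntick = 0
    for i in range(n_samples):
        # controller / policy (uses the stress score of the previous sample)
        if is_task:
            if i < phase_n:
                speed = initial_speed
            elif policy_code == 0:
                speed = constant_speed
            elif policy_code == 1:
                completed = (i - phase_n) // ramp_int_n
                v = initial_speed + ramp_step * completed
                speed = v if v < max_speed else max_speed
            else:
                if i % tick_n == 0 and not np.isnan(s_cur):
                    if s_cur > s_hi:
                        speed = speed - adapt_step_sz
                    elif s_cur < s_lo:
                        speed = speed + adapt_step_sz
                    if speed < min_speed:
                        speed = min_speed
                    elif speed > max_speed:
                        speed = max_speed
            mu = kappa * (speed - speed_ref)
        else:
            mu = 0.0
        # latent stress: exact OU discretisation
        x = mu + (x - mu) * a + sd * z_stress[i]
        # grip force read-out (sensor cannot go negative)
        f = g0 + g1 * x + gnoise * z_force[i]
        if f < 0.0:
            f = 0.0
        # streaming estimator: capped window, running sums
        if count == cap:
            old = buf[start]
            ssum -= old
            ssq -= old * old
            buf[start] = f
            start = (start + 1) % cap
        else:
            buf[(start + count) % cap] = f
            count += 1
        ssum += f
        ssq += f * f
        sma = ssum / count
        var = ssq / count - sma * sma
        if var < 0.0:
            var = 0.0
        smsd = math.sqrt(var)
        if count >= warmup_n:
            d = smsd if smsd > sd_floor else sd_floor
            s_cur = (f - sma) / d
        if is_task:
            t_loc = i * dt
            t_next = (i + 1) * dt
            lf = 1.0 - math.exp(-inv_tau * (task_time0 + t_loc))
            # thin the dominating hit process
            while ph < hit_t.shape[0] and hit_t[ph] < t_next:
                dx = x - s_opt
                lam = h_max * math.exp(-dx * dx * inv_2w2) * lf
                if hit_u[ph] * hit_lmax < lam:
                    hit_out[nh] = task_time0 + hit_t[ph]
                    nh += 1
                ph += 1
            # thin the dominating loss process
            while pl < loss_t.shape[0] and loss_t[pl] < t_next:
                lam = loss_base * (speed / speed_ref) * (2.0 - lf)
                if loss_u[pl] * loss_lmax < lam:
                    loss_out[nl] = task_time0 + loss_t[pl]
                    nl += 1
                pl += 1
            if i % tick_n == 0:
                tick_t[ntick] = task_time0 + t_loc
                tick_speed[ntick] = speed
                tick_s[ntick] = s_cur
                ntick += 1
        force_out[i] = f
        latent_out[i] = x
    est_meta[0] = count
    est_meta[1] = start
    est_meta[2] = ssum
    est_meta[3] = ssq
    return x, speed, nh, nl, ntick


def _simulate_protocol(
    params: TraineeParams,
    policy: PolicyConfig,
    protocol: SessionProtocol,
    stress_config: StressConfig,
    seed,
    condition: str,
    participant_id: str,
) -> SessionRecord:
    rate = stress_config.rate_hz
    dt = 1.0 / rate
    if protocol.task_seconds <= policy.initial_phase_seconds:
        raise ConfigError("task duration must exceed the initial phase")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_stress, rng_force, rng_hit, rng_loss = (np.random.default_rng(c) for c in ss.spawn(4))

    cap = window_capacity(stress_config)
    warm_n = warmup_samples(stress_config)
    buf = np.zeros(cap, dtype=float)
    est_meta = np.zeros(4, dtype=float)

    tick_n = max(1, round(policy.adapt_interval_seconds * rate))
    phase_n = round(policy.initial_phase_seconds * rate)
    ramp_int_n = max(1, round(policy.ramp_interval_seconds * rate))
    pcode = _POLICY_CODE[policy.policy]
    hit_lmax = params.h_max
    loss_lmax = params.loss_base * (policy.max_speed / params.speed_ref) * 2.0
    inv_2w2 = 1.0 / (2.0 * params.u_width**2)
    inv_tau = 1.0 / params.tau_learn

    # build the segment plan: [rest, task] * n_sessions (zero-length rests skipped)
    plan: list[tuple[str, float]] = []
    for _ in range(protocol.n_sessions):
        if protocol.rest_seconds > 0:
            plan.append(("rest", protocol.rest_seconds))
        plan.append(("task", protocol.task_seconds))

    force_parts, latent_parts = [], []
    tick_t_parts, tick_speed_parts, tick_s_parts = [], [], []
    hit_parts, loss_parts = [], []
    segments = []
    x = 0.0
    wall = 0.0
    task_time = 0.0
    for kind, seconds in plan:
        n = round(seconds * rate)
        is_task = kind == "task"
        if is_task:
            n_h = rng_hit.poisson(hit_lmax * seconds)
            hit_t = np.sort(rng_hit.uniform(0.0, seconds, n_h))
            hit_u = rng_hit.random(n_h)
            n_l = rng_loss.poisson(loss_lmax * seconds)
            loss_t = np.sort(rng_loss.uniform(0.0, seconds, n_l))
            loss_u = rng_loss.random(n_l)
            n_ticks = -(-n // tick_n)  # ceil
        else:
            if protocol.reset_estimator_at_rest:
                est_meta[:] = 0.0
            hit_t = hit_u = loss_t = loss_u = np.empty(0, dtype=float)
            n_ticks = 0
        z_stress = rng_stress.standard_normal(n)
        z_force = rng_force.standard_normal(n)
        force_out = np.empty(n, dtype=float)
        latent_out = np.empty(n, dtype=float)
        tick_t = np.empty(n_ticks, dtype=float)
        tick_speed = np.empty(n_ticks, dtype=float)
        tick_s = np.empty(n_ticks, dtype=float)
        hit_out = np.empty(hit_t.size, dtype=float)
        loss_out = np.empty(loss_t.size, dtype=float)
        x, _speed, nh, nl, ntick = _segment_kernel(
            is_task,
            n,
            dt,
            params.theta,
            params.sigma,
            params.kappa,
            params.speed_ref,
            params.s_opt,
            inv_2w2,
            params.h_max,
            params.loss_base,
            inv_tau,
            params.g0,
            params.g1,
            params.gnoise,
            pcode,
            policy.initial_speed,
            phase_n,
            policy.constant_speed,
            policy.ramp_step,
            ramp_int_n,
            policy.stress_high,
            policy.stress_low,
            policy.adapt_step,
            tick_n,
            policy.min_speed,
            policy.max_speed,
            cap,
            warm_n,
            stress_config.sd_floor,
            buf,
            est_meta,
            x,
            policy.initial_speed,  # each session is a fresh game
            task_time,
            z_stress,
            z_force,
            hit_t,
            hit_u,
            hit_lmax,
            loss_t,
            loss_u,
            loss_lmax,
            force_out,
            latent_out,
            tick_t,
            tick_speed,
            tick_s,
            hit_out,
            loss_out,
        )
        force_parts.append(force_out)
        latent_parts.append(latent_out)
        seg = {
            "kind": kind,
            "wall_start": wall,
            "wall_end": wall + seconds,
            "task_start": task_time,
            "task_end": task_time + (seconds if is_task else 0.0),
        }
        segments.append(seg)
        if is_task:
            tick_t_parts.append(tick_t[:ntick])
            tick_speed_parts.append(tick_speed[:ntick])
            tick_s_parts.append(tick_s[:ntick])
            hit_parts.append(hit_out[:nh])
            loss_parts.append(loss_out[:nl])
            task_time += seconds
        wall += seconds

    force = np.concatenate(force_parts)
    latent = np.concatenate(latent_parts)
    t_wall = np.arange(force.size) * dt
    hits = np.concatenate(hit_parts) if hit_parts else np.empty(0)
    losses = np.concatenate(loss_parts) if loss_parts else np.empty(0)
    events = EventLog(
        np.concatenate([hits, losses]),
        np.array(["hit"] * hits.size + ["life_loss"] * losses.size, dtype=object),
    )
    trace = DifficultyTrace(np.concatenate(tick_t_parts), np.concatenate(tick_speed_parts))
    est = StressSeries(np.concatenate(tick_t_parts), np.concatenate(tick_s_parts))
    seed_int = None if isinstance(seed, np.random.SeedSequence) else int(seed)
    return SessionRecord(
        force=ForceSeries(t_wall, force, rate_hz=rate),
        events=events,
        speed=trace,
        est_stress=est,
        latent_stress=latent,
        condition=condition,
        participant_id=participant_id,
        seed=seed_int,
        segments=segments,
    )


def simulate_session(
    params: TraineeParams,
    policy: PolicyConfig,
    duration: float,
    seed,
    stress_config: StressConfig | None = None,
    condition: str | None = None,
    participant_id: str = "p0",
) -> SessionRecord:
    """Simulate a single uninterrupted task session of ``duration`` seconds."""
    if duration <= policy.initial_phase_seconds:
        raise ConfigError("duration must exceed the initial phase")
    protocol = SessionProtocol(n_sessions=1, task_seconds=float(duration), rest_seconds=0.0)
    cond = condition or _condition_for_policy(policy.policy)
    return _simulate_protocol(
        params, policy, protocol, stress_config or StressConfig(), seed, cond, participant_id
    )


def simulate_participant(
    params: TraineeParams,
    policy: PolicyConfig,
    seed,
    protocol: SessionProtocol | None = None,
    stress_config: StressConfig | None = None,
    condition: str | None = None,
    participant_id: str = "p0",
) -> SessionRecord:
    """Simulate the full protocol (default: three 10-min sessions, each
    preceded by a 2-min rest) for one participant.

    The estimator window persists across rests unless the protocol says to
    reset it; the adaptive controller restarts each session at the initial
    speed (a fresh game).
    """
    cond = condition or _condition_for_policy(policy.policy)
    return _simulate_protocol(
        params,
        policy,
        protocol or SessionProtocol(),
        stress_config or StressConfig(),
        seed,
        cond,
        participant_id,
    )


def _condition_for_policy(policy_name: str) -> str:
    for cond, pol in CONDITIONS.items():
        if pol == policy_name:
            return cond
    raise ConfigError(f"unknown policy {policy_name!r}")


def simulate_cohort(
    n_per_condition: int,
    params: TraineeParams | None = None,
    policies: dict[str, PolicyConfig] | None = None,
    seed=0,
    protocol: SessionProtocol | None = None,
    stress_config: StressConfig | None = None,
) -> list[SessionRecord]:
    """Simulate ``n_per_condition`` participants in each of the three arms.

    Per-participant seeds are independent substreams of the master seed, so
    the same master seed reproduces the cohort exactly.  This generator does
    not yoke the constant-control speed (pass explicit policies, or use
    :func:`satkit.evaluate.run_experiment` for the full batch protocol).
    """
    if n_per_condition < 1:
        raise ConfigError("n_per_condition must be >= 1")
    params = params or TraineeParams()
    policies = policies or {c: default_policy_for(c) for c in CONDITIONS}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(3 * n_per_condition)
    records = []
    k = 0
    for cond in CONDITIONS:
        for i in range(n_per_condition):
            records.append(
                _simulate_protocol(
                    params,
                    policies[cond],
                    protocol or SessionProtocol(),
                    stress_config or StressConfig(),
                    children[k],
                    cond,
                    f"{cond}-{i + 1:02d}",
                )
            )
            k += 1
    return records


def yoked_policies(yoked_speed: float, base: dict[str, PolicyConfig] | None = None) -> dict[str, PolicyConfig]:
    """Per-condition policies with the constant control set to a yoked speed."""
    policies = dict(base or {c: default_policy_for(c) for c in CONDITIONS})
    policies["control_constant"] = replace(policies["control_constant"], constant_speed=float(yoked_speed))
    return policies
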