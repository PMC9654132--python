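"""Condition comparisons, speed yoking and the end-to-end experiment harness.

With one outcome value per participant the mixed-model analysis of the
three-arm design reduces to its estimable core: a fixed-effects linear model
with condition as a 3-level factor.  ``compare_conditions`` reports the
omnibus condition F, the planned contrast of stress-adaptive against the
pooled controls (+1 vs -1/2, -1/2), p-values and adjusted R².

``run_experiment`` executes the full batch protocol: within each batch the
adaptive third runs first, their realized average game speed is computed,
the constant control of the same batch is *yoked* to that speed (so average
difficulty cannot explain differences between those two arms), the controls
run, and per-participant learning-curve metrics feed the comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._exceptions import (
    ConfigError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)
from .metrics import build_curve, find_cutoff, NoKneeError
from .policies import CONDITIONS, DifficultyTrace, PolicyConfig, default_policy_for
from .simulate import (
    SessionProtocol,
    SessionRecord,
    TraineeParams,
    _simulate_protocol,
    yoked_policies,
)
from .stress import StressConfig

OUTCOMES = ("time_to_criterion", "performance_at_criterion")

_CONDITION_ORDER = tuple(CONDITIONS)  # control_constant, control_time, stress_adaptive


@dataclass
class ComparisonResult:
    """Condition-effect statistics for one outcome."""

    outcome: str
    f_stat: float
    f_df: tuple[int, int]
    p_omnibus: float
    contrast_estimate: float
    t_adaptive: float
    p_contrast: float
    adj_r2: float
    n_per_condition: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "f_stat": self.f_stat,
            "df": list(self.f_df),
            "p_omnibus": self.p_omnibus,
            "contrast_estimate": self.contrast_estimate,
            "t_adaptive": self.t_adaptive,
            "p_contrast": self.p_contrast,
            "adj_r2": self.adj_r2,
            "n_per_condition": self.n_per_condition,
        }


def compare_conditions(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
) -> ComparisonResult:
    """Fixed-effects linear model of an outcome on the 3-level condition.

    The contrast "stress-adaptive vs the two controls" is coded
    adaptive = +1, each control = -1/2, i.e. the estimate is
    mean(adaptive) - mean(controls' means); a negative t on time to
    criterion means the adaptive group finished training sooner.

    Rows with a missing outcome are dropped; each condition must retain at
    least two rows.
    """
    if outcome not in table.columns:
        raise ValidationError(f"outcome column {outcome!r} not in table")
    unknown = set(table["condition"]) - set(_CONDITION_ORDER)
    if unknown:
        raise ValidationError(f"unknown condition(s): {sorted(unknown)}")
    data = table.dropna(subset=[outcome])
    counts = data["condition"].value_counts()
    n_per = {c: int(counts.get(c, 0)) for c in _CONDITION_ORDER}
    if any(v < 2 for v in n_per.values()):
        raise InsufficientDataError(f"need >= 2 rows per condition, have {n_per}")

    y = data[outcome].to_numpy(dtype=float)
    d_time = (data["condition"] == "control_time").to_numpy(dtype=float)
    d_adapt = (data["condition"] == "stress_adaptive").to_numpy(dtype=float)
    cols = [np.ones(len(data)), d_time, d_adapt]
    if covariates:
        for c in covariates:
            cols.append(pd.to_numeric(data[c]).to_numpy(dtype=float))
    X = np.column_stack(cols)
    res = sm.OLS(y, X).fit()

    k = X.shape[1]
    # omnibus F on the two condition dummies
    r_omni = np.zeros((2, k))
    r_omni[0, 1] = 1.0
    r_omni[1, 2] = 1.0
    ftest = res.f_test(r_omni)
    f_stat = float(np.squeeze(ftest.fvalue))
    p_omni = float(ftest.pvalue)
    f_df = (int(ftest.df_num), int(ftest.df_denom))
    # adaptive vs pooled controls: mu_A - (mu_CC + mu_CT)/2 = b_adapt - b_time/2
    r_con = np.zeros(k)
    r_con[1] = -0.5
    r_con[2] = 1.0
    ttest = res.t_test(r_con)
    estimate = float(np.squeeze(ttest.effect))
    t_val = float(np.squeeze(ttest.tvalue))
    p_con = float(np.squeeze(ttest.pvalue))
    adj_r2 = float(res.rsquared_adj)
    se = float(np.squeeze(ttest.sd))

    # degenerate tables: residuals at floating-point-noise scale make the
    # contrast a 0/0 — report a null effect instead of noise ratios
    eps = 1e-9 * (1.0 + float(np.abs(y).mean()))
    if se < eps or not np.isfinite(t_val):
        if abs(estimate) < eps:
            estimate, t_val, p_con = 0.0, 0.0, 1.0
        else:
            t_val, p_con = math_copysign_inf(estimate), 0.0
    if math.sqrt(max(res.ssr, 0.0) / max(res.df_resid, 1)) < eps and abs(f_stat) < 1.0:
        f_stat, p_omni = 0.0, 1.0
    if not np.isfinite(f_stat):
        f_stat, p_omni = 0.0, 1.0
    if not np.isfinite(adj_r2):
        adj_r2 = 0.0

    return ComparisonResult(
        outcome=outcome,
        f_stat=f_stat,
        f_df=f_df,
        p_omnibus=p_omni,
        contrast_estimate=estimate,
        t_adaptive=t_val,
        p_contrast=p_con,
        adj_r2=adj_r2,
        n_per_condition=n_per,
    )


def math_copysign_inf(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


def yoke_constant_speed(adaptive_sessions) -> float:
    """Time-weighted mean speed across adaptive sessions (the yoked value).

    Accepts SessionRecords or DifficultyTraces.  Invariant to session order
    and to splitting sessions into sub-segments.
    """
    if not adaptive_sessions:
        raise ValidationError("need at least one adaptive session to yoke")
    num = 0.0
    den = 0.0
    for obj in adaptive_sessions:
        trace: DifficultyTrace = obj.speed if isinstance(obj, SessionRecord) else obj
        if len(trace) == 0:
            raise ValidationError("empty difficulty trace")
        if len(trace) == 1:
            w = np.array([1.0])
        else:
            dt = np.diff(trace.t)
            w = np.append(dt, np.median(dt))
        num += float(np.sum(trace.speed * w))
        den += float(np.sum(w))
    return num / den


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation of two per-participant mean vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or xa.shape != ya.shape:
        raise ValidationError("x and y must be 1-d and of equal length")
    if xa.size < 3:
        raise InsufficientDataError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return float(stats.pearsonr(xa, ya).statistic)


@dataclass
class ExperimentResult:
    """Outcome table plus comparisons from one full in-silico experiment."""

    outcomes: pd.DataFrame
    comparisons: dict[str, ComparisonResult]
    yoked_speeds: list[float]
    n_cutoff_failures: int = 0
    seed: int | None = None

    def report(self) -> dict:
        return {
            "seed": self.seed,
            "yoked_speeds": self.yoked_speeds,
            "n_cutoff_failures": self.n_cutoff_failures,
            "comparisons": {k: v.to_dict() for k, v in self.comparisons.items()},
            "condition_means": {
                out: self.outcomes.groupby("condition")[out].mean().to_dict() for out in OUTCOMES
            },
        }


def session_metrics(
    record: SessionRecord,
    grid_seconds: float = 1.0,
    slope_fraction: float = 0.5,
    smoother_bandwidth: float = 15.0,
) -> dict:
    """Learning-curve outcomes for one participant (NaN if no knee exists)."""
    curve = build_curve(record.events, grid_seconds=grid_seconds, t_max=record.task_duration)
    try:
        cut = find_cutoff(curve, slope_fraction=slope_fraction, smoother_bandwidth=smoother_bandwidth)
        ttc, pac = cut.time_to_criterion, cut.performance_at_criterion
        failed = False
    except (NoKneeError, InsufficientDataError, ValidationError):
        ttc = pac = float("nan")
        failed = True
    return {
        "participant_id": record.participant_id,
        "condition": record.condition,
        "time_to_criterion": ttc,
        "performance_at_criterion": pac,
        "mean_speed": record.speed.time_weighted_mean(),
        "n_hits": record.events.n_hits,
        "n_losses": record.events.n_losses,
        "cutoff_failed": failed,
    }


def _batch_sizes(n: int, n_batches: int) -> list[int]:
    base, extra = divmod(n, n_batches)
    return [base + (1 if b < extra else 0) for b in range(n_batches)]


def run_experiment(
    n_per_condition: int = 15,
    params: TraineeParams | None = None,
    policies: dict[str, PolicyConfig] | None = None,
    n_batches: int = 4,
    seed=0,
    protocol: SessionProtocol | None = None,
    stress_config: StressConfig | None = None,
    keep_records: bool = False,
) -> ExperimentResult:
    """Full three-arm in-silico experiment with batched speed yoking.

    Per batch: simulate the stress-adaptive participants first, compute their
    time-weighted average game speed, yoke the batch's constant control to
    it, then simulate both control arms.  Learning-curve metrics per
    participant are assembled into the outcome table and both outcomes are
    compared across conditions.
    """
    if n_per_condition < 1:
        raise ConfigError("n_per_condition must be >= 1")
    if n_batches < 1:
        raise ConfigError("n_batches must be >= 1")
    n_batches = min(n_batches, n_per_condition)
    params = params or TraineeParams()
    base_policies = policies or {c: default_policy_for(c) for c in CONDITIONS}
    protocol = protocol or SessionProtocol()
    stress_config = stress_config or StressConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_int = None if isinstance(seed, np.random.SeedSequence) else int(seed)
    children = iter(ss.spawn(3 * n_per_condition))

    rows = []
    records = []
    yoked_speeds = []
    sizes = _batch_sizes(n_per_condition, n_batches)
    idx = {c: 0 for c in _CONDITION_ORDER}
    for b, size in enumerate(sizes):
        if size == 0:
            continue
        # the first third of each batch: stress-adaptive, run to completion
        adaptive = []
        for _ in range(size):
            idx["stress_adaptive"] += 1
            rec = _simulate_protocol(
                params,
                base_policies["stress_adaptive"],
                protocol,
                stress_config,
                next(children),
                "stress_adaptive",
                f"b{b + 1}-stress_adaptive-{idx['stress_adaptive']:02d}",
            )
            adaptive.append(rec)
        yoked = yoke_constant_speed(adaptive)
        yoked_speeds.append(yoked)
        batch_policies = yoked_policies(yoked, base_policies)
        batch_records = list(adaptive)
        for cond in ("control_constant", "control_time"):
            for _ in range(size):
                idx[cond] += 1
                batch_records.append(
                    _simulate_protocol(
                        params,
                        batch_policies[cond],
                        protocol,
                        stress_config,
                        next(children),
                        cond,
                        f"b{b + 1}-{cond}-{idx[cond]:02d}",
                    )
                )
        for rec in batch_records:
            rows.append(session_metrics(rec))
        if keep_records:
            records.extend(batch_records)

    outcomes = pd.DataFrame(rows)
    n_failed = int(outcomes["cutoff_failed"].sum())
    comparisons = {out: compare_conditions(outcomes, out) for out in OUTCOMES}
    result = ExperimentResult(
        outcomes=outcomes,
        comparisons=comparisons,
        yoked_speeds=yoked_speeds,
        n_cutoff_failures=n_failed,
        seed=seed_int,
    )
    if keep_records:
        result.records = records  # type: ignore[attr-defined]
    return result


def condition_means(outcomes: pd.DataFrame, outcome: str) -> dict[str, float]:
    """Per-condition mean of one outcome (NaN rows excluded)."""
    return outcomes.groupby("condition")[outcome].mean().to_dict()
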