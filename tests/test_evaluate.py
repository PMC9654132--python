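import numpy as np
import pandas as pd
import pytest

import satkit as sk

CONDS = ("control_constant", "control_time", "stress_adaptive")


def make_table(values: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for cond, vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"participant_id": f"{cond}-{i}", "condition": cond, "time_to_criterion": v})
    return pd.DataFrame(rows)


def anova_oracle(values: dict[str, np.ndarray]) -> tuple[float, float, float]:
    """Textbook one-way ANOVA F and pooled-variance contrast t for
    adaptive vs mean of the two controls (independent of the OLS route)."""
    groups = [np.asarray(values[c], float) for c in CONDS]
    all_y = np.concatenate(groups)
    grand = all_y.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = 2, all_y.size - 3
    f = (ssb / df_b) / (ssw / df_w)
    msw = ssw / df_w
    n_cc, n_ct, n_sa = (g.size for g in groups)
    est = groups[2].mean() - 0.5 * (groups[0].mean() + groups[1].mean())
    se = np.sqrt(msw * (1.0 / n_sa + 0.25 / n_cc + 0.25 / n_ct))
    return f, est, est / se


class TestCompareConditions:
    def test_identical_groups_are_null(self):
        table = make_table({c: np.full(5, 7.3) for c in CONDS})
        res = sk.compare_conditions(table, "time_to_criterion")
        assert res.t_adaptive == 0.0
        assert res.adj_r2 <= 0.0

    def test_exact_shift_recovery(self):
        delta = -4.25
        table = make_table(
            {
                "control_constant": np.full(4, 10.0),
                "control_time": np.full(4, 10.0),
                "stress_adaptive": np.full(4, 10.0 + delta),
            }
        )
        res = sk.compare_conditions(table, "time_to_criterion")
        assert res.contrast_estimate == pytest.approx(delta, abs=1e-10)

    def test_matches_textbook_anova(self, rng):
        values = {
            "control_constant": rng.normal(100, 12, 15),
            "control_time": rng.normal(110, 12, 17),
            "stress_adaptive": rng.normal(92, 12, 20),
        }
        res = sk.compare_conditions(make_table(values), "time_to_criterion")
        f, est, t = anova_oracle(values)
        assert res.f_stat == pytest.approx(f, abs=1e-8)
        assert res.contrast_estimate == pytest.approx(est, abs=1e-8)
        assert res.t_adaptive == pytest.approx(t, abs=1e-8)
        assert res.f_df == (2, 49)

    def test_unbalanced_nan_rows_dropped(self, rng):
        table = make_table({c: rng.normal(50, 5, 6) for c in CONDS})
        table.loc[0, "time_to_criterion"] = np.nan
        res = sk.compare_conditions(table, "time_to_criterion")
        assert res.n_per_condition["control_constant"] == 5

    def test_insufficient_rows_rejected(self, rng):
        table = make_table(
            {
                "control_constant": rng.normal(50, 5, 1),
                "control_time": rng.normal(50, 5, 5),
                "stress_adaptive": rng.normal(50, 5, 5),
            }
        )
        with pytest.raises(sk.InsufficientDataError):
            sk.compare_conditions(table, "time_to_criterion")

    def test_unknown_condition_rejected(self):
        table = make_table({c: np.ones(3) for c in CONDS})
        table.loc[1, "condition"] = "placebo"
        with pytest.raises(sk.ValidationError):
            sk.compare_conditions(table, "time_to_criterion")


class TestYokeConstantSpeed:
    def test_single_flat_session(self):
        trace = sk.DifficultyTrace(np.arange(600.0), np.full(600, 20.0))
        assert sk.yoke_constant_speed([trace]) == pytest.approx(20.0)

    def test_two_flat_sessions_average(self):
        t = np.arange(600.0)
        traces = [
            sk.DifficultyTrace(t, np.full(600, 10.0)),
            sk.DifficultyTrace(t, np.full(600, 30.0)),
        ]
        assert sk.yoke_constant_speed(traces) == pytest.approx(20.0)

    def test_piecewise_time_weighted_mean(self):
        t = np.arange(600.0)
        speed = np.where(t < 12, 6.0, 30.0)
        got = sk.yoke_constant_speed([sk.DifficultyTrace(t, speed)])
        assert got == pytest.approx((6 * 12 + 30 * 588) / 600.0)

    def test_order_and_split_invariance(self, rng):
        t = np.arange(600.0)
        speed = rng.choice([6.0, 28.0, 30.0, 32.0], 600)
        whole = sk.DifficultyTrace(t, speed)
        first, second = (
            sk.DifficultyTrace(t[:300], speed[:300]),
            sk.DifficultyTrace(t[300:], speed[300:]),
        )
        v = sk.yoke_constant_speed([whole])
        assert sk.yoke_constant_speed([first, second]) == pytest.approx(v)
        assert sk.yoke_constant_speed([second, first]) == pytest.approx(v)

    def test_empty_input_rejected(self):
        with pytest.raises(sk.ValidationError):
            sk.yoke_constant_speed([])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert sk.pearson_correlation(x, x) == pytest.approx(1.0)
        assert sk.pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # product-moment by hand: r = 0.6
        assert sk.pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(sk.UndefinedCorrelationError):
            sk.pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_grip_force_hr_validation_path(self, default_params):
        """Mechanism check on simulated physiology: per-participant mean grip
        force correlates positively with a latent-stress-driven 'heart rate'."""
        mean_force, mean_hr = [], []
        pol = sk.default_policy_for("control_constant")
        for child in np.random.SeedSequence(5150).spawn(12):
            r = sk.simulate_session(default_params, pol, 300.0, child)
            mean_force.append(r.force.force.mean())
            # HR as an independent affine read-out of the same latent stress
            mean_hr.append(70.0 + 8.0 * r.latent_stress.mean())
        assert sk.pearson_correlation(mean_force, mean_hr) > 0.9


class TestRunExperiment:
    def test_fixed_seed_is_reproducible(self, default_params):
        proto = sk.SessionProtocol(n_sessions=1, task_seconds=120.0, rest_seconds=0.0)
        a = sk.run_experiment(n_per_condition=2, params=default_params, seed=99, protocol=proto)
        b = sk.run_experiment(n_per_condition=2, params=default_params, seed=99, protocol=proto)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
        assert a.yoked_speeds == b.yoked_speeds

    def test_yoking_sets_constant_arm_speed(self, default_params):
        res = sk.run_experiment(
            n_per_condition=3,
            params=default_params,
            seed=5,
            n_batches=1,
            protocol=sk.SessionProtocol(n_sessions=1, task_seconds=120.0, rest_seconds=0.0),
        )
        assert len(res.yoked_speeds) == 1
        cc = res.outcomes[res.outcomes.condition == "control_constant"]
        # constant arm's realized mean speed: initial phase at 6, then the yoked speed
        yoked = res.yoked_speeds[0]
        expected = (12 * 6.0 + 108 * yoked) / 120.0
        np.testing.assert_allclose(cc.mean_speed, expected, rtol=1e-6)

    def test_report_schema(self, default_params):
        proto = sk.SessionProtocol(n_sessions=1, task_seconds=120.0, rest_seconds=0.0)
        res = sk.run_experiment(n_per_condition=2, params=default_params, seed=1, protocol=proto)
        rep = res.report()
        assert set(rep["comparisons"]) == {"time_to_criterion", "performance_at_criterion"}
        for comp in rep["comparisons"].values():
            assert {"f_stat", "df", "t_adaptive", "p_omnibus", "p_contrast", "adj_r2"} <= set(comp)
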