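import numpy as np
import pytest

import satkit as sk


def _records_equal(a: sk.SessionRecord, b: sk.SessionRecord) -> bool:
    return (
        np.array_equal(a.force.force, b.force.force)
        and np.array_equal(a.latent_stress, b.latent_stress)
        and np.array_equal(a.events.t, b.events.t)
        and np.array_equal(a.events.kind, b.events.kind)
        and np.array_equal(a.speed.speed, b.speed.speed)
    )


class TestDeterminism:
    def test_same_seed_same_session(self, default_params):
        pol = sk.default_policy_for("stress_adaptive")
        a = sk.simulate_session(default_params, pol, 120.0, seed=7)
        b = sk.simulate_session(default_params, pol, 120.0, seed=7)
        assert _records_equal(a, b)
        c = sk.simulate_session(default_params, pol, 120.0, seed=8)
        assert not np.array_equal(a.force.force, c.force.force)

    def test_same_master_seed_same_cohort(self, default_params):
        proto = sk.SessionProtocol(n_sessions=1, task_seconds=60.0, rest_seconds=30.0)
        a = sk.simulate_cohort(2, default_params, seed=11, protocol=proto)
        b = sk.simulate_cohort(2, default_params, seed=11, protocol=proto)
        assert len(a) == len(b) == 6
        assert all(_records_equal(x, y) for x, y in zip(a, b))


class TestDegenerateDynamics:
    def test_frozen_stress_gives_flat_latent_and_noisy_force(self):
        params = sk.TraineeParams(sigma=0.0, kappa=0.0)
        rec = sk.simulate_session(params, sk.default_policy_for("control_constant"), 300.0, seed=3)
        assert np.all(rec.latent_stress == 0.0)
        assert rec.force.force.mean() == pytest.approx(params.g0, abs=0.02)
        assert rec.force.force.std() == pytest.approx(params.gnoise, rel=0.1)
        # estimator output fluctuates around zero
        s = rec.est_stress.s[np.isfinite(rec.est_stress.s)]
        assert abs(np.mean(s)) < 0.2

    def test_poisson_hit_count_at_optimal_stress(self):
        # stress pinned at s_opt, learning saturated: rate = h_max = 1.2/s
        params = sk.TraineeParams(sigma=0.0, kappa=0.0, tau_learn=1e-9)
        rec = sk.simulate_session(params, sk.default_policy_for("control_constant"), 600.0, seed=5)
        expected = params.h_max * 600.0
        assert abs(rec.events.n_hits - expected) <= 3.0 * np.sqrt(expected)


class TestCohortStructure:
    def test_one_per_condition_yields_three_records(self, default_params):
        proto = sk.SessionProtocol(n_sessions=1, task_seconds=60.0, rest_seconds=0.0)
        recs = sk.simulate_cohort(1, default_params, seed=1, protocol=proto)
        assert len(recs) == 3
        assert sorted({r.condition for r in recs}) == sorted(sk.CONDITIONS)

    def test_default_cohort_counts(self, default_params):
        proto = sk.SessionProtocol(n_sessions=1, task_seconds=30.0, rest_seconds=0.0)
        recs = sk.simulate_cohort(15, default_params, seed=2, protocol=proto)
        assert len(recs) == 45
        for cond in sk.CONDITIONS:
            assert sum(r.condition == cond for r in recs) == 15

    def test_protocol_structure(self, adaptive_record):
        # three 10-min sessions, each preceded by 2 min of rest
        kinds = [s["kind"] for s in adaptive_record.segments]
        assert kinds == ["rest", "task"] * 3
        assert len(adaptive_record.force) == 43_200  # 36 min at 20 Hz
        assert adaptive_record.task_duration == 1800.0
        # events only on the game clock, never beyond total task time
        assert np.all(adaptive_record.events.t <= 1800.0)
        assert len(adaptive_record.speed) == 1800  # 1 Hz controller ticks


class TestClosedLoop:
    def test_recorded_stress_matches_offline_recomputation(self, adaptive_record):
        """The S values the controller saw equal batch_stress on the recorded
        force log at the tick samples (streaming kernel vs pandas route)."""
        cfg = sk.StressConfig()
        batch = sk.batch_stress(adaptive_record.force, cfg)
        s_full = np.full(len(adaptive_record.force), np.nan)
        s_full[239:] = batch.s
        rate = cfg.rate_hz
        k = 0
        for seg in adaptive_record.segments:
            if seg["kind"] != "task":
                continue
            n_ticks = round((seg["task_end"] - seg["task_start"]))
            base = round(seg["wall_start"] * rate)
            for j in range(n_ticks):
                idx = base + j * round(rate * 1.0)  # 1-s ticks
                want = s_full[idx]
                got = adaptive_record.est_stress.s[k]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-9)
                k += 1
        assert k == len(adaptive_record.est_stress)

    def test_adaptive_regulates_stress_better_than_time_ramp(self, default_params):
        """Closed-loop sanity: |latent - s_opt| is smaller under the adaptive
        policy than under the time ramp, pooled over 100 seeded session pairs."""
        pol_a = sk.default_policy_for("stress_adaptive")
        pol_t = sk.default_policy_for("control_time")
        devs_a, devs_t = [], []
        ss = np.random.SeedSequence(314159)
        for c1, c2 in zip(*[iter(ss.spawn(200))] * 2):
            ra = sk.simulate_session(default_params, pol_a, 600.0, c1)
            rt = sk.simulate_session(default_params, pol_t, 600.0, c2)
            devs_a.append(np.mean(np.abs(ra.latent_stress - default_params.s_opt)))
            devs_t.append(np.mean(np.abs(rt.latent_stress - default_params.s_opt)))
        assert np.mean(devs_a) < np.mean(devs_t)

    def test_force_is_a_valid_stress_proxy(self, default_params):
        """Generative faithfulness: corr(mean force, mean latent stress) > 0.9
        across sessions — the premise the estimator relies on."""
        pol = sk.default_policy_for("control_constant")
        mean_force, mean_latent = [], []
        for child in np.random.SeedSequence(2718).spawn(200):
            r = sk.simulate_session(default_params, pol, 600.0, child)
            mean_force.append(r.force.force.mean())
            mean_latent.append(r.latent_stress.mean())
        assert np.corrcoef(mean_force, mean_latent)[0, 1] > 0.9


def test_inverted_u_hit_rate():
    """Holding learning fixed, the empirical hit rate against binned latent
    stress is unimodal with its maximum in the bin containing s_opt."""
    params = sk.TraineeParams(sigma=1.2, tau_learn=1e-9)  # wide exploration, learning saturated
    pol = sk.default_policy_for("control_constant")
    latent_all, hit_latent = [], []
    for child in np.random.SeedSequence(42).spawn(60):
        r = sk.simulate_session(params, pol, 600.0, child)
        latent_all.append(r.latent_stress)
        idx = np.minimum((r.events.times_of("hit") * 20).astype(int), r.latent_stress.size - 1)
        hit_latent.append(r.latent_stress[idx])
    latent = np.concatenate(latent_all)
    hits = np.concatenate(hit_latent)
    edges = np.arange(-2.5, 2.6, 1.0)  # centre bin (-0.5, 0.5) contains s_opt = 0
    occupancy, _ = np.histogram(latent, edges)
    hit_counts, _ = np.histogram(hits, edges)
    rate = hit_counts / (occupancy / 20.0)
    peak = int(np.argmax(rate))
    assert peak == 2
    assert np.all(np.diff(rate[: peak + 1]) > 0)
    assert np.all(np.diff(rate[peak:]) < 0)


def test_invalid_params_rejected():
    with pytest.raises(sk.ConfigError):
        sk.TraineeParams(u_width=0.0)
    with pytest.raises(sk.ConfigError):
        sk.TraineeParams(tau_learn=-1.0)
    with pytest.raises(sk.ConfigError):
        sk.simulate_session(
            sk.TraineeParams(), sk.default_policy_for("control_constant"), 10.0, seed=0
        )  # shorter than the initial phase
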