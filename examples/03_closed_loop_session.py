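"""One closed-loop training session of the synthetic trainee.

The simulated operator's latent stress drifts with task speed; grip force is
read from that stress; the estimator + controller close the loop on the
force signal alone.  The learning-curve knee then summarises training
quality: its x is the time to criterion, its y the performance at criterion.
"""

import satkit as sk

params = sk.TraineeParams()
record = sk.simulate_participant(
    params, sk.default_policy_for("stress_adaptive"), seed=7
)

m = sk.session_metrics(record)
print(f"protocol: 3 x 10-min sessions, each after 2 min rest (36 min wall clock)")
print(f"hits: {m['n_hits']}, life losses: {m['n_losses']}")
print(f"mean game speed: {m['mean_speed']:.1f} p/s")
print(f"time to criterion:        {m['time_to_criterion']:.0f} s")
print(f"performance at criterion: {m['performance_at_criterion']:.2f}")
print()
print(f"latent stress (hidden truth) mean |X - s_opt|: "
      f"{abs(record.latent_stress - params.s_opt).mean():.2f}")
print("The controller never sees the latent stress - only the grip force;")
print("the knee is computed from ln(cumulative hits - 10 * cumulative losses).")
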