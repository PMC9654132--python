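"""The three difficulty policies side by side.

Every condition starts with 12 s at 6 p/s (the stress window's warm-up).
Afterwards the constant policy holds 30 p/s, the time ramp adds 2 p/s every
5 s, and the stress-adaptive controller steps the speed +/-2 p/s against the
live stress score.
"""

import numpy as np

import satkit as sk

t = np.arange(0.0, 120.0)
# a stress trace that starts relaxed (below -0.5) and turns stressed (above +0.5)
s = np.where(t < 60, -0.8, 0.9)

for condition in sk.CONDITIONS:
    cfg = sk.default_policy_for(condition)
    stream = sk.StressSeries(t, s) if cfg.policy == "stress_adaptive" else None
    trace = sk.run_policy(cfg, stress=stream, duration=120.0)
    pick = lambda sec: trace.speed[np.searchsorted(trace.t, sec)]
    print(
        f"{condition:18s} speed at t=5: {pick(5):6.1f}  t=30: {pick(30):6.1f} "
        f" t=59: {pick(59):6.1f}  t=119: {pick(119):6.1f} p/s"
    )

print()
print("Relaxed stress drives the adaptive speed up 2 p/s per second; once the")
print("trace crosses +0.5 the controller backs off at the same rate, while")
print("the open-loop controls ignore the operator entirely.")
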