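"""Estimate operator stress from a grip-force log.

Builds a 5-minute synthetic grip-force recording whose underlying stress
rises halfway through, then scores every sample with the capped moving
z-score S = (CGF - SMA) / SMSD.  S near 0 means "gripping as usual"; S above
+0.5 is the controller's "stressed" region.
"""

import numpy as np

import satkit as sk

rng = np.random.default_rng(0)
rate = 20.0
t = np.arange(0, 300.0, 1 / rate)
calm = 5.0 + rng.normal(0, 0.2, t.size // 2)
tense = 6.0 + rng.normal(0, 0.2, t.size - t.size // 2)  # grip tightens at t = 150 s
series = sk.ForceSeries(t, np.concatenate([calm, tense]).clip(min=0))

stress = sk.batch_stress(series, sk.StressConfig())

s_at = lambda sec: stress.s[np.searchsorted(stress.t, sec)]
print(f"window capacity: {sk.window_capacity(sk.StressConfig())} samples (40 min at 20 Hz)")
print(f"stress at t=100 s (calm):        {s_at(100):+.2f}")
print(f"stress at t=151 s (just tensed): {s_at(151):+.2f}")
print(f"stress at t=290 s (still tense): {s_at(290):+.2f}")
print()
print("The z-score spikes when the grip departs from its own history and")
print("decays as the window absorbs the new grip level - the adaptation that")
print("makes the score person- and sensor-calibration-free.")
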