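# Methods

## Stress estimation

The stress score of the latest grip-force sample is the moving z-score
`S = (CGF − SMA) / SMSD` over a trailing window capped at
`window_seconds × rate_hz` samples (default 2400 s × 20 Hz = 48,000).
Choices that matter:

* **Population divisor.** SMSD divides the summed squared deviations by the
  sample count, not count − 1.  At 48,000 samples the difference is
  negligible, but the population form is the definition used throughout.
* **Current sample included.** The newest sample enters the window before
  SMA/SMSD are computed.  This keeps the streaming update one-pass; with
  windows of thousands of samples the alternative differs by O(1/n).
* **Constant-grip guard.** When the window is (numerically) constant,
  SMSD = 0 and S is 0/0.  The estimator substitutes a floor
  (`sd_floor`, default 1e-9) for SMSD, so a constant grip scores S = 0 — the
  "no information" case holds the difficulty steady instead of crashing a
  real-time controller.
* **Warm-up.** No score is emitted during the first 12 s (240 samples), the
  same interval during which every policy holds the initial 6 p/s speed.
* **Numerical stability.** The streaming path keeps running sum and
  sum-of-squares and re-sums them from the buffer once per full window of
  updates; drift against direct recomputation stays below 1e-6 over 10^6
  samples (tested).  The offline path (`batch_stress`) is an independent
  pandas rolling-window computation; the two agree to 1e-9 (tested).

## Difficulty policies

All speeds in pixels/second, clamped to `[min_speed, max_speed]` =
[2, 200].  The floor prevents a zero or negative asteroid speed; the
ceiling bounds the time-ramp's unbounded escalation.

* constant: 30 p/s (or the yoked value) after the initial phase;
* time ramp: +2 p/s per *completed* 5-s interval, so speed at t = 12 s is
  still 6 p/s;
* stress-adaptive: ±2 p/s steps at threshold ±0.5, strict inequalities
  (S exactly 0.5 does not trigger — an arbitrary tie-break fixed for
  bit-reproducibility).

The controller tick is 1 s (configurable).  The underlying design is
described only as "continuous"; 1 s puts the ±2 p/s adaptive steps on the
same dynamic scale as the 2-p/s-per-5-s ramp while leaving 20 force samples
between decisions.  In the multi-session protocol the controller restarts
each session at the initial speed: each session is a fresh game with its own
12-s initial phase.

## Synthetic trainee

The generator is this package's own construction; the literature it
emulates supplies only the qualitative shape (inverted-U stress-performance
relation, saturating learning curve).  No parameter claims empirical
calibration.

* Latent stress `X` is an Ornstein-Uhlenbeck process, reversion rate
  `theta = 0.1 /s`, diffusion `sigma = 0.3`, equilibrium
  `kappa (speed − speed_ref)` with `kappa = 0.04` per p/s and
  `speed_ref = 30 p/s` during play, 0 during rest.  Discretisation is the
  exact OU transition at 0.05-s steps.
* Grip force = `g0 + g1 X + N(0, gnoise)` with g0 = 5, g1 = 1.5,
  gnoise = 0.2 sensor units, clipped at zero (a force sensor cannot read
  negative).
* Hits: inhomogeneous Poisson, rate
  `h_max · exp(−(X − s_opt)²/(2 u_width²)) · (1 − e^{−t/tau_learn})` with
  `h_max = 1.2 /s`, `s_opt = 0`, `u_width = 1`, `tau_learn = 240 s` of
  cumulative task time.
* Losses: Poisson, rate `loss_base (speed/speed_ref)(2 − learned)` with
  `loss_base = 0.005 /s` — faster asteroids cost lives, novices lose twice
  as often as trained players.
* Events are realized by thinning dominating homogeneous processes
  (`h_max` for hits; the loss rate at `max_speed`, fully unlearned, for
  losses).  Stress diffusion, force noise, hit thinning and loss thinning
  draw from independent substreams of the seed; a seed reproduces a session
  bit for bit.
* Protocol: three 10-min task sessions, each preceded by 2 min of rest.
  Rest produces force (the window keeps filling; resetting it at rest is a
  protocol flag) but no events, and relaxes latent stress toward baseline.
* Clocks: force and latent stress are on the wall clock; events, speed and
  estimated stress are on the game clock (cumulative task time).  Learning
  curves are built on the game clock — leaving 2-min event-free rest gaps in
  the curve would plant an artificial zero-slope "knee" at the first rest
  for every condition.  `SessionRecord.segments` maps between the clocks.

What the generator does **not** emulate: within-game structure (respawns,
aiming geometry), fatigue or boredom, strategic slowing, inter-individual
parameter variation, or any fitted relation to real grip-force
distributions.  Passing tests therefore demonstrate that the pipeline's
machinery behaves as specified under a plausible generative model, not that
stress-adaptive training outperforms controls in humans.

## Learning-curve knee

`find_cutoff` smooths the curve, takes the first derivative by central
finite differences, finds the slope maximum, and returns the first grid
point after it where the slope is at or below `slope_fraction` (default
0.5) of the maximum.

* **Smoother.** Savitzky-Golay, quadratic, window 15 s.  A plain centred
  moving average was considered and rejected: its truncated windows at the
  boundary of the defined region damp the slope exactly where learning
  curves are steepest, which biases the detected maximum down and pushes the
  cutoff several seconds late — outside tolerance even on the closed-form
  curve `1 − e^{−t/60}`, whose knee at `60·ln 2 ≈ 41.6 s` the implementation
  recovers within 2 s (tested).  Savitzky-Golay's edge handling fits a local
  polynomial instead and is slope-unbiased to first order.
* **Undefined points.** `ln(hits − 10·losses)` is undefined while the
  argument is non-positive — routine early in a session and, in loss-heavy
  conditions, again later.  Undefined points are flagged (NaN) and never
  imputed.  The knee is computed on the *longest contiguous defined run*
  (earliest on ties): the analyzable stretch of the curve.  At least 10
  defined points are required.
* **Degenerate curves.** A never-flattening curve (straight line) raises a
  no-knee error; an everywhere-undefined curve is rejected.  In cohort
  analyses such participants enter the outcome table as missing and are
  dropped (with a count) before model fitting.

A known and deliberate property of this criterion: log-count learning curves
are steepest right where they first become stably defined, so the half-max
cutoff fires in that early region.  The y-value at the cutoff consequently
tends to *reward* conditions whose curves stabilise late (they are measured
further up the curve).  In the in-silico experiment this makes
`performance_at_criterion` higher for the time-ramp arm — whose curve
repeatedly collapses under loss pressure and re-stabilises mid-protocol —
than for the adaptive arm, even while the adaptive arm's
`time_to_criterion` is far shorter; and it makes the adaptive and yoked
constant arms statistically indistinguishable on both outcomes, since the
threshold controller regulates the z-score against the operator's own
40-min history (not against the performance-optimal stress) and confers no
hit-rate advantage over a well-matched constant speed in this trainee
model.  `scripts/acceptance.py` reports the measured per-condition means;
the directional acceptance test documents the expected-versus-observed
orderings and is allowed to fail on the performance axis rather than
adjusting the generator to force agreement.

## Evaluation

With one outcome row per participant, a mixed model over the three-arm
design is not identifiable beyond its fixed-effects core, so
`compare_conditions` fits OLS with the 3-level condition factor (optional
covariates).  The planned contrast codes stress-adaptive +1 and each control
−1/2; its estimate is the adaptive mean minus the average of the control
means, and its t equals the textbook pooled-variance contrast (cross-checked
to 1e-8 against a hand ANOVA in the tests).  Significance is two-sided at
0.05 with no multiplicity correction across the two outcomes.  Degenerate
tables (zero between- or within-group variance) report a null effect rather
than 0/0 noise.

Yoking is the time-weighted mean of the adaptive arm's speed traces,
computed per batch (default 4 batches; the adaptive third of each batch is
simulated first, exactly as the batch protocol prescribes).  The sample size
of 15 per condition is carried as a design constant.

## Problem sizes

Defaults used by the shipped analyses: full protocol = 43,200 force samples
per participant; the acceptance script runs 30 replicate cohorts of 45
participants (1,350 simulated participants) and the test suite's directional
check runs 100 default cohorts plus 60 null cohorts.  The simulation kernel
is numba-compiled; one full-protocol participant takes ~10 ms after the
first call.
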