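# Methods

## Estimation model and calibration

The device model is a static population-level linear regression over the C
multi-sensor channels, `ĝ_uncal(t) = β·x(t) + intercept`, with `β`
identified by L1-penalised least squares (LASSO) on pooled
(channel-vector, RBG) pairs from the identification sessions.  Pairing
uses the grid sample nearest each RBG instant; with a 20 s grid against
10–20 min RBG sampling the nearest sample is always within half a step, so
the pairing is unambiguous.

Per-session deployment applies baseline calibration: at a calibration
instant `t_cal` (an RBG instant), `b = ĝ_uncal(t_cal) − g(t_cal)` and
`ĝ(t) = ĝ_uncal(t) − b` from `t_cal` onwards; `b` is held until the next
calibration instant.  Written this way the calibrated profile passes
through the reference value exactly (shift-to-match), which is the
behaviour the calibration rule is meant to have; before the first
calibration instant the estimate is undefined and excluded from every
metric.  The initial calibration instant is the first RBG at or after the
75-min sensor–skin equilibration.

### Identification details

* **Session fixed effects.**  Before the penalised fit, channels and
  targets are centred within each session (equivalently: unpenalised
  per-session intercepts).  Each session carries an additive baseline
  inside its glucose-related channels — precisely the quantity the
  calibration parameter `b` absorbs at deployment — and with a single
  pooled intercept those baselines act as errors-in-variables that
  attenuate `β` by roughly `var(b)/var(g)`.  The within transformation
  removes them, so that in the noise-free limit the generative model is
  recovered exactly.  The reported model intercept is the population one,
  `mean(g) − β·mean(x)` over all pooled pairs.
* **Standardisation.**  Channels are scaled to unit standard deviation on
  the identification data (computed per CV training fold); coefficients
  are mapped back to the original units.
* **Penalty selection.**  The L1 strength is selected from a log-spaced
  grid (default 1e-4 … 10^1.5, 12 points) by cross-validation grouped by
  session — no session contributes to both training and validation of a
  fold — scoring within-session-centred residuals, i.e. the error that
  survives calibration.  Ties prefer the larger penalty (sparser model).
* The regression target is the RBG samples only (no interpolated profile);
  sparse targets are what a real study provides.

## Accuracy indices

Per session, over RBG instants at or after the initial calibration:
`RMSE = sqrt(mean (g−ĝ)²)` and `MAD = mean |g−ĝ|` in mg/dL,
`MARD = mean |g−ĝ|/g` in percent, with `ĝ` read at the grid sample
nearest each RBG instant.  By default the RBG points used for
(re)calibration are *included* in the score: their zero-error contribution
is exactly the mechanical benefit of an extra calibration point, and the
Monte Carlo null controls for the number of points used, which presumes
that contribution is part of the score.  A flag excludes them for
sensitivity analyses.  Aggregation across sessions uses the unweighted
mean and the sample (n−1) standard deviation, sessions being the
independent units (different study days).

## Sweat-event detection

The sweat-sensitive channel is smoothed with a moving average (default 5
samples) and differentiated with central finite differences (one-sided at
the endpoints).  An event opens at the first sample whose derivative
exceeds the threshold TH with no open event within the refractory window
(default 10 min, merging the multi-sample rise of one physiological
episode); only positive-going crossings trigger, since sweat onset raises
the signal.  TH is selected from a candidate pool as the value maximising
F1 between detections and annotated events (matching window 10 min), ties
going to the larger TH (fewer false alarms): F1 is one concrete reading of
"best trade-off between missed and identified events".

## Calibration schemes and the Monte Carlo null

All schemes share the initial calibration entry (time and `b`).  The
event-triggered scheme adds one entry at the first RBG strictly after each
detected event (events without a later RBG contribute nothing; duplicate
instants collapse).  Scheduled schemes add one entry at the first RBG at
or after `t0 + Tc` for each delay in the grid (Tc = 1…7 h, plus the
combined 1 h + 4 h schedule).  The random scheme draws Ns distinct RBG
instants uniformly *without replacement* from the instants strictly after
`t0` — recalibrating twice at one instant would be a no-op, so replacement
is immaterial and uniqueness keeps plans well-formed.

The null distribution is built from N iterations (default 1,000).  Each
iteration draws an independent random plan per test session — the RNG
stream is derived from (seed, iteration, session id), making the loop
deterministic and parallel-safe — applies the calibration, scores every
session and stores the across-session mean of each index.  `Ns` is the
mean detected-event count over test sessions rounded half away from zero
(at least 1 if any event exists) for the sweat scenario, and the number of
scheduled delays otherwise.  `percent_better` counts iterations with a
*strictly* smaller mean index than the scheme under test; ties count as
not-better, the conservative direction for the scheme.

Scheme-vs-scheme significance: per-session index values of the two schemes
are compared with the two-sample Student t-test when both groups pass a
Kolmogorov–Smirnov normality check at α = 0.05 (parameters estimated from
each sample — the Lilliefors caveat is acknowledged; the gate is a
screening device, not a calibrated test), otherwise with the Wilcoxon
rank-sum test.  Groups are treated as independent.

## The simulator

The generator emulates the study conditions the methodology assumes —
not the physics of any particular device.

* **Study design**: 45 sessions dealt round-robin over 6 subjects, 8 h at
  20 s (1,440 samples), RBG at t = 0 and then at i.i.d. uniform 10–20 min
  gaps, with 2 % coefficient-of-variation measurement noise.
* **Glucose**: a euglycaemic plateau (90–140 mg/dL) for the 75-min
  equilibration, then a sum of logistic ramps toward plateau levels drawn
  in 60–300 mg/dL, clipped to 40–400 mg/dL.  Only smoothness and range
  matter to the methodology, so logistic ramps stand in for whatever
  induced profile a protocol prescribes; an amplitude factor of 0 yields a
  constant profile for degenerate-case tests.
* **Channels**: glucose-related channels (default 30 of 150) couple
  `gain_c·(g(t) + b_true − G0)` with gains 0.01–0.03 a.u. per mg/dL around
  the population centre G0 = 120 mg/dL, plus `κ_c·s(t)` sweat leakage
  (κ = 0.05–0.2 on half of them), a slow sinusoidal drift (amplitude
  ~0.3 a.u., period 2–8 h) and white noise (sd 0.05 a.u.).  The designated
  sweat channel records the raw transient `s(t)` on a constant resting
  level; remaining channels are pure nuisance.  Gains and κ are device
  properties shared across subjects — a single population `β` can only
  exist under that assumption, and it makes the sweat disturbance exactly
  representable (hence compensable) by the linear model, which is the
  "fully compensated" regime of the sweat case study.  Setting the leakage
  scale to 0 gives a κ = 0 device.
* **Baselines**: subject baseline means are spread evenly over
  ±25 mg/dL; per-session `b_true` adds N(0, 4²) mg/dL.  The baseline is
  realised *inside* the glucose channels, so the calibration rule recovers
  it: `β·x + intercept = g + b_true` in the noiseless limit.
* **Sweat events**: per session, a uniform count in {1, 2, 3} of events
  with onsets separated by ≥ 30 min, linear rise over 1–3 min to an
  amplitude of 3–8 a.u., exponential decay with a 10–30 min constant, and
  (with probability ½) a persistent offset of 0.5–1.5 a.u. — the level
  does not always return to its pre-event value.
* **Drift scenario**: an optional uncompensated baseline step (default
  30 mg/dL, 55 min after the initial calibration instant) enters every
  glucose channel through its gain.  It is indistinguishable from a
  glucose change within the channel space, so no linear model can
  compensate it — the regime in which scheduled recalibration genuinely
  helps.
* **Seeding**: one master seed spawns per-session substreams keyed on a
  stable hash of the session id, so regeneration is order-independent and
  byte-identical.

What the simulator does **not** emulate: physiological glucose–insulin
dynamics, the dielectric physics of any sensor, inter-subject variation in
channel couplings, temperature/movement artefacts beyond generic nuisance
channels, or missing samples.  Passing tests therefore demonstrate that
the methodology behaves correctly on data with the assumed structure; they
say nothing about the absolute accuracy any real device would reach.

## Numerical choices and problem sizes

* Times are seconds from session start throughout; hours/minutes appear
  only at the CLI boundary.  Files with grid gaps are rejected rather than
  imputed — the pipeline assumes a complete grid and any imputation rule
  would be arbitrary.
* `compute_baseline` accepts the RBG nearest the requested instant within
  a 5-min window and errors otherwise.
* The Monte Carlo loop evaluates plans directly at the RBG evaluation
  instants from a per-session cache (uncalibrated predictions and
  candidate baselines precomputed); the cache path is tested to agree with
  the full plan-construction + series-calibration path to 1e-12.
* The test suite runs its studies at reduced size (12–16 channels, 8–12
  sessions) where the property under test does not need the full study;
  the full 45-session, 150-channel conditions are used for the scenario
  and detector checks and in `scripts/acceptance.py` (N = 1,000 Monte
  Carlo iterations there, N = 500 in the scenario tests).
* The percentile-calibration check (scheme drawn from the null itself →
  percent-better uniform on [0, 100]) uses 200 repetitions of an N = 150
  null on a 4-session subset.

## Known limitations

* The KS normality gate with estimated parameters is anti-conservative;
  it is retained because it is the gate the methodology prescribes.
* Threshold selection needs annotated events; on real data those would be
  human annotations, here the simulator's ground truth.
* With identification and test halves drawn from the same study, the
  split controls overfitting of `β` but not covariate shift; the swap
  consistency check (exchanging the halves) is available through
  `split_dataset` but not automated in the report.
* `percent_better` has resolution 100/N; N = 1,000 gives 0.1 %.
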