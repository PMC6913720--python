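# Methods

## Model

Net metabolic power during treadmill walking is modelled as a piecewise
function of two mechanical power regressors.  The kinetic regressor
*P*<sub>K</sub> = 2 *M v*² *f* arises from treating each stride as one
acceleration–deceleration cycle of both legs: the work per cycle is
4 · ½ *m v*₀² = 2 α β² *M v*², where *m* = α *M* is the combined leg mass and
*v*₀ = β *v* the peak leg speed.  The unmeasurable ratios α and β and the
chemical-to-kinetic conversion efficiency η<sub>K</sub> are absorbed into
the fitted gain γ = α β² / η<sub>K</sub>, leaving the measurable grouping
2 *M v*² *f*.  The potential regressor *P*<sub>U</sub> = *M g v* sin *θ* is
the rate of change of gravitational potential energy; its gain *b*₀ is the
inverse of the chemical-to-potential efficiency η<sub>U</sub>.  Downhill,
a linear model would predict arbitrarily negative cost on steep descents;
a quadratic correction *b*₁ *P*<sub>U</sub>²/*P*₀ (kept dimensionless by
the *P*₀ normalization) models the braking work that makes the cost curve
turn back up.  With the published coefficients the downhill minimum falls
near −10° to −14° depending on *M* and *v*, consistent with the classical
observation of a minimum energy cost at moderate downhill grades; for
light, slow walkers the stationary point can fall just outside the
−14° validated range.

Assumptions worth making explicit: the trunk moves at constant speed (all
kinetic fluctuation is in the legs); step length approximately equals
standing height, which ties cadence to speed through *f h* ≈ 0.52 *v* +
1.02 (m/s); efficiencies are constant across subjects of one gender; and
coefficients are gender-pooled averages, not individual parameters.

Internally all mechanical powers are computed in watts with
*g* = 9.80665 m/s² and converted at the model boundary with 1 kcal =
4184 J; because γ, *b*₀, *b*₁ are dimensionless and *b*₁ is expressed in
units of *P*₀, predictions are invariant to the internal unit choice (this
is property-tested to 1e-12 relative).  Angles are degrees at every public
interface, converted to radians internally.  The θ = 0 boundary is
assigned to the uphill branch; the branches agree there identically since
*P*<sub>U</sub>(0) = 0.

### Coefficient decomposition

With η<sub>K</sub> = η<sub>U</sub> = 1/*b*₀ assumed, the peak-leg-speed
ratio can be recovered from fitted coefficients as
β = √(γ/(α *b*₀)), using leg-mass fractions α = 0.185 (women) and 0.165
(men) from anatomical tables.  For the published men's coefficients this
gives β = 1.360, matching the published 1.36.  For women the same formula
gives 1.50 against a published 1.47, and 1/*b*₀ gives η<sub>U</sub> = 0.629
against a published 0.547 (men: 0.590 vs 0.596).  The published women's
values are not reproducible from the published inputs under any
reconstruction we found; we report the formula's value and do not force
agreement.

## Step detection

Foot contact is classified from the per-foot sum of the eight {0,1,2}
pressure channels by hysteresis: starting on-ground, a frame goes
off-ground when the sum falls strictly below the lower threshold (default
2) and returns on-ground when it rises strictly above the upper threshold
(default 5).  Strict inequalities are a deliberate reading of
"below"/"above": boundary sums hold the current state.  The dual threshold
tolerates a sensor stuck at 1 (swing sums of 1 still classify off-ground)
and brief mid-stance dips.  The implementation is a vectorized
formulation — each frame takes the state demanded by the most recent
threshold crossing — and is tested for exact equality against a direct
recursive evaluation of the transition rules on random sequences.

Stride frequency per foot is the toe-off (on→off) count divided by the
observation time after trimming 50 s from the head and 10 s from the tail;
a transition is counted when its off-ground frame lies inside the trimmed
window, so a final unterminated swing still contributes its toe-off.  The
reported frequency is the mean of the two feet and is the per-foot cycle
rate (the *f* in *P*<sub>K</sub> and in the cadence relation).

## Calorimetry

The gross rate is the OLS slope of cumulative kcal against time over the
trimmed window rather than an endpoint difference, which is more robust to
measurement noise; for an exactly linear series every trim choice gives
the identical rate.  The basal rate is subtracted to give the net walking
power; the default formula is the revised Harris–Benedict equation
(Roza & Shizgal 1984, kcal/day ÷ 86 400) because the basal-rate reference
in the source protocol is not further specified — the model is pluggable
(a per-second constant can be configured instead).  Negative net rates are
reported with a warning, not clamped, unless clamping is requested.

## Two-stage calibration

Stage 1 regresses measured net power on [*P*<sub>K</sub>, *P*<sub>U</sub>,
1] over θ ≥ 0 trials (statsmodels OLS), yielding γ, *b*₀, *P*₀ and the
stage-1 adjusted R².  Stage 2 fixes those values and fits *b*₁ alone on
θ ≤ 0 trials; with residual r = P − γP<sub>K</sub> − b₀P<sub>U</sub> − P₀
and u = P<sub>U</sub>²/P₀ the least-squares solution is the closed form
b₁ = Σru/Σu².  Flat trials enter both stages but carry zero weight in
stage 2 (u = 0), so their inclusion is harmless (tested).  Trials are
pooled across participants without weighting; fitting is per gender.
Coefficient signs are unconstrained, with a post-fit warning if any is
negative.  Reported metrics: RMSD of the full piecewise prediction over
all of a gender's trials (kcal/s and kcal/min), absolute percent error
100·|P − P′|/P′ against the calorimetry standard, and adjusted R².

## Synthetic data

The generator produces studies that satisfy the model's assumptions
exactly, so an end-to-end recovery failure localizes bugs to the
processing code.  Defaults mirror the calibration study conditions:
inclines {−14, −9, −4, 0, 4, 9, 14}°, 300 s sessions, observation noise
sd 0.016 kcal/s on net power (the residual scale of the calibrated model),
and cohort anthropometrics with pooled mean height ≈ 168.3 cm, mass
≈ 68.1 kg, ages 20–60.  Choices the source conditions do not pin down,
made once here:

- speed set {0.8, 1.1, 1.4, 1.7, 2.0} m/s, bracketing normal walking;
- per-gender height/mass distributions (women N(161, 6) cm, N(61, 10) kg;
  men N(175, 6) cm, N(74, 10) kg, truncated at ±3 sd) — synthetic values
  matching the pooled cohort moments, not estimates of the real per-gender
  distributions;
- cadence scatter sd 0.1 m/s on the *f h* product about the empirical
  line, matching the visual spread of cadence–speed data;
- stance occupies 62% of the gait cycle; sensors load heel-to-toe, each
  for half the stance, with 10% of loaded readings flickering from 2 to 1;
  the right foot runs half a cycle out of phase;
- calorimetry sampled at 1 Hz with a 30 s linear ramp-in (the measured
  rate takes roughly 30 s to stabilize, which the 50 s head trim must
  absorb) and per-sample increment noise sd 0.005 kcal, clipped at zero to
  keep the cumulative series nondecreasing.

What the generator does **not** emulate: inter-stride timing variability,
sensor drift beyond a stuck channel, fatigue or drift in metabolic rate,
breath-by-breath calorimetry structure, and any real covariance between
anthropometrics and gait style.  Passing round-trip tests therefore
demonstrates correctness of the processing chain under the model's own
assumptions, not accuracy on real walking data.

When a generated net power plus its basal rate would be negative (possible
in the extreme noise tail for light subjects walking slowly downhill), the
net rate is floored so the gross calorimetry rate is nonnegative; at the
default noise level this is a < 0.1% tail event.

## Statistical design of the recovery checks

Parameter-recovery tolerances (5% relative) are assessed on the **mean**
over seeded replicate studies (20 replicates of the 1,000-trial-per-gender
study; 12 replicates of the 40-subject end-to-end study).  A single study
of these sizes carries sampling error comparable to the tolerance — at
n = 1,000 per gender the women's *b*₁ estimate has a per-study sd near 7%,
dominated by propagation of stage-1 estimation error into the stage-2
residuals — so a single-seed check would measure seed luck rather than
estimator accuracy.  The replicate mean tests what the tolerance is about:
that the estimator is centred on the generating values.  Monte-Carlo error
of the reported means is below 2% for every coefficient.

## Numerical notes and limitations

- Stage-1 singularity (collinear regressors) and an all-flat stage-2
  (Σu² = 0) raise explicit errors rather than returning NaN.
- The percent-error denominator is the reference measurement; zero
  references are rejected.
- Step-frequency quantization error is at most one stride over the trimmed
  window (≤ 1/240 Hz for a 300 s session), negligible against the 5%
  round-trip tolerance.
- The model is calibrated for |θ| ≤ 14°; conditions outside that range
  warn and extrapolate.
- Problem sizes used by the test suite and acceptance script (1,000 trials
  per gender, 40-subject end-to-end studies, 300 s traces) are the package's
  reference study sizes; they reproduce the conditions the calibration
  assumes while keeping full runs fast.
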