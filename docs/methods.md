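# Methods

`aquamet` implements the analysis chain used in whole-animal respirometry
studies of fish cardiorespiratory performance — here modelled on a
two-treatment (sham-operated vs coronary-ligated) by two-sex design in
maturing coho salmon — together with a synthetic cohort generator that makes
every stage testable in the absence of deposited raw data.

## Oxygen uptake from intermittent-flow traces

During each sealed measurement phase the dissolved-O2 concentration declines
approximately linearly.  The mass-specific uptake is

    MO2 = |dO2/dt| * (v_R - v_F) / m

with `v_R` the respirometer volume (l), `v_F` the fish volume (l, assuming
1 kg of fish displaces 1 l) and `m` the body mass (kg).  Slopes are ordinary
least squares of O2 on time per sealed phase; a cycle is *validated* when
its regression is negative and has r² > 0.90 (an automated stand-in for
visual negative-linearity checks).  The canonical rate unit throughout the
package is mg O2 kg⁻¹ min⁻¹ — the unit on which the study's results are
reported — with an explicit ×60 converter to mg O2 kg⁻¹ h⁻¹, the unit its
methods text names; the package treats per-minute as canonical rather than
resolving that editorial discrepancy.

No background-respiration correction is applied by default (none was applied
in the modelled study); `process_trace` exposes a `blank_slope` hook for
users who measure one.  Likewise no initial-seconds trimming for mixing lag
(`wait_s`, default 0).

## Metabolic metrics

* **MMR** — over the first post-exhaustion measurement, every window of
  duration ≥ 180 s is advanced in 1-s steps; the steepest slope among
  windows with r² > 0.95 is MMR.  The scan is an exact enumeration (slices
  are at most a few hundred seconds, so thinning the window lengths buys
  nothing; a `lengths=` ladder remains available for long slices).
  Tie-break: slopes within one part in 10⁹ are treated as tied — an exact
  float tie-break is ill-defined when e.g. a perfectly linear slice makes
  every window mathematically equal — and the earliest window of the
  shortest length wins.  If no window passes the r² gate, MMR is
  *undetermined* and flagged, never filled.
* **RMR** — the 0.10 quantile (linear-interpolation convention, numpy
  default) of all validated cycle uptakes, defined only when ≥ 60 validated
  cycles exist.  "Lowest 10% quantile" is read as the 0.10 quantile value,
  not the mean of the lowest decile; the exact quantile type used by any
  given field pipeline is rarely stated, shifts RMR by <1% at n ≥ 60, and is
  configurable here.  By default all validated cycles enter the sample —
  the low quantile ignores the elevated early-recovery cycles — with an
  `overnight_start_h` option to restrict to late cycles.
* **AAS / FAS** — `MMR − RMR` and `MMR / RMR`, asserted as exact identities
  for every fish.
* **EPOC** — the cycle-level recovery points, starting at the midpoint of
  the MMR window (MMR is the curve's first ordinate; the precise anchor
  within the first measurement is a free choice), are interpolated with a
  monotone shape-preserving cubic (PCHIP).  A natural cubic spline can
  overshoot below RMR between points; PCHIP cannot.  Recovery ends at the
  first down-crossing of the interpolant through RMR that *stays* at or
  below RMR until the midpoint of the following inter-sample gap — a guard
  against noise-induced early termination.  EPOC is the integral of
  (uptake − RMR) to that time; when the record ends above RMR the estimate
  is censored and reported as a lower bound over the whole record.

For the generator's exponential recovery (below), EPOC has the closed form
`(MMR − RMR)/k`; the PCHIP estimate reproduces it within 0.2% at 10-min
sampling and within 10⁻⁵ at 1-min sampling (the tests assert the looser 2%
and 0.5% bounds).

## Other endpoints

Somatic indices are `organ mass / body mass × 100`; percent compact
myocardium is `compact dry mass / (compact + spongy) × 100`.  CTmax is
`start temperature + ramp rate × time to loss of equilibrium` for a
constant 0.1 °C min⁻¹ ramp, with a logged temperature (when available)
taking precedence and a 0.5 °C disagreement raising a warning.  The venous
PO2 of a sealed sensor chamber is read as the mean of the final 30 s once
the tail slope falls below 0.5 Torr min⁻¹ — the plateau criterion is this
package's own; the modelled protocol only states that readings plateau at
about 3 min, and the default tolerance reproduces that timing on
exponential approach curves with a 30 s time constant.

## Statistical workflow

Endpoints pass a normality gate (Shapiro–Wilk, with Levene across treatment
groups) applied per endpoint across all observations — one transform
decision per metric; failures are log10-transformed and retested.
Treatment × sex effects are tested with type III sums of squares under
sum-to-zero coding (type III is contrast-dependent; sum-to-zero is the
convention under which it tests main effects in the presence of an
interaction).  A non-significant interaction is dropped and main effects
reported from the additive type II fit; on balanced designs the two types
coincide exactly, which the tests assert.  A constant response is reported
as all-zero F statistics rather than 0/0.

Repeated blood/recovery endpoints use a linear mixed model with a per-fish
random intercept.  Candidate fixed-effect structures — every subset of the
two-way interactions on top of the three main effects, plus the full
factorial — are fit by ML and ranked by BIC; the winner is refit by REML.
Terms are tested with Wald chi-square statistics (the convention in the
modelled study's reports); an F version with containment-style denominator
df (`n_obs − k_fixed − n_fish + 1`) is emitted alongside because software
conventions differ.  A Satterthwaite approximation would be preferable but
is not exposed by the underlying fitter; the containment df is conservative
at these designs' sizes.  A between-fish variance below 0.1% of the
residual variance is treated as a singular fit: flagged, and the model
falls back to ordinary least squares.

Pairwise comparisons use Tukey's HSD on estimated marginal means (equally
weighted reference grid), with p-values from the studentized-range
distribution (`p = SR.sf(|diff|/se · √2, k, df)`); at k = 2 this equals the
unadjusted two-sided t test.  A compact letter display is built by the
insert-and-absorb algorithm, guaranteeing that no letter spans a
significant pair and every non-significant pair shares one.  Endpoints
whose treatment × sex cells fall below 5 observations drop sex and use a
one-way treatment ANOVA (the small-cell guard; threshold configurable).

## The synthetic cohort generator

The generator is the package's stand-in for the study's fish, and its
defaults *are* the study conditions:

* **Recovery kinetics** — uptake decays from MMR toward RMR as a single
  exponential `RMR + (MMR−RMR)·e^{−kt}`, k = 0.05 min⁻¹ (time constant
  20 min, recovery essentially complete within ~2 h).  A single exponential
  is the simplest monotone model consistent with the steadily declining
  recovery curves such experiments report, and its closed-form EPOC makes
  it an analytic oracle.
* **Cycle-level discretization** — within each sealed phase the programmed
  consumption is held constant at the recovery curve evaluated at the phase
  start.  Metabolic rate varies slowly relative to a 4–6 min phase, and a
  continuously decaying rate would make the trace non-invertible by *any*
  cycle-level estimator (a 180-s window average of the exponential sits ~7%
  below its initial value at k = 0.05 min⁻¹); with cycle-level programming,
  noiseless traces invert exactly, which the round-trip tests exploit.
* **Schedule** — 4-min first measurement at time zero (end of chase), then
  15-min cycles of 9 min flush + 6 min sealed at 1 Hz (a typical optode
  logging rate) for ~20 h, ≈ 80 overnight cycles.  Flush phases re-approach
  air saturation (10.78 mg l⁻¹ at 12 °C freshwater) exponentially with a
  120 s time constant; their exact shape is irrelevant downstream because
  flush samples never enter a fit.  The programmed concentration is clamped
  at the 80%-saturation floor (the husbandry rule such protocols enforce)
  and the cycle flagged if clamping occurs; with the default truths the
  floor is not reached.
* **Spontaneous activity** — overnight cycle-level consumption is jittered
  by a *folded* lognormal factor `exp(cv·|Z|) ≥ 1` (cv 0.05, first
  post-chase cycle unjittered).  Activity can only elevate uptake above
  rest — that asymmetry is the entire rationale for estimating RMR by a low
  quantile — and under it the 0.10-quantile estimator recovers the
  programmed resting rate to ~+0.6%.  A symmetric (median-1) lognormal
  would instead bias the quantile ~6% low and misrepresent what the
  estimator is for.  One consequence: measured uptake never dips below the
  *true* resting rate, so EPOC's return-to-RMR is defined against the
  *estimated* RMR, exactly as with real data.
* **Sensor noise and drift** — additive Gaussian noise per sample
  (default sd 0.005 mg l⁻¹) and optional linear drift (default 0).
* **Endpoints** — per-fish truths are drawn around treatment × sex cell
  means: metabolic rates (RMR sd 0.35, MMR sd 2.0 mg O2 kg⁻¹ min⁻¹ between
  fish — chosen once so that a 16% treatment effect on MMR at n ≈ 13/19 is
  borderline-significant, matching the magnitude of the published F
  statistics, since the study's group s.e.m. table is not available in
  text form), CTmax (sd 0.8 °C around 26.9/25.8), five-point blood panels
  (cortisol and glucose drawn on the log10 scale, so the transform gate is
  exercised), and organ masses generated from somatic-index truths.
  Blood/organ means not printed in the study text (e.g. the sham 60-min
  venous PO2, most panel values, all organ indices) are synthetic fillers
  at physiologically plausible values for maturing coho; they affect no
  recovery target.

What the generator does **not** emulate: post-chase activity bursts or
handling artefacts (no spike filtering exists downstream, so none is
simulated), optode calibration drift beyond the linear term, background
(microbial) respiration, hydrodynamic mixing lags, and any correlation
between a fish's metabolic rates and its blood chemistry.  Passing the
recovery tests therefore shows the estimators are correct and calibrated
*for data of this structure*; it cannot certify behaviour on pathologies
the generator omits.

## Parameter recovery and known limitations

`scripts/acceptance.py` (and the mirror tests) set generator truth to the
published group values — resting rates 2.96/2.92 mg O2 kg⁻¹ min⁻¹, a 16%
MMR reduction, CTmax 26.9/25.8 °C, 15-min venous PO2 23.0 Torr — at the
published group sizes, and require the pipeline's averaged estimates to
recover them.  The sham MMR itself is not printed; 11.94 mg O2 kg⁻¹ min⁻¹
is adopted so that the absolute scope is ~9 and the published 16% fixes the
ligated mean at 10.03.

One published figure cannot be reproduced from the other published
figures: with resting rates 2.96/2.92 and a 16% MMR reduction, the
factorial-scope reduction is algebraically
`1 − 0.84·(2.96/2.92) ≈ 14.9%`, not the published 20% (the underlying
group-mean table, which must differ slightly from the recovery-figure
caption's resting rates, is not available as text).  The package recovers
the implied ~15% and documents the discrepancy rather than adjusting the
ligated resting rate upward (~3.11 would be needed — contradicting the
published statement that resting rates did not differ between treatments).

Problem sizes used throughout (100 simulated cohorts per recovered
quantity; 500 null cohorts for the type-I-error calibration of the
gate→ANOVA chain; 1000 slices for the window-scan equivalence check) were
chosen so Monte-Carlo error is comfortably below every tolerance asserted.
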