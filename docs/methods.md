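# Methods

## Data model

Daily process ratings are long-format (patient, day, item, value) on a
declared bounded scale; day indices are 0-based integers from each patient's
first rating day (all analyses operate on day counts, never calendar dates).
Missing ratings are carried as NaN.  Outcome series (Y-BOCS totals, 0–40)
are sparser — about twice per week — and event metadata records treatment
start/end and, for participants, the onset day of exposure with response
prevention (ERP).  Item scale bounds are mandatory configuration (default
[0, 6]): the complexity measures are undefined without the scale range R,
and values are validated against the bounds, never silently clamped,
because clamping would distort both F and D.

Short gaps (≤ 2 consecutive missing days by default) are linearly
interpolated; longer and leading/trailing gaps stay missing, and any window
containing a remaining missing value yields an *undefined* complexity value,
flagged as NaN rather than zero — zero is a meaningful value (stability),
not a missing code.

## Dynamic complexity

C = F·D in a moving window of m = 7 consecutive daily points; the window
anchor is its first day, so the value at anchor t summarizes days t…t+6.
Series shorter than 20 points are rejected (validity floor for a windowed
statistic this coarse).

**Fluctuation F.**  Turning points are the window's two endpoints plus every
local extremum.  The window is run-length encoded; an interior run whose
neighbouring runs lie on the same side of it (a peak or trough, possibly
flat) contributes turning points at *both* of its ends, while plateaus
inside a monotone stretch and terminal plateaus are absorbed into the
surrounding segment.  F is the sum of |y(n_{k+1}) − y(n_k)| / (n_{k+1} −
n_k) over successive turning points, divided by R·(m−1), the maximal
possible fluctuation.  The both-ends rule for flat extrema is deliberate: it
is the unique treatment that keeps F exactly invariant under time reversal
(a single turning point placed at either plateau end breaks the symmetry —
e.g. [0,6,6,3] vs its reverse), and the flat segment itself contributes
zero, so marking additional interior plateau points would not change the
value.

**Distribution D.**  With the window sorted ascending, uniform coverage of
the full scale would put pair (i, j) at separation I_ij = (j−i)·R/(m−1);
only shortfalls below the ideal are penalized,
D = 1 − Σ_{i<j} max(0, I_ij − A_ij) / Σ_{i<j} I_ij.  Clustering lowers D;
super-uniform spreading cannot push it above 1.

Both measures are affine-invariant (rescaling values and scale bounds
together) and time-reversal invariant, and the suite verifies them to
1e−12 against independent brute-force enumerations.

## Instability detection

Day t of a complexity series is flagged when z_t = (C_t − mean C)/sd C
exceeds the one-sided standard-normal critical value (1.645 at α = 0.05),
with mean and sd over the item's own complete defined series — there are no
population norms for such ratings, so the series is its own reference, and
no multiple-testing correction is applied across days or items (deliberately
liberal, matching how the p < 0.05 rule is used in monitoring practice).
Phases of critical instability are maximal runs of consecutive elevated days
of a per-day curve, by default the cross-item instability frequency (percent
of items flagged per day); the mean complexity curve is available as an
alternative phase source.

A known property of the raw z-rule: the null distribution of C is
right-skewed (skew ≈ 1.8 for 7-point windows of bounded ordinal noise), so
the **item-level** flag rate under a stationary null is ≈ 7–8%, not the
nominal 5% — intrinsic to applying a normal threshold to a skewed statistic,
and verified to be independent of the noise model (iid continuous, iid
rounded, AR(1)).  Aggregation largely removes the skew: the fraction of days
inside detected *phases* under the null is ≈ 5.5–6%, close to nominal.
Users who need exact item-level error control should calibrate the threshold
against a permutation null; the package keeps the field-standard rule.

The patient-level instability intensity is the max − mean complexity score:
per item, max(C) − mean(C) over defined values, averaged across items
(a `mean_curve` variant computes the same difference on the patient's mean
complexity curve; which aggregation the original procedure used is ambiguous,
so both are provided and the per-item rule is the default).  The score is
permutation-invariant within an item — it is a summary of peak intensity,
not a temporal detector; temporal claims belong to phase detection.

## Event-aligned transition analysis

Outcome series are z-transformed within patient (n−1 denominator), aligned
so ERP onset is relative day 0, and averaged on a half-weekly grid (step
3.5 days, anchored at 0): each patient contributes a grid point their
nearest assessment within ±2 days, and grid points with fewer than two
contributors are not reported.  The order transition is located as the
steepest (most negative) difference between consecutive assessments, ties
going to the earliest pair; the gradient is the raw difference because
assessments are near-equidistant.  "Located before onset" means the later
day of the steepest pair is ≤ 0.  Elevation tests (symptom level at onset
vs pre-drop level; mean complexity inside a candidate window vs outside) are
paired two-sided t-tests over patients with Cohen's d_z; candidate windows
(start of treatment, 11–4 days pre-onset) are analysis inputs, not
auto-discovered, though the phase detector can propose them.

For the cross-item frequency peak test two orientations are provided: a
one-sample t of in-window daily frequencies against the whole-process mean
(df = n_window − 1, the default) and a two-sample day-axis variant (window
days vs all other days, df = n_days − 2); degrees of freedom on the order of
the series length imply the day-axis orientation, but the per-window test is
the more conservative default.

## Outcome statistics

Relative change = (post − pre)/pre × 100, negative = improvement; the
process-based outcome uses the symptom factor's first-week vs last-week
means (each week requiring ≥ 3 observed days).  Correlations are Pearson
with two-sided p (t distribution, n−2 df) and listwise deletion.  Median
splits send ties to the low group (for 23 distinct values this yields the
12/11 split).  The 2×2 ANOVA uses Type III sums of squares with sum-to-zero
contrasts (cells are unbalanced after median splits; Type III keeps main
effects interpretable with the interaction present) and partial
η² = SS_effect/(SS_effect + SS_error); numerically null sums of squares
(zero-noise designs) are reported as F = 0 rather than a ratio of rounding
residue.  Post-hoc t-tests are pooled-variance by default (Welch optional)
with Cohen's d on the pooled sd.  Hierarchical regression fits nested OLS
models in block order (motivation; + ward atmosphere; + complexity) on
z-scored variables, reporting standardized β, per-predictor t and p, R²,
ΔR², and F-change = ΔR²·(n − p_k − 1)/((1 − R²_k)·q_k).  scipy and
statsmodels provide the fitting machinery behind these surfaces; the test
suite checks every statistic against naive-summation references.

## Synthetic cohort generator

The generator emulates the study conditions the analyses assume: 23
patients (configurable), treatment duration ~ N(60.2, 12.7²) days truncated
at the 20-point validity floor, 47 items in 5 factors on a [0, 6] scale, a
twice-weekly Y-BOCS readout with pre level ~ N(21.8, 8.5²), symptom-factor
pre level ~ N(4.5, 1²), and an 18/23 ERP participation fraction.

Mechanics per patient:

* a latent symptom state s(t) that steps from s_pre to s_pre + δ at a
  transition day τ drawn at 45–65% of the stay;
* a critical-instability burst in the 7–11 days before τ: item noise
  inflated by the gain κ (per patient ~ N(2.5, 0.6²), floored at 1.2) and
  values excursioning to the scale extremes with alternating sign.  The
  excursion probability scales with the gain, p_eff = p_flip·(κ−1)/(κ̄−1)
  with p_flip = 0.3, so that κ is the single dial of burst intensity — both
  F (amplitude/frequency) and D (range coverage) respond, and κ = 1 means
  no burst at all;
* an optional milder instability window at the start of treatment (the
  initial group-formation instability; on by default, giving the two-phase
  group-level signature);
* state-coupled items: the symptom factor tracks s(t); progress and
  dysphoric-affect items shift by ±0.6 after τ; the burst applies to these
  three factors.  Ward-atmosphere and therapist-relationship items fluctuate
  mildly around stable patient levels a and a_rel (a ~ N(4.2, 0.6²),
  a_rel correlated ≈ 0.6 with a); the motivation item sits at a stable
  patient level weakly coupled to the relationship level;
* item noise is AR(1) (φ = 0.5, stationary sd 0.8, halved for the climate
  factors), rounded to the ordinal grid and then clamped, in that order, so
  bounds are guaranteed;
* the improvement is coupled to the conditions:
  δ = δ_base + β_c·κ + β_w·a + β_int·κ·a + ε, with β_c = −0.35,
  β_w = −0.25, β_int = −0.04 (negative change = improvement, so all three
  couplings are negative and improvement concentrates in the high-gain ×
  good-atmosphere cell), ε ~ N(0, 0.3²), and δ_base = 1.545 chosen so the
  cohort mean δ ≈ −0.8, i.e. the symptom factor falls from ≈ 4.5 to ≈ 3.7.
  The coupling magnitude was set so the realized max-mean-score vs
  symptom-change correlation at large n is ≈ −0.4…−0.5, a strong effect of
  the size this literature reports; the score is a lossy readout of κ, so
  the coupling is necessarily larger than the target correlation;
* Y-BOCS on days ≡ 0 or 3 (mod 7): y = y_pre + 8.9·(s(t) − s_pre) + N(0,
  1.5²), rounded and clipped to [0, 40]; ERP onset = τ + Δ with Δ uniform
  on 4–7 days for participants.

All randomness flows from the master seed through per-patient spawned
streams; identical configs give bitwise-identical cohorts.  Ground truth
(τ, burst window, κ, a, δ, onset) is emitted alongside the data, and
`score_detection` scores phase hits (a detected phase, extended to the days
its windows cover, intersecting the true burst), localization error (the
distance between the argmax-complexity window's midpoint and the burst
midpoint — the burst necessarily *precedes* τ, so distance to τ itself
would be biased by about half the burst length plus half the window), and
the fraction of ERP patients whose steepest drop completes by relative
day 0.

### What the generator does and does not emulate

It reproduces the marginal sample statistics above, the qualitative
two-phase instability structure, and the coupling signs.  It does **not**
emulate: item-level covariance structure beyond factor membership (real
items within a factor share more than a level), non-stationary climate
factors, dropout or irregular rating compliance (missingness must be
injected explicitly), floor/ceiling pathologies of real ordinal scales, or
any pharmacological/comorbidity heterogeneity.  Passing the suite therefore
shows the chain recovers what it is designed to recover under its own
assumptions — not that those assumptions hold in clinical data.

## Problem sizes and numerics

The validation suite uses the sizes its questions need: 1000 random windows
for oracle agreement (tolerance 1e−12), 500 for the invariances, 200
ground-truth patients for detection/localization, 500 null patients for the
false-positive rate, a 200-patient cohort for effect-structure recovery
(sign and cell-ordering checks — the emulated study's n = 23 cannot and
should not reproduce printed statistics), 200 cohorts of 18 for the
pre-onset gradient fraction, and 100 random datasets for the statistics
oracles (tolerance 1e−8).  Degenerate inputs are errors, not silent
results: zero-variance z-transforms, zero pooled variance, rank-deficient
designs, empty ANOVA cells, and windows outside the declared scale all
raise with the offending patient/item named.  Identical paired samples are
the one deliberate exception (t = 0, p = 1: no effect, not a degeneracy).

## Known limitations

* The item-level z-rule is anti-conservative under the null (above); all
  headline analyses use curve-level phases or the max-mean score, which are
  less affected.
* The max-mean score grows slowly with series length under pure noise
  (a maximum over more windows is larger), so cross-patient comparisons
  implicitly assume comparable durations; the generator's duration spread
  (sd ≈ 13 days) leaves this nuisance small relative to the burst signal.
* The steepest-gradient rule is a point estimate with no uncertainty; no
  formal change-point model is provided by design.
* The aligned group curve interpolates by nearest assessment within ±2
  days; with assessment cadences much sparser than twice weekly the grid
  would need widening.
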