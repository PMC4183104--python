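# dyncomp

Nonlinear process-outcome analysis of daily psychotherapy self-ratings:
dynamic complexity, critical-instability detection, event-aligned
order-transition analysis, and the patient-level outcome statistics that tie
them together — plus a synthetic-cohort generator with programmed ground
truth so the whole chain can be validated without clinical data.

## The scientific problem

Self-organization accounts of psychotherapy predict that symptom change is
often *discontinuous*: an order transition (a sudden gain) preceded by a
transient burst of critical fluctuations, occurring under stable
interpersonal boundary conditions (ward atmosphere, working alliance) and
not necessarily in response to a specific intervention.  Testing these
predictions requires intensive longitudinal data — here, daily self-ratings
on a 47-item process questionnaire (5 factors, bounded ordinal scale) and
twice-weekly Y-BOCS outcome scores over a stay of roughly 60 days — and a
fluctuation statistic that works on short, coarse-grained, bounded series.

That statistic is **dynamic complexity**,

```
C = F · D,
```

computed in a moving 7-day window over each item's trajectory.  The
fluctuation measure F sums |Δy|/Δt between successive turning points of the
window, normalized by the maximal possible fluctuation `R·(m−1)` (R = scale
range, m = window width): 0 for a constant window, 1 for a min/max
alternation at every step.  The distribution measure D compares the sorted
values' pairwise spacings against perfectly uniform coverage of the scale,
penalizing only shortfalls: `D = 1 − Σ max(0, I_ij − A_ij) / Σ I_ij`.  Both
lie in [0, 1], are invariant under affine rescaling of the scale and under
time reversal, and windows touching missing data are flagged undefined
rather than zeroed.

On top of C the package provides: item-wise significance masks and phase
detection (one-sided z-rule at p < 0.05 against the series' own
distribution), the **max − mean complexity score** (intensity of local
instability peaks, the patient-level predictor), the cross-item instability
frequency distribution, ERP-aligned z-transformed outcome trajectories with
steepest-gradient localization, and the statistics layer (Pearson
correlations, median-split 2×2 Type III ANOVA with partial η² and post-hoc
Cohen's d, block-wise hierarchical regression with R² change and F change).

## Worked example

The numbered drivers under `analysis/` run the full chain on a synthetic
23-patient cohort (fixed seed) and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_complexity_maps.py
python analysis/03_instability_phases.py
python analysis/04_event_alignment.py
python analysis/05_outcome_statistics.py
```

which prints, among other lines:

```
wrote cohort of 23 patients to .../results/cohort
  treatment duration: mean 61.3 days (range 40-84)
  ERP participants: 18 of 23
...
  true burst recovered by a detected phase: 91% of patients
  argmax-complexity localization error: median 1.5 days from burst centre
...
aligned 18 ERP participants (5 excluded: no onset)
  steepest individual symptom drop at or before onset: 16 of 18 patients (89%)
  group mean z-curve steepest gradient: -1.66 z-units over relative days (-7, -3)
  mean complexity in the 11-4 days pre-onset window vs outside:
    t(17) = 3.31, p = 0.00413, d_z = 0.78
...
  ANOVA on rel_ybocs_change: ... largest improvement in the
    high_complexity/high_atmosphere cell (-51.9%)
```

Reading: the programmed pre-transition instability burst is found by the
phase detector in 91% of patients and localized to ~1.5 days; the steepest
symptom drop precedes the exposure intervention (relative days −7…−3 on the
group curve); complexity is significantly elevated in the window 11–4 days
before onset; and improvement concentrates in patients with both high
instability and a good ward atmosphere.  At n = 23 the patient-level
correlations are noisy — the direction, not the p-value, is the point at
this sample size.

The same pipeline is scriptable on any data in the package's CSV formats via
the CLI:

```
dyncomp simulate --n-patients 23 --seed 7 --out cohort/
dyncomp analyze --ratings cohort/ratings.csv --outcomes cohort/outcomes.csv \
    --events cohort/events.csv --factors cohort/factors.yaml --out analysis/
dyncomp render --ratings cohort/ratings.csv --factors cohort/factors.yaml \
    --patient p001 --events cohort/events.csv --out p001.png
```

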