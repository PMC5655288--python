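# Methods

## Model and assumptions

The package implements a cohort-level cost-minimization analysis: the
two trastuzumab formulations are assumed clinically equivalent, so only
costs are compared. Every administration cycle is one preparation plus
one infusion/injection. Costs are accounted bottom-up per cycle and
attributed to the cycle's patient, so per-patient vectors sum exactly
to scenario totals (additivity is an invariant, not an approximation).

Assumptions inherited from the study design:

- **Robotic, exact preparation.** Doses are exact mg amounts (no vial
  rounding); drug waste is a flat 0.11% of the IV drug cost. SC is a
  prefilled fixed dose and incurs no waste.
- **Loading events are data.** Whether a cycle is a loading dose is part
  of the cohort's schedule, never synthesized by the planner; in
  particular the IV→SC switch in scenario 3 does not trigger re-loading,
  and SC "loading" cycles are ordinary 600 mg / 5 min cycles (SC needs
  no pharmacological loading dose).
- **Weekly→SC conversion is 3:1 with ceiling remainders**, per phase and
  per patient: a partial block of 1–2 remaining weekly cycles still
  requires one SC administration.
- **Indwelling-catheter costs are out of scope**, as are clinical
  outcomes (cardiotoxicity, relapse) and staffing/queueing models of the
  day hospital.

## Parameters

| parameter | default | unit | note |
|---|---|---|---|
| IV / SC drug price | 4.15 / 2.87 | €/mg | configurable (`costs` section) |
| weekly loading / maintenance | 4 / 2 | mg/kg | IV during chemotherapy |
| q3w loading / maintenance | 8 / 6 | mg/kg | label-standard regimen |
| SC fixed dose | 600 | mg | weight-independent |
| waste fraction | 0.0011 | – | applied to IV drug cost only |
| prep cost per cycle IV / SC | 8.17 / 6.99 | € | printed constants, not derived from staff rates |
| clinic occupancy | 89.80 | €/h | unrounded hours × rate |
| admin time IV loading / IV maint / SC | 90 / 30 / 5 | min | chair time per cycle |
| unit prep time IV / SC | 844 / 641 | s | isolated single-preparation time |
| effective prep time IV / SC | 334.37 / 130.63 | s | see below |

**Unit vs effective preparation seconds.** The isolated unit times
(844 s / 641 s) multiplied by cycle counts give ≈303 h / 167 h, which is
inconsistent with the observed overall workloads of 120 h (1,292 IV
cycles) and 34 h (937 SC cycles). Both are carried: the *effective*
per-cycle seconds (120·3600/1292 and 34·3600/937) are authoritative for
all aggregate time and cost figures — they also reproduce the mixed
scenario's 78 h — while unit seconds are retained only for the
per-cycle reduction statistic (24.1%). Per-cycle preparation *costs*
are taken as the printed €8.17/€6.99 constants; the €21/h technician
and €60/h pharmacist rates do not reproduce them under any single-rate
assumption and are kept in the config for sensitivity use only.

**Rounding.** All internal arithmetic is unrounded. Printed-precision
rounding happens only at report time, half away from zero
(`round_half_up`): e.g. the scenario-3 drug total 1,612,274.50 €
prints as 1,612,275.

## Reference cohort

The bundled cohort (`reference_cohort()`) is a hand-constructed,
deterministic stand-in for the unreleased 2014 patient-level extract.
Its 114 patients fall into six schedule blocks chosen so the cycle
tallies are exact: 53 patients with a weekly phase (24×(1L+8M),
8×(1L+11M), 21×(1L+10M), each followed by 6 q3w maintenance cycles),
32 q3w starters (1L+5M) and 29 carried-over q3w patients (22×8M,
7×9M) — totalling 85 loading + 1,207 maintenance cycles, 543 weekly /
749 q3w. The 114 frozen weights were solved (greedy pair swaps plus a
two-patient fine-tune) so that the weight order statistics pin median
63.75 kg, quartile bounds 55 / 74.9 kg and range 42–95 kg, while the
dose-weighted sums hit the administered totals exactly: 372,214 mg
overall and 77,710 mg in the weekly phases. The q3w 8/6 mg/kg
coefficients are not themselves observed; they are the label-standard
regimen, and the break-even calibration validates them: the implied
dose-weighted mean weight 372,214 / 5,750 = 64.73 kg is consistent with
the printed weight distribution.

## Synthetic-cohort generator

`generate_cohort` emulates what a one-calendar-year extract of such a
unit looks like:

- **Weights**: truncated log-normal, log-median 63.75 kg, σ=0.229,
  truncated to [42, 95] kg (right-skewed positive weights matching the
  reference quartiles); rejection-sampled, rounded to 0.01 kg.
- **Trajectories**: weekly-then-q3w with probability 0.58, q3w-only
  0.42, weekly-only 0. A completer receives 12 weekly cycles + 12 q3w
  (weekly trajectory) or 16 q3w cycles. These probabilities are
  calibrated against the reference cycle tallies (loading-cycle split
  53:32 among in-window starters), not against the histology table's
  chemotherapy-scheme frequencies, which would imply far more weekly
  cycles than observed.
- **Censoring**: with probability 29/114 a patient carried treatment
  over from the previous year (start uniformly deep into the course, so
  no in-window loading cycle); otherwise the course starts uniformly
  within the 52-week window. Cycles outside the window are dropped;
  patients with no in-window cycle are redrawn. A single uniform start
  offset cannot reproduce both the loading count and the total cycle
  count, which is why the carried-over fraction is explicit.
- **Discontinuation**: probability 0.035 of truncating the course at a
  uniform cycle (the observed cardiotoxicity-interruption rate).

At these defaults the generator averages ≈1,314 IV cycles (within 1.7%
of the reference 1,292), ≈85 loading cycles, and ≈550/764 weekly/q3w
cycles over 200 seeds. Everything flows from one `numpy` generator
seeded by `params.seed`, so cohorts are bit-reproducible.

What the generator does *not* emulate: correlation between weight and
schedule, seasonal accrual patterns, per-phase dose adjustments or
delays, and clinical covariates. Tests passing on synthetic cohorts
therefore validate the accounting pipeline and aggregate calibration,
not patient-level realism.

## Break-even model

The functional form is the minimal one consistent with two cost lines
over mean weight: affine, with the cycle structure frozen at the
cohort's counts, drug+waste weight-proportional and prep+clinic fixed.
The cohort's mean weight is never assumed — it is derived as
`total IV mg / Σ(count × mg/kg)`. At default prices the scenario-1
slope is 4.15 × 5,750 × 1.0011 ≈ €23,889/kg and the model intersects at
64.92 kg; the exact crossing moves within ≈64.9–65.2 kg depending on
the q3w loading-dose assumption. Scenario 3 is excluded from break-even
reporting by default (it is dominated at every weight) but the curve
machinery accepts it.

## Statistics

Scenario comparisons use the independent-groups one-way ANOVA with
Bonferroni-adjusted pooled-variance pairwise t-tests, mirroring the
original analysis — although the scenarios are counterfactuals of the
*same* patients (correlated samples). A repeated-measures variant
(`one_way_anova(..., repeated=True)`) is provided for the stricter
reading; Welch tests via `equal_var=False`. Degenerate inputs: all
observations identical ⇒ F=0, p=1; zero within-variance with non-zero
between-variance ⇒ F=∞, p=0. The pairwise tables are always computed
but flagged `ran=False` when the omnibus p ≥ 0.05 (gated protocol).

## Known limitations and unreproduced figures

Several of the printed 2014 aggregates the model was calibrated
against are internally inconsistent and are deliberately *not*
reproduced; the bottom-up model is treated as authoritative:

- the €1.9M "overall cost" block (inconsistent with its own per-patient
  means × 114);
- mean preparation/administration hours per patient (a factor ~10 off
  overall hours ÷ 114); the package reports overall ÷ n;
- scenario-1 "direct cost" 13,655 €/patient (matches neither drug+waste
  nor drug+waste+prep);
- scenario-3 waste €344 (0.11% of the scenario-3 IV drug cost gives
  €355, which is what the model reports);
- the all-SC scenario's bracketed maintenance cycle count "1,212"
  (85+1,212 ≠ 937; the 78 h total matches 937 × 5 min).

Per-patient standard deviations depend on the unpublished patient-level
distribution; they are computed from whatever cohort is supplied and
never asserted against printed ± values, and the printed p-values
(0.832 / 0.959) are likewise not reproducible without the original
patient-level data.
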