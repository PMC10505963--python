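# Methods

## The decision problem

First-line treatment of extensive-stage small cell lung cancer (ES-SCLC):
serplulimab (an anti-PD-1 antibody) added to four cycles of
carboplatin–etoposide, versus carboplatin–etoposide alone, evaluated from
the Chinese healthcare payer perspective in 2021 USD. Effectiveness and
safety come from the ASTRUM-005 randomized trial population; the model
asks what the added drug buys (life-years, QALYs) and costs over a 10-year
horizon, and summarises value as an ICER and as incremental net
health/monetary benefit at willingness-to-pay thresholds of $37,669 and
$86,569 per QALY (1x and 3x regional per-capita GDP).

## Model structure

A partitioned survival model with three mutually exclusive states —
progression-free (PFS), progressed (PD), dead — on a weekly cycle over 520
cycles. State occupancy is read directly off the overall-survival and
progression-free-survival curves at each cycle boundary:

    occ_pfs(t) = min(PFS(t), OS(t))
    occ_pd(t)  = max(OS(t) − PFS(t), 0)
    occ_dead(t) = 1 − OS(t)

The min/max clamp repairs PFS/OS crossing in the extrapolated tail; it is
logged, never fatal. Between boundaries, occupancy-time is integrated by
the trapezoid rule, which at a 1-week step is equivalent to a half-cycle
correction; halving the cycle length changes total QALYs by < 0.5%
(tested).

## Survival inputs

Treatment arm: the published log-logistic fits to the digitized trial
curves, parameterized as S(t) = 1/(1 + (λt)^γ) with t in weeks
(OS: γ = 1.7870, λ = 0.0124; PFS: γ = 2.0490, λ = 0.0294). This rate
parameterization is pinned by calibration: it reproduces the published
restricted areas and medians, while S(t) = 1/(1 + λt^γ) does not.

Comparator arm: proportional-hazards scaling of the treatment curves with
the trial hazard ratios, S_c(t) = S_t(t)^(1/HR), HR_OS = 0.63,
HR_PFS = 0.48. The source publication also prints separate parametric
fits for the comparator (lognormal OS μ = 4.1481, σ = 1.0719;
log-logistic PFS γ = 2.5671, λ = 0.0448) — but those curves are
numerically incompatible with the publication's own results table (they
give a comparator restricted area of 2.01 undiscounted years against a
printed 1.487), whereas the PH construction reproduces the printed
per-arm life-years to < 1% and the whole subgroup table besides. The
printed fits remain available via `printed_chemo_models()` and are what
the fitting module recovers when refitting reconstructed data; they are
not used in the base case. This is the single most consequential
interpretation decision in the package.

The same PH mechanism is the treatment-effect lever everywhere: subgroup
analysis substitutes the subgroup's OS hazard ratio, and the sensitivity
analyses vary/draw HR_OS and HR_PFS, each time rebuilding the comparator
from the fixed treatment curves.

## Discounting and reporting conventions

Costs and QALYs are discounted at 5% per year in annual steps:
everything accruing in model year k is multiplied by 1.05^(−k)
(`discount_mode="annual"`; a continuous-equivalent 1.05^(−t/52) mode is
available). A year is 52 weeks, so the 10-year horizon is exactly 520
cycles. Life-years are reported undiscounted — the convention the source
tables evidently use — with discounted life-years also carried on every
result object; the ICER per life-year uses the undiscounted increment,
the ICER per QALY the discounted one.

Utilities: 0.673 (PFS) and 0.473 (PD), weighting the discounted
occupancy-time. The published one-off adverse-event disutilities (0.050 /
0.053 QALYs) are carried in the configuration but NOT subtracted by
default: the publication's own per-arm QALYs are arithmetically
impossible with the subtraction applied (the chemo arm would need its
discounted QALYs to exceed its undiscounted ones) and match within 0.7%
without it. `utilities.apply_ae_disutility=True` restores the
subtraction.

## Costing

"Per cycle" for disease-management and second-line costs means per model
cycle (1 week); drug regimens run on 3-week treatment cycles whose cost
is spread evenly over their weeks, weighted by the discounted probability
of still being progression-free:

- serplulimab 4.5 mg/kg × $8.32/mg every 3 weeks until progression, plus
  one administration unit ($19.11) per infusion;
- etoposide 100 mg/m² × 3 days and carboplatin by the Calvert formula
  (AUC 5 × (CrCl + 25), capped at 750 mg — the AUC target is a protocol
  value, exposed in config) for the first four 3-week cycles, three
  administration days per cycle (carboplatin shares day 1);
- supportive care $185/week (PFS) and $552/week (PD); second-line therapy
  $33.28 / $57.19 per week of PD occupancy (arm-specific, read as already
  weighted by the share receiving second-line treatment);
- adverse-event management ($1,562 / $1,697) once at entry, undiscounted;
- terminal care $2,596 attached to the death mass in the cycle it occurs,
  at that cycle's discount factor.

Reference body metrics: BSA 1.80 m², weight 65 kg, CrCl 90 mL/min.

## Curve reconstruction and refitting

The pseudo-IPD module inverts digitized KM coordinates plus a
numbers-at-risk table into patient-level records (Guyot-style): per risk
interval, the number censored is searched so the implied risk set matches
the published count, censoring times are spread uniformly across the
interval, and events follow from survival drops against the running
product-limit estimate. Small (≤ max(2, 5% of the risk set)) deficits
from event rounding are carried forward, as in the published algorithm;
larger inconsistencies raise a reconstruction error naming the interval.
Ties put events before censorings; digitized survival is monotone-repaired
by a running minimum first. The record count always equals the initial
number at risk.

Refitting maximises the right-censored likelihood
Π f(t_i)^{e_i} S(t_i)^{1−e_i} per family by Nelder–Mead on
log-transformed positive parameters from five deterministic moment-based
starts (tolerance 1e−8 on the log-likelihood), with AIC/BIC selection and
family-order tie-breaks. Generalized-gamma fits with |Q| > 10 or extreme
σ are flagged non-converged and excluded — a known small-sample pathology
of that family. On simulated cohorts the optimizer matches (and on the
generalized gamma sometimes beats) the lifelines fitters' optima; at
n = 1000 the generating log-logistic wins AIC selection in 88% of 50
replicates, at n = 500 only 78% — the three-parameter generalized gamma
legitimately overtakes more often on smaller samples.

## Sensitivity and subgroup analysis

One-way analysis sweeps every input over its published 95% CI (or ±20%
where none is printed) and ranks ICER ranges; serplulimab price and body
weight dominate, matching the source. Threshold search bisects a single
input (price per mg, body weight) to the value where the ICER equals a
WTP threshold (relative tolerance 1e−6).

The probabilistic analysis draws, independently per iteration: costs from
gamma, utilities and disutilities from beta (method-of-moments with
SE = (CI width)/3.92; infeasible beta moments fall back to logit-normal
with a logged warning), and hazard ratios from lognormal distributions
on their trial CIs. Body metrics are varied in the one-way analysis only
— the source's Monte-Carlo enumeration omits them, and its printed
acceptability (0.04% at $86,569) is irreconcilable with drawing body
weight (weight < 42 kg alone is a ~1.2% tail event that flips the
decision). The CEAC reports P(INMB(λ) > 0) on a $0–150,000 grid; draws
are reproducible bit-for-bit under a fixed seed.

## Synthetic data

`SimulationSpec` draws event times by inverse-CDF from any supported
family, censors them by min(administrative cutoff, exponential random
censoring), and `emit_digitized_km` samples the resulting KM step
function on a digitization-like grid with uniform survival-axis jitter
(default ±0.002, the scale of plot-digitizer noise) plus a true risk
table. This emulates the structure of digitized figures, not every real
artefact (systematic local bias, risk-table rounding): a green roundtrip
test establishes algorithmic correctness of reconstruction and fitting,
not robustness to arbitrary figure quality.

## Reproduction accuracy and known gaps

With the conventions above, the package reproduces the source's headline
results: ICER $120,146/QALY vs $120,149 printed (0.003%); incremental
cost −2.9%, incremental QALYs −3.0%, incremental life-years +0.4%;
per-arm life-years and QALYs within 0.7%; price threshold $5.33/mg vs
$5.24 and weight threshold 41.6 kg vs 40.96 at the $86,569 threshold
(≈1.6%). Residual gaps trace to the source's own internal inconsistencies
(its comparator parametric fits vs its results; QALY conventions) and are
not tunable away. Two quantities stay outside their bands by
construction: the lower price threshold ($0.97 vs $0.76 — the crossing
condition nearly cancels at $37,669/QALY, amplifying the ±3%
reproduction error roughly eightfold) and the probabilistic
acceptability at $86,569 (0.5% vs 0.04% printed — the stated input
distributions generate more spread than the printed probability implies).

## Limitations

- The comparator-arm construction (PH scaling vs the printed parametric
  fits) is an inference from the source's numbers, not a statement in its
  text; both options are in the package.
- No drug-wastage/vial rounding, no inflation adjustment, no cure-fraction
  or spline extrapolation, no state-transition reformulation.
- PSA draws are independent; correlations between inputs (e.g., the two
  utilities) are not modelled.
- Subgroup analysis varies the OS hazard ratio only, holding PFS and all
  costs at base, so subgroup results are comparative, not absolute.
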