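# psmcea

Partitioned-survival cost-effectiveness analysis of first-line serplulimab
plus carboplatin–etoposide versus carboplatin–etoposide alone in
extensive-stage small cell lung cancer (ES-SCLC), from the Chinese
healthcare perspective, built as a reusable pipeline for trial-based
economic evaluations.

## Who this is for

Health-economics and HTA analysts who need the full workflow behind a
partitioned survival model (PSM) as programmable, testable components:

- **Survival extrapolation** — seven parametric families (exponential,
  Weibull, gamma, lognormal, Gompertz, log-logistic, generalized gamma)
  with restricted discounted areas, plus proportional-hazards-derived
  comparator curves, `S_c(t) = S_t(t)^{1/HR}`.
- **Pseudo-IPD reconstruction** — the standard (Guyot-style) inversion of
  digitized Kaplan–Meier coordinates plus numbers-at-risk into
  patient-level records, with a synthetic-figure generator for offline
  testing.
- **Model fitting** — right-censored maximum likelihood per family with
  AIC/BIC selection.
- **The economic model** — a weekly-cycle, three-state (progression-free /
  progressed / dead) PSM over a 10-year horizon with trial dosing rules
  (weight-based serplulimab, BSA-based etoposide, Calvert-formula
  carboplatin), ICER, and incremental net health/monetary benefit
  INHB(λ) = ΔE − ΔC/λ, INMB(λ) = ΔE·λ − ΔC.
- **Uncertainty** — one-way (tornado) analysis, threshold bisection,
  10,000-iteration probabilistic sensitivity analysis with
  cost-effectiveness acceptability curves, and hazard-ratio-driven
  subgroup re-analysis.

## Worked example

```python
>>> from psmcea import PartitionedSurvivalCEA
>>> res = PartitionedSurvivalCEA().fit()     # published base case
>>> print(res.summary().round(3))
                              serplulimab+chemo  chemotherapy  incremental
Cost, drug ($)                        42989.657      3837.681    39151.976
Cost, nondrug ($)                     47439.702     35773.011    11666.690
Cost, overall ($)                     90429.359     39610.692    50818.666
Life-years, progression-free              0.968         0.498        0.470
Life-years, overall                       2.325         1.496        0.829
QALYs                                     1.199         0.776        0.423
ICER per life-year ($)                      NaN           NaN    61286.824
ICER per QALY ($)                           NaN           NaN   120146.218
INHB at $37,669/QALY                        NaN           NaN       -0.926
INMB at $37,669/QALY ($)                    NaN           NaN   -34885.678
INHB at $86,569/QALY                        NaN           NaN       -0.164
INMB at $86,569/QALY ($)                    NaN           NaN   -14202.273
```

Adding serplulimab buys 0.83 life-years (0.42 QALYs) for an extra
$50,819, i.e. about $120,146 per QALY — far above both willingness-to-pay
thresholds used for China (1× and 3× per-capita GDP: $37,669 and $86,569
per QALY), so the net benefits are negative at either threshold.

```python
>>> model = PartitionedSurvivalCEA()
>>> model.threshold_search("costs.serplulimab_per_mg", wtp=86_569.0)
5.328...           # price per mg at which the regimen becomes cost-effective
>>> psa = model.psa(n_iter=10_000, seed=1)
>>> psa.prob_cost_effective(86_569.0)
0.0046             # probability cost-effective at the affluent-region WTP
```

A thin CLI mirrors the library (`psmcea basecase|oneway|threshold|psa|
subgroups|simulate|fit`); YAML configs override any subset of the defaults.

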