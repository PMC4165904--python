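# ceassay

A risk-stratified Markov cohort model for the societal cost-effectiveness of
the 21-gene recurrence-score assay in estrogen-receptor–positive,
lymph-node–negative early breast cancer in Japan.

## The problem

In ER+, LN− early breast cancer, adjuvant chemotherapy prevents distant
recurrence in only a minority of patients but carries acute costs, adverse
events and a quality-of-life penalty for everyone treated.  The 21-gene
assay stratifies patients into low, intermediate and high recurrence-risk
groups and, in a 104-patient Japanese decision-impact cohort, changed
physicians' chemotherapy recommendations: overall use fell from 46.2% to
26.9% (−19.2 points), with treatment *increasing* in the high-risk group
where it is most effective.  This package asks whether paying ¥350,000 per
assay is good value from the societal perspective, in 2013 JPY.

It is a library for health-economics analysts: all inputs (costs, utilities,
risk-group data, background mortality, discounting) live in a validated YAML
configuration, every published uncertainty range is machine-readable, and
the cohort engine is cross-checked by an independent patient-level
microsimulation.

## The model

Four health states: recurrence-free → distant recurrence → breast-cancer
death, with other-cause death reachable from any living state.  Annual
cycles from the starting age (49.8 y) until cohort extinction.

* **Hazard bridge.** Published 10-year distant-recurrence risks `R₁₀` are
  converted to annual probabilities under a constant hazard,
  `p = 1 − (1 − R₁₀)^{1/10}`, and chemotherapy multiplies the risk by
  `(1 − RRR)` for treated subgroups.  By default the hazard continues for
  life.
* **Competing risks** are combined on the rate scale: with cause-specific
  rates `r₁ = −ln(1−p₁)` and `r₂ = −ln(1−p₂)` the total event probability is
  `1 − e^{−(r₁+r₂)}`, apportioned `r₁:(r₁+r₂)`.  After recurrence, a 40%
  annual breast-cancer mortality competes with life-table mortality.
* **Rewards.** QALYs weight each discounted year by the state utility (0.98
  recurrence-free, 0.30 after recurrence); a one-time 0.53-QALY tariff and
  the acute chemotherapy costs apply undiscounted at time zero to each
  chemo-treated patient.  Cycle rewards use a half-cycle correction and a 3%
  annual discount rate.
* **Strategies.** `without_assay` applies each group's pre-assay
  chemotherapy recommendation rate, `with_assay` the post-assay rates plus
  the assay cost.  The incremental cost-effectiveness ratio is
  `ICER = ΔC / ΔE` on unrounded internals.

Background other-cause mortality comes from an age-indexed life table; the
bundled `life_table_japan_female_synthetic.csv` is a Gompertz–Makeham
approximation calibrated to Japanese female period life expectancy (see
`docs/methods.md`).

## Worked example

```python
from ceassay import default_inputs, evaluate_both, threshold_chemo_cost

bundle = default_inputs("japan")
without, with_assay, inc = evaluate_both(bundle)
print(f"{inc.delta_qaly:.3f}", f"{inc.icer:,.0f}")
print(f"{threshold_chemo_cost(bundle):,.0f}")
```

prints `0.253 606,678` and `1,358,630`: assay-guided treatment gains 0.253
QALYs per patient at ¥606,678 per QALY, and becomes outright cost-saving
once chemotherapy drug costs exceed ≈¥1.36M.  `python
examples/run_base_case.py` prints the full per-arm table; the acute rows
are exact consequences of the decision-impact counts — chemotherapy drugs
¥259,298 → ¥151,257 (−¥108,041), adverse events −¥32,852, patient
time/transport −¥13,173, a total acute saving of ¥154,066 per patient.

The `examples/` directory has one narrative script per capability (base
case, tornado sensitivity, break-even threshold, microsimulation
validation, synthetic decision-impact cohorts, structural-choice
calibration), and the `ceassay` command exposes the same operations from
the shell (`ceassay run --usd`, `ceassay sensitivity --plot`,
`ceassay threshold`, `ceassay validate-microsim`, `ceassay make-synthetic`).

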