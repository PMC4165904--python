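# Methods

## Model structure

A deterministic state-transition (Markov) cohort model with four states —
recurrence-free, distant recurrence, breast-cancer death, other-cause
death — evaluated in annual cycles from the mean age at diagnosis (49.8
years) until the living mass falls below 1e−12 or age 110, whichever comes
first.  The cohort is partitioned into six homogeneous subgroups: three
21-gene-assay risk strata × chemotherapy yes/no.  Strategy arms differ only
in the per-stratum probability of receiving chemotherapy (the pre- vs
post-assay recommendation rates of the 104-patient decision-impact cohort)
and in whether the assay is paid for.

Recommendation rates are stored as integer counts (16/50, 18/37, 14/17
before the assay; 0/50, 11/37, 17/17 after) rather than rounded
percentages.  This makes the arm-level chemotherapy proportions exact
rationals (48/104 and 28/104) and the acute cost components exact to the
yen; the rounded percentages in the source tables would be off by tens of
yen per patient.

## Transition dynamics

**Recurrence.**  The published inputs are 10-year distant-recurrence risks
per stratum.  They are bridged to annual probabilities with a constant
hazard, `p = 1 − (1 − R₁₀)^{1/10}`, whose inverse property (compounding `p`
over 10 cycles recovers `R₁₀`) is enforced by a property test.
Chemotherapy multiplies the 10-year risk by `1 − RRR` before bridging.
Two hazard modes exist: `lifetime` (default — the annual hazard continues
past year 10) and `first_10_years` (hazard switched off afterwards).  The
lifetime default was chosen because the downstream recurrence-cost level it
implies is consistent with the published lifetime recurrence-cost
accounting, while a 10-year-only hazard roughly halves the recurrence-cost
offset (see `examples/calibration_sensitivity.py` for the exact grid).

**Competing risks.**  Within a cycle, recurrence competes with other-cause
death (and, after recurrence, breast-cancer death competes with other-cause
death) on the rate scale: cause-specific rates `rᵢ = −ln(1−pᵢ)` add, the
joint event probability is `1 − e^{−Σr}` and is apportioned in proportion to
the rates.  At the magnitudes involved this differs from independent
per-cause probabilities by <1e−4, but it keeps every transition row on the
probability simplex even at the extreme ends of the sensitivity ranges.  An
infinite rate (an input probability of exactly 1, possible only in
degenerate test configurations) is resolved by giving the certain cause the
whole cycle.

**Post-recurrence mortality** (40%/year, range 20–60%) is breast-cancer
mortality and competes with, rather than replaces, life-table mortality.

**Fatal chemotherapy toxicity** (default 0.2% of treated patients,
configurable to 0) is applied at time zero and counted as breast-cancer
death.  The source analysis cites a toxicity reference without printing the
value; 0.2% is a small conventional figure and the calibration grid shows
the ICER moves by about 3% between 0 and 0.2%.

## Rewards and discounting

Acute quantities — assay cost, chemotherapy drug cost (¥561,813), adverse
events (¥170,831, already probability-weighted), patient time and transport
(¥68,500), and the 0.53 chemotherapy QALY tariff — are time-zero lump sums
per treated patient, undiscounted.  State rewards accrue per cycle:
utilities 0.98 (recurrence-free) and 0.30 (after recurrence), surveillance
¥25,416/year while recurrence-free (for life), recurrence management
¥2,405,924/year while alive after recurrence.  With the half-cycle
correction (default on) cycle `k` accrues on the mean of cycle-start and
cycle-end occupancy at discount factor `(1+r)^−(k+½)`; switched off, it
accrues on cycle-start occupancy at `(1+r)^−k`.  The half-cycle default
follows the convention that the published lifetime recurrence-cost total
(≈1.96 expected years × the annual cost) reflects mid-cycle transitions at
40% annual mortality; in this model the choice moves the ICER by <0.1%, so
it is a convention, not a driver.  The discount rate is 3%/year (range
1–5%).

The source tables print immediate QALY losses (−0.246/−0.144) that exceed
tariff × proportion (−0.2446/−0.1427) by ~0.001–0.003, consistent with an
unrounded tariff slightly above 0.53.  The model computes the product from
the printed 0.53 and makes no ad-hoc adjustment; the difference is inside
every stated tolerance.

10-year recurrence-free survival counts distant recurrence and death from
*any* cause (including time-zero fatal toxicity) as events; this is the
convention that reproduces the published 94.5%/95.0%.

## Life table

The background-mortality reference is a national female life table whose
values are not printed in the source material, so the package treats the
life table as an explicit input (`age,q_annual` CSV) and bundles a
clearly-labelled synthetic stand-in.  The fixture is Gompertz–Makeham,
`q(x) = 1 − exp(−(c + a·e^{b(x+½)}))` with `a = 6.211e−6`, `b = 0.105`,
`c = 2e−4`, calibrated to Japanese female period life expectancy of the
era: e₀ ≈ 86.5, e₅₀ ≈ 37.6, e₆₅ ≈ 23.9 years.  The calibration targets are
demographic, chosen before any comparison with the published
cost-effectiveness results.  `ceassay.generate_life_table` regenerates it,
and `flat`/`gompertz` variants support degenerate test worlds.  Any
analysis can substitute a real national life table by pointing the config
at a different CSV.

## Sensitivity, scenarios, threshold

Every input with published bounds (19 parameters: six stratum risk/RRR
pairs, six costs, three utilities, age, discount rate, post-recurrence
mortality, fatal toxicity) is varied to its bounds one at a time —
endpoints only, matching the published one-way design.  Tornado rows carry
the ratio ΔC/ΔE at each bound plus a dominance annotation and are ranked by
the ratio-scale swing.  Reporting the raw ratio at dominant bounds (where
the assay arm saves money and gains QALYs, making the ratio negative) is a
deliberate choice: it preserves the published ranking in which the
chemotherapy drug cost — whose upper bound makes the assay cost-saving —
is the widest bar.  Bounds that produce an infeasible model are flagged
`invalid` and the analysis continues.

The alternative scenario swaps in the US/UK validation-study 10-year risks
(5.4%/13.7%/29.2%); everything else, including all acute-cost differences,
is unchanged by construction.

The break-even chemotherapy drug cost solves ΔC(d) = 0 by Brent
root-finding on [0, ¥10M] to ±¥0.5.  ΔC is affine and strictly decreasing
in `d` (the assay arm treats 20/104 fewer patients), so the bracket check
doubles as a monotonicity assertion; absence of a sign change returns an
explicit no-threshold result.

## Microsimulation oracle and synthetic data

`microsim_oracle` is an independent patient-level implementation: each
simulated patient draws a risk group, a chemotherapy assignment, a possible
fatal-toxicity death, and then annual Bernoulli transitions using exactly
the per-cycle probabilities of the cohort engine, accruing discounted
rewards with the same half-cycle convention (mean of start/end state
rewards per cycle).  Cohort-model expectations must fall within 3
Monte-Carlo standard errors of the microsimulation means for every cost and
QALY component, both arms and both risk sources, at n = 200,000 — this is a
standing acceptance test.  The simulation is driven by a single seeded
PCG64 stream and fully vectorised over patients; seeded runs are
bit-reproducible.

`generate_decision_impact_table` emulates the decision-impact study:
per-patient group membership and pre/post recommendations are sampled
independently given the group (the pairing of pre and post within a patient
is not used by the cohort model, so no within-patient correlation is
imposed).  What the generator does *not* emulate — patient covariates, the
referral-center exclusion criteria, any correlation between risk group and
age — bounds what passing tests show: they validate the computational
pipeline against its own stated dynamics, not the clinical
representativeness of the 104-patient cohort.

## Problem sizes and numerics

The cohort engine runs ≤61 annual cycles per subgroup (age 49.8 → 110);
a full two-arm evaluation is ~12 subgroup runs and takes milliseconds, the
19-parameter tornado well under a second, and the four 200,000-patient
microsimulation audits a few seconds in total.  Cohort extinction is cut at
1e−12 living mass; occupancy conservation is asserted at 1e−9 per row.  The
synthetic-cohort parameter-recovery check uses n = 200,000, where the
binomial sampling error of the recommendation rates propagates to ~2% of
the ICER; the test allows 6% (≈3σ).

## Known limitations

* The bundled life table is a two-parameter-family approximation; lifetime
  absolute levels (total QALYs, monitoring-cost levels) inherit its shape,
  which is why acceptance checks level differences and ratios rather than
  absolute lifetime levels.
* Local recurrence, second primaries, HER2+ disease and post-recurrence
  treatment lines are out of scope, as in the source analysis.
* Costs are 2013 JPY taken as given; no re-indexing machinery is included.
* Probabilistic (Monte-Carlo) sensitivity analysis over joint parameter
  distributions is not implemented; uncertainty handling is one-way only.
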