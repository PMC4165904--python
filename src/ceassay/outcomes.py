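"""Discounted lifetime costs, QALYs and the incremental cost-effectiveness ratio.

Accounting conventions
----------------------
* Acute chemotherapy costs (drugs, adverse events, patient time/transport),
  the assay cost and the one-time chemotherapy QALY tariff are time-zero lump
  sums and are not discounted.
* State rewards (utilities, surveillance and post-recurrence costs) accrue per
  annual cycle with discount factor (1+r)^-(k+1/2) under the default
  half-cycle correction, applied to the mean of cycle-start and cycle-end
  occupancy; with the correction off, cycle-start occupancy at (1+r)^-k.
* Surveillance cost accrues only while recurrence-free; the annual recurrence
  cost only while alive after distant recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import (
    DISTANT_RECURRENCE,
    RECURRENCE_FREE,
    CohortTrace,
    run_subgroup_cohort,
    subgroup_spec,
)
from .parameters import (
    CostInputs,
    InputBundle,
    ModelSettings,
    StrategyArm,
    UtilityInputs,
    strategy_arms,
)

__all__ = [
    "StrategyResult",
    "IncrementalResult",
    "acute_costs",
    "immediate_chemo_qaly_loss",
    "lifetime_outcomes",
    "evaluate_strategy",
    "incremental",
    "evaluate_both",
]

ACUTE_COST_FIELDS = ("cost_chemo_drugs", "cost_adverse_events", "cost_time_transport")


@dataclass(frozen=True)
class StrategyResult:
    """Per-average-patient discounted outcomes of one strategy arm."""

    name: str
    chemo_proportion: float
    rfs_10y: float  # P(alive and recurrence-free at 10 years), all-cause
    qaly_immediate_chemo: float  # ≤ 0: one-time chemo tariff
    qaly_long_term: float
    cost_assay: float
    cost_chemo_drugs: float
    cost_adverse_events: float
    cost_time_transport: float
    cost_monitoring: float
    cost_recurrence: float

    @property
    def qaly_total(self) -> float:
        return self.qaly_immediate_chemo + self.qaly_long_term

    @property
    def cost_total(self) -> float:
        return (
            self.cost_assay
            + self.cost_chemo_drugs
            + self.cost_adverse_events
            + self.cost_time_transport
            + self.cost_monitoring
            + self.cost_recurrence
        )


@dataclass(frozen=True)
class IncrementalResult:
    """Difference between two arms and the resulting cost per QALY gained."""

    delta_cost: float
    delta_qaly: float
    icer: float | None  # JPY per QALY; None when flagged
    dominance: str | None  # 'dominant' | 'dominated' | 'undefined' | None


def acute_costs(
    chemo_proportion: float, costs: CostInputs
) -> tuple[float, float, float]:
    """Time-zero chemotherapy-related costs (drugs, adverse events,
    patient time and transportation) per average patient, undiscounted."""
    if not 0.0 <= chemo_proportion <= 1.0:
        raise ValueError(f"chemo proportion must lie in [0, 1], got {chemo_proportion}")
    return (
        costs.chemo_drugs.base * chemo_proportion,
        costs.adverse_events.base * chemo_proportion,
        costs.time_transport.base * chemo_proportion,
    )


def immediate_chemo_qaly_loss(chemo_proportion: float, tariff: float) -> float:
    """One-time QALY decrement of undergoing chemotherapy, per average patient."""
    if chemo_proportion < 0 or tariff < 0:
        raise ValueError("chemo proportion and tariff must be non-negative")
    return -tariff * chemo_proportion


def lifetime_outcomes(
    trace: CohortTrace,
    costs: CostInputs,
    utilities: UtilityInputs,
    settings: ModelSettings,
) -> tuple[float, float, float]:
    """Discounted (qaly_long_term, cost_monitoring, cost_recurrence) of a trace."""
    occ = trace.occupancy
    n = occ.shape[0] - 1
    if n < 1:
        return 0.0, 0.0, 0.0
    k = np.arange(n)
    hcc = settings.half_cycle_correction
    df = (1.0 + settings.discount_rate.base) ** -(k + (0.5 if hcc else 0.0))
    if hcc:
        rf = 0.5 * (occ[:-1, RECURRENCE_FREE] + occ[1:, RECURRENCE_FREE])
        rec = 0.5 * (occ[:-1, DISTANT_RECURRENCE] + occ[1:, DISTANT_RECURRENCE])
    else:
        rf = occ[:-1, RECURRENCE_FREE]
        rec = occ[:-1, DISTANT_RECURRENCE]
    qaly = float(
        np.sum(
            df
            * (
                rf * utilities.u_recurrence_free.base
                + rec * utilities.u_progression.base
            )
        )
    )
    cost_monitoring = float(np.sum(df * rf)) * costs.surveillance_annual.base
    cost_recurrence = float(np.sum(df * rec)) * costs.recurrence_annual.base
    return qaly, cost_monitoring, cost_recurrence


def evaluate_strategy(arm: StrategyArm, bundle: InputBundle) -> StrategyResult:
    """Run the six subgroup cohorts of one arm and aggregate Table-style results.

    Each risk group is split into a chemo-treated and an untreated subgroup,
    weighted by cohort share × the arm's recommendation rate.
    """
    settings = bundle.settings
    chemo_proportion = arm.overall_chemo_proportion(bundle.groups)
    qaly_lt = cost_mon = cost_rec = rfs = 0.0
    for group in bundle.groups:
        rate = arm.chemo_rates[group.label]
        for treated, weight in ((True, rate), (False, 1.0 - rate)):
            w = group.cohort_share * weight
            if w == 0.0:
                continue
            spec = subgroup_spec(group, treated, settings)
            trace = run_subgroup_cohort(
                spec, 1.0 if treated else 0.0, bundle.life_table, settings
            )
            q, m, c = lifetime_outcomes(trace, bundle.costs, bundle.utilities, settings)
            qaly_lt += w * q
            cost_mon += w * m
            cost_rec += w * c
            if trace.occupancy.shape[0] > 10:
                rfs += w * trace.occupancy[10, RECURRENCE_FREE]
    drugs, ae, tt = acute_costs(chemo_proportion, bundle.costs)
    return StrategyResult(
        name=arm.name,
        chemo_proportion=chemo_proportion,
        rfs_10y=rfs,
        qaly_immediate_chemo=immediate_chemo_qaly_loss(
            chemo_proportion, bundle.utilities.chemo_qaly_tariff.base
        ),
        qaly_long_term=qaly_lt,
        cost_assay=bundle.costs.assay.base if arm.assay_cost_applied else 0.0,
        cost_chemo_drugs=drugs,
        cost_adverse_events=ae,
        cost_time_transport=tt,
        cost_monitoring=cost_mon,
        cost_recurrence=cost_rec,
    )


def incremental(
    base: StrategyResult, intervention: StrategyResult
) -> IncrementalResult:
    """Incremental cost-effectiveness of the intervention arm versus base.

    The ICER is computed on unrounded internals.  Dominance: the intervention
    is *dominant* if it is cheaper and more effective, *dominated* if costlier
    and less effective; ΔQALY = 0 with Δcost ≠ 0 yields an undefined-ICER flag.
    """
    dc = intervention.cost_total - base.cost_total
    dq = intervention.qaly_total - base.qaly_total
    if dc < 0 and dq > 0:
        return IncrementalResult(dc, dq, None, "dominant")
    if dc > 0 and dq < 0:
        return IncrementalResult(dc, dq, None, "dominated")
    if dq == 0.0:
        return IncrementalResult(dc, dq, None, "undefined" if dc != 0.0 else None)
    return IncrementalResult(dc, dq, dc / dq, None)


def evaluate_both(
    bundle: InputBundle,
) -> tuple[StrategyResult, StrategyResult, IncrementalResult]:
    """Evaluate usual care and the assay-guided arm, plus their increment."""
    without, with_ = strategy_arms(bundle.groups)
    r_without = evaluate_strategy(without, bundle)
    r_with = evaluate_strategy(with_, bundle)
    return r_without, r_with, incremental(r_without, r_with)
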