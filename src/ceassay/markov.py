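"""Annual-cycle four-state Markov cohort engine.

State space: recurrence-free (on study), distant recurrence, breast-cancer
death (including fatal chemotherapy toxicity) and other-cause death.  The
cohort is split into six homogeneous subgroups (three recurrence-score strata
× chemotherapy yes/no); each subgroup is propagated deterministically from
the starting age until the living mass is exhausted or the age horizon is
reached.

Competing risks within a cycle are combined on the rate scale: with
cause-specific rates r1, r2 the total event probability is 1 − e^−(r1+r2),
apportioned r1:(r1+r2) and r2:(r1+r2).  This keeps rows on the probability
simplex even at extreme sensitivity bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import LifeTable, ModelSettings, RiskGroupInput

__all__ = [
    "STATES",
    "RECURRENCE_FREE",
    "DISTANT_RECURRENCE",
    "DEAD_BREAST_CANCER",
    "DEAD_OTHER",
    "SubgroupSpec",
    "CohortTrace",
    "annual_prob_from_cumulative",
    "chemo_adjusted_risk",
    "transition_row_recurrence_free",
    "transition_row_recurrence",
    "apply_time_zero_events",
    "run_subgroup_cohort",
    "subgroup_spec",
]

STATES = ("recurrence_free", "distant_recurrence", "dead_bc", "dead_other")
RECURRENCE_FREE, DISTANT_RECURRENCE, DEAD_BREAST_CANCER, DEAD_OTHER = range(4)

_EXTINCTION = 1e-12
_RISK_HORIZON_YEARS = 10.0  # the published cumulative risks are 10-year risks


def annual_prob_from_cumulative(cum_risk: float, horizon_years: float) -> float:
    """Annual event probability equivalent to a cumulative risk over a horizon.

    Assumes a constant hazard: p = 1 − (1 − cum_risk)^(1/horizon_years), the
    inverse of compounding p over ``horizon_years`` cycles.
    """
    if not 0.0 <= cum_risk < 1.0:
        raise ValueError(f"cumulative risk must lie in [0, 1), got {cum_risk}")
    if horizon_years <= 0:
        raise ValueError(f"horizon must be positive, got {horizon_years}")
    return 1.0 - (1.0 - cum_risk) ** (1.0 / horizon_years)


def chemo_adjusted_risk(baseline_risk_10y: float, rrr: float, treated: bool) -> float:
    """10-year recurrence risk after applying the chemo relative risk reduction."""
    if not 0.0 <= baseline_risk_10y <= 1.0 or not 0.0 <= rrr <= 1.0:
        raise ValueError("baseline risk and RRR must lie in [0, 1]")
    return baseline_risk_10y * (1.0 - rrr) if treated else baseline_risk_10y


@dataclass(frozen=True)
class SubgroupSpec:
    """One homogeneous subgroup: a risk stratum with a fixed chemo decision."""

    label: str
    chemo_treated: bool
    annual_recurrence_prob: float
    recurrence_active_horizon: float | None  # years; None = lifetime hazard
    start_age: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_recurrence_prob < 1.0:
            raise ValueError(
                f"annual recurrence probability must lie in [0, 1), "
                f"got {self.annual_recurrence_prob}"
            )


def subgroup_spec(
    group: RiskGroupInput, treated: bool, settings: ModelSettings
) -> SubgroupSpec:
    """Derive a subgroup's annual recurrence dynamics from published inputs."""
    risk10 = chemo_adjusted_risk(
        group.baseline_risk_10y.base, group.rrr_chemo.base, treated
    )
    horizon = (
        None
        if settings.recurrence_hazard_mode == "lifetime"
        else _RISK_HORIZON_YEARS
    )
    return SubgroupSpec(
        label=group.label,
        chemo_treated=treated,
        annual_recurrence_prob=annual_prob_from_cumulative(
            risk10, _RISK_HORIZON_YEARS
        ),
        recurrence_active_horizon=horizon,
        start_age=settings.start_age.base,
    )


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of one subgroup (row 0 = after time-zero
    events; row k = after k annual cycles)."""

    occupancy: np.ndarray  # shape (n_cycles + 1, 4)
    ages: np.ndarray  # attained age at each row

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != 4 or occ.shape[0] != len(self.ages):
            raise ValueError("occupancy must be (n_rows, 4) aligned with ages")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ValueError("occupancy values must lie in [0, 1]")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every occupancy row must sum to 1")
        dead = occ[:, [DEAD_BREAST_CANCER, DEAD_OTHER]]
        if np.any(np.diff(dead, axis=0) < -1e-12):
            raise ValueError("death-state occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _competing(p1: float, p2: float) -> tuple[float, float]:
    """Split the joint event probability of two competing annual risks.

    Returns (prob of cause 1, prob of cause 2); the joint survival is the
    product (1-p1)(1-p2), apportioned by cause-specific rates.
    """
    with np.errstate(divide="ignore"):
        r1 = -np.log1p(-p1)
        r2 = -np.log1p(-p2)
    if np.isinf(r1) or np.isinf(r2):
        # a certain event: the infinite-rate cause takes the whole cycle
        if np.isinf(r1) and np.isinf(r2):
            return 0.5, 0.5
        return (1.0, 0.0) if np.isinf(r1) else (0.0, 1.0)
    total_rate = r1 + r2
    if total_rate <= 0.0:
        return 0.0, 0.0
    total_prob = -np.expm1(-total_rate)
    return total_prob * r1 / total_rate, total_prob * r2 / total_rate


def transition_row_recurrence_free(
    age: float,
    spec: SubgroupSpec,
    life_table: LifeTable,
    settings: ModelSettings,
    cycle: int | None = None,
) -> np.ndarray:
    """One-cycle transition probabilities out of the recurrence-free state.

    ``cycle`` (years since model start) is needed only when the recurrence
    hazard is limited to the first 10 years; with the default lifetime hazard
    it may be omitted.
    """
    p_rec = spec.annual_recurrence_prob
    if spec.recurrence_active_horizon is not None:
        elapsed = age - spec.start_age if cycle is None else float(cycle)
        if elapsed >= spec.recurrence_active_horizon:
            p_rec = 0.0
    to_rec, to_other = _competing(p_rec, life_table.q(age))
    return np.array([1.0 - to_rec - to_other, to_rec, 0.0, to_other])


def transition_row_recurrence(
    age: float, settings: ModelSettings, life_table: LifeTable
) -> np.ndarray:
    """One-cycle transition probabilities out of the distant-recurrence state."""
    to_bc, to_other = _competing(
        settings.post_recurrence_mortality_annual.base, life_table.q(age)
    )
    return np.array([0.0, 1.0 - to_bc - to_other, to_bc, to_other])


def apply_time_zero_events(chemo_rate: float, settings: ModelSettings) -> np.ndarray:
    """Initial occupancy after fatal chemotherapy toxicity at time zero.

    Toxicity deaths are treatment-attributable and counted as breast-cancer
    deaths.
    """
    if not 0.0 <= chemo_rate <= 1.0:
        raise ValueError(f"chemo rate must lie in [0, 1], got {chemo_rate}")
    dead = chemo_rate * settings.fatal_toxicity_risk.base
    return np.array([1.0 - dead, 0.0, dead, 0.0])


def run_subgroup_cohort(
    spec: SubgroupSpec,
    chemo_rate_context: float,
    life_table: LifeTable,
    settings: ModelSettings,
) -> CohortTrace:
    """Propagate one subgroup from the starting age to extinction.

    ``chemo_rate_context`` is the fraction of this subgroup exposed to
    chemotherapy at time zero (1.0 for a treated subgroup, 0.0 untreated);
    it controls only the fatal-toxicity entry event.  Fully deterministic.
    """
    start_age = spec.start_age
    n_cycles = max(1, int(np.ceil(settings.max_age - start_age)))
    rows = [apply_time_zero_events(chemo_rate_context, settings)]
    for k in range(n_cycles):
        row = rows[-1]
        if row[RECURRENCE_FREE] + row[DISTANT_RECURRENCE] < _EXTINCTION:
            break
        age = start_age + k
        t_rf = transition_row_recurrence_free(age, spec, life_table, settings, cycle=k)
        t_rec = transition_row_recurrence(age, settings, life_table)
        new = (
            row[RECURRENCE_FREE] * t_rf
            + row[DISTANT_RECURRENCE] * t_rec
            + np.array([0.0, 0.0, row[DEAD_BREAST_CANCER], row[DEAD_OTHER]])
        )
        rows.append(new)
    occupancy = np.vstack(rows)
    ages = start_age + np.arange(occupancy.shape[0], dtype=float)
    return CohortTrace(occupancy=occupancy, ages=ages)
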