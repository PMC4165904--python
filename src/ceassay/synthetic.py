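"""Synthetic inputs and an individual-level microsimulation oracle.

Three generators:

* :func:`generate_decision_impact_table` emulates the decision-impact study —
  patient-level risk-group membership and paired pre/post-assay chemotherapy
  recommendations — and aggregates it back into risk-group inputs.
* :func:`generate_life_table` produces parametric background-mortality tables
  (flat, Gompertz, or Gompertz–Makeham).  The bundled synthetic
  Japanese-female fixture is the Gompertz–Makeham variant with
  a=6.211e-6, b=0.105, c=2e-4.
* :func:`microsim_oracle` re-implements the cohort model as a patient-level
  Monte-Carlo simulation using the same per-cycle transition probabilities
  and the same accrual rules, providing an independent stochastic check of
  the deterministic engine.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import (
    DEAD_BREAST_CANCER,
    DEAD_OTHER,
    DISTANT_RECURRENCE,
    RECURRENCE_FREE,
    subgroup_spec,
)
from .parameters import (
    RISK_LABELS,
    Bounded,
    InputBundle,
    LifeTable,
    RiskGroupInput,
    StrategyArm,
    ValidationError,
    default_inputs,
)

__all__ = [
    "SyntheticCohortSpec",
    "MicrosimEstimate",
    "generate_decision_impact_table",
    "generate_life_table",
    "microsim_oracle",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Sampling design for a synthetic decision-impact study."""

    n_patients: int
    group_probs: dict[str, float]
    chemo_probs_pre: dict[str, float]
    chemo_probs_post: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be at least 1")
        total = sum(self.group_probs[lab] for lab in RISK_LABELS)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"group probabilities sum to {total}, expected 1")

    @classmethod
    def from_bundle(
        cls, bundle: InputBundle, n_patients: int, seed: int
    ) -> "SyntheticCohortSpec":
        """Use the observed cohort's shares and recommendation rates."""
        return cls(
            n_patients=n_patients,
            group_probs={g.label: g.cohort_share for g in bundle.groups},
            chemo_probs_pre={g.label: g.chemo_rate_pre for g in bundle.groups},
            chemo_probs_post={g.label: g.chemo_rate_post for g in bundle.groups},
            seed=seed,
        )


def generate_decision_impact_table(
    spec: SyntheticCohortSpec, template: InputBundle | None = None
) -> tuple[pd.DataFrame, tuple[RiskGroupInput, ...]]:
    """Sample a patient-level decision-impact table and aggregate it.

    Each patient draws a risk group, then independent Bernoulli pre- and
    post-assay chemotherapy recommendations at the group's rates.  The
    aggregate recovers empirical counts; recurrence risks and chemo relative
    risk reductions are copied from ``template`` (the bundled base case by
    default).  Groups that receive no patients are omitted from the
    aggregate, since their recommendation rates are undefined.
    """
    template = template if template is not None else default_inputs()
    rng = np.random.default_rng(spec.seed)
    probs = np.array([spec.group_probs[lab] for lab in RISK_LABELS])
    group_idx = rng.choice(len(RISK_LABELS), size=spec.n_patients, p=probs)
    p_pre = np.array([spec.chemo_probs_pre[lab] for lab in RISK_LABELS])[group_idx]
    p_post = np.array([spec.chemo_probs_post[lab] for lab in RISK_LABELS])[group_idx]
    rec_pre = (rng.random(spec.n_patients) < p_pre).astype(int)
    rec_post = (rng.random(spec.n_patients) < p_post).astype(int)
    table = pd.DataFrame(
        {
            "patient_id": np.arange(spec.n_patients),
            "risk_group": [RISK_LABELS[i] for i in group_idx],
            "rec_pre": rec_pre,
            "rec_post": rec_post,
        }
    )
    groups = []
    for i, label in enumerate(RISK_LABELS):
        mask = group_idx == i
        n = int(mask.sum())
        if n == 0:
            continue
        tg = template.group(label)
        groups.append(
            dataclasses.replace(
                tg,
                n_patients=n,
                n_chemo_pre=int(rec_pre[mask].sum()),
                n_chemo_post=int(rec_post[mask].sum()),
                cohort_share=n / spec.n_patients,
            )
        )
    return table, tuple(groups)


def generate_life_table(
    model: str, params: dict[str, float], max_age: int = 110
) -> LifeTable:
    """Parametric background-mortality table.

    ``flat``: constant annual probability ``q``.
    ``gompertz``: q(age) = 1 − exp(−a·e^(b·age)).
    ``gompertz_makeham``: q(age) = 1 − exp(−(c + a·e^(b·(age+1/2)))) — the
    age-offset mid-year hazard used for the bundled synthetic fixture.
    """
    ages = np.arange(0, max_age + 1, dtype=float)
    if model == "flat":
        q = np.full_like(ages, float(params["q"]))
    elif model == "gompertz":
        a, b = float(params["a"]), float(params["b"])
        if a <= 0 or b <= 0:
            raise ValidationError("gompertz parameters must be positive")
        q = 1.0 - np.exp(-a * np.exp(b * ages))
    elif model == "gompertz_makeham":
        a, b, c = float(params["a"]), float(params["b"]), float(params["c"])
        if a <= 0 or b <= 0 or c < 0:
            raise ValidationError("gompertz-makeham parameters must be positive")
        q = 1.0 - np.exp(-(c + a * np.exp(b * (ages + 0.5))))
    else:
        raise ValidationError(f"unknown life-table model {model!r}")
    if np.any(q > 1.0):
        warnings.warn("life-table probabilities clamped to 1", stacklevel=2)
        q = np.clip(q, 0.0, 1.0)
    if np.any(q < 0.0):
        raise ValidationError("life-table probabilities must be non-negative")
    return LifeTable(ages, q)


@dataclass(frozen=True)
class MicrosimEstimate:
    """Monte-Carlo means and standard errors for one strategy arm."""

    arm: str
    n_patients: int
    seed: int
    mean: dict[str, float] = field(repr=False)
    se: dict[str, float] = field(repr=False)

    KEYS = (
        "chemo_proportion",
        "rfs_10y",
        "qaly_immediate_chemo",
        "qaly_long_term",
        "qaly_total",
        "cost_assay",
        "cost_chemo_drugs",
        "cost_adverse_events",
        "cost_time_transport",
        "cost_monitoring",
        "cost_recurrence",
        "cost_total",
    )


def microsim_oracle(
    bundle: InputBundle, arm: StrategyArm, n_patients: int, seed: int
) -> MicrosimEstimate:
    """Patient-level Monte-Carlo re-implementation of one strategy arm.

    Uses the same per-cycle transition probabilities as the cohort engine but
    realises them as Bernoulli draws, and accrues discounted rewards with the
    same (half-cycle) convention: each cycle's reward is the mean of the
    cycle-start and cycle-end state rewards.  A single seeded PCG64 stream
    drives the fully vectorised simulation, so runs are bit-reproducible.
    """
    if n_patients < 1:
        raise ValidationError("n_patients must be at least 1")
    settings = bundle.settings
    costs, utilities = bundle.costs, bundle.utilities
    rng = np.random.default_rng(seed)

    shares = np.array([g.cohort_share for g in bundle.groups])
    group_idx = rng.choice(len(bundle.groups), size=n_patients, p=shares)
    rate_by_group = np.array(
        [arm.chemo_rates[g.label] for g in bundle.groups]
    )
    chemo = rng.random(n_patients) < rate_by_group[group_idx]

    # per-patient annual recurrence probability and hazard horizon
    p_rec = np.empty(n_patients)
    horizon = np.full(n_patients, np.inf)
    for i, g in enumerate(bundle.groups):
        for treated in (False, True):
            spec = subgroup_spec(g, treated, settings)
            mask = (group_idx == i) & (chemo == treated)
            p_rec[mask] = spec.annual_recurrence_prob
            if spec.recurrence_active_horizon is not None:
                horizon[mask] = spec.recurrence_active_horizon

    state = np.full(n_patients, RECURRENCE_FREE, dtype=np.int8)
    toxic = chemo & (rng.random(n_patients) < settings.fatal_toxicity_risk.base)
    state[toxic] = DEAD_BREAST_CANCER

    start_age = settings.start_age.base
    rate = settings.discount_rate.base
    hcc = settings.half_cycle_correction
    n_cycles = max(1, int(np.ceil(settings.max_age - start_age)))
    u_rf, u_prog = utilities.u_recurrence_free.base, utilities.u_progression.base
    p_bc = settings.post_recurrence_mortality_annual.base

    qaly_lt = np.zeros(n_patients)
    mon_years = np.zeros(n_patients)  # discounted years recurrence-free
    rec_years = np.zeros(n_patients)  # discounted years in recurrence
    rfs_10y = np.zeros(n_patients)

    r1_all = -np.log1p(-p_rec)
    for k in range(n_cycles):
        if k == 10:
            rfs_10y = (state == RECURRENCE_FREE).astype(float)
        if not np.any((state == RECURRENCE_FREE) | (state == DISTANT_RECURRENCE)):
            if k >= 10:
                break
        age = start_age + k
        q_other = bundle.life_table.q(age)
        r2 = -np.log1p(-q_other)

        start_rf = state == RECURRENCE_FREE
        start_rec = state == DISTANT_RECURRENCE
        u = rng.random(n_patients)
        new_state = state.copy()

        # recurrence-free: competing recurrence vs other-cause death
        r1 = np.where(k < horizon, r1_all, 0.0)
        total_rate = r1 + r2
        with np.errstate(invalid="ignore", divide="ignore"):
            total_prob = -np.expm1(-total_rate)
            frac = np.where(total_rate > 0, r1 / np.where(total_rate > 0, total_rate, 1.0), 0.0)
        a_rec = total_prob * frac
        a_oth = total_prob - a_rec
        go_rec = start_rf & (u < a_rec)
        go_oth = start_rf & ~go_rec & (u < a_rec + a_oth)
        new_state[go_rec] = DISTANT_RECURRENCE
        new_state[go_oth] = DEAD_OTHER

        # distant recurrence: breast-cancer death vs other-cause death
        rb = -np.log1p(-p_bc)
        tot = rb + r2
        if tot > 0:
            tp = -np.expm1(-tot)
            b_bc, b_oth = tp * rb / tot, tp * r2 / tot
        else:
            b_bc = b_oth = 0.0
        die_bc = start_rec & (u < b_bc)
        die_oth = start_rec & ~die_bc & (u < b_bc + b_oth)
        new_state[die_bc] = DEAD_BREAST_CANCER
        new_state[die_oth] = DEAD_OTHER

        df = (1.0 + rate) ** -(k + (0.5 if hcc else 0.0))
        if hcc:
            w_rf = 0.5 * (
                start_rf.astype(float) + (new_state == RECURRENCE_FREE)
            )
            w_rec = 0.5 * (
                start_rec.astype(float) + (new_state == DISTANT_RECURRENCE)
            )
        else:
            w_rf = start_rf.astype(float)
            w_rec = start_rec.astype(float)
        qaly_lt += df * (w_rf * u_rf + w_rec * u_prog)
        mon_years += df * w_rf
        rec_years += df * w_rec
        state = new_state
    if n_cycles <= 10:
        rfs_10y = (state == RECURRENCE_FREE).astype(float) if n_cycles == 10 else rfs_10y

    chemo_f = chemo.astype(float)
    per_patient = {
        "chemo_proportion": chemo_f,
        "rfs_10y": rfs_10y,
        "qaly_immediate_chemo": -utilities.chemo_qaly_tariff.base * chemo_f,
        "qaly_long_term": qaly_lt,
        "cost_assay": np.full(
            n_patients, costs.assay.base if arm.assay_cost_applied else 0.0
        ),
        "cost_chemo_drugs": costs.chemo_drugs.base * chemo_f,
        "cost_adverse_events": costs.adverse_events.base * chemo_f,
        "cost_time_transport": costs.time_transport.base * chemo_f,
        "cost_monitoring": costs.surveillance_annual.base * mon_years,
        "cost_recurrence": costs.recurrence_annual.base * rec_years,
    }
    per_patient["qaly_total"] = (
        per_patient["qaly_immediate_chemo"] + per_patient["qaly_long_term"]
    )
    per_patient["cost_total"] = sum(
        per_patient[k]
        for k in (
            "cost_assay",
            "cost_chemo_drugs",
            "cost_adverse_events",
            "cost_time_transport",
            "cost_monitoring",
            "cost_recurrence",
        )
    )
    mean = {k: float(np.mean(v)) for k, v in per_patient.items()}
    se = {
        k: float(np.std(v, ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0
        for k, v in per_patient.items()
    }
    return MicrosimEstimate(
        arm=arm.name, n_patients=n_patients, seed=seed, mean=mean, se=se
    )
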