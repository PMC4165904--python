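"""One-way sensitivity (tornado) analysis, alternative risk scenario and the
chemotherapy-cost break-even threshold.

Every input carrying sensitivity bounds is varied one at a time to its low and
high bound, with all other inputs at base, and the full model re-evaluated.
Tornado bars are plotted and ranked on the cost-per-QALY ratio ΔC/ΔE, which is
defined whenever ΔQALY ≠ 0 — a negative ratio simply means the assay arm is
cost-saving (dominant) at that bound.  Ranking on this scale keeps cost-saving
bounds, such as the upper chemotherapy drug cost, at the top of the diagram
where the published analysis places them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.optimize import brentq

from .outcomes import IncrementalResult, evaluate_both
from .parameters import Bounded, InputBundle, ValidationError

__all__ = [
    "SensitivityParameter",
    "TornadoRow",
    "enumerate_parameters",
    "one_way_sensitivity",
    "run_alternative_scenario",
    "threshold_chemo_cost",
    "tornado_frame",
    "plot_tornado",
]


@dataclass(frozen=True)
class SensitivityParameter:
    """One scalar input with its one-way range (dotted id into the bundle)."""

    id: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValidationError(f"{self.id}: bounds must bracket base")


@dataclass(frozen=True)
class TornadoRow:
    """Cost-per-QALY ratio at the low and high bound of one varied input.

    ``dominance_at_low``/``_high`` annotate bounds where the assay arm is
    strictly dominant or dominated; the ratio itself is still reported there.
    A bound whose evaluation is infeasible (e.g. a probability leaving [0,1])
    or where ΔQALY = 0 leaves the ratio as NaN and sets ``invalid``.
    """

    id: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    dominance_at_low: str | None = None
    dominance_at_high: str | None = None
    invalid: bool = False

    @property
    def swing(self) -> float:
        if self.invalid:
            return math.nan
        return abs(self.icer_at_high - self.icer_at_low)


def enumerate_parameters(bundle: InputBundle) -> list[SensitivityParameter]:
    """All inputs with sensitivity bounds, in bundle order."""
    out = []
    for dotted_id, b in bundle.bounded_inputs():
        assert isinstance(b, Bounded)
        out.append(SensitivityParameter(dotted_id, b.base, b.low, b.high))
    return out


def _ratio(inc: IncrementalResult) -> tuple[float, str | None]:
    if inc.delta_qaly == 0.0:
        return math.nan, inc.dominance
    return inc.delta_cost / inc.delta_qaly, inc.dominance


def _evaluate_at(bundle: InputBundle, param_id: str, value: float):
    inc = evaluate_both(bundle.replace_value(param_id, value))[2]
    return _ratio(inc)


def one_way_sensitivity(bundle: InputBundle) -> list[TornadoRow]:
    """Tornado analysis: two full model evaluations per bounded input.

    Rows are sorted by descending swing; infeasible rows sort last.
    Deterministic.
    """
    rows: list[TornadoRow] = []
    for p in enumerate_parameters(bundle):
        try:
            icer_lo, dom_lo = _evaluate_at(bundle, p.id, p.low)
            icer_hi, dom_hi = _evaluate_at(bundle, p.id, p.high)
            invalid = math.isnan(icer_lo) or math.isnan(icer_hi)
        except (ValidationError, ValueError):
            icer_lo = icer_hi = math.nan
            dom_lo = dom_hi = None
            invalid = True
        rows.append(
            TornadoRow(
                id=p.id,
                low_value=p.low,
                high_value=p.high,
                icer_at_low=icer_lo,
                icer_at_high=icer_hi,
                dominance_at_low=dom_lo,
                dominance_at_high=dom_hi,
                invalid=invalid,
            )
        )
    return sorted(
        rows, key=lambda r: (math.isnan(r.swing), -(r.swing if r.swing == r.swing else 0.0))
    )


def run_alternative_scenario(bundle: InputBundle) -> IncrementalResult:
    """Re-run the full analysis with US/UK validation-study recurrence risks.

    Only the three baseline 10-year risks change; acute-cost differences are
    untouched because they do not depend on recurrence risk.
    """
    return evaluate_both(bundle.with_risk_source("us_uk"))[2]


def threshold_chemo_cost(
    bundle: InputBundle,
    bracket: tuple[float, float] = (0.0, 1e7),
    tol_yen: float = 1.0,
) -> float | None:
    """Chemotherapy drug cost at which the assay arm becomes cost-saving.

    Bisects the incremental cost (assay arm minus usual care) over
    ``bracket``; the incremental cost is affine and strictly decreasing in
    the drug cost because the assay arm treats fewer patients.  Returns the
    break-even drug cost in JPY, or None when the incremental cost does not
    change sign over the bracket.
    """

    def delta_cost(drug_cost: float) -> float:
        return evaluate_both(bundle.replace_value("costs.chemo_drugs", drug_cost))[
            2
        ].delta_cost

    lo, hi = bracket
    f_lo, f_hi = delta_cost(lo), delta_cost(hi)
    if f_lo * f_hi > 0:
        return None
    return float(brentq(delta_cost, lo, hi, xtol=tol_yen / 2.0))


def tornado_frame(rows: list[TornadoRow]) -> pd.DataFrame:
    """Tabular tornado output (sorted as given)."""
    return pd.DataFrame(
        {
            "parameter": [r.id for r in rows],
            "low_value": [r.low_value for r in rows],
            "high_value": [r.high_value for r in rows],
            "icer_at_low": [r.icer_at_low for r in rows],
            "icer_at_high": [r.icer_at_high for r in rows],
            "swing": [r.swing for r in rows],
            "dominance_at_low": [r.dominance_at_low for r in rows],
            "dominance_at_high": [r.dominance_at_high for r in rows],
        }
    )


def plot_tornado(
    rows: list[TornadoRow],
    base_icer: float,
    path: str | Path,
    title: str = "One-way sensitivity analysis",
) -> None:
    """Write a tornado diagram (horizontal bars around the base-case ICER)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotted = [r for r in rows if not r.invalid][::-1]  # widest on top
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(plotted) + 1.5))
    for i, r in enumerate(plotted):
        lo, hi = sorted((r.icer_at_low, r.icer_at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base case")
    ax.set_yticks(range(len(plotted)))
    ax.set_yticklabels([r.id for r in plotted], fontsize=8)
    ax.set_xlabel("cost per QALY gained (JPY)")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
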