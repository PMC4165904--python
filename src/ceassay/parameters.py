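"""Model inputs: risk strata, costs, utilities, settings, life table, strategy arms.

Every uncertain input is a :class:`Bounded` triple (base value plus the low/high
range used in one-way sensitivity analysis).  The bundled default configuration
reproduces the base case of the decision-impact cohort: 104 ER+, LN− early
breast cancer patients stratified by the 21-gene recurrence score into
low (n=50), intermediate (n=37) and high (n=17) risk groups, with physicians'
adjuvant-chemotherapy recommendations recorded before and after seeing the
assay result.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Bounded",
    "RiskGroupInput",
    "CostInputs",
    "UtilityInputs",
    "ModelSettings",
    "LifeTable",
    "StrategyArm",
    "InputBundle",
    "ConfigurationError",
    "ValidationError",
    "load_inputs",
    "default_inputs",
    "write_config",
    "strategy_arms",
    "default_config_path",
]

RISK_LABELS = ("low", "intermediate", "high")
RISK_SOURCES = ("japan", "us_uk")
HAZARD_MODES = ("lifetime", "first_10_years")


class ConfigurationError(ValueError):
    """Raised when a config file has missing/extra keys or cannot be parsed."""


class ValidationError(ValueError):
    """Raised when an input value violates a model invariant."""


@dataclass(frozen=True)
class Bounded:
    """A scalar input with its one-way sensitivity range (low ≤ base ≤ high)."""

    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"bounds must bracket base value: low={self.low}, "
                f"base={self.base}, high={self.high}"
            )

    def with_base(self, value: float) -> "Bounded":
        """Return a copy whose base is replaced (bounds widened if needed).

        Used by the sensitivity machinery, which evaluates the model at the
        range endpoints themselves.
        """
        return Bounded(value, min(self.low, value), max(self.high, value))


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class RiskGroupInput:
    """One 21-gene-assay risk stratum of the decision-impact cohort.

    ``chemo_rate_pre``/``chemo_rate_post`` are the proportions of the stratum
    recommended adjuvant chemotherapy before/after the assay result was seen,
    stored as exact count ratios so that arm-level acute costs reproduce the
    source counts to the yen.
    """

    label: str
    n_patients: int
    n_chemo_pre: int
    n_chemo_post: int
    cohort_share: float
    baseline_risk_10y: Bounded  # 10-year distant recurrence risk, no chemo
    rrr_chemo: Bounded  # relative risk reduction of recurrence with chemo

    def __post_init__(self) -> None:
        if self.label not in RISK_LABELS:
            raise ValidationError(f"unknown risk group label {self.label!r}")
        for name in ("n_chemo_pre", "n_chemo_post"):
            n = getattr(self, name)
            if not 0 <= n <= self.n_patients:
                raise ValidationError(
                    f"{self.label}.{name}={n} outside [0, {self.n_patients}]"
                )
        _check_unit(f"{self.label}.cohort_share", self.cohort_share)
        for name in ("baseline_risk_10y", "rrr_chemo"):
            b = getattr(self, name)
            for v in (b.low, b.base, b.high):
                _check_unit(f"{self.label}.{name}", v)

    @property
    def chemo_rate_pre(self) -> float:
        return self.n_chemo_pre / self.n_patients

    @property
    def chemo_rate_post(self) -> float:
        return self.n_chemo_post / self.n_patients


@dataclass(frozen=True)
class CostInputs:
    """Costs in 2013 JPY.  Acute components are one-time, per chemo-treated
    patient; surveillance/recurrence costs accrue annually by health state."""

    assay: Bounded
    chemo_drugs: Bounded
    adverse_events: Bounded
    time_transport: Bounded
    surveillance_annual: Bounded
    recurrence_annual: Bounded

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            b: Bounded = getattr(self, f.name)
            if b.low < 0:
                raise ValidationError(f"cost {f.name} must be non-negative")


@dataclass(frozen=True)
class UtilityInputs:
    u_recurrence_free: Bounded
    u_progression: Bounded
    chemo_qaly_tariff: Bounded  # one-time QALY loss per chemo-treated patient

    def __post_init__(self) -> None:
        for name in ("u_recurrence_free", "u_progression"):
            b: Bounded = getattr(self, name)
            for v in (b.low, b.base, b.high):
                _check_unit(name, v)
        if self.chemo_qaly_tariff.low < 0:
            raise ValidationError("chemo_qaly_tariff must be non-negative")


@dataclass(frozen=True)
class ModelSettings:
    start_age: Bounded
    discount_rate: Bounded
    post_recurrence_mortality_annual: Bounded
    fatal_toxicity_risk: Bounded
    max_age: float = 110.0
    cycle_length: float = 1.0
    recurrence_hazard_mode: str = "lifetime"
    half_cycle_correction: bool = True
    risk_source: str = "japan"

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate.base < 1.0:
            raise ValidationError(
                f"discount_rate must lie in [0, 1), got {self.discount_rate.base}"
            )
        if self.start_age.base >= self.max_age:
            raise ValidationError(
                f"start_age {self.start_age.base} must be below max_age {self.max_age}"
            )
        if self.cycle_length != 1.0:
            raise ValidationError("only an annual cycle length is supported")
        if self.recurrence_hazard_mode not in HAZARD_MODES:
            raise ValidationError(
                f"recurrence_hazard_mode must be one of {HAZARD_MODES}"
            )
        if self.risk_source not in RISK_SOURCES:
            raise ValidationError(f"risk_source must be one of {RISK_SOURCES}")
        for name in ("post_recurrence_mortality_annual", "fatal_toxicity_risk"):
            b: Bounded = getattr(self, name)
            for v in (b.low, b.base, b.high):
                _check_unit(name, v)


class LifeTable:
    """Age-indexed annual probabilities of death from other (non-breast-cancer)
    causes.  Lookups beyond the last tabulated age return the last value."""

    def __init__(self, ages: np.ndarray, q_annual: np.ndarray):
        ages = np.asarray(ages, dtype=float)
        q = np.asarray(q_annual, dtype=float)
        if ages.ndim != 1 or ages.shape != q.shape or ages.size == 0:
            raise ValidationError("life table needs matching 1-d age/q columns")
        if np.any(np.diff(ages) <= 0):
            raise ValidationError("life table ages must be strictly increasing")
        if np.any((q < 0) | (q > 1)):
            bad = q[(q < 0) | (q > 1)][0]
            raise ValidationError(f"life table q_annual {bad} outside [0, 1]")
        self.ages = ages
        self.q_annual = q

    def q(self, age: float) -> float:
        """Annual other-cause death probability at (floor of) ``age``."""
        i = int(np.searchsorted(self.ages, np.floor(age), side="right")) - 1
        return float(self.q_annual[max(0, min(i, len(self.ages) - 1))])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if list(df.columns) != ["age", "q_annual"]:
            raise ConfigurationError(
                f"life table {path} must have columns age,q_annual; "
                f"got {list(df.columns)}"
            )
        return cls(df["age"].to_numpy(), df["q_annual"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages.astype(int), "q_annual": self.q_annual}).to_csv(
            path, index=False
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.q_annual, other.q_annual)
        )


@dataclass(frozen=True)
class StrategyArm:
    """One strategy: chemotherapy recommendation rates per risk group.

    The ``without_assay`` arm uses pre-assay rates and incurs no assay cost;
    the ``with_assay`` arm uses post-assay rates and pays for the assay once
    per patient at time zero.
    """

    name: str
    chemo_rates: dict[str, float]  # label -> proportion recommended chemo
    assay_cost_applied: bool

    def __post_init__(self) -> None:
        for label, r in self.chemo_rates.items():
            _check_unit(f"{self.name}.chemo_rates[{label}]", r)

    def overall_chemo_proportion(self, groups: tuple[RiskGroupInput, ...]) -> float:
        return sum(g.cohort_share * self.chemo_rates[g.label] for g in groups)


@dataclass(frozen=True)
class InputBundle:
    """Fully validated model inputs for one risk source."""

    groups: tuple[RiskGroupInput, RiskGroupInput, RiskGroupInput]
    costs: CostInputs
    utilities: UtilityInputs
    settings: ModelSettings
    life_table: LifeTable
    # 10-year baseline recurrence risks for both sources, keyed
    # source -> label -> Bounded, so scenarios can swap risk source.
    risk_tables: dict[str, dict[str, Bounded]] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(g.cohort_share for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"cohort shares sum to {total}, expected 1")

    def group(self, label: str) -> RiskGroupInput:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    def with_risk_source(self, source: str) -> "InputBundle":
        """Return a bundle using the other validation-study risk estimates."""
        if source not in RISK_SOURCES:
            raise ValidationError(f"risk_source must be one of {RISK_SOURCES}")
        if not self.risk_tables:
            raise ValidationError("bundle carries no alternative risk tables")
        groups = tuple(
            dataclasses.replace(g, baseline_risk_10y=self.risk_tables[source][g.label])
            for g in self.groups
        )
        settings = dataclasses.replace(self.settings, risk_source=source)
        return dataclasses.replace(self, groups=groups, settings=settings)

    # -- dotted-path access used by the sensitivity machinery ---------------

    def replace_value(self, dotted_id: str, value: float) -> "InputBundle":
        """Return a new bundle with one scalar base value replaced.

        ``dotted_id`` addresses Bounded inputs, e.g. ``costs.chemo_drugs``,
        ``utilities.u_progression``, ``groups.high.rrr_chemo`` or
        ``settings.start_age``.
        """
        parts = dotted_id.split(".")
        if parts[0] == "groups" and len(parts) == 3:
            label, name = parts[1], parts[2]
            groups = tuple(
                dataclasses.replace(
                    g, **{name: getattr(g, name).with_base(value)}
                )
                if g.label == label
                else g
                for g in self.groups
            )
            if all(g is o for g, o in zip(groups, self.groups)):
                raise KeyError(dotted_id)
            return dataclasses.replace(self, groups=groups)
        if len(parts) == 2 and parts[0] in ("costs", "utilities", "settings"):
            section = getattr(self, parts[0])
            if not hasattr(section, parts[1]):
                raise KeyError(dotted_id)
            bounded: Bounded = getattr(section, parts[1])
            new_section = dataclasses.replace(
                section, **{parts[1]: bounded.with_base(value)}
            )
            return dataclasses.replace(self, **{parts[0]: new_section})
        raise KeyError(dotted_id)

    def bounded_inputs(self) -> Iterator[tuple[str, Bounded]]:
        """Yield (dotted_id, Bounded) for every input with sensitivity bounds."""
        for g in self.groups:
            yield f"groups.{g.label}.baseline_risk_10y", g.baseline_risk_10y
            yield f"groups.{g.label}.rrr_chemo", g.rrr_chemo
        for section_name in ("costs", "utilities", "settings"):
            section = getattr(self, section_name)
            for f in dataclasses.fields(section):
                v = getattr(section, f.name)
                if isinstance(v, Bounded):
                    yield f"{section_name}.{f.name}", v


# ---------------------------------------------------------------------------
# configuration I/O


def default_config_path() -> Path:
    """Path of the bundled base-case configuration."""
    return Path(resources.files("ceassay") / "data" / "default_config.yaml")


_TOP_KEYS = {"risk_source", "life_table", "groups", "costs", "utilities", "settings"}
_GROUP_KEYS = {"n_patients", "n_chemo_pre", "n_chemo_post", "baseline_risk_10y", "rrr_chemo"}
_SETTINGS_KEYS = {
    "start_age",
    "discount_rate",
    "post_recurrence_mortality_annual",
    "fatal_toxicity_risk",
    "max_age",
    "cycle_length",
    "recurrence_hazard_mode",
    "half_cycle_correction",
}


def _require_keys(mapping: dict, required: set[str], context: str) -> None:
    missing = required - set(mapping)
    extra = set(mapping) - required
    if missing:
        raise ConfigurationError(f"{context}: missing key(s) {sorted(missing)}")
    if extra:
        raise ConfigurationError(f"{context}: unexpected key(s) {sorted(extra)}")


def _bounded(node: object, context: str) -> Bounded:
    if not isinstance(node, dict):
        raise ConfigurationError(f"{context}: expected a base/low/high mapping")
    _require_keys(node, {"base", "low", "high"}, context)
    return Bounded(float(node["base"]), float(node["low"]), float(node["high"]))


def load_inputs(config_path: str | Path) -> InputBundle:
    """Load and validate a full input bundle from a YAML config.

    The life-table CSV referenced by the config is resolved relative to the
    config file's directory.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigurationError(f"config file not found: {config_path}")
    with open(config_path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - parser detail
            raise ConfigurationError(f"cannot parse {config_path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{config_path}: top level must be a mapping")
    _require_keys(raw, _TOP_KEYS, str(config_path))

    lt_path = Path(raw["life_table"])
    if not lt_path.is_absolute():
        lt_path = config_path.parent / lt_path
    if not lt_path.exists():
        raise ConfigurationError(f"life table file not found: {lt_path}")
    life_table = LifeTable.from_csv(lt_path)

    risk_source = str(raw["risk_source"])
    risk_tables: dict[str, dict[str, Bounded]] = {s: {} for s in RISK_SOURCES}
    groups = []
    n_total = sum(int(raw["groups"][lab]["n_patients"]) for lab in RISK_LABELS)
    for label in RISK_LABELS:
        if label not in raw["groups"]:
            raise ConfigurationError(f"groups: missing risk group {label!r}")
        node = raw["groups"][label]
        _require_keys(node, _GROUP_KEYS, f"groups.{label}")
        risk_node = node["baseline_risk_10y"]
        _require_keys(risk_node, set(RISK_SOURCES), f"groups.{label}.baseline_risk_10y")
        for source in RISK_SOURCES:
            risk_tables[source][label] = _bounded(
                risk_node[source], f"groups.{label}.baseline_risk_10y.{source}"
            )
        n = int(node["n_patients"])
        groups.append(
            RiskGroupInput(
                label=label,
                n_patients=n,
                n_chemo_pre=int(node["n_chemo_pre"]),
                n_chemo_post=int(node["n_chemo_post"]),
                cohort_share=n / n_total,
                baseline_risk_10y=risk_tables[risk_source][label],
                rrr_chemo=_bounded(node["rrr_chemo"], f"groups.{label}.rrr_chemo"),
            )
        )

    cost_fields = {f.name for f in dataclasses.fields(CostInputs)}
    _require_keys(raw["costs"], cost_fields, "costs")
    costs = CostInputs(
        **{k: _bounded(v, f"costs.{k}") for k, v in raw["costs"].items()}
    )

    util_fields = {f.name for f in dataclasses.fields(UtilityInputs)}
    _require_keys(raw["utilities"], util_fields, "utilities")
    utilities = UtilityInputs(
        **{k: _bounded(v, f"utilities.{k}") for k, v in raw["utilities"].items()}
    )

    s = raw["settings"]
    _require_keys(s, _SETTINGS_KEYS, "settings")
    settings = ModelSettings(
        start_age=_bounded(s["start_age"], "settings.start_age"),
        discount_rate=_bounded(s["discount_rate"], "settings.discount_rate"),
        post_recurrence_mortality_annual=_bounded(
            s["post_recurrence_mortality_annual"],
            "settings.post_recurrence_mortality_annual",
        ),
        fatal_toxicity_risk=_bounded(
            s["fatal_toxicity_risk"], "settings.fatal_toxicity_risk"
        ),
        max_age=float(s["max_age"]),
        cycle_length=float(s["cycle_length"]),
        recurrence_hazard_mode=str(s["recurrence_hazard_mode"]),
        half_cycle_correction=bool(s["half_cycle_correction"]),
        risk_source=risk_source,
    )

    return InputBundle(
        groups=tuple(groups),
        costs=costs,
        utilities=utilities,
        settings=settings,
        life_table=life_table,
        risk_tables=risk_tables,
    )


def default_inputs(risk_source: str = "japan") -> InputBundle:
    """The bundled base case (the published decision-impact cohort)."""
    bundle = load_inputs(default_config_path())
    if risk_source != bundle.settings.risk_source:
        bundle = bundle.with_risk_source(risk_source)
    return bundle


def _bounded_dict(b: Bounded) -> dict:
    return {"base": b.base, "low": b.low, "high": b.high}


def write_config(bundle: InputBundle, config_path: str | Path,
                 life_table_name: str = "life_table.csv") -> Path:
    """Serialize a bundle to YAML (+ life-table CSV next to it).

    Round-trips bit-exactly through :func:`load_inputs`.
    """
    config_path = Path(config_path)
    config_path.parent.mkdir(parents=True, exist_ok=True)
    bundle.life_table.to_csv(config_path.parent / life_table_name)
    risk_tables = bundle.risk_tables or {
        bundle.settings.risk_source: {
            g.label: g.baseline_risk_10y for g in bundle.groups
        }
    }
    doc = {
        "risk_source": bundle.settings.risk_source,
        "life_table": life_table_name,
        "groups": {
            g.label: {
                "n_patients": g.n_patients,
                "n_chemo_pre": g.n_chemo_pre,
                "n_chemo_post": g.n_chemo_post,
                "baseline_risk_10y": {
                    s: _bounded_dict(risk_tables[s][g.label]) for s in risk_tables
                },
                "rrr_chemo": _bounded_dict(g.rrr_chemo),
            }
            for g in bundle.groups
        },
        "costs": {
            f.name: _bounded_dict(getattr(bundle.costs, f.name))
            for f in dataclasses.fields(CostInputs)
        },
        "utilities": {
            f.name: _bounded_dict(getattr(bundle.utilities, f.name))
            for f in dataclasses.fields(UtilityInputs)
        },
        "settings": {
            "start_age": _bounded_dict(bundle.settings.start_age),
            "discount_rate": _bounded_dict(bundle.settings.discount_rate),
            "post_recurrence_mortality_annual": _bounded_dict(
                bundle.settings.post_recurrence_mortality_annual
            ),
            "fatal_toxicity_risk": _bounded_dict(bundle.settings.fatal_toxicity_risk),
            "max_age": bundle.settings.max_age,
            "cycle_length": bundle.settings.cycle_length,
            "recurrence_hazard_mode": bundle.settings.recurrence_hazard_mode,
            "half_cycle_correction": bundle.settings.half_cycle_correction,
        },
    }
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return config_path


def strategy_arms(
    groups: tuple[RiskGroupInput, ...],
) -> tuple[StrategyArm, StrategyArm]:
    """Build the two strategy arms from the decision-impact data.

    Returns ``(without_assay, with_assay)``: usual care uses the pre-assay
    recommendation rates, the assay arm the post-assay rates.
    """
    without = StrategyArm(
        name="without_assay",
        chemo_rates={g.label: g.chemo_rate_pre for g in groups},
        assay_cost_applied=False,
    )
    with_ = StrategyArm(
        name="with_assay",
        chemo_rates={g.label: g.chemo_rate_post for g in groups},
        assay_cost_applied=True,
    )
    return without, with_
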