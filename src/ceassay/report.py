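"""Machine- and human-readable reports, plus a run manifest for auditability."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .outcomes import IncrementalResult, StrategyResult
from .parameters import InputBundle

__all__ = ["RunManifest", "results_frame", "write_results", "write_manifest"]

# Table row labels (stable field order for CSV/JSON output)
_FIELDS = [
    ("chemo_proportion", "Proportion receiving adjuvant chemotherapy"),
    ("rfs_10y", "10-year recurrence-free survival"),
    ("qaly_immediate_chemo", "QALYs: adjuvant chemotherapy (immediate)"),
    ("qaly_long_term", "QALYs: recurrence (long-term)"),
    ("qaly_total", "QALYs: total"),
    ("cost_assay", "Costs: 21-gene assay"),
    ("cost_chemo_drugs", "Costs: chemotherapy drugs"),
    ("cost_adverse_events", "Costs: adverse events"),
    ("cost_time_transport", "Costs: patient time and transportation"),
    ("cost_monitoring", "Costs: monitoring until recurrence"),
    ("cost_recurrence", "Costs: after recurrence"),
    ("cost_total", "Costs: total"),
]


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one model run; identical manifests imply identical outputs
    (the timestamp is informational only)."""

    config_sha256: str
    risk_source: str
    settings: dict
    package_version: str
    timestamp: str
    seed: int | None = None


def build_manifest(
    config_path: str | Path, bundle: InputBundle, seed: int | None = None
) -> RunManifest:
    digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    s = bundle.settings
    return RunManifest(
        config_sha256=digest,
        risk_source=s.risk_source,
        settings={
            "start_age": s.start_age.base,
            "discount_rate": s.discount_rate.base,
            "max_age": s.max_age,
            "post_recurrence_mortality_annual": s.post_recurrence_mortality_annual.base,
            "fatal_toxicity_risk": s.fatal_toxicity_risk.base,
            "recurrence_hazard_mode": s.recurrence_hazard_mode,
            "half_cycle_correction": s.half_cycle_correction,
        },
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        seed=seed,
    )


def results_frame(
    without: StrategyResult,
    with_: StrategyResult,
    inc: IncrementalResult,
    usd: bool = False,
) -> pd.DataFrame:
    """Base-case results table: one row per outcome, columns per arm + difference.

    ``usd`` adds a display-only column for the incremental values at the fixed
    100 JPY = 1 USD conversion used for reporting.
    """
    rows = []
    for field, label in _FIELDS:
        a = getattr(without, field)
        b = getattr(with_, field)
        rows.append((label, a, b, b - a))
    rows.append(
        (
            "Cost per QALY gained (JPY/QALY)",
            float("nan"),
            float("nan"),
            inc.icer if inc.icer is not None else float("nan"),
        )
    )
    df = pd.DataFrame(
        rows, columns=["outcome", "without_assay", "with_assay", "difference"]
    )
    if usd:
        df["difference_usd"] = df["difference"] / 100.0
    return df


def write_results(
    out_dir: str | Path,
    without: StrategyResult,
    with_: StrategyResult,
    inc: IncrementalResult,
    manifest: RunManifest,
    usd: bool = False,
) -> Path:
    """Write results.csv, results.json and manifest.json into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = results_frame(without, with_, inc, usd=usd)
    df.to_csv(out_dir / "results.csv", index=False)
    payload = {
        "without_assay": {f: getattr(without, f) for f, _ in _FIELDS},
        "with_assay": {f: getattr(with_, f) for f, _ in _FIELDS},
        "incremental": {
            "delta_cost": inc.delta_cost,
            "delta_qaly": inc.delta_qaly,
            "icer": inc.icer,
            "dominance": inc.dominance,
        },
    }
    (out_dir / "results.json").write_text(json.dumps(payload, indent=2) + "\n")
    write_manifest(out_dir / "manifest.json", manifest)
    return out_dir


def write_manifest(path: str | Path, manifest: RunManifest) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2) + "\n")
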