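"""Tabular report bundles and deterministic CSV/JSON exports.

Figures (price breakdowns, tornado data) are exported as tidy tables rather
than rendered images, keeping the core dependency-light; any plotting stack
can consume the CSVs. Exports are deterministic: fixed column order, fixed row
order (model, scenario, parameter alphabetical), '.' decimal, UTF-8.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import CaseConfig, MODEL_IDS
from .engine import (
    SCENARIOS,
    ScenarioSet,
    fixed_population_analysis,
    oat_sensitivity,
    range_overlap,
    run_scenarios,
)
from .models import PriceResult

__all__ = ["ReportBundle", "build_bundle", "export_bundle", "build_fixed_population_table"]

log = logging.getLogger("omppricer")

_SHARE_RTOL = 1e-9
_SCENARIO_ORDER = {name: i for i, name in enumerate(SCENARIOS)}
_MODEL_ORDER = {name: i for i, name in enumerate(MODEL_IDS)}


@dataclass(frozen=True)
class ReportBundle:
    """Scenario, breakdown and tornado tables plus the cross-model overlap."""

    scenario_table: pd.DataFrame
    breakdown_table: pd.DataFrame
    tornado_table: pd.DataFrame
    overlap: tuple[float, float] | None

    def __post_init__(self) -> None:
        if len(self.breakdown_table):
            sums = self.breakdown_table.groupby(["model", "scenario"])["share_of_price"].sum()
            bad = sums[(sums - 1.0).abs() > _SHARE_RTOL]
            if len(bad):
                raise ValueError(f"breakdown shares do not sum to 1: {bad.to_dict()}")


def _scenario_row(model_id: str, scenario: str, result: PriceResult) -> dict:
    row = {
        "model": model_id,
        "scenario": scenario,
        "price_ppppy_eur": result.price_ppppy,
        "reported_price_eur": result.reported_price,
    }
    row.update({f"i_{k}": v for k, v in sorted(result.intermediates.items())})
    return row


def _breakdown_rows(model_id: str, scenario: str, result: PriceResult) -> list[dict]:
    shares = result.shares
    return [
        {
            "model": model_id,
            "scenario": scenario,
            "component": comp,
            "value_eur": value,
            "share_of_price": shares[comp],
        }
        for comp, value in sorted(result.components.items())
    ]


def build_bundle(
    config: CaseConfig,
    model_ids: tuple[str, ...] = MODEL_IDS,
    scenarios: tuple[str, ...] = SCENARIOS,
) -> ReportBundle:
    """Run the scenario engine and assemble all report tables."""
    scenario_rows, breakdown_rows, tornado_rows = [], [], []
    sets: list[ScenarioSet] = []
    for model_id in model_ids:
        scen_set = run_scenarios(model_id, config)
        sets.append(scen_set)
        for scenario in scenarios:
            result = scen_set.results[scenario]
            log.info(
                "%s/%s: reported price %d EUR ppppy", model_id, scenario, result.reported_price
            )
            scenario_rows.append(_scenario_row(model_id, scenario, result))
            breakdown_rows.extend(_breakdown_rows(model_id, scenario, result))
        for rec in oat_sensitivity(model_id, config):
            tornado_rows.append(
                {
                    "model": rec.model_id,
                    "parameter": rec.parameter_name,
                    "base_price_eur": rec.base_price,
                    "price_at_param_min_eur": rec.price_at_param_min,
                    "price_at_param_max_eur": rec.price_at_param_max,
                    "width_eur": rec.width,
                }
            )

    scenario_table = pd.DataFrame(scenario_rows)
    lead = ["model", "scenario", "price_ppppy_eur", "reported_price_eur"]
    rest = sorted(c for c in scenario_table.columns if c not in lead)
    scenario_table = scenario_table[lead + rest]
    scenario_table = scenario_table.sort_values(
        ["model", "scenario"],
        key=lambda s: s.map(_MODEL_ORDER if s.name == "model" else _SCENARIO_ORDER),
        kind="stable",
    ).reset_index(drop=True)

    breakdown_table = (
        pd.DataFrame(breakdown_rows)
        .sort_values(
            ["model", "scenario", "component"],
            key=lambda s: s.map(_MODEL_ORDER)
            if s.name == "model"
            else (s.map(_SCENARIO_ORDER) if s.name == "scenario" else s),
            kind="stable",
        )
        .reset_index(drop=True)
    )

    tornado_table = (
        pd.DataFrame(tornado_rows)
        .sort_values(
            ["model", "parameter"],
            key=lambda s: s.map(_MODEL_ORDER) if s.name == "model" else s,
            kind="stable",
        )
        .reset_index(drop=True)
    )

    overlap = range_overlap(sets) if len(sets) >= 2 else None
    return ReportBundle(scenario_table, breakdown_table, tornado_table, overlap)


def build_fixed_population_table(
    config: CaseConfig, n_patients: float = 1000, model_ids: tuple[str, ...] = MODEL_IDS
) -> pd.DataFrame:
    """Fixed-population supplementary analysis as a tidy table."""
    rows = []
    for model_id in model_ids:
        for scenario, result in fixed_population_analysis(model_id, config, n_patients).items():
            log.info(
                "fixed-population %s/%s (n=%g): reported price %d EUR ppppy",
                model_id, scenario, n_patients, result.reported_price,
            )
            rows.append(
                {
                    "model": model_id,
                    "scenario": scenario,
                    "n_patients": n_patients,
                    "price_ppppy_eur": result.price_ppppy,
                    "reported_price_eur": result.reported_price,
                }
            )
    return pd.DataFrame(rows)


def _write_table(df: pd.DataFrame, out_dir: Path, stem: str) -> list[Path]:
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    df.to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps(df.to_dict(orient="records"), indent=2, sort_keys=True, allow_nan=False)
        + "\n",
        encoding="utf-8",
    )
    return [csv_path, json_path]


def export_bundle(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write the bundle as CSV + JSON pairs; reruns are byte-identical."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    written += _write_table(bundle.scenario_table.fillna(""), out_dir, "scenario_table")
    written += _write_table(bundle.breakdown_table, out_dir, "breakdown_table")
    written += _write_table(bundle.tornado_table, out_dir, "tornado_table")
    overlap_path = out_dir / "overlap.json"
    if bundle.overlap is None:
        payload = {"empty": True, "lower_eur": None, "upper_eur": None}
    else:
        payload = {"empty": False, "lower_eur": bundle.overlap[0], "upper_eur": bundle.overlap[1]}
    overlap_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(overlap_path)
    return written
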