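"""Scenario orchestration: min/max/average runs, one-at-a-time sensitivity,
fixed-population supplementary analysis, and cross-model range summaries.

The average scenario is always recomputed from averaged *inputs* (never the
average of the two prices), and sensitivity baselines are those same averaged
inputs. Rounding to the reporting granularity is applied only when a price is
reported; orderings (min <= avg <= max) are evaluated on unrounded prices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .config import CaseConfig, GlobalConstants, MODEL_IDS, build_average_inputs
from .errors import OutOfRangeError
from .models import PriceResult, aim_price, dcf_price, ncp_price, roror_price
from .population import constant_schedule

__all__ = [
    "ScenarioSet",
    "SensitivityRecord",
    "SCENARIOS",
    "OAT_GROUPS",
    "PRICE_DIRECTIONS",
    "price_inputs",
    "run_scenarios",
    "oat_sensitivity",
    "fixed_population_analysis",
    "range_overlap",
]

SCENARIOS = ("min", "max", "avg")


@dataclass(frozen=True)
class ScenarioSet:
    """Minimum-, maximum- and average-scenario price results for one model."""

    model_id: str
    results: Mapping[str, PriceResult]

    @property
    def reported_range(self) -> tuple[int, int]:
        return (self.results["min"].reported_price, self.results["max"].reported_price)


@dataclass(frozen=True)
class SensitivityRecord:
    """One OAT substitution: the average-scenario price with a single
    parameter (or jointly-defined parameter group) moved to its
    minimum-column / maximum-column value."""

    model_id: str
    parameter_name: str
    base_price: float
    price_at_param_min: float
    price_at_param_max: float

    @property
    def width(self) -> float:
        return abs(self.price_at_param_max - self.price_at_param_min)


#: per-model OAT parameter groups: (display name, scenario-input fields varied
#: together). Groups with more than one field are parameters the source tables
#: only define jointly (DCF prescription restrictions).
OAT_GROUPS: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = {
    "ncp": (
        ("prevalence_per_million", ("prevalence_per_million",)),
        ("treatment_rate", ("treatment_rate",)),
        ("patent_years", ("patent_years",)),
        ("rd_cost_total", ("rd_cost_total",)),
        ("cogs_ppppy", ("cogs_ppppy",)),
        ("marketing_fraction", ("marketing_fraction",)),
        ("profit_margin", ("profit_margin",)),
    ),
    "aim": (
        ("prevalence_per_million", ("prevalence_per_million",)),
        ("treatment_rate", ("treatment_rate",)),
        ("market_share", ("market_share",)),
        ("patent_years", ("patent_years",)),
        ("rd_cost_total", ("rd_cost_total",)),
        ("production_overhead_ppppy", ("production_overhead_ppppy",)),
        ("sales_fraction", ("sales_fraction",)),
        ("basic_profit", ("basic_profit",)),
        ("innovation_bonus", ("innovation_bonus",)),
    ),
    "dcf": (
        ("prevalence_per_million", ("prevalence_per_million",)),
        ("incidence_per_million", ("incidence_per_million",)),
        ("response_rate", ("response_rate",)),
        ("failure_rate", ("failure_rate",)),
        ("adverse_event_rate", ("adverse_event_rate",)),
        ("contraindication_rate", ("contraindication_rate",)),
        ("prescription_restrictions", ("restriction_prevalent", "restriction_incident")),
        ("population_growth", ("population_growth",)),
        ("uptake_cap", ("uptake_cap",)),
        ("patent_years", ("patent_years",)),
        ("rd_lumpsum_total", ("rd_lumpsum_total",)),
        ("drug_cost_fraction_of_revenue", ("drug_cost_fraction_of_revenue",)),
        ("cost_of_capital", ("cost_of_capital",)),
        ("innovation_premium", ("innovation_premium",)),
    ),
    "roror": (
        ("prevalence_per_million", ("prevalence_per_million",)),
        ("treatment_rate", ("treatment_rate",)),
        ("patent_years", ("patent_years",)),
        ("rd_cost_total", ("rd_cost_total",)),
        ("production_cost_ppppy", ("production_cost_ppppy",)),
        ("wacc", ("wacc",)),
        ("gdp_deflator", ("gdp_deflator",)),
        ("years_until_approval", ("years_until_approval",)),
        ("profit_margin", ("profit_margin",)),
    ),
}

#: sign of dprice/dparameter: +1 cost-like (price rises with the parameter),
#: -1 patient-like (price falls). Drives synthetic column orientation and the
#: monotonicity property suite. ROROR years_until_approval is +1 only when
#: wacc >= gdp_deflator; the synthetic sampler enforces that ordering.
PRICE_DIRECTIONS: dict[str, dict[str, int]] = {
    "ncp": {
        "prevalence_per_million": -1,
        "treatment_rate": -1,
        "patent_years": -1,
        "rd_cost_total": +1,
        "cogs_ppppy": +1,
        "marketing_fraction": +1,
        "profit_margin": +1,
    },
    "aim": {
        "prevalence_per_million": -1,
        "treatment_rate": -1,
        "market_share": -1,
        "patent_years": -1,
        "rd_cost_total": +1,
        "production_overhead_ppppy": +1,
        "sales_fraction": +1,
        "basic_profit": +1,
        "innovation_bonus": +1,
    },
    "dcf": {
        "prevalence_per_million": -1,
        "incidence_per_million": -1,
        "response_rate": -1,
        "failure_rate": +1,
        "adverse_event_rate": +1,
        "contraindication_rate": +1,
        "restriction_prevalent": +1,
        "restriction_incident": +1,
        "population_growth": -1,
        "uptake_cap": -1,
        "uptake_ramp_years": +1,
        "patent_years": -1,
        "rd_lumpsum_total": +1,
        "drug_cost_fraction_of_revenue": +1,
        "cost_of_capital": +1,
        "innovation_premium": +1,
    },
    "roror": {
        "prevalence_per_million": -1,
        "treatment_rate": -1,
        "patent_years": -1,
        "rd_cost_total": +1,
        "production_cost_ppppy": +1,
        "wacc": +1,
        "gdp_deflator": -1,
        "years_until_approval": +1,
        "profit_margin": +1,
    },
}

_PRICE_FNS: dict[str, Callable] = {
    "ncp": ncp_price,
    "aim": aim_price,
    "dcf": dcf_price,
    "roror": roror_price,
}


def price_inputs(
    model_id: str,
    inputs,
    constants: GlobalConstants,
    *,
    n_patients: float | None = None,
) -> PriceResult:
    """Price one scenario-input column under the named model.

    ``n_patients`` pins the treated population: the static models take it as
    the eligible-patient count, the DCF model as a flat schedule over the
    patent years (uptake, restrictions and clinical attrition bypassed).
    """
    if model_id not in MODEL_IDS:
        raise OutOfRangeError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    if model_id == "dcf":
        sched = None
        if n_patients is not None:
            sched = constant_schedule(n_patients, inputs.patent_years)
        return dcf_price(inputs, constants, schedule=sched)
    return _PRICE_FNS[model_id](inputs, constants, n_patients=n_patients)


def run_scenarios(model_id: str, config: CaseConfig) -> ScenarioSet:
    """Price the minimum, maximum and recomputed average scenarios."""
    pair = config.pair(model_id)
    avg = build_average_inputs(pair.min, pair.max)
    results = {
        "min": price_inputs(model_id, pair.min, config.constants),
        "max": price_inputs(model_id, pair.max, config.constants),
        "avg": price_inputs(model_id, avg, config.constants),
    }
    return ScenarioSet(model_id=model_id, results=results)


def oat_sensitivity(model_id: str, config: CaseConfig) -> list[SensitivityRecord]:
    """One-at-a-time sensitivity around the average scenario.

    Each parameter (group) is substituted with its minimum-column and
    maximum-column values while all others stay at their averages; by
    construction, substituting the average value itself reproduces the base
    price exactly.
    """
    pair = config.pair(model_id)
    avg = build_average_inputs(pair.min, pair.max)
    base = price_inputs(model_id, avg, config.constants).price_ppppy
    records = []
    for name, fields in OAT_GROUPS[model_id]:
        low = avg.model_copy(update={f: getattr(pair.min, f) for f in fields})
        high = avg.model_copy(update={f: getattr(pair.max, f) for f in fields})
        records.append(
            SensitivityRecord(
                model_id=model_id,
                parameter_name=name,
                base_price=base,
                price_at_param_min=price_inputs(model_id, low, config.constants).price_ppppy,
                price_at_param_max=price_inputs(model_id, high, config.constants).price_ppppy,
            )
        )
    return records


def fixed_population_analysis(
    model_id: str, config: CaseConfig, n_patients: float = 1000
) -> dict[str, PriceResult]:
    """Supplementary analysis with the treated population pinned.

    Re-prices the minimum and maximum scenarios with exactly ``n_patients``
    treated patients, disregarding treatment rates, market shares and uptake
    curves; isolates how each model's patient-estimation strategy drives its
    price.
    """
    if n_patients < 1:
        raise OutOfRangeError(f"n_patients must be >= 1, got {n_patients}")
    pair = config.pair(model_id)
    return {
        "min": price_inputs(model_id, pair.min, config.constants, n_patients=n_patients),
        "max": price_inputs(model_id, pair.max, config.constants, n_patients=n_patients),
    }


def range_overlap(scenario_sets: list[ScenarioSet]) -> tuple[float, float] | None:
    """Intersection of the models' reported [min, max] price ranges.

    Returns (max of minima, min of maxima), or None when the ranges are
    disjoint.
    """
    if len(scenario_sets) < 2:
        raise OutOfRangeError("range_overlap needs at least two scenario sets")
    lows = [s.reported_range[0] for s in scenario_sets]
    highs = [s.reported_range[1] for s in scenario_sets]
    lo, hi = max(lows), min(highs)
    if lo > hi:
        return None
    return (lo, hi)
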