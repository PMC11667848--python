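"""Random admissible scenario generation for property testing.

Every property test in the suite runs against inputs drawn here, so the
sampler guarantees admissibility by construction (type invariants) plus a
bounded resampling loop for the one constraint that is not box-shaped: the
resulting treated population must be at least one patient.

A single integer seed controls everything; each pricing model draws from its
own substream (a fixed per-model offset into numpy's seed sequence), so adding
a model never shifts another model's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    AIMInputs,
    CaseConfig,
    DCFInputs,
    GlobalConstants,
    MODEL_IDS,
    NCPInputs,
    RORORInputs,
    build_average_inputs,
)
from .engine import PRICE_DIRECTIONS, price_inputs
from .errors import ExhaustedRetriesError, OutOfRangeError
from .models import PriceResult

__all__ = ["SyntheticRanges", "sample_inputs", "sample_config"]

_MODEL_OFFSETS = {"ncp": 101, "aim": 211, "dcf": 307, "roror": 401}
_MAX_RETRIES = 1000

#: default constants used by sampled configs (EU market of the study period)
_DEFAULT_CONSTANTS = GlobalConstants(
    eu_population=447e6,
    eu_attribution_share=0.3585,
    usd_to_eur_rate=0.8458,
    reporting_rounding=1000,
)


@dataclass(frozen=True)
class SyntheticRanges:
    """Per-parameter sampling intervals (inclusive bounds).

    Defaults span the admissible domains the analysis assumes: orphan-scale
    prevalence/incidence, rates on the unit interval (treatment response at
    least 0.5), patent lives of 1-20 years, R&D lump sums log-uniform between
    €50M and the €2.5B cap, unit costs log-uniform €1k-€200k, cost of
    capital/WACC up to 20% and GDP deflators up to 8%.
    """

    prevalence_per_million: tuple[float, float] = (0.1, 30.0)
    incidence_per_million: tuple[float, float] = (0.0, 2.0)
    rate: tuple[float, float] = (0.0, 1.0)  # treatment/market/restriction/attrition rates
    response_rate: tuple[float, float] = (0.5, 1.0)
    population_growth: tuple[float, float] = (0.0, 0.02)
    uptake_cap: tuple[float, float] = (0.1, 1.0)
    uptake_ramp_years: tuple[int, int] = (0, 5)
    patent_years: tuple[int, int] = (1, 20)
    rd_cost_total: tuple[float, float] = (50e6, 2.5e9)  # log-uniform
    unit_cost_ppppy: tuple[float, float] = (1e3, 200e3)  # log-uniform
    margin: tuple[float, float] = (0.0, 0.5)  # profits, bonuses, premiums, cost fractions
    drug_cost_fraction: tuple[float, float] = (0.0, 0.6)
    cost_of_capital: tuple[float, float] = (0.0, 0.20)
    gdp_deflator: tuple[float, float] = (0.0, 0.08)
    years_until_approval: tuple[int, int] = (0, 15)
    constants: GlobalConstants = field(default_factory=lambda: _DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        for name in type(self).__dataclass_fields__:
            value = getattr(self, name)
            if isinstance(value, tuple):
                lo, hi = value
                if lo > hi:
                    raise OutOfRangeError(f"{name}: lower bound {lo} > upper bound {hi}")


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _loguniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if hi <= lo:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _int_uniform(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(rng.integers(lo, hi + 1))


def _draw_column(model_id: str, ranges: SyntheticRanges, rng: np.random.Generator) -> dict:
    """One scenario column of raw parameter values (fixed draw order)."""
    r = ranges
    if model_id == "ncp":
        return {
            "prevalence_per_million": _uniform(rng, r.prevalence_per_million),
            "treatment_rate": _uniform(rng, r.rate),
            "patent_years": _int_uniform(rng, r.patent_years),
            "rd_cost_total": _loguniform(rng, r.rd_cost_total),
            "cogs_ppppy": _loguniform(rng, r.unit_cost_ppppy),
            "marketing_fraction": _uniform(rng, r.margin),
            "profit_margin": _uniform(rng, r.margin),
        }
    if model_id == "aim":
        return {
            "prevalence_per_million": _uniform(rng, r.prevalence_per_million),
            "treatment_rate": _uniform(rng, r.rate),
            "market_share": max(_uniform(rng, r.rate), 1e-3),
            "patent_years": _int_uniform(rng, r.patent_years),
            "rd_cost_total": _loguniform(rng, r.rd_cost_total),
            "production_overhead_ppppy": _loguniform(rng, r.unit_cost_ppppy),
            "sales_fraction": _uniform(rng, r.margin),
            "basic_profit": _uniform(rng, r.margin),
            "innovation_bonus": _uniform(rng, r.margin),
            "bonus_convention": "additive",
        }
    if model_id == "dcf":
        return {
            "prevalence_per_million": _uniform(rng, r.prevalence_per_million),
            "incidence_per_million": _uniform(rng, r.incidence_per_million),
            "response_rate": _uniform(rng, r.response_rate),
            "failure_rate": _uniform(rng, r.rate),
            "adverse_event_rate": _uniform(rng, r.rate),
            "contraindication_rate": _uniform(rng, r.rate),
            "restriction_prevalent": _uniform(rng, r.rate),
            "restriction_incident": _uniform(rng, r.rate),
            "population_growth": _uniform(rng, r.population_growth),
            "uptake_cap": _uniform(rng, r.uptake_cap),
            "uptake_ramp_years": _int_uniform(rng, r.uptake_ramp_years),
            "patent_years": _int_uniform(rng, r.patent_years),
            "rd_lumpsum_total": _loguniform(rng, r.rd_cost_total),
            "drug_cost_fraction_of_revenue": _uniform(rng, r.drug_cost_fraction),
            "cost_of_capital": _uniform(rng, r.cost_of_capital),
            "innovation_premium": _uniform(rng, r.margin),
        }
    if model_id == "roror":
        wacc = _uniform(rng, r.cost_of_capital)
        # keep wacc >= deflator so compounding (and price vs development time)
        # stays oriented; sampled jointly for both columns in sample_config
        deflator = _uniform(rng, (r.gdp_deflator[0], min(r.gdp_deflator[1], wacc)))
        return {
            "prevalence_per_million": _uniform(rng, r.prevalence_per_million),
            "treatment_rate": _uniform(rng, r.rate),
            "patent_years": _int_uniform(rng, r.patent_years),
            "rd_cost_total": _loguniform(rng, r.rd_cost_total),
            "production_cost_ppppy": _loguniform(rng, r.unit_cost_ppppy),
            "wacc": wacc,
            "gdp_deflator": deflator,
            "years_until_approval": _int_uniform(rng, r.years_until_approval),
            "profit_margin": _uniform(rng, r.margin),
        }
    raise OutOfRangeError(f"unknown model id {model_id!r}")


_INPUT_TYPES = {"ncp": NCPInputs, "aim": AIMInputs, "dcf": DCFInputs, "roror": RORORInputs}


def _admissible(model_id: str, inputs, constants: GlobalConstants) -> bool:
    """At least one treated patient (static count, or DCF schedule revenue)."""
    try:
        result: PriceResult = price_inputs(model_id, inputs, constants)
    except Exception:
        return False
    key = "eligible_patients" if model_id != "dcf" else "eligible_patients_mean"
    return result.intermediates[key] >= 1.0


def sample_inputs(model_id: str, ranges: SyntheticRanges, seed: int):
    """Draw one admissible scenario-input column for ``model_id``.

    Deterministic in ``seed``; resamples (bounded) until the implied treated
    population reaches one patient.
    """
    if model_id not in MODEL_IDS:
        raise OutOfRangeError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    rng = np.random.default_rng([_MODEL_OFFSETS[model_id], seed])
    cls = _INPUT_TYPES[model_id]
    for _ in range(_MAX_RETRIES):
        inputs = cls(**_draw_column(model_id, ranges, rng))
        if _admissible(model_id, inputs, ranges.constants):
            return inputs
    raise ExhaustedRetriesError(
        f"no admissible {model_id} draw within {_MAX_RETRIES} attempts"
    )


def _orient_pair(model_id: str, a: dict, b: dict) -> tuple[dict, dict]:
    """Split two raw columns into (min-price, max-price) columns per the table
    convention: each parameter's price-minimizing end goes to the min column."""
    directions = PRICE_DIRECTIONS[model_id]
    low, high = {}, {}
    for key in a:
        va, vb = a[key], b[key]
        if not isinstance(va, (int, float)) or isinstance(va, bool):
            low[key] = high[key] = va
            continue
        sign = directions.get(key, +1)
        lo_end, hi_end = (min(va, vb), max(va, vb))
        if sign > 0:  # cost-like: small value minimizes the price
            low[key], high[key] = lo_end, hi_end
        else:  # patient-like: large value minimizes the price
            low[key], high[key] = hi_end, lo_end
    return low, high


def sample_config(ranges: SyntheticRanges, seed: int) -> CaseConfig:
    """Draw a full admissible case configuration.

    For every model two parameter columns are sampled and re-oriented so the
    minimum column holds each parameter's price-minimizing end; min, max and
    the recomputed average scenario are all checked for admissibility.
    """
    blocks: dict = {}
    for model_id in MODEL_IDS:
        rng = np.random.default_rng([7_000 + _MODEL_OFFSETS[model_id], seed])
        cls = _INPUT_TYPES[model_id]
        for _ in range(_MAX_RETRIES):
            raw_a = _draw_column(model_id, ranges, rng)
            raw_b = _draw_column(model_id, ranges, rng)
            if model_id == "roror":
                # joint wacc/deflator ordering across both columns keeps the
                # development-time direction consistent in min, max and avg
                wacc_lo = min(raw_a["wacc"], raw_b["wacc"])
                raw_a["gdp_deflator"] = min(raw_a["gdp_deflator"], wacc_lo)
                raw_b["gdp_deflator"] = min(raw_b["gdp_deflator"], wacc_lo)
            low, high = _orient_pair(model_id, raw_a, raw_b)
            mn, mx = cls(**low), cls(**high)
            avg = build_average_inputs(mn, mx)
            if all(
                _admissible(model_id, column, ranges.constants) for column in (mn, mx, avg)
            ):
                blocks[model_id] = {"min": mn, "max": mx}
                break
        else:
            raise ExhaustedRetriesError(
                f"no admissible {model_id} column pair within {_MAX_RETRIES} attempts"
            )
    return CaseConfig(
        metadata={"medicine": f"synthetic-seed-{seed}", "source_tables": "sample_config"},
        constants=ranges.constants,
        **blocks,
    )
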