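"""The four cost-based pricing models.

Each model turns a scenario input column into a price per patient per year
(PPPPY) with an additive component breakdown:

NCP    price = (rd_ppppy + cogs x (1 + marketing)) x (1 + profit_margin)
AIM    price = (rd_ppppy x (1 + sales) + production) x (1 + profit [+|x] bonus)
DCF    price = P* x (1 + premium), P* the break-even price at patent expiry:
       P* = K / sum_t[n_t x (1 - delta) / (1 + r)^t], K the EU-attributed
       R&D lump sum, delta the drug-cost share of revenue, r the cost of
       capital, n_t the treated-patient schedule
ROROR  price = (production + rd_ppppy x ((1+wacc)/(1+deflator))^T_dev)
               x (1 + profit_margin)

where rd_ppppy spreads the EU-attributable per-product R&D lump sum over the
eligible patients and the remaining patent years. Components always sum to
the unrounded price; reported prices are rounded half-up to the configured
granularity (nearest thousand euro by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .config import AIMInputs, DCFInputs, GlobalConstants, NCPInputs, RORORInputs
from .errors import NoRevenueError, OutOfRangeError, ZeroPatientsError, ZeroYearsError
from .population import (
    DCFPopulationInputs,
    PatientSchedule,
    StaticPopulationInputs,
    dcf_patient_schedule,
    eligible_patients_static,
    round_half_up,
    schedule_mean,
)

__all__ = [
    "PriceResult",
    "rd_cost_ppppy",
    "compose_ncp",
    "ncp_price",
    "aim_price",
    "dcf_break_even_price",
    "dcf_price",
    "roror_price",
    "npv",
    "report_price",
]

_BREAKDOWN_RTOL = 1e-9


@dataclass(frozen=True)
class PriceResult:
    """A price per patient per year with its additive breakdown.

    ``components`` sum to ``price_ppppy`` (relative tolerance 1e-9);
    ``intermediates`` carries informational quantities (eligible patients,
    R&D PPPY, break-even price, ...) that are not additive parts of the price.
    """

    price_ppppy: float
    reported_price: int
    components: Mapping[str, float]
    intermediates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.price_ppppy < 0:
            raise ValueError(f"price must be non-negative, got {self.price_ppppy}")
        total = sum(self.components.values())
        tol = _BREAKDOWN_RTOL * max(1.0, abs(self.price_ppppy))
        if abs(total - self.price_ppppy) > tol:
            raise ValueError(
                f"components sum to {total}, price is {self.price_ppppy}"
            )

    @property
    def shares(self) -> dict[str, float]:
        """Each component's share of the price (empty price -> zeros)."""
        if self.price_ppppy == 0:
            return {k: 0.0 for k in self.components}
        return {k: v / self.price_ppppy for k, v in self.components.items()}


def report_price(price: float, granularity: float) -> int:
    """Round a price half-up to the reporting granularity."""
    if granularity <= 0:
        raise OutOfRangeError(f"granularity must be > 0, got {granularity}")
    return int(round_half_up(price / granularity) * granularity)


def rd_cost_ppppy(
    rd_cost_total: float, eu_share: float, patients: float, patent_years: float
) -> float:
    """EU-attributable R&D lump sum per patient per patent year."""
    if patients < 1:
        raise ZeroPatientsError(f"patients must be >= 1, got {patients}")
    if patent_years < 1:
        raise ZeroYearsError(f"patent_years must be >= 1, got {patent_years}")
    if not 0 < eu_share <= 1:
        raise OutOfRangeError(f"eu_share must be in (0, 1], got {eu_share}")
    if rd_cost_total < 0:
        raise OutOfRangeError(f"rd_cost_total must be >= 0, got {rd_cost_total}")
    return rd_cost_total * eu_share / (patients * patent_years)


def npv(cash_flows, rate: float) -> float:
    """Net present value, end-of-year convention; flow at t=0 undiscounted."""
    if rate <= -1:
        raise OutOfRangeError(f"rate must be > -1, got {rate}")
    return float(sum(cf / (1.0 + rate) ** t for t, cf in enumerate(cash_flows)))


# ---------------------------------------------------------------------------
# NCP


def _ncp_patients(inputs: NCPInputs, constants: GlobalConstants) -> int:
    pop = StaticPopulationInputs(
        prevalence_per_million=inputs.prevalence_per_million,
        eu_population=constants.eu_population,
        treatment_rate=inputs.treatment_rate,
        market_share=1.0,
    )
    return eligible_patients_static(pop)


def compose_ncp(rd_ppppy: float, drug_cost_ppppy: float, profit_margin: float) -> float:
    """NCP composition from its two PPPY intermediates.

    Exposed separately so the published intermediate rows (R&D PPPY, drug
    costs PPPY) can be priced directly.
    """
    return (rd_ppppy + drug_cost_ppppy) * (1.0 + profit_margin)


def ncp_price(
    inputs: NCPInputs, constants: GlobalConstants, *, n_patients: float | None = None
) -> PriceResult:
    """Novel Cancer Pricing model price with breakdown.

    ``n_patients`` pins the patient count (fixed-population analysis); by
    default it is the eligible-patient count from prevalence and treatment
    rate.
    """
    patients = n_patients if n_patients is not None else _ncp_patients(inputs, constants)
    rd = rd_cost_ppppy(
        inputs.rd_cost_total, constants.eu_attribution_share, patients, inputs.patent_years
    )
    marketing = inputs.cogs_ppppy * inputs.marketing_fraction
    drug = inputs.cogs_ppppy + marketing
    price = compose_ncp(rd, drug, inputs.profit_margin)
    components = {
        "rd": rd,
        "cogs": inputs.cogs_ppppy,
        "marketing": marketing,
        "profit": (rd + drug) * inputs.profit_margin,
    }
    intermediates = {
        "eligible_patients": float(patients),
        "rd_ppppy": rd,
        "drug_cost_ppppy": drug,
    }
    return PriceResult(price, report_price(price, constants.reporting_rounding),
                       components, intermediates)


# ---------------------------------------------------------------------------
# AIM


def _aim_patients(inputs: AIMInputs, constants: GlobalConstants) -> int:
    pop = StaticPopulationInputs(
        prevalence_per_million=inputs.prevalence_per_million,
        eu_population=constants.eu_population,
        treatment_rate=inputs.treatment_rate,
        market_share=inputs.market_share,
    )
    return eligible_patients_static(pop)


def aim_price(
    inputs: AIMInputs, constants: GlobalConstants, *, n_patients: float | None = None
) -> PriceResult:
    """AIM model price with breakdown, under either bonus convention."""
    patients = n_patients if n_patients is not None else _aim_patients(inputs, constants)
    rd = rd_cost_ppppy(
        inputs.rd_cost_total, constants.eu_attribution_share, patients, inputs.patent_years
    )
    sales = inputs.sales_fraction * rd
    base = rd + inputs.production_overhead_ppppy + sales
    if inputs.bonus_convention == "additive":
        profit = base * inputs.basic_profit
        bonus = base * inputs.innovation_bonus
    else:  # multiplicative: the bonus applies on top of the profit-inclusive price
        profit = base * inputs.basic_profit
        bonus = base * (1.0 + inputs.basic_profit) * inputs.innovation_bonus
    price = base + profit + bonus
    components = {
        "rd": rd,
        "production": inputs.production_overhead_ppppy,
        "sales": sales,
        "profit": profit,
        "bonus": bonus,
    }
    intermediates = {"eligible_patients": float(patients), "rd_ppppy": rd}
    return PriceResult(price, report_price(price, constants.reporting_rounding),
                       components, intermediates)


# ---------------------------------------------------------------------------
# DCF


def _dcf_schedule(inputs: DCFInputs, constants: GlobalConstants) -> PatientSchedule:
    pop = DCFPopulationInputs(
        prevalence_per_million=inputs.prevalence_per_million,
        incidence_per_million=inputs.incidence_per_million,
        eu_population=constants.eu_population,
        response_rate=inputs.response_rate,
        failure_rate=inputs.failure_rate,
        adverse_event_rate=inputs.adverse_event_rate,
        contraindication_rate=inputs.contraindication_rate,
        restriction_prevalent=inputs.restriction_prevalent,
        restriction_incident=inputs.restriction_incident,
        population_growth=inputs.population_growth,
        uptake_cap=inputs.uptake_cap,
        uptake_ramp_years=inputs.uptake_ramp_years,
    )
    return dcf_patient_schedule(pop, inputs.patent_years)


def _discounted_break_even(
    eu_lumpsum: float, schedule: PatientSchedule, delta: float, rate: float
) -> float:
    discounted = sum(
        n * (1.0 - delta) / (1.0 + rate) ** t
        for t, n in enumerate(schedule.counts, start=1)
    )
    if discounted <= 0:
        raise NoRevenueError("discounted patient-year total is zero")
    return eu_lumpsum / discounted


def dcf_break_even_price(
    inputs: DCFInputs,
    constants: GlobalConstants,
    *,
    schedule: PatientSchedule | None = None,
    compound_rd_years: float = 0.0,
) -> float:
    """Break-even price P*: the unique price at which the NPV of the launch
    cash flows (R&D lump sum out at t=0, net revenues in at t=1..T) is zero.

    The R&D lump sum is treated as a sunk, undiscounted outflow at launch.
    ``compound_rd_years`` optionally compounds it forward at the cost of
    capital over a pre-launch development period (off by default).
    """
    sched = schedule if schedule is not None else _dcf_schedule(inputs, constants)
    lumpsum = inputs.rd_lumpsum_total * constants.eu_attribution_share
    lumpsum *= (1.0 + inputs.cost_of_capital) ** compound_rd_years
    return _discounted_break_even(
        lumpsum, sched, inputs.drug_cost_fraction_of_revenue, inputs.cost_of_capital
    )


def dcf_price(
    inputs: DCFInputs,
    constants: GlobalConstants,
    *,
    schedule: PatientSchedule | None = None,
    compound_rd_years: float = 0.0,
) -> PriceResult:
    """DCF model price: break-even price plus the fixed innovation premium.

    Breakdown: ``rd_principal`` is the undiscounted cost-recovery price
    (break-even at r=0), ``cost_of_capital`` the increment attributable to
    discounting (P* - P*|r=0), ``premium`` the surcharge. The drug-cost share
    of revenue is a margin-style deduction and appears in the intermediates.
    """
    sched = schedule if schedule is not None else _dcf_schedule(inputs, constants)
    lumpsum = inputs.rd_lumpsum_total * constants.eu_attribution_share
    lumpsum *= (1.0 + inputs.cost_of_capital) ** compound_rd_years
    delta = inputs.drug_cost_fraction_of_revenue
    p_star = _discounted_break_even(lumpsum, sched, delta, inputs.cost_of_capital)
    p_zero = _discounted_break_even(lumpsum, sched, delta, 0.0)
    premium = p_star * inputs.innovation_premium
    price = p_star * (1.0 + inputs.innovation_premium)
    components = {
        "rd_principal": p_zero,
        "cost_of_capital": p_star - p_zero,
        "premium": premium,
    }
    intermediates = {
        "eligible_patients_mean": schedule_mean(sched),
        "eu_rd_lumpsum": lumpsum,
        "break_even_price": p_star,
        "drug_cost_ppppy": delta * price,
    }
    return PriceResult(price, report_price(price, constants.reporting_rounding),
                       components, intermediates)


# ---------------------------------------------------------------------------
# ROROR


def _roror_patients(inputs: RORORInputs, constants: GlobalConstants) -> int:
    pop = StaticPopulationInputs(
        prevalence_per_million=inputs.prevalence_per_million,
        eu_population=constants.eu_population,
        treatment_rate=inputs.treatment_rate,
        market_share=1.0,
    )
    return eligible_patients_static(pop)


def roror_price(
    inputs: RORORInputs, constants: GlobalConstants, *, n_patients: float | None = None
) -> PriceResult:
    """ROROR model price with breakdown.

    The per-patient-year R&D cost is compounded at WACC and deflated by the
    GDP deflator over the development period as a single real-terms ratio
    ((1+w)/(1+d))^T_dev; the compounding increment is reported as the
    cost-of-capital component.
    """
    patients = n_patients if n_patients is not None else _roror_patients(inputs, constants)
    rd = rd_cost_ppppy(
        inputs.rd_cost_total, constants.eu_attribution_share, patients, inputs.patent_years
    )
    factor = ((1.0 + inputs.wacc) / (1.0 + inputs.gdp_deflator)) ** inputs.years_until_approval
    rd_compounded = rd * factor
    price = (inputs.production_cost_ppppy + rd_compounded) * (1.0 + inputs.profit_margin)
    components = {
        "production": inputs.production_cost_ppppy,
        "rd_principal": rd,
        "cost_of_capital": rd_compounded - rd,
        "profit": (inputs.production_cost_ppppy + rd_compounded) * inputs.profit_margin,
    }
    intermediates = {
        "eligible_patients": float(patients),
        "rd_ppppy": rd,
        "compounding_factor": factor,
    }
    return PriceResult(price, report_price(price, constants.reporting_rounding),
                       components, intermediates)
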