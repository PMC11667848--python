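"""Eligible- and treated-patient estimation.

The static models (NCP, AIM, ROROR) price against a single eligible-patient
count: prevalence scaled to the EU population, thinned by a treatment rate and
a market share. The DCF model instead prices against a per-year schedule of
treated patients over the remaining patent life, combining a prevalent pool
and an incident inflow, clinical attrition filters, prescription restrictions,
population growth and an uptake cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field

from .errors import EmptyScheduleError

__all__ = [
    "StaticPopulationInputs",
    "DCFPopulationInputs",
    "PatientSchedule",
    "round_half_up",
    "eligible_patients_static",
    "dcf_patient_schedule",
    "constant_schedule",
    "schedule_mean",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1).

    Used for reported patient counts and reported prices; plain ``round``
    would apply banker's rounding.
    """
    return int(math.floor(x + 0.5))


class StaticPopulationInputs(BaseModel):
    """Population inputs for the one-shot eligible-patient count."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    prevalence_per_million: float = Field(ge=0)
    eu_population: float = Field(gt=0)
    treatment_rate: float = Field(default=1.0, ge=0, le=1)
    market_share: float = Field(default=1.0, gt=0, le=1)


class DCFPopulationInputs(BaseModel):
    """Population inputs for the per-year treated-patient schedule.

    ``restriction_prevalent``/``restriction_incident`` are the fractions of the
    prevalent/incident pools excluded by prescription restrictions (e.g. prior
    liver transplantation, full pyridoxine responsiveness). The four clinical
    rates compose multiplicatively into one attrition factor — they are treated
    as independent filters.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    prevalence_per_million: float = Field(ge=0)
    incidence_per_million: float = Field(ge=0)
    eu_population: float = Field(gt=0)
    response_rate: float = Field(default=1.0, ge=0, le=1)
    failure_rate: float = Field(default=0.0, ge=0, le=1)
    adverse_event_rate: float = Field(default=0.0, ge=0, le=1)
    contraindication_rate: float = Field(default=0.0, ge=0, le=1)
    restriction_prevalent: float = Field(default=0.0, ge=0, le=1)
    restriction_incident: float = Field(default=0.0, ge=0, le=1)
    population_growth: float = Field(default=0.0, gt=-1)
    uptake_cap: float = Field(default=1.0, gt=0, le=1)
    uptake_ramp_years: float = Field(default=0.0, ge=0)

    @property
    def clinical_factor(self) -> float:
        return (
            self.response_rate
            * (1.0 - self.failure_rate)
            * (1.0 - self.adverse_event_rate)
            * (1.0 - self.contraindication_rate)
        )


@dataclass(frozen=True)
class PatientSchedule:
    """Treated patient-years per patent year t = 1..T.

    ``years`` may be fractional; the final entry of ``counts`` is then already
    pro-rated by the fractional part, so entries are patient-years per period
    and sum(counts)/years is the average annual treated count.
    """

    counts: tuple[float, ...]
    years: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("patient counts must be non-negative")


def eligible_patients_static(inputs: StaticPopulationInputs) -> int:
    """Eligible patients for the static models.

    round_half_up(prevalence/1e6 x EU population x treatment rate x market
    share). Monotone non-decreasing in every factor.
    """
    raw = (
        inputs.prevalence_per_million
        * inputs.eu_population
        / 1e6
        * inputs.treatment_rate
        * inputs.market_share
    )
    return round_half_up(raw)


def _uptake(t: int, cap: float, ramp_years: float) -> float:
    if ramp_years <= 0:
        return cap
    return cap * min(1.0, t / ramp_years)


def dcf_patient_schedule(inputs: DCFPopulationInputs, patent_years: float) -> PatientSchedule:
    """Per-year treated patients over the patent horizon.

    The prevalent pool is modelled as a steady-state stock (incident inflow
    offsets attrition), so both the prevalence and the incidence terms are
    applied every year rather than accumulating the incident cohort:

        pool(t) = [prev x pop(t)/1e6 x (1 - restriction_prev)
                   + inc x pop(t)/1e6 x (1 - restriction_inc)] x clinical_factor
        treated(t) = pool(t) x uptake(t)

    with pop(t) = eu_population x (1 + growth)^(t-1) and uptake ramping
    linearly to the cap over ``uptake_ramp_years`` (instantly when 0). A
    fractional final patent year contributes a pro-rated patient-year weight.
    """
    if patent_years < 1:
        raise ValueError("patent_years must be >= 1")
    whole = int(math.floor(patent_years))
    frac = patent_years - whole
    n_periods = whole + (1 if frac > 1e-12 else 0)
    cf = inputs.clinical_factor
    counts = []
    for t in range(1, n_periods + 1):
        pop_t = inputs.eu_population * (1.0 + inputs.population_growth) ** (t - 1)
        pool = (
            inputs.prevalence_per_million * pop_t / 1e6 * (1.0 - inputs.restriction_prevalent)
            + inputs.incidence_per_million * pop_t / 1e6 * (1.0 - inputs.restriction_incident)
        ) * cf
        n = pool * _uptake(t, inputs.uptake_cap, inputs.uptake_ramp_years)
        if t == whole + 1:
            n *= frac
        counts.append(n)
    return PatientSchedule(counts=tuple(counts), years=float(patent_years))


def constant_schedule(n_patients: float, patent_years: float) -> PatientSchedule:
    """A flat schedule of ``n_patients`` treated per year (pro-rated final year)."""
    if patent_years < 1:
        raise ValueError("patent_years must be >= 1")
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    whole = int(math.floor(patent_years))
    frac = patent_years - whole
    counts = [float(n_patients)] * whole
    if frac > 1e-12:
        counts.append(n_patients * frac)
    return PatientSchedule(counts=tuple(counts), years=float(patent_years))


def schedule_mean(schedule: PatientSchedule) -> float:
    """Average annual treated-patient count over the horizon."""
    if not schedule.counts or schedule.years <= 0:
        raise EmptyScheduleError("schedule has no years")
    return sum(schedule.counts) / schedule.years
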