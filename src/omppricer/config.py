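"""Case configuration: schema, loading, normalization.

A case configuration parameterizes all four pricing models for one medicine:
global constants (EU population, EU cost-attribution share, FX rate, reporting
granularity) plus a minimum-scenario and a maximum-scenario input column per
model. The schema is strict — unknown keys are rejected — because fixtures are
transcribed from published tables and silent typos are the main failure mode.

Monetary fields are stored internally in EUR at full precision. A field may be
written in the file as ``{value: X, currency: USD}``; it is converted once, at
load time, with the configured 2021 average exchange rate.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Generic, Literal, TypeVar

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import (
    MissingKeyError,
    ModelMismatchError,
    NegativeAmountError,
    OutOfRangeError,
    ParseError,
    UnknownKeyError,
    ZeroProductsError,
)

__all__ = [
    "GlobalConstants",
    "NCPInputs",
    "AIMInputs",
    "DCFInputs",
    "RORORInputs",
    "ScenarioPair",
    "CaseConfig",
    "MODEL_IDS",
    "load_config",
    "parse_config",
    "write_config",
    "load_lumasiran",
    "lumasiran_path",
    "usd_to_eur",
    "eu_attributable",
    "average_rd_per_product",
    "build_average_inputs",
]

MODEL_IDS = ("ncp", "aim", "dcf", "roror")

#: scenario-column fields that hold EUR lump sums and accept a currency flag
MONETARY_FIELDS = frozenset(
    {
        "rd_cost_total",
        "rd_lumpsum_total",
        "cogs_ppppy",
        "production_overhead_ppppy",
        "production_cost_ppppy",
    }
)


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GlobalConstants(_StrictModel):
    """Case-wide constants shared by all models.

    ``eu_attribution_share`` is the fraction of global R&D spend attributed to
    the EU market (EU population over the population of developed countries).
    ``reporting_rounding`` is the granularity reported prices are rounded to.
    """

    eu_population: float = Field(gt=0)
    eu_attribution_share: float = Field(gt=0, le=1)
    usd_to_eur_rate: float = Field(gt=0)
    reporting_rounding: float = Field(default=1000.0, gt=0)


class NCPInputs(_StrictModel):
    """Novel Cancer Pricing model: audited cost build-up plus a clinical-benefit
    profit margin. Market share is fixed at 1 for this model."""

    prevalence_per_million: float = Field(ge=0)
    treatment_rate: float = Field(ge=0, le=1)
    patent_years: float = Field(ge=1)
    rd_cost_total: float = Field(ge=0)
    cogs_ppppy: float = Field(ge=0)
    marketing_fraction: float = Field(ge=0)
    profit_margin: float = Field(ge=0)


class AIMInputs(_StrictModel):
    """AIM model: lump-sum R&D recovery with standardized cost assumptions,
    a basic profit and an innovation bonus (0-40%).

    ``bonus_convention`` selects how basic profit and bonus compose:
    ``additive`` -> base x (1 + profit + bonus); ``multiplicative`` ->
    base x (1 + profit) x (1 + bonus).
    """

    prevalence_per_million: float = Field(ge=0)
    treatment_rate: float = Field(ge=0, le=1)
    market_share: float = Field(gt=0, le=1)
    patent_years: float = Field(ge=1)
    rd_cost_total: float = Field(ge=0)
    production_overhead_ppppy: float = Field(ge=0)
    sales_fraction: float = Field(ge=0)
    basic_profit: float = Field(ge=0, le=1)
    innovation_bonus: float = Field(ge=0, le=1)
    bonus_convention: Literal["additive", "multiplicative"] = "additive"


class DCFInputs(_StrictModel):
    """Discounted-cash-flow model: break-even price at patent expiry with the
    cost of capital as discount rate, plus a fixed innovation premium."""

    prevalence_per_million: float = Field(ge=0)
    incidence_per_million: float = Field(ge=0)
    response_rate: float = Field(ge=0, le=1)
    failure_rate: float = Field(ge=0, le=1)
    adverse_event_rate: float = Field(ge=0, le=1)
    contraindication_rate: float = Field(ge=0, le=1)
    restriction_prevalent: float = Field(ge=0, le=1)
    restriction_incident: float = Field(ge=0, le=1)
    population_growth: float = Field(gt=-1)
    uptake_cap: float = Field(gt=0, le=1)
    uptake_ramp_years: float = Field(default=0.0, ge=0)
    patent_years: float = Field(ge=1)
    rd_lumpsum_total: float = Field(ge=0)
    drug_cost_fraction_of_revenue: float = Field(ge=0, lt=1)
    cost_of_capital: float = Field(ge=0)
    innovation_premium: float = Field(ge=0)


class RORORInputs(_StrictModel):
    """Real-option rate-of-return model: R&D per patient-year compounded at
    WACC net of the GDP deflator over the development period."""

    prevalence_per_million: float = Field(ge=0)
    treatment_rate: float = Field(default=1.0, ge=0, le=1)
    patent_years: float = Field(ge=1)
    rd_cost_total: float = Field(ge=0)
    production_cost_ppppy: float = Field(ge=0)
    wacc: float = Field(ge=0)
    gdp_deflator: float = Field(gt=-1)
    years_until_approval: float = Field(ge=0)
    profit_margin: float = Field(ge=0)


ModelInputs = NCPInputs | AIMInputs | DCFInputs | RORORInputs
T = TypeVar("T", NCPInputs, AIMInputs, DCFInputs, RORORInputs)


class ScenarioPair(_StrictModel, Generic[T]):
    """One model's minimum-price and maximum-price input columns.

    Column orientation follows the source tables: a parameter that is
    inversely proportional to the price (e.g. prevalence) takes its highest
    value in the *minimum* column.
    """

    min: T
    max: T


class CaseConfig(_StrictModel):
    """Full parameterization of the four pricing models for one medicine."""

    metadata: dict[str, str] = Field(min_length=1)
    constants: GlobalConstants
    ncp: ScenarioPair[NCPInputs]
    aim: ScenarioPair[AIMInputs]
    dcf: ScenarioPair[DCFInputs]
    roror: ScenarioPair[RORORInputs]

    def pair(self, model_id: str) -> ScenarioPair:
        if model_id not in MODEL_IDS:
            raise OutOfRangeError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
        return getattr(self, model_id)


# ---------------------------------------------------------------------------
# elementary normalization operations


def usd_to_eur(amount_usd: float, rate: float) -> float:
    """Convert a USD amount to EUR at ``rate`` EUR per USD."""
    if amount_usd < 0:
        raise NegativeAmountError(f"amount_usd must be >= 0, got {amount_usd}")
    if rate <= 0:
        raise OutOfRangeError(f"rate must be > 0, got {rate}")
    return amount_usd * rate


def eu_attributable(global_cost: float, share: float) -> float:
    """EU-attributable part of a global cost lump sum."""
    if global_cost < 0:
        raise NegativeAmountError(f"global_cost must be >= 0, got {global_cost}")
    if not 0 < share <= 1:
        raise OutOfRangeError(f"share must be in (0, 1], got {share}")
    return global_cost * share


def average_rd_per_product(total_rd_spend: float, n_approved_products: int) -> float:
    """Company-level R&D spend divided by the number of approved products.

    Spreading the aggregate over all approvals folds the cost of failed
    projects into each product's lump sum.
    """
    if total_rd_spend < 0:
        raise NegativeAmountError(f"total_rd_spend must be >= 0, got {total_rd_spend}")
    if int(n_approved_products) != n_approved_products or n_approved_products < 1:
        raise ZeroProductsError(
            f"n_approved_products must be an integer >= 1, got {n_approved_products}"
        )
    return total_rd_spend / n_approved_products


def build_average_inputs(min_inputs: T, max_inputs: T) -> T:
    """Average-scenario inputs: field-wise arithmetic mean of the two columns.

    Averaging applies to *inputs*, which are then re-priced — never to output
    prices. Non-numeric fields (e.g. the AIM bonus convention) must agree in
    both columns and are copied through.
    """
    if type(min_inputs) is not type(max_inputs):
        raise ModelMismatchError(
            f"cannot average {type(min_inputs).__name__} with {type(max_inputs).__name__}"
        )
    update: dict = {}
    for name in type(min_inputs).model_fields:
        a, b = getattr(min_inputs, name), getattr(max_inputs, name)
        if isinstance(a, bool) or not isinstance(a, (int, float)):
            if a != b:
                raise ModelMismatchError(
                    f"non-numeric field {name!r} differs between scenarios ({a!r} vs {b!r})"
                )
            update[name] = a
        else:
            update[name] = (a + b) / 2.0
    return type(min_inputs)(**update)


# ---------------------------------------------------------------------------
# loading / writing


def _read_raw(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix == ".json":
            raw = json.loads(text)
        else:  # YAML is a JSON superset, so .yaml/.yml and bare JSON both land here
            raw = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path} does not contain a mapping at top level")
    return raw


def _deep_merge(base: dict, overlay: dict) -> dict:
    out = dict(base)
    for key, val in overlay.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict) and not _is_currency(val):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def _is_currency(value) -> bool:
    return isinstance(value, dict) and set(value) == {"value", "currency"}


def _convert_currencies(raw: dict, rate: float) -> dict:
    out = dict(raw)
    for model_id in MODEL_IDS:
        block = out.get(model_id)
        if not isinstance(block, dict):
            continue
        block = dict(block)
        for col in ("min", "max"):
            scen = block.get(col)
            if not isinstance(scen, dict):
                continue
            scen = dict(scen)
            for field, value in scen.items():
                if not _is_currency(value):
                    continue
                if field not in MONETARY_FIELDS:
                    raise OutOfRangeError(
                        f"{model_id}.{col}.{field}: currency flag only allowed on "
                        f"monetary fields {sorted(MONETARY_FIELDS)}"
                    )
                currency = value["currency"]
                if currency == "EUR":
                    scen[field] = float(value["value"])
                elif currency == "USD":
                    scen[field] = usd_to_eur(float(value["value"]), rate)
                else:
                    raise OutOfRangeError(
                        f"{model_id}.{col}.{field}: unknown currency {currency!r}"
                    )
            block[col] = scen
        out[model_id] = block
    return out


def _translate_validation_error(exc: ValidationError) -> Exception:
    err = exc.errors()[0]
    loc = ".".join(str(part) for part in err["loc"])
    if err["type"] == "missing":
        return MissingKeyError(loc)
    if err["type"] == "extra_forbidden":
        return UnknownKeyError(loc)
    return OutOfRangeError(f"{loc}: {err['msg']} (got {err.get('input')!r})")


def parse_config(raw: dict) -> CaseConfig:
    """Validate an in-memory mapping into a :class:`CaseConfig`."""
    constants_raw = raw.get("constants")
    if constants_raw is None:
        raise MissingKeyError("constants")
    try:
        constants = GlobalConstants.model_validate(constants_raw)
    except ValidationError as exc:
        raise _translate_validation_error(exc) from exc
    normalized = _convert_currencies(raw, constants.usd_to_eur_rate)
    try:
        return CaseConfig.model_validate(normalized)
    except ValidationError as exc:
        raise _translate_validation_error(exc) from exc


def load_config(path: str | Path, overlay: str | Path | None = None) -> CaseConfig:
    """Load and validate a YAML or JSON case configuration.

    ``overlay``, when given, is a second file deep-merged over the base before
    validation — used e.g. to swap printed "~"-rounded lump sums for
    higher-precision values without touching the transcription fixture.
    """
    raw = _read_raw(path)
    if overlay is not None:
        raw = _deep_merge(raw, _read_raw(overlay))
    return parse_config(raw)


def write_config(config: CaseConfig, path: str | Path) -> Path:
    """Write a configuration back to YAML (or JSON by suffix). Round-trips."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
    return path


def lumasiran_path() -> Path:
    """Path of the bundled lumasiran case fixture (published scenario tables)."""
    return Path(str(resources.files("omppricer").joinpath("data/lumasiran.yaml")))


def load_lumasiran() -> CaseConfig:
    """The bundled lumasiran / primary hyperoxaluria type 1 case."""
    return load_config(lumasiran_path())
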