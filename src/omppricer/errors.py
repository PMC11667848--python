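"""Exception hierarchy for the pricing engine.

Configuration problems (bad files, schema violations) and domain problems
(inadmissible values reaching a computation) are kept on separate branches so
the CLI can map them to distinct exit codes.
"""

from __future__ import annotations


class OmpPricerError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(OmpPricerError):
    """A case configuration could not be loaded or validated."""


class ParseError(ConfigError):
    """The file is not valid YAML/JSON or not a mapping."""


class MissingKeyError(ConfigError):
    """A required key is absent; the message names the key path."""


class UnknownKeyError(ConfigError):
    """An unrecognized key is present (strict schema catches typos)."""


class OutOfRangeError(ConfigError):
    """A field value is outside its admissible range."""


class DomainError(OmpPricerError):
    """An inadmissible value reached a pricing computation."""


class ModelMismatchError(DomainError):
    """Two scenario-input objects of different model types were combined."""


class NegativeAmountError(DomainError):
    """A monetary amount that must be non-negative was negative."""


class ZeroProductsError(DomainError):
    """R&D averaging requires at least one approved product."""


class ZeroPatientsError(DomainError):
    """Per-patient amortization requires at least one patient."""


class ZeroYearsError(DomainError):
    """Per-year amortization requires at least one patent year."""


class NoRevenueError(DomainError):
    """The discounted patient-year total is zero; no break-even price exists."""


class EmptyScheduleError(DomainError):
    """A patient schedule with no years has no mean."""


class ExhaustedRetriesError(DomainError):
    """The synthetic sampler could not find an admissible draw."""
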