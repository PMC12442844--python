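"""Exception hierarchy for the assay-to-dosage pipeline.

Every error raised by this package derives from :class:`FruitEthanolError`,
so callers can catch the whole family with one clause while tests can pin
down the specific failure mode.
"""


class FruitEthanolError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(FruitEthanolError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(FruitEthanolError):
    """Too few observations for the requested computation."""


class DegenerateDesignError(FruitEthanolError):
    """Regression design has no usable variation (e.g. constant responses)."""


class MethodMismatchError(FruitEthanolError):
    """A calibration fit was paired with a reading from a different assay."""


class InconsistentMeasurementError(FruitEthanolError):
    """Physically impossible measurement combination (e.g. dry mass >= 1)."""


class MissingWeightError(FruitEthanolError):
    """A species summary has no feeding-time entry to weight it by."""


class SchemaError(FruitEthanolError):
    """An input table is missing a required column."""


class ParseError(FruitEthanolError):
    """A cell in an input table could not be parsed."""


class IntegrityError(FruitEthanolError):
    """Cross-row consistency violation (e.g. duplicated sample ids)."""
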