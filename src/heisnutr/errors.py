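"""Exception hierarchy for the heisnutr pipeline."""


class HeisnutrError(Exception):
    """Base class for all package errors."""


class SchemaError(HeisnutrError):
    """An input file does not conform to the expected column schema."""


class ValidationError(HeisnutrError):
    """Input values violate a documented invariant (bounds, uniqueness, references)."""


class CoverageError(HeisnutrError):
    """A purchase or food item references a category the table does not cover."""


class DegenerateDataError(HeisnutrError):
    """A computation cannot proceed (all values missing, every item dropped, ...)."""
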