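"""Exception hierarchy."""


class IsofitError(Exception):
    """Base class for all isofit errors."""


class AnnotationParseError(IsofitError):
    """Malformed annotation record; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ModelError(IsofitError):
    """Inconsistent transcript model (e.g. CDS outside exons)."""


class CoordinateError(IsofitError):
    """Feature coordinates outside the transcript/protein space."""


class ContractError(IsofitError):
    """Operation precondition violated by the caller."""


class NormalizationError(IsofitError):
    """Normalization cannot proceed (e.g. all-zero sample)."""


class AggregationError(IsofitError):
    """Expression aggregation failed (e.g. transcript missing from models)."""


class SpecError(IsofitError):
    """Infeasible simulation specification."""
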