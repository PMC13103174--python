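"""Exception hierarchy shared across the package."""


class PhimprintError(Exception):
    """Base class for all package errors."""


class UnknownCategoryError(KeyError, PhimprintError):
    """Raised when a taxonomy category id is not registered."""


class InvalidContentError(ValueError, PhimprintError):
    """Raised when imprint content violates its invariants (e.g. empty main text)."""


class InvalidSizeError(ValueError, PhimprintError):
    """Raised for non-positive or too-small image dimensions."""


class InvalidRequestError(ValueError, PhimprintError):
    """Raised when an operation is asked for more than the input provides."""


class ConfigError(ValueError, PhimprintError):
    """Raised for inconsistent dataset or pipeline configuration."""


class PlacementError(PhimprintError):
    """Raised when imprints cannot be placed without violating the overlap policy."""


class LabelParseError(PhimprintError):
    """Raised for malformed label files; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc}: {message}" if path else message)


class StructuredOutputError(PhimprintError):
    """Raised when an analyzer response does not satisfy the output contract."""


class InstanceEvalUnavailableError(PhimprintError):
    """Raised when instance-level evaluation is requested on coordinate-free predictions."""


class AlignmentError(PhimprintError):
    """Raised when ground-truth and prediction image ids do not line up."""


class AggregationError(PhimprintError):
    """Raised when evaluation reports with mixed level/scope are aggregated."""
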