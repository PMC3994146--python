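"""Exception hierarchy for the chipsip pipeline."""


class ChipSipError(Exception):
    """Base class for all chipsip errors."""


class FormatError(ChipSipError):
    """A file could not be parsed into the expected schema."""


class ValidationError(ChipSipError):
    """Parsed data violates a schema invariant (offending rows are named)."""


class ParameterError(ChipSipError):
    """A configuration or function parameter is out of its admissible range."""


class InsufficientDataError(ChipSipError):
    """Too few observations to fit the requested model."""


class DegenerateDesignError(ChipSipError):
    """The regression design matrix is rank-deficient (e.g. constant fluorescence)."""
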