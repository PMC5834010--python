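"""Exception hierarchy shared across the pipeline."""


class TilquantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TilquantError):
    """A configuration value violates its contract (negative intensity, ...)."""


class FormatError(TilquantError):
    """An input image or table does not have the expected format."""


class ContractViolation(TilquantError):
    """A function was called outside its stated preconditions."""


class TrainingError(TilquantError):
    """The classifier training set violates its contract (e.g. missing class)."""


class FitError(TilquantError):
    """A statistical model could not be fitted (no events, empty data, ...)."""


class ValidationError(TilquantError):
    """Internally inconsistent data (e.g. a subset larger than its superset)."""
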