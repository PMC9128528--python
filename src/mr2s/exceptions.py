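"""Exception hierarchy shared across the package."""


class Mr2sError(Exception):
    """Base class for all package errors."""


class SumstatFormatError(Mr2sError):
    """A summary-statistics file is structurally malformed (e.g. missing column)."""


class SumstatValidationError(Mr2sError):
    """Table-level validation failed (e.g. duplicate SNP identifiers)."""


class ConfigError(Mr2sError):
    """A configuration value is outside its legal range."""


class InsufficientInstrumentsError(Mr2sError):
    """Too few instruments for the requested estimator.

    Carries ``required`` and ``available`` counts so callers (the pipeline's
    method-selection rule) can fall back, e.g. from IVW to the Wald ratio.
    """

    def __init__(self, required: int, available: int, method: str = ""):
        self.required = required
        self.available = available
        self.method = method
        msg = f"need >= {required} instruments, got {available}"
        if method:
            msg = f"{method}: {msg}"
        super().__init__(msg)


class UndefinedRatioError(Mr2sError):
    """Wald ratio requested with a zero exposure effect."""
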