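"""Exception hierarchy shared across the package."""


class DemostratError(Exception):
    """Base class for all package-specific errors."""


class InputError(DemostratError, ValueError):
    """Invalid user-supplied value or malformed input data."""


class DegeneratePredictorError(InputError):
    """A predictor of interest is constant or otherwise unusable."""


class ConfigurationError(InputError):
    """A configuration object is incomplete or inconsistent."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConvergenceError(DemostratError, RuntimeError):
    """Model fitting failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
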