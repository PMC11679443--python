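"""Exception hierarchy shared across the package."""


class WelfareMetricsError(Exception):
    """Base class for all package errors."""


class ParseError(WelfareMetricsError):
    """A stream record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(WelfareMetricsError):
    """A record parsed but violates a type invariant."""


class ConfigError(WelfareMetricsError):
    """A configuration file is invalid or inconsistent."""


class DegeneratePoseError(WelfareMetricsError):
    """Keypoint geometry is degenerate (e.g. zero body length)."""


class InsufficientEdgeError(WelfareMetricsError):
    """A back-silhouette edge has too few points to score."""


class DegenerateTrainingError(WelfareMetricsError):
    """A training set cannot support the requested fit (e.g. one class)."""


class DegenerateGeometryError(WelfareMetricsError):
    """Pen corner geometry does not admit a projective transform."""
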