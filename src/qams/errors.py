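"""Exception hierarchy shared across the package."""


class QAMSError(Exception):
    """Base class for all package-specific errors."""


class FormatError(QAMSError):
    """A file does not follow the expected dialect (e.g. missing column)."""


class RowParseError(FormatError):
    """A single row failed to parse; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class PanelError(QAMSError):
    """Component panel violates its invariants (internal reference, codes)."""


class DegenerateDesignError(QAMSError):
    """Calibration design cannot identify a slope (all masses identical)."""


class CurveError(QAMSError):
    """A calibration curve is unusable (e.g. non-positive slope)."""


class AmbiguityError(QAMSError):
    """Two or more peaks match one expected relative retention time."""


class AssignmentError(QAMSError):
    """No internal-reference candidate peak could be located."""


class PairingError(QAMSError):
    """Paired collections do not cover the same (sample, component) keys."""


class ConfigError(QAMSError):
    """A configuration document is missing keys or malformed."""
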