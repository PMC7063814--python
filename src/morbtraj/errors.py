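"""Exception types shared across the pipeline."""


class MorbtrajError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MorbtrajError):
    """Invalid configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ValidationError(MorbtrajError):
    """Malformed value (e.g. an ICD-10 code that is not level-3)."""


class BlockTableParseError(MorbtrajError):
    """Malformed block-definition file; carries the offending line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class DataConsistencyError(MorbtrajError):
    """Registry rows contradict each other (e.g. a stay after death)."""
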