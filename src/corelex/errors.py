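"""Exception types shared across the package."""


class CorelexError(Exception):
    """Base class for all package-specific errors."""


class ChatParseError(CorelexError):
    """A transcript line could not be parsed as the supported CHAT subset."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TaskNotFoundError(CorelexError):
    """The requested discourse task has no gem segment in the transcript."""


class LexiconValidationError(CorelexError):
    """A checklist file violates the core-lexicon format rules."""


class ModalityMismatchError(CorelexError):
    """Two score tables cannot be compared (samples, task or checklist differ)."""
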