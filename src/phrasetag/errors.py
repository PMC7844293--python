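"""Exception hierarchy for the phrasetag pipeline."""


class PhraseTagError(Exception):
    """Base class for all phrasetag errors."""


class InvalidInputError(PhraseTagError, ValueError):
    """An argument violates a documented precondition."""


class StreamConstructionError(PhraseTagError, RuntimeError):
    """A seeded stream builder exhausted its retry budget.

    Carries a ``diagnostics`` mapping from constraint name to the number of
    times that constraint caused a restart, so callers can see which
    requirement is binding.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


class ParseError(PhraseTagError, ValueError):
    """A text input file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line
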