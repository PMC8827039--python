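"""Exception hierarchy for pathlinc.

All errors raised on purpose by this package derive from :class:`PathlincError`
so callers can catch one base class at pipeline level.
"""


class PathlincError(Exception):
    """Base class for all pathlinc errors."""


class ValidationError(PathlincError, ValueError):
    """An input object violates a documented invariant."""


class ParseError(PathlincError, ValueError):
    """A file could not be parsed; message carries row/column context."""


class ZeroVarianceError(PathlincError, ValueError):
    """A vector with zero variance was passed where a correlation is needed."""


class NoOverlapError(PathlincError, ValueError):
    """A gene set shares no member with the ranked list it is scored against."""


class PipelineError(PathlincError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
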