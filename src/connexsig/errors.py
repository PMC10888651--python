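"""Exception hierarchy shared across the pipeline."""


class ConnexsigError(Exception):
    """Base class for all package errors."""


class FormatError(ConnexsigError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ConnexsigError):
    """An in-memory object violates one of its invariants."""


class SpecError(ConnexsigError):
    """A simulation specification is inconsistent."""


class SelectionError(ConnexsigError):
    """A compendium subsetting step produced an empty or impossible selection."""


class QueryError(ConnexsigError):
    """A connectivity query cannot be evaluated against the reference."""


class StageError(ConnexsigError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
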