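"""Exception hierarchy shared across the package."""


class GCSearchError(Exception):
    """Base class for all package errors."""


class FormatError(GCSearchError):
    """A table is missing a required column or is otherwise malformed."""


class ValidationError(GCSearchError):
    """Parsed data violates a model invariant (e.g. non-monotone time)."""


class PackingError(GCSearchError):
    """Hard-sphere placement could not satisfy the non-overlap/dispersion
    constraints within the attempt budget."""

    def __init__(self, message: str, attempts: int | None = None):
        super().__init__(message)
        self.attempts = attempts
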