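"""Exception hierarchy shared across the package.

All argument-validation failures derive from :class:`InvalidArgumentError`
(a ``ValueError``) so callers can catch one type; the remaining classes
exist where the *kind* of failure carries protocol meaning (e.g. an
unknown identity must be distinguishable from a rejected probe).
"""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class ShapeError(InvalidArgumentError):
    """An array does not have the shape the trained model expects."""


class LeadNotFoundError(KeyError):
    """Requested ECG lead is absent from a multi-lead record."""

    def __init__(self, requested: str, available: list[str]):
        super().__init__(requested)
        self.requested = requested
        self.available = list(available)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"lead {self.requested!r} not found; available leads: "
            f"{', '.join(map(repr, self.available))}"
        )


class ParseError(ValueError):
    """A text input file is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CapacityError(InvalidArgumentError):
    """Not enough segments/subjects to satisfy a request."""


class AlreadyEnrolledError(ValueError):
    """The user id is already present in the template repository."""


class IdentityNotFoundError(KeyError):
    """A claimed identity is not enrolled (distinct from a reject decision)."""


class UnsupportedVersionError(ValueError):
    """A serialized file declares a format version this build cannot read."""
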