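"""Structured exception hierarchy used across the package."""


class RefineError(Exception):
    """Base class for all package errors."""


class ValidationError(RefineError, ValueError):
    """Invalid input values, shapes, or domain-contract violations."""


class ParseError(RefineError, ValueError):
    """A structure file could not be parsed into a usable chain."""


class DegenerateFrameError(ValidationError):
    """Backbone geometry too degenerate to define a residue frame."""

    def __init__(self, message: str, residue_index: int | None = None):
        super().__init__(message)
        self.residue_index = residue_index


class SuperpositionError(ValidationError):
    """Too few or degenerate points for a rigid superposition."""
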