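"""Exception hierarchy for filatrans.

All package-specific failures derive from :class:`FilatransError` so callers
can catch one base class at CLI or batch level.
"""


class FilatransError(Exception):
    """Base class for all filatrans errors."""


class InvalidSpecError(FilatransError, ValueError):
    """A synthetic filament specification violates its invariants."""


class NoFilamentError(FilatransError):
    """No filament could be separated from the background."""


class FilamentTooShortError(FilatransError):
    """The detected filament covers too few image columns to analyze."""


class NoTransitionError(FilatransError):
    """The color profile never completes a 90-to-10 transition."""

    def __init__(self, message: str, failed_bound: str | None = None):
        super().__init__(message)
        self.failed_bound = failed_bound


class DegenerateDesignError(FilatransError, ValueError):
    """A regression design carries no information (e.g. all times zero)."""


class InvalidInputError(FilatransError, ValueError):
    """Inputs are structurally invalid (length mismatch, missing fields)."""


class CorrectionRefusedError(FilatransError):
    """Diffusion correction was requested without an elapsed time."""


class MixedCorrectionError(FilatransError):
    """Corrected summaries were requested but some results lack correction."""
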