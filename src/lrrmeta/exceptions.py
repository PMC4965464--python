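"""Exception types shared across the package."""


class LrrMetaError(Exception):
    """Base class for all package-specific errors."""


class InvalidValueError(LrrMetaError, ValueError):
    """A numeric input violates a precondition (non-positive mean, bad range...)."""


class UnusableStudyError(LrrMetaError):
    """A study cannot contribute a ratio effect size (e.g. all values <= 0)."""


class InsufficientDataError(LrrMetaError):
    """Too few studies / units / time-points for the requested computation."""


class ConvergenceError(LrrMetaError):
    """Iterative estimation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


class RankDeficiencyError(LrrMetaError):
    """The regression design is rank deficient; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "rank-deficient design; collinear or constant columns: "
            + ", ".join(self.columns)
        )
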