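"""Exception types raised across the package.

Every contract violation raises an explicit, typed error rather than
returning a sentinel, so pipeline code can distinguish bad inputs from
genuine analysis failures.
"""


class AggrheoError(Exception):
    """Base class for all package errors."""


class PlacementError(AggrheoError):
    """Synthetic aggregate placement could not satisfy the separation
    constraint within the rejection-sampling budget."""

    def __init__(self, placed: int, requested: int, attempts: int):
        self.placed = placed
        self.requested = requested
        self.attempts = attempts
        super().__init__(
            f"placed only {placed} of {requested} aggregates after "
            f"{attempts} rejection attempts for the next one"
        )


class ImageFormatError(AggrheoError):
    """Input image is not single-channel 8-bit."""


class ConfigurationError(AggrheoError):
    """A configuration value violates its documented invariant."""


class UndefinedScoreError(AggrheoError):
    """A morphometric score is undefined for this region (e.g. empty
    foreground under the detection)."""


class EmptySampleError(AggrheoError):
    """A summary statistic was requested for an empty sample."""


class FitFailureError(AggrheoError):
    """A model fit failed or the data are degenerate; carries diagnostics
    instead of silently returning parameters."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class NoYieldError(AggrheoError):
    """The storage modulus never drops below the yield criterion: the
    material did not yield within the probed amplitude range."""
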