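"""Exception hierarchy shared across the package."""


class HoctError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HoctError, ValueError):
    """A physical parameter is non-positive, out of range, or inconsistent."""


class InvalidSweepError(HoctError, ValueError):
    """A sweep profile violates its invariants (e.g. non-monotone frequency)."""


class DomainError(HoctError, ValueError):
    """A query lies outside the modeled sweep window."""


class AliasingError(HoctError, ValueError):
    """A fringe component exceeds the Nyquist rate of the acquisition."""


class FitFailureError(HoctError, RuntimeError):
    """Sweep recovery from the k-clock did not converge to an acceptable residual."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoSignalError(HoctError, RuntimeError):
    """All distribution columns fall below the envelope-power threshold."""


class GridMismatchError(HoctError, ValueError):
    """Two objects that must share a wavenumber grid do not."""


class ScheduleError(HoctError, ValueError):
    """A modulation schedule cannot be realised within the VCO range."""


class ConfigError(HoctError, ValueError):
    """A run configuration is missing keys or fails validation."""
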