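"""Exception hierarchy for the flianirs package."""

from __future__ import annotations


class FliaNirsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FliaNirsError, ValueError):
    """An input parameter violates a documented precondition."""


class FormatError(FliaNirsError, ValueError):
    """A file or in-memory record violates the recording/table format."""


class SignalTooShortError(FliaNirsError, ValueError):
    """A series is too short for the requested filtering operation."""


class DetectionError(FliaNirsError, RuntimeError):
    """A signal-driven detector found no admissible event.

    Carries a diagnostic envelope (``time``, ``envelope`` arrays) so the
    failure can be inspected.
    """

    def __init__(self, message: str, time=None, envelope=None):
        super().__init__(message)
        self.time = time
        self.envelope = envelope


class SelectionError(FliaNirsError, ValueError):
    """Analysis-leg selection could not be resolved for a subject."""


class RankDeficiencyError(FliaNirsError, ValueError):
    """The design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(map(str, self.columns))
        )


class ConfigError(FliaNirsError, ValueError):
    """A run configuration failed schema validation."""
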