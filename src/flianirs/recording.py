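"""In-memory containers for muscle-oximetry recordings.

A recording holds three channels sampled on a uniform 10 Hz grid:

* ``o2hb`` — oxygenated heme-pigment concentration (a.u.),
* ``hhb``  — deoxygenated heme-pigment concentration (a.u.),
* ``tsi``  — tissue saturation index in percent (optional; either
  device-provided or derived as 100 * O2Hb / (O2Hb + HHb)),

plus phase markers delimiting warm-up, exercise (incremental ramp to task
failure) and post-exercise recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import FormatError

SAMPLE_RATE_HZ = 10.0
DT_S = 1.0 / SAMPLE_RATE_HZ

#: Signal names accepted throughout the package.
SIGNALS = ("tsi", "o2hb", "dhb")


@dataclass(frozen=True)
class PhaseMarkers:
    """Phase boundaries of an exercise-test recording, in seconds.

    ``t_recovery_start`` may be ``None`` when the boundary has to be located
    from the cadence artifact (see :func:`flianirs.preprocess.detect_recovery_start`).
    """

    t_warmup_start: float
    t_exercise_start: float
    t_recovery_start: Optional[float]
    t_end: float

    def __post_init__(self):
        seq = [self.t_warmup_start, self.t_exercise_start]
        if self.t_recovery_start is not None:
            seq.append(self.t_recovery_start)
        seq.append(self.t_end)
        if any(not np.isfinite(v) for v in seq):
            raise FormatError("phase markers must be finite")
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise FormatError(f"phase markers must be strictly ordered, got {seq}")


@dataclass
class NirsRecording:
    """One leg's NIRS time series with phase markers and metadata."""

    time: np.ndarray
    o2hb: np.ndarray
    hhb: np.ndarray
    markers: PhaseMarkers
    tsi: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.o2hb = np.asarray(self.o2hb, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        if self.tsi is not None:
            self.tsi = np.asarray(self.tsi, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.time.size
        if n < 2:
            raise FormatError("recording must contain at least two samples")
        for name in ("o2hb", "hhb"):
            if getattr(self, name).shape != (n,):
                raise FormatError(f"channel {name!r} length differs from time axis")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise FormatError("time axis must be strictly increasing")
        if not np.allclose(steps, DT_S, atol=1e-6):
            raise FormatError("time axis must be a uniform 10 Hz grid (step 0.1 s)")
        if self.tsi is not None:
            if self.tsi.shape != (n,):
                raise FormatError("tsi length differs from time axis")
            finite = self.tsi[np.isfinite(self.tsi)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
                raise FormatError("tsi values must lie in [0, 100] %")
        m = self.markers
        span = (self.time[0] - 1e-9, self.time[-1] + 1e-9)
        for v in (m.t_warmup_start, m.t_exercise_start, m.t_recovery_start, m.t_end):
            if v is not None and not (span[0] <= v <= span[1]):
                raise FormatError(f"marker {v} outside recording span {span}")

    # -- small conveniences -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def index_at(self, t: float) -> int:
        """Index of the grid sample closest to time ``t`` (seconds)."""
        return int(round((t - self.time[0]) * SAMPLE_RATE_HZ))

    def phase_labels(self) -> np.ndarray:
        """Per-sample phase label (warmup / exercise / recovery)."""
        m = self.markers
        if m.t_recovery_start is None:
            raise FormatError("recovery marker required to label phases")
        labels = np.full(self.n_samples, "recovery", dtype=object)
        labels[self.time < m.t_recovery_start] = "exercise"
        labels[self.time < m.t_exercise_start] = "warmup"
        return labels

    def replace(self, **kwargs) -> "NirsRecording":
        return dataclasses.replace(self, **kwargs)
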