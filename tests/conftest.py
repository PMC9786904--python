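import numpy as np
import pytest

import flianirs as fl
from flianirs.recording import DT_S, NirsRecording, PhaseMarkers


@pytest.fixture(scope="session")
def noiseless_recording():
    """Clean recording: baseline 60 %, nadir 40 %, recovery max 67 %."""
    params = fl.RecordingParams(baseline_tsi=60.0, delta_exercise=20.0,
                                delta_recovery=27.0, tau=20.0, td=15.0,
                                noise_sd=0.0, spike_rate_per_min=0.0,
                                oscillation_amplitude=0.0)
    return fl.generate_recording(params, seed=42)


@pytest.fixture(scope="session")
def noisy_recording():
    params = fl.RecordingParams(tau=20.0, td=15.0)
    return fl.generate_recording(params, seed=7)


def make_recovery_recording(recovery: np.ndarray, offset: float = 50.0,
                            warmup_s: float = 20.0,
                            exercise_s: float = 60.0) -> NirsRecording:
    """Build a recording whose TSI recovery segment is the given array.

    Warm-up and exercise are flat filler at ``offset``; the recovery values
    are ``offset + recovery`` (keep them within [0, 100]).
    """
    n_pre = int(round((warmup_s + exercise_s) / DT_S))
    tsi = np.concatenate([np.full(n_pre, offset), offset + recovery])
    t = np.arange(tsi.size) * DT_S
    markers = PhaseMarkers(0.0, warmup_s, warmup_s + exercise_s, float(t[-1]))
    o2hb = tsi.copy()
    hhb = 100.0 - tsi
    return NirsRecording(time=t, o2hb=o2hb, hhb=hhb, tsi=tsi, markers=markers)
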