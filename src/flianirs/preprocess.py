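"""Signal conditioning for exercise-recovery NIRS recordings.

The conditioning chain mirrors common practice for pedalling NIRS data:

1. Hampel outlier replacement (movement-artifact spikes),
2. zero-lag 5th-order Butterworth low-pass at 1 Hz (removes the
   cadence-frequency oscillation without phase shift),
3. derivation of the tissue saturation index (TSI) and the differential
   hemoglobin signal dHb = O2Hb - HHb,
4. recovery-start localization from the end of the cyclic cadence pattern.

All stages preserve series length and timestamps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .errors import DetectionError, FormatError, ParameterError, SignalTooShortError
from .recording import DT_S, SAMPLE_RATE_HZ, NirsRecording, PhaseMarkers

log = logging.getLogger(__name__)

#: Consistency factor turning the median absolute deviation into a Gaussian
#: standard-deviation estimate.
MAD_SCALE = 1.4826

REQUIRED_COLUMNS = ("time_s", "O2Hb", "HHb", "phase")


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_recording(path) -> NirsRecording:
    """Read a delimited-text recording written by the synthetic generator.

    Expected columns: ``time_s, O2Hb, HHb[, TSI], phase`` with phase labels in
    ``{warmup, exercise, recovery}``. A missing ``TSI`` column is tolerated
    (it is derived later). Non-uniform timestamps are resampled onto the
    10 Hz grid by linear interpolation, with a logged warning.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    t = frame["time_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise FormatError(f"{path}: non-finite timestamps")
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time axis not strictly increasing (duplicate "
                          "or reversed timestamps)")

    o2hb = frame["O2Hb"].to_numpy(dtype=float)
    hhb = frame["HHb"].to_numpy(dtype=float)
    tsi = frame["TSI"].to_numpy(dtype=float) if "TSI" in frame.columns else None
    phase = frame["phase"].astype(str).to_numpy()

    if not np.allclose(np.diff(t), DT_S, atol=1e-6):
        log.warning("%s: non-uniform timestamps; resampling to the 10 Hz grid", path)
        grid = np.arange(t[0], t[-1] + DT_S / 2, DT_S)
        o2hb = np.interp(grid, t, o2hb)
        hhb = np.interp(grid, t, hhb)
        if tsi is not None:
            tsi = np.interp(grid, t, tsi)
        # nearest-neighbour phase labels on the new grid
        phase = phase[np.searchsorted(t, grid, side="right") - 1]
        t = grid

    markers = _markers_from_phase(t, phase)
    return NirsRecording(time=t, o2hb=o2hb, hhb=hhb, tsi=tsi, markers=markers,
                         meta={"source": str(path)})


def _markers_from_phase(t: np.ndarray, phase: np.ndarray) -> PhaseMarkers:
    for label in ("warmup", "exercise", "recovery"):
        if label not in phase:
            raise FormatError(f"phase column lacks any {label!r} samples")
    return PhaseMarkers(
        t_warmup_start=float(t[0]),
        t_exercise_start=float(t[phase == "exercise"][0]),
        t_recovery_start=float(t[phase == "recovery"][0]),
        t_end=float(t[-1]),
    )


# ---------------------------------------------------------------------------
# outlier replacement
# ---------------------------------------------------------------------------

def hampel_filter(x, half_window: int = 3, n_sigmas: float = 3.0,
                  max_passes: int = 30) -> np.ndarray:
    """Hampel identifier with robust (MAD-based) scale, run to a fixed point.

    Each sample is compared to the median of its window (the sample plus
    ``half_window`` neighbours to each side); when the deviation exceeds
    ``n_sigmas`` times the robust scale ``1.4826 * MAD`` of the window, the
    sample is replaced by the window median. When the MAD is zero the
    threshold is zero, so any sample differing from the window median is
    replaced. Windows shrink at the series edges rather than padding.

    Within one pass, decisions are made against the input series. Because a
    replacement tightens the MAD of neighbouring windows, a single pass is not
    a projection; the identifier is therefore re-applied until the series no
    longer changes (a fixed point, so the filter is idempotent). Convergence
    is fast in practice; passes are capped at ``max_passes``.
    """
    if half_window < 1:
        raise ParameterError("half_window must be >= 1")
    x = np.asarray(x, dtype=float)
    for _ in range(max_passes):
        out = _hampel_pass(x, half_window, n_sigmas)
        if np.array_equal(out, x, equal_nan=True):
            return out
        x = out
    log.warning("hampel filter did not reach a fixed point in %d passes",
                max_passes)
    return x


def _hampel_pass(x: np.ndarray, half_window: int, n_sigmas: float) -> np.ndarray:
    out = x.copy()
    n = x.size
    if n == 0:
        return out
    w = 2 * half_window + 1
    if n >= w:
        win = sliding_window_view(x, w)
        med = np.median(win, axis=1)
        sig = MAD_SCALE * np.median(np.abs(win - med[:, None]), axis=1)
        centre = x[half_window:n - half_window]
        mask = np.abs(centre - med) > n_sigmas * sig
        out[half_window:n - half_window][mask] = med[mask]
    # shrunken windows at the edges
    edge = range(min(half_window, n)) if n >= w else range(n)
    tail = range(max(n - half_window, half_window), n) if n >= w else range(0)
    for i in list(edge) + list(tail):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        wnd = x[lo:hi]
        med = np.median(wnd)
        sig = MAD_SCALE * np.median(np.abs(wnd - med))
        if abs(x[i] - med) > n_sigmas * sig:
            out[i] = med
    return out


# ---------------------------------------------------------------------------
# zero-lag low-pass
# ---------------------------------------------------------------------------

def lowpass_zero_lag(x, order: int = 5, cutoff_hz: float = 1.0,
                     fs_hz: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward application).

    The filter is designed at the stated ``order`` and applied forward then
    backward, which cancels the phase response and squares the magnitude
    response. Edge transients are handled by reflect-padding of length
    ``3 * order``.
    """
    if not 0 < cutoff_hz < fs_hz / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist) = (0, {fs_hz / 2}), got {cutoff_hz}")
    x = np.asarray(x, dtype=float)
    padlen = 3 * order
    if x.size <= padlen:
        raise SignalTooShortError(
            f"series of {x.size} samples too short for order-{order} zero-lag filter")
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=fs_hz)
    return sps.filtfilt(b, a, x, padtype="even", padlen=padlen)


# ---------------------------------------------------------------------------
# derived signals
# ---------------------------------------------------------------------------

def compute_tsi(o2hb, hhb):
    """Tissue saturation index: 100 * O2Hb / (O2Hb + HHb), in percent.

    Samples with non-positive total are undefined and flagged as NaN rather
    than raising. Requires inputs on a scale with a positive total
    (device-like absolute values, or relative values plus a baseline offset).
    """
    o2hb = np.asarray(o2hb, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    total = o2hb + hhb
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, 100.0 * o2hb / total, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def compute_dhb(o2hb, hhb):
    """Differential hemoglobin [dHb] = [O2Hb] - [HHb] (net oxygenation change)."""
    out = np.asarray(o2hb, dtype=float) - np.asarray(hhb, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# recovery-start localization
# ---------------------------------------------------------------------------

def detect_recovery_start(rec: NirsRecording,
                          cadence_band_hz=(1.0, 2.0),
                          rms_window_s: float = 5.0,
                          threshold_frac: float = 0.2,
                          hold_s: float = 5.0,
                          channel: str = "o2hb",
                          prefer_marker: bool = True) -> float:
    """Locate the start of recovery as the end of the cadence oscillation.

    The channel (Hampel-filtered, *before* low-pass filtering, since the 1 Hz
    low-pass removes the cadence component) is band-passed over the cadence
    band, and a forward-looking moving RMS envelope is computed. The recovery
    start is the first time after exercise onset at which the envelope falls
    below ``threshold_frac`` of its median over the exercise phase and stays
    below for at least ``hold_s`` seconds.

    When the recording carries an explicit recovery marker the marker takes
    precedence; the detector result is computed and logged for comparison.
    """
    marker = rec.markers.t_recovery_start
    if prefer_marker and marker is not None:
        try:
            detected = _detect_recovery_start(
                rec, cadence_band_hz, rms_window_s, threshold_frac, hold_s, channel)
            log.info("recovery marker %.1f s kept; detector found %.1f s "
                     "(difference %.2f s)", marker, detected, detected - marker)
        except (DetectionError, ParameterError) as exc:
            log.info("recovery marker %.1f s kept; detector failed: %s", marker, exc)
        return float(marker)
    return _detect_recovery_start(
        rec, cadence_band_hz, rms_window_s, threshold_frac, hold_s, channel)


def _detect_recovery_start(rec, cadence_band_hz, rms_window_s, threshold_frac,
                           hold_s, channel) -> float:
    m = rec.markers
    t = rec.time
    exercise_end = m.t_recovery_start if m.t_recovery_start is not None else m.t_end
    if exercise_end - m.t_exercise_start < 60.0:
        raise ParameterError("exercise phase must last at least 60 s for "
                             "cadence-based recovery detection")
    x = np.asarray(getattr(rec, channel), dtype=float)
    lo, hi = cadence_band_hz
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=SAMPLE_RATE_HZ, output="sos")
    xb = sps.sosfiltfilt(sos, x)

    w = max(2, int(round(rms_window_s * SAMPLE_RATE_HZ)))
    sq = np.concatenate([[0.0], np.cumsum(xb * xb)])
    n_env = x.size - w + 1
    rms = np.sqrt((sq[w:] - sq[:-w]) / w)  # rms[i] over samples [i, i+w)
    t_env = t[:n_env]

    i_ex0 = rec.index_at(m.t_exercise_start)
    i_ex1 = min(rec.index_at(exercise_end), n_env)
    if i_ex1 <= i_ex0:
        raise DetectionError("no envelope samples within the exercise phase",
                             time=t_env, envelope=rms)
    med = float(np.median(rms[i_ex0:i_ex1]))
    thr = threshold_frac * med
    below = rms < thr

    hold = max(1, int(round(hold_s * SAMPLE_RATE_HZ)))
    if below.size >= hold:
        runs = sliding_window_view(below, hold).all(axis=1)
        candidates = np.flatnonzero(runs[i_ex0:]) + i_ex0
        if candidates.size:
            return float(t_env[candidates[0]])
    raise DetectionError(
        "cadence envelope never falls below threshold: no cyclic pattern end found",
        time=t_env, envelope=rms)


# ---------------------------------------------------------------------------
# full conditioning chain
# ---------------------------------------------------------------------------

def preprocess_recording(rec: NirsRecording,
                         hampel_half_window: int = 3,
                         hampel_n_sigmas: float = 3.0,
                         lowpass_order: int = 5,
                         lowpass_cutoff_hz: float = 1.0,
                         detect_recovery: bool = True,
                         cadence_band_hz=(1.0, 2.0)) -> NirsRecording:
    """Apply the full conditioning chain and derive TSI.

    Returns a new recording with cleaned, low-passed channels; the TSI channel
    is recomputed from the cleaned O2Hb/HHb channels unless the recording
    carries a device TSI (which is then cleaned the same way). Series length
    and timestamps are never changed.
    """
    o2hb = hampel_filter(rec.o2hb, hampel_half_window, hampel_n_sigmas)
    hhb = hampel_filter(rec.hhb, hampel_half_window, hampel_n_sigmas)

    meta = dict(rec.meta)
    markers = rec.markers
    interim = rec.replace(o2hb=o2hb, hhb=hhb, tsi=None, meta=meta)
    if detect_recovery:
        try:
            t_rec = detect_recovery_start(interim, cadence_band_hz=cadence_band_hz)
            meta["recovery_start_s"] = t_rec
            if markers.t_recovery_start is None:
                markers = replace(markers, t_recovery_start=t_rec)
        except (DetectionError, ParameterError) as exc:
            if markers.t_recovery_start is None:
                raise
            log.info("recovery detection skipped: %s", exc)

    o2hb = lowpass_zero_lag(o2hb, lowpass_order, lowpass_cutoff_hz)
    hhb = lowpass_zero_lag(hhb, lowpass_order, lowpass_cutoff_hz)
    if rec.tsi is not None:
        tsi = lowpass_zero_lag(hampel_filter(rec.tsi, hampel_half_window,
                                             hampel_n_sigmas),
                               lowpass_order, lowpass_cutoff_hz)
    else:
        tsi = compute_tsi(o2hb, hhb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tsi may contain NaN for undefined totals
        tsi = np.clip(tsi, 0.0, 100.0)
    meta["preprocessed"] = {
        "hampel_half_window": hampel_half_window,
        "hampel_n_sigmas": hampel_n_sigmas,
        "lowpass_order": lowpass_order,
        "lowpass_cutoff_hz": lowpass_cutoff_hz,
    }
    return NirsRecording(time=rec.time.copy(), o2hb=o2hb, hhb=hhb, tsi=tsi,
                         markers=markers, meta=meta)
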