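"""Reoxygenation kinetics of post-exercise muscle-oximetry recovery.

During recovery from maximal exercise, muscle oxygenation signals (TSI, O2Hb,
dHb) rise back towards a hyperemic maximum. After an initial time delay Td the
rise is described by the empirical mono-exponential

    Y(t) = Y_min + amp * (1 - exp(-t / Tau)),    t measured from fit onset,

whose time constant Tau, delay Td, mean response time MRT = Td + Tau and half
value time HVT (time from recovery start to half the recovery amplitude)
discriminate flow-limited from healthy legs. Onset is located by a matched
filter (sliding a mono-exponential-shaped kernel and maximizing the normalized
cross-correlation), the endpoint by the first peak not exceeded within 30 s,
and fits with R^2 <= 0.85 or values unobservable within the 300-s recovery
window are treated as censored and substituted by 300 s.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import curve_fit, least_squares

from .errors import ParameterError
from .preprocess import compute_dhb
from .recording import DT_S, SAMPLE_RATE_HZ, NirsRecording, SIGNALS

CENSOR_HORIZON_S = 300.0
R2_GATE = 0.85
TAU_BOUNDS = (0.1, 300.0)

#: Seconds of warm-up used as the zero reference for relative signals.
_ZERO_REF_S = 1.0


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalSummary:
    """Absolute values and amplitudes of one signal (baseline is TSI-only)."""

    signal: str
    baseline: Optional[float]
    minimal: float
    maximal: float
    delta_exercise: float
    delta_recovery: float


@dataclass(frozen=True)
class KineticFit:
    """Mono-exponential recovery fit for one signal of one leg.

    ``mrt = td + tau`` holds exactly for every uncensored fit; after censor
    substitution, censored values equal the horizon (300 s) exactly while the
    flags are preserved. ``r2`` is recorded even when below the quality gate.
    """

    signal: str
    y_min: float
    amp: float
    tau: float
    td: float
    mrt: float
    hvt: float
    r2: float
    fit_window: tuple
    censored_mrt: bool
    censored_hvt: bool
    converged: bool = True

    def replace(self, **kwargs) -> "KineticFit":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class OnsetDetection:
    t_on: Optional[float]
    td: Optional[float]
    correlation: Optional[float]
    censored: bool


@dataclass(frozen=True)
class EndpointDetection:
    t_peak: Optional[float]
    t_fit_end: Optional[float]
    censored: bool


@dataclass(frozen=True)
class HvtEstimate:
    hvt_s: Optional[float]
    censored: bool


# ---------------------------------------------------------------------------
# series access
# ---------------------------------------------------------------------------

def signal_series(rec: NirsRecording, signal: str) -> np.ndarray:
    """Return the named signal on its analysis scale.

    TSI is absolute (%); O2Hb and dHb are relative concentrations and are
    zero-referenced at the start of the warm-up phase (mean of the first
    second, exact on a flat noiseless baseline).
    """
    if signal not in SIGNALS:
        raise ParameterError(f"unknown signal {signal!r}; expected one of {SIGNALS}")
    if signal == "tsi":
        if rec.tsi is None:
            raise ParameterError("recording has no TSI channel; preprocess first")
        return np.asarray(rec.tsi, dtype=float)
    raw = rec.o2hb if signal == "o2hb" else compute_dhb(rec.o2hb, rec.hhb)
    n_ref = max(1, int(round(_ZERO_REF_S * SAMPLE_RATE_HZ)))
    return raw - float(np.mean(raw[:n_ref]))


def _slice(rec, t0, t1):
    i0 = max(0, rec.index_at(t0))
    i1 = min(rec.n_samples - 1, rec.index_at(t1))
    return i0, i1


# ---------------------------------------------------------------------------
# absolute values and amplitudes
# ---------------------------------------------------------------------------

def summarize_signal(rec: NirsRecording, signal: str) -> SignalSummary:
    """Baseline, minimal, maximal and amplitude summary of one signal.

    Baseline (TSI only) is the 10-s mean before exercise onset. The minimal
    value is a 5-s mean centred on the global nadir between exercise onset and
    the recording end; the maximal value a 5-s mean centred on the
    recovery-phase peak. Windows crossing a recording edge are truncated with
    a warning. ``delta_exercise`` is baseline - minimal for TSI and -minimal
    for the zero-referenced O2Hb/dHb; ``delta_recovery`` is maximal - minimal.
    """
    m = rec.markers
    if m.t_recovery_start is None:
        raise ParameterError("recovery marker required; preprocess or mark first")
    if m.t_end - m.t_recovery_start < 10.0:
        raise ParameterError("recovery phase shorter than 10 s")
    y = signal_series(rec, signal)
    t = rec.time

    baseline = None
    if signal == "tsi":
        i0, i1 = _slice(rec, m.t_exercise_start - 10.0, m.t_exercise_start)
        baseline = float(np.mean(y[i0:i1]))

    def window_mean(i_centre):
        half = int(round(2.5 * SAMPLE_RATE_HZ))
        lo, hi = i_centre - half, i_centre + half + 1
        if lo < 0 or hi > y.size:
            warnings.warn("5-s averaging window truncated at a recording edge",
                          stacklevel=3)
        return float(np.mean(y[max(0, lo):min(y.size, hi)]))

    def centred_extreme(seg, sign):
        # centre of the tied extreme samples, so a flat nadir plateau is
        # averaged from its middle rather than from its leading edge
        ties = np.flatnonzero(sign * seg == (sign * seg).max())
        return int(ties[ties.size // 2])

    i_ex, i_end = _slice(rec, m.t_exercise_start, m.t_end)
    i_nadir = i_ex + centred_extreme(y[i_ex:i_end + 1], -1.0)
    minimal = window_mean(i_nadir)

    i_rec, _ = _slice(rec, m.t_recovery_start, m.t_end)
    i_peak = i_rec + centred_extreme(y[i_rec:i_end + 1], 1.0)
    maximal = window_mean(i_peak)

    delta_ex = (baseline - minimal) if signal == "tsi" else -minimal
    return SignalSummary(signal=signal, baseline=baseline, minimal=minimal,
                         maximal=maximal, delta_exercise=delta_ex,
                         delta_recovery=maximal - minimal)


# ---------------------------------------------------------------------------
# onset / endpoint detection
# ---------------------------------------------------------------------------

def detect_fit_endpoint(rec: NirsRecording, signal: str,
                        lookahead_s: float = 30.0,
                        min_rise_frac: float = 0.25) -> EndpointDetection:
    """First recovery running maximum that no later sample exceeds within 30 s.

    The fit window ends ``lookahead_s`` after that peak (clipped to the
    recording end). The rule presumes a genuine reoxygenation peak, so
    candidates must additionally have risen at least ``min_rise_frac`` of the
    recovery segment's range above its minimum — otherwise a noise excursion
    during a long pre-reoxygenation delay (nothing rises past it for 30 s)
    would terminate the window before the kinetics even start. When no sample
    can be confirmed before the recording ends (e.g., a signal still strictly
    rising at the last sample) the endpoint is censored.
    """
    m = rec.markers
    if m.t_recovery_start is None:
        raise ParameterError("recovery marker required")
    y = signal_series(rec, signal)
    i_rec, i_end = _slice(rec, m.t_recovery_start, m.t_end)
    seg = y[i_rec:i_end + 1]
    look = int(round(lookahead_s * SAMPLE_RATE_HZ))
    if seg.size <= look:
        return EndpointDetection(None, None, censored=True)
    ahead_max = sliding_window_view(seg[1:], look).max(axis=1)
    running_max = np.maximum.accumulate(seg)[:ahead_max.size]
    floor = seg.min() + min_rise_frac * np.ptp(seg)
    head = seg[:ahead_max.size]
    ok = (head >= ahead_max) & (head >= running_max) & (head >= floor)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return EndpointDetection(None, None, censored=True)
    t_peak = float(rec.time[i_rec + idx[0]])
    t_fit_end = min(t_peak + lookahead_s, float(m.t_end))
    return EndpointDetection(t_peak, t_fit_end, censored=False)


def _monoexp_kernel(kernel_tau_s: float, kernel_len_s: float) -> np.ndarray:
    tk = np.arange(0.0, kernel_len_s, DT_S)
    k = -np.expm1(-tk / kernel_tau_s)
    k = k - k.mean()
    return k / np.linalg.norm(k)


def detect_fit_onset(rec: NirsRecording, signal: str,
                     kernel_tau_s: float = 10.0, kernel_len_s: float = 60.0,
                     t_end: Optional[float] = None, refine: bool = True,
                     min_correlation: float = 0.0) -> OnsetDetection:
    """Matched-filter localization of the mono-exponential onset.

    A zero-mean, unit-norm mono-exponential kernel ``1 - exp(-t/kernel_tau)``
    is slid along the recovery segment; the onset is the lag maximizing the
    normalized cross-correlation, and Td = t_on - t_recovery_start. Because
    the fully normalized (Pearson) statistic is scale-invariant, every lag
    past the true onset of a clean delayed exponential ties at the maximum;
    the earliest lag within numerical tolerance of the peak is therefore
    taken. A kernel-normalized projection score (sharper localization, small
    shape-dependent bias) provides a second coarse estimate, and with
    ``refine`` (default) the onset is polished by a least-squares fit of a
    delayed mono-exponential with the delay free within the span of the two
    coarse estimates +/- 5 s, giving sub-sample delay resolution.

    The onset is censored when the segment is shorter than the kernel or when
    no lag correlates positively (no rising mono-exponential shape present,
    e.g. a monotonically decreasing recovery).
    """
    m = rec.markers
    if m.t_recovery_start is None:
        raise ParameterError("recovery marker required")
    t_stop = float(m.t_end if t_end is None else min(t_end, m.t_end))
    y = signal_series(rec, signal)
    i0, i1 = _slice(rec, m.t_recovery_start, t_stop)
    seg = y[i0:i1 + 1]

    k = _monoexp_kernel(kernel_tau_s, kernel_len_s)
    if seg.size < k.size + 1:
        return OnsetDetection(None, None, None, censored=True)
    win = sliding_window_view(seg, k.size)
    wc = win - win.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(wc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(norms > 0, wc @ k / norms, -np.inf)
    r_max = float(np.max(r))
    # The Pearson statistic is scale-invariant, so on a clean delayed
    # exponential every lag past the onset ties at the maximum: take the
    # earliest lag within numerical tolerance of the peak (the onset itself).
    best = int(np.flatnonzero(r >= r_max - 1e-9)[0])
    r_best = float(r[best])
    if not np.isfinite(r_best) or r_best <= min_correlation:
        return OnsetDetection(None, None, None, censored=True)

    td = best * DT_S
    if refine:
        td_proj = int(np.argmax(wc @ k)) * DT_S
        td = _refine_delay(rec.time[i0:i1 + 1] - rec.time[i0], seg, td, td_proj)
    t_on = float(m.t_recovery_start + td)
    return OnsetDetection(t_on=t_on, td=float(td), correlation=r_best,
                          censored=False)


def _refine_delay(t: np.ndarray, seg: np.ndarray, td0: float,
                  td_alt: float) -> float:
    """Least-squares polish of the delay via a delayed mono-exponential.

    Fits ``y_min + amp*(1 - exp(-(t - td)/tau)) * [t >= td]`` over the whole
    recovery segment with the delay free within the span of the two coarse
    matched-filter estimates +/- 5 s; falls back to the primary coarse
    estimate on failure.
    """
    lo = max(0.0, min(td0, td_alt) - 5.0)
    hi = min(float(t[-1]) - 1.0, max(td0, td_alt) + 5.0)
    if hi <= lo:
        return td0
    y_min0 = float(seg.min())
    amp0 = max(float(np.ptp(seg)), 1e-6)
    half = y_min0 + amp0 / 2
    above = np.flatnonzero(seg >= half)
    tau0 = max((t[above[0]] - td0) / np.log(2.0), 0.5) if above.size else 10.0

    def residuals(p):
        y_min, amp, tau, td = p
        model = y_min + amp * -np.expm1(-np.maximum(t - td, 0.0) / tau)
        return model - seg

    try:
        sol = least_squares(
            residuals, x0=[y_min0, amp0, min(max(tau0, 0.5), 250.0),
                           min(max(td0, lo), hi)],
            bounds=([-np.inf, 0.0, TAU_BOUNDS[0], lo],
                    [np.inf, np.inf, TAU_BOUNDS[1], hi]),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if sol.success:
            return float(sol.x[3])
    except Exception:
        pass
    return td0


# ---------------------------------------------------------------------------
# mono-exponential fit
# ---------------------------------------------------------------------------

def _monoexp(t, y_min, amp, tau):
    return y_min + amp * -np.expm1(-t / tau)


def fit_monoexponential(rec: NirsRecording, signal: str, t_on: float,
                        t_end: float, r2_gate: float = R2_GATE) -> KineticFit:
    """Least-squares mono-exponential fit over [t_on, t_end].

    Time is re-zeroed at ``t_on``. Starting values: window minimum, window
    range, and (time to half-range)/ln 2; bounds: amp > 0, tau in (0.1, 300].
    ``td`` is ``t_on`` minus the recovery start. Non-convergence or
    R^2 <= ``r2_gate`` marks the MRT censored (never raises), since excluding
    such legs would bias the downstream diagnostic model.
    """
    m = rec.markers
    if m.t_recovery_start is None:
        raise ParameterError("recovery marker required")
    td = float(t_on - m.t_recovery_start)
    y = signal_series(rec, signal)
    i0, i1 = _slice(rec, t_on, t_end)
    seg = y[i0:i1 + 1]
    t = rec.time[i0:i1 + 1] - rec.time[i0]
    window = (float(rec.time[i0]), float(rec.time[i1]))

    if t.size < 20 or t[-1] < 10.0:
        return KineticFit(signal=signal, y_min=np.nan, amp=np.nan, tau=np.nan,
                          td=td, mrt=np.nan, hvt=np.nan, r2=0.0,
                          fit_window=window, censored_mrt=True,
                          censored_hvt=False, converged=False)

    y_min0 = float(seg.min())
    amp0 = max(float(np.ptp(seg)), 1e-9)
    above = np.flatnonzero(seg >= y_min0 + amp0 / 2)
    tau0 = float(np.clip(t[above[0]] / np.log(2.0) if above.size else 10.0,
                         0.5, 250.0))
    try:
        popt, _ = curve_fit(
            _monoexp, t, seg, p0=[y_min0, amp0, tau0],
            bounds=([-np.inf, 1e-12, TAU_BOUNDS[0]],
                    [np.inf, np.inf, TAU_BOUNDS[1]]),
            maxfev=20000)
        converged = True
        y_min, amp, tau = (float(v) for v in popt)
    except RuntimeError:
        converged = False
        y_min = amp = tau = np.nan

    if converged:
        resid = seg - _monoexp(t, y_min, amp, tau)
        sst = float(np.sum((seg - seg.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 0.0
    else:
        r2 = 0.0
    censored = (not converged) or (r2 <= r2_gate)
    mrt = td + tau if converged else np.nan
    return KineticFit(signal=signal, y_min=y_min, amp=amp, tau=tau, td=td,
                      mrt=mrt, hvt=np.nan, r2=float(r2), fit_window=window,
                      censored_mrt=censored, censored_hvt=False,
                      converged=converged)


# ---------------------------------------------------------------------------
# half value time and censoring
# ---------------------------------------------------------------------------

def compute_hvt(rec: NirsRecording, signal: str,
                summary: SignalSummary) -> HvtEstimate:
    """Time from recovery start to half the recovery amplitude.

    The (filtered) signal is searched for its first crossing of
    ``minimal + delta_recovery / 2`` after the recovery start, with linear
    interpolation between the bracketing samples. A level unreached within the
    recording — or an ill-defined amplitude — is censored.
    """
    m = rec.markers
    if m.t_recovery_start is None:
        raise ParameterError("recovery marker required")
    if not summary.delta_recovery > 0:
        return HvtEstimate(None, censored=True)
    target = summary.minimal + summary.delta_recovery / 2.0
    y = signal_series(rec, signal)
    i0, i1 = _slice(rec, m.t_recovery_start, m.t_end)
    seg = y[i0:i1 + 1]
    idx = np.flatnonzero(seg >= target)
    if idx.size == 0:
        return HvtEstimate(None, censored=True)
    i = int(idx[0])
    if i == 0:
        return HvtEstimate(0.0, censored=False)
    frac = (target - seg[i - 1]) / (seg[i] - seg[i - 1])
    return HvtEstimate(float((i - 1 + frac) * DT_S), censored=False)


def apply_censor_substitution(fit: KineticFit,
                              horizon_s: float = CENSOR_HORIZON_S) -> KineticFit:
    """Substitute censored kinetic values by the observation horizon.

    Every censored value is set to ``horizon_s`` exactly (flags preserved,
    uncensored values untouched); the substitution is idempotent.
    """
    changes = {}
    if fit.censored_mrt:
        changes.update(mrt=float(horizon_s))
    if fit.censored_hvt:
        changes.update(hvt=float(horizon_s))
    return fit.replace(**changes) if changes else fit


# ---------------------------------------------------------------------------
# per-leg feature extraction
# ---------------------------------------------------------------------------

def extract_leg_features(rec: NirsRecording, signals=SIGNALS,
                         kernel_tau_s: float = 10.0, kernel_len_s: float = 60.0,
                         r2_gate: float = R2_GATE,
                         horizon_s: float = CENSOR_HORIZON_S,
                         refine: bool = True) -> dict:
    """Summaries plus censor-substituted kinetics for each signal of one leg.

    Orchestrates endpoint detection (falling back to the recording end when
    the 30-s rule cannot confirm a peak), matched-filter onset detection,
    mono-exponential fitting, half value time, and censor substitution.
    Returns a flat feature row suitable for the cohort feature table.
    """
    row = {"subject_id": rec.meta.get("subject_id"),
           "leg_side": rec.meta.get("leg_side")}
    for sig in signals:
        summary = summarize_signal(rec, sig)
        endpoint = detect_fit_endpoint(rec, sig)
        t_fit_end = endpoint.t_fit_end if not endpoint.censored else rec.markers.t_end
        onset = detect_fit_onset(rec, sig, kernel_tau_s=kernel_tau_s,
                                 kernel_len_s=kernel_len_s, t_end=t_fit_end,
                                 refine=refine)
        if onset.censored:
            fit = KineticFit(signal=sig, y_min=np.nan, amp=np.nan, tau=np.nan,
                             td=np.nan, mrt=np.nan, hvt=np.nan, r2=0.0,
                             fit_window=(np.nan, np.nan), censored_mrt=True,
                             censored_hvt=False, converged=False)
        else:
            fit = fit_monoexponential(rec, sig, onset.t_on, t_fit_end,
                                      r2_gate=r2_gate)
        hvt = compute_hvt(rec, sig, summary)
        fit = fit.replace(hvt=np.nan if hvt.censored else hvt.hvt_s,
                          censored_hvt=hvt.censored)
        fit = apply_censor_substitution(fit, horizon_s)

        if summary.baseline is not None:
            row[f"{sig}_baseline"] = summary.baseline
        row[f"{sig}_minimal"] = summary.minimal
        row[f"{sig}_maximal"] = summary.maximal
        row[f"{sig}_delta_exercise"] = summary.delta_exercise
        row[f"{sig}_delta_recovery"] = summary.delta_recovery
        row[f"{sig}_td_s"] = fit.td
        row[f"{sig}_tau_s"] = fit.tau
        row[f"{sig}_mrt_s"] = fit.mrt
        row[f"{sig}_hvt_s"] = fit.hvt
        row[f"{sig}_r2"] = fit.r2
        row[f"{sig}_mrt_censored"] = fit.censored_mrt
        row[f"{sig}_hvt_censored"] = fit.censored_hvt
        row[f"{sig}_endpoint_censored"] = endpoint.censored
    return row
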