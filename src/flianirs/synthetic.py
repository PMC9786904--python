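"""Synthetic exercise-NIRS recordings and cohorts.

Real recordings of athletes with iliac-artery flow limitation are not
publicly deposited, so this module emulates the statistical structure the
downstream analysis assumes:

* per-recording morphology — flat warm-up baseline, monotone exercise
  deoxygenation with a cadence-frequency oscillation, then delayed
  mono-exponential reoxygenation in recovery, plus Gaussian noise and
  Poisson-placed single-sample movement spikes;
* per-cohort structure — group-specific kinetic parameter distributions
  (healthy vs. affected vs. non-affected legs), ankle-brachial indices,
  clinical covariates, the unilateral/bilateral patient mix, and censoring
  (kinetics unobservable within the 300-s recovery window).

The generator is purely phenomenological: it reproduces signal shape and
group statistics, not cardiovascular physiology.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .diagnostics import LegRecord
from .errors import ParameterError
from .preprocess import compute_tsi
from .recording import DT_S, SAMPLE_RATE_HZ, NirsRecording, PhaseMarkers, SIGNALS

#: Normal quantile of 0.75; converts an IQR into log-normal / normal scale.
_Z75 = 0.6744897501960817

#: Constant total heme-pigment concentration (a.u.) used to build channel
#: pairs whose derived TSI and dHb are mutually consistent.
TOTAL_HB_AU = 100.0


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianIqr:
    """A skewed summary ``median (q1-q3)`` as printed in clinical tables."""

    median: float
    q1: float
    q3: float

    def __post_init__(self):
        if not (self.q1 < self.median < self.q3):
            raise ParameterError(f"require q1 < median < q3, got {self}")

    def lognormal(self, rng: np.random.Generator, size=None):
        """Draw log-normally with matching median and IQR ratio."""
        sigma = np.log(self.q3 / self.q1) / (2 * _Z75)
        return np.exp(rng.normal(np.log(self.median), sigma, size=size))

    def normal(self, rng: np.random.Generator, size=None):
        """Draw normally with the median as mean and IQR-implied SD."""
        sd = (self.q3 - self.q1) / (2 * _Z75)
        return rng.normal(self.median, sd, size=size)


@dataclass(frozen=True)
class KineticDistribution:
    """Per-signal recovery-kinetics distribution for one leg group.

    The mean response time MRT = Td + Tau is drawn log-normally (clinical
    tables report skewed median/IQR values); the delay fraction Td/MRT is
    drawn from a Beta law centred on the observed median ratio. Tau and the
    half value time HVT = Td + Tau ln 2 follow by construction, so
    MRT = Td + Tau holds exactly for every draw.
    """

    mrt: MedianIqr
    td_fraction: float
    td_concentration: float = 12.0

    def draw(self, rng: np.random.Generator) -> dict:
        mrt = float(self.mrt.lognormal(rng))
        a = self.td_fraction * self.td_concentration
        b = (1 - self.td_fraction) * self.td_concentration
        frac = float(rng.beta(a, b))
        td = frac * mrt
        tau = mrt - td
        return {"td": td, "tau": tau, "mrt": mrt,
                "hvt": td + tau * np.log(2.0)}


# Group kinetic distributions: medians/IQRs of MRT per NIRS signal, and the
# median Td/MRT ratio, for healthy legs, affected patient legs, and the
# non-affected legs of unilateral patients.
DEFAULT_KINETICS = {
    "healthy": {
        "tsi": KineticDistribution(MedianIqr(22.9, 17.5, 31.4), 9.8 / 22.9),
        "o2hb": KineticDistribution(MedianIqr(29.1, 22.2, 38.7), 8.6 / 29.1),
        "dhb": KineticDistribution(MedianIqr(28.7, 22.4, 40.3), 11.1 / 28.7),
    },
    "affected": {
        "tsi": KineticDistribution(MedianIqr(57.5, 38.6, 86.5), 23.1 / 57.5),
        "o2hb": KineticDistribution(MedianIqr(62.0, 45.8, 93.7), 21.6 / 62.0),
        "dhb": KineticDistribution(MedianIqr(65.2, 47.7, 98.9), 23.0 / 65.2),
    },
    "nonaffected": {
        "tsi": KineticDistribution(MedianIqr(37.4, 29.2, 60.4), 17.8 / 37.4),
        "o2hb": KineticDistribution(MedianIqr(45.9, 36.3, 65.0), 17.0 / 45.9),
        "dhb": KineticDistribution(MedianIqr(47.2, 38.3, 68.2), 18.8 / 47.2),
    },
}

DEFAULT_ABI = {
    "healthy": MedianIqr(0.74, 0.62, 0.79),
    "affected": MedianIqr(0.58, 0.47, 0.68),
    "nonaffected": MedianIqr(0.67, 0.59, 0.74),
}

DEFAULT_COVARIATES = {
    "healthy": {
        "age": MedianIqr(26, 21, 38), "male_prop": 30 / 33,
        "bmi": MedianIqr(21.9, 20.6, 23.1), "wpeak_mean": 5.9, "wpeak_sd": 0.9,
        "att_mean": 5.0, "att_sd": 1.2,
    },
    "patient": {
        "age": MedianIqr(40, 28, 51), "male_prop": 177 / 201,
        "bmi": MedianIqr(22.3, 20.9, 24.2), "wpeak_mean": 5.1, "wpeak_sd": 1.1,
        "att_mean": 5.0, "att_sd": 1.2,
    },
}

DEFAULT_AMPLITUDES = {
    "healthy": {"baseline_tsi": MedianIqr(60.6, 58.1, 64.0),
                "delta_exercise": MedianIqr(18.1, 14.1, 23.4),
                "delta_recovery": MedianIqr(25.6, 21.1, 29.8)},
    "patient": {"baseline_tsi": MedianIqr(58.5, 54.5, 62.7),
                "delta_exercise": MedianIqr(17.5, 13.5, 23.3),
                "delta_recovery": MedianIqr(25.4, 20.9, 33.9)},
}


# ---------------------------------------------------------------------------
# single-recording generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingParams:
    """Parameters of one synthetic exercise-test recording.

    Units: TSI quantities in %, times in s, cadence in rev/min. The cadence
    oscillation amplitude, noise SD and spike scale share the signal's units.
    ``delta_recovery`` defaults to 1.35 x ``delta_exercise`` (recovery
    overshoot above baseline, as seen in post-exercise hyperemia); set it to 0
    for a non-reoxygenating (censored) leg.
    """

    baseline_tsi: float = 60.0
    delta_exercise: float = 20.0
    delta_recovery: Optional[float] = None
    tau: float = 20.0
    td: float = 15.0
    cadence_rpm: float = 90.0
    oscillation_amplitude: float = 2.0
    noise_sd: float = 0.35
    spike_rate_per_min: float = 2.0
    warmup_s: float = 240.0
    exercise_s: float = 600.0
    recovery_s: float = 300.0
    sample_rate_hz: float = SAMPLE_RATE_HZ

    def __post_init__(self):
        if self.delta_recovery is None:
            object.__setattr__(self, "delta_recovery", 1.35 * self.delta_exercise)
        for name in ("warmup_s", "exercise_s", "recovery_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 80.0 <= self.cadence_rpm <= 100.0:
            raise ParameterError("cadence must lie in [80, 100] rev/min")
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise ParameterError("sample rate is fixed at 10 Hz")
        if self.tau <= 0 or self.td < 0:
            raise ParameterError("require tau > 0 and td >= 0")
        if min(self.delta_exercise, self.delta_recovery) < 0:
            raise ParameterError("amplitudes must be non-negative")
        if min(self.oscillation_amplitude, self.noise_sd,
               self.spike_rate_per_min) < 0:
            raise ParameterError("oscillation, noise and spike rate must be >= 0")
        if not 0 < self.baseline_tsi - self.delta_exercise:
            raise ParameterError("exercise nadir must stay above 0 % TSI")
        if self.baseline_tsi - self.delta_exercise + self.delta_recovery >= 100:
            raise ParameterError("recovery peak must stay below 100 % TSI")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate_recording(params: RecordingParams, seed: int) -> NirsRecording:
    """Generate one synthetic recording; identical seeds give identical series.

    The clean TSI trajectory is: flat baseline during warm-up; a smooth
    monotone decline to the exercise nadir (reached at 85% of the exercise
    phase, leaving a plateau) with a sinusoidal cadence oscillation whose
    amplitude tapers over the final 2 s of exercise; then, in recovery, the
    nadir held for ``td`` seconds followed by the mono-exponential
    reoxygenation ``y_min + delta_recovery * (1 - exp(-(t - td)/tau))``.

    O2Hb/HHb channels are built around a constant total of 100 a.u., so the
    derived TSI equals the designed trajectory and dHb = 2*TSI - 100. Channel
    noise is Gaussian; movement spikes are single-sample, Poisson-placed, with
    amplitude uniform in +/-[5, 20] noise SDs. Ground-truth parameters, phase
    boundaries and spike positions are stored in ``meta['truth']``.
    """
    p = params
    rng = np.random.default_rng(seed)
    total_s = p.warmup_s + p.exercise_s + p.recovery_s
    t = np.arange(0.0, total_s, DT_S)
    t_ex = p.warmup_s
    t_rec = p.warmup_s + p.exercise_s

    tsi = np.full(t.size, p.baseline_tsi)
    ex = (t >= t_ex) & (t < t_rec)
    u = (t[ex] - t_ex) / (0.85 * p.exercise_s)
    tsi[ex] = p.baseline_tsi - p.delta_exercise * _smoothstep(u)

    tsi_min = p.baseline_tsi - p.delta_exercise
    rec_mask = t >= t_rec
    tr = t[rec_mask] - t_rec
    reox = np.where(tr < p.td, 0.0,
                    p.delta_recovery * -np.expm1(-(tr - p.td) / p.tau))
    tsi[rec_mask] = tsi_min + reox

    # cadence oscillation, tapering over the last 2 s of exercise
    f = p.cadence_rpm / 60.0
    taper = np.minimum(1.0, (t_rec - t[ex]) / 2.0)
    tsi[ex] += p.oscillation_amplitude * taper * np.sin(2 * np.pi * f * (t[ex] - t_ex))

    o2hb = TOTAL_HB_AU * tsi / 100.0
    hhb = TOTAL_HB_AU - o2hb

    if p.noise_sd > 0:
        o2hb = o2hb + rng.normal(0.0, p.noise_sd, t.size)
        hhb = hhb + rng.normal(0.0, p.noise_sd, t.size)

    n_spikes = int(rng.poisson(p.spike_rate_per_min * total_s / 60.0))
    spike_idx = np.sort(rng.integers(0, t.size, size=n_spikes))
    if n_spikes:
        amp = rng.uniform(5.0, 20.0, n_spikes) * p.noise_sd
        sign = rng.choice([-1.0, 1.0], n_spikes)
        np.add.at(o2hb, spike_idx, sign * amp)

    tsi_out = compute_tsi(o2hb, hhb)
    markers = PhaseMarkers(0.0, t_ex, t_rec, float(t[-1]))
    truth = {
        "params": dataclasses.asdict(p),
        "td": p.td, "tau": p.tau,
        "baseline_tsi": p.baseline_tsi, "tsi_min": tsi_min,
        "t_exercise_start": t_ex, "t_recovery_start": t_rec,
        "spike_indices": spike_idx.tolist(),
        # per-signal truths on the zero-referenced scales used downstream
        "signals": {
            "tsi": {"y_min": tsi_min, "amp": p.delta_recovery},
            "o2hb": {"y_min": -p.delta_exercise, "amp": p.delta_recovery},
            "dhb": {"y_min": -2 * p.delta_exercise, "amp": 2 * p.delta_recovery},
        },
    }
    return NirsRecording(time=t, o2hb=o2hb, hhb=hhb, tsi=tsi_out,
                         markers=markers, meta={"truth": truth})


def write_recording(rec: NirsRecording, path) -> None:
    """Write a recording as delimited text (time_s, O2Hb, HHb, TSI, phase)."""
    frame = pd.DataFrame({
        "time_s": rec.time,
        "O2Hb": rec.o2hb,
        "HHb": rec.hhb,
        "TSI": rec.tsi if rec.tsi is not None else compute_tsi(rec.o2hb, rec.hhb),
        "phase": rec.phase_labels(),
    })
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic diagnostic cohort.

    Defaults reproduce the study conditions of the clinical cohort the
    analysis targets: 33 healthy athletes and 201 patients (95 unilateral,
    15 bilateral-symmetric, 91 bilateral-asymmetric), group kinetic and
    ankle-brachial-index distributions from the reported medians/IQRs, and a
    small per-leg probability that recovery kinetics are unobservable within
    the 300-s window (censored, substituted by 300 s downstream).
    """

    n_healthy: int = 33
    n_patients: int = 201
    n_unilateral: Optional[int] = None
    n_bilateral_symmetric: Optional[int] = None
    n_bilateral_asymmetric: Optional[int] = None
    kinetics: dict = field(default_factory=lambda: DEFAULT_KINETICS)
    abi: dict = field(default_factory=lambda: DEFAULT_ABI)
    covariates: dict = field(default_factory=lambda: DEFAULT_COVARIATES)
    amplitudes: dict = field(default_factory=lambda: DEFAULT_AMPLITUDES)
    censor_probability: dict = field(
        default_factory=lambda: {"healthy": 0.0, "affected": 0.07,
                                 "nonaffected": 0.0})
    censor_horizon_s: float = 300.0
    include_recordings: bool = False
    recording_noise_sd: float = 0.35
    recording_spike_rate_per_min: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_healthy <= 0 or self.n_patients <= 0:
            raise ParameterError("cohort counts must be positive")
        if any(not 0 <= p <= 1 for p in self.censor_probability.values()):
            raise ParameterError("censor probabilities must lie in [0, 1]")
        mix = (self.n_unilateral, self.n_bilateral_symmetric,
               self.n_bilateral_asymmetric)
        if all(v is None for v in mix):
            mix = _scale_mix(self.n_patients)
            object.__setattr__(self, "n_unilateral", mix[0])
            object.__setattr__(self, "n_bilateral_symmetric", mix[1])
            object.__setattr__(self, "n_bilateral_asymmetric", mix[2])
        elif any(v is None for v in mix):
            raise ParameterError("specify all three patient-mix counts or none")
        if any(v < 0 for v in (self.n_unilateral, self.n_bilateral_symmetric,
                               self.n_bilateral_asymmetric)):
            raise ParameterError("patient-mix counts must be non-negative")
        if (self.n_unilateral + self.n_bilateral_symmetric
                + self.n_bilateral_asymmetric) != self.n_patients:
            raise ParameterError(
                "impossible patient mix: unilateral + bilateral counts "
                f"({self.n_unilateral}+{self.n_bilateral_symmetric}+"
                f"{self.n_bilateral_asymmetric}) must equal n_patients "
                f"({self.n_patients})")
        # patient kinetic medians must exceed healthy medians (generator default)
        for sig in SIGNALS:
            if (self.kinetics["affected"][sig].mrt.median
                    <= self.kinetics["healthy"][sig].mrt.median):
                raise ParameterError(
                    f"affected {sig} MRT median must exceed the healthy median")


def _scale_mix(n_patients: int) -> tuple:
    """Proportional 95/15/91 patient mix by largest remainder."""
    base = np.array([95, 15, 91], dtype=float)
    raw = base / base.sum() * n_patients
    out = np.floor(raw).astype(int)
    rem = raw - out
    for i in np.argsort(-rem)[: n_patients - out.sum()]:
        out[i] += 1
    return tuple(int(v) for v in out)


def _draw_kinetics(cfg: CohortConfig, rng, group: str, censored: bool):
    """Per-signal kinetic features for one leg, with censor flags.

    Censoring is the explicit per-leg event (no observable reoxygenation
    within the recording window): censored legs carry the horizon value and
    both flags. Uncensored legs draw from the kinetic distribution truncated
    at the horizon, so a zero censor probability yields a cohort with no
    flags at all.
    """
    horizon = cfg.censor_horizon_s
    kin, flags = {}, {}
    for sig in SIGNALS:
        draw = cfg.kinetics[group][sig].draw(rng)
        if not censored:
            for _ in range(100):
                if draw["mrt"] <= horizon:
                    break
                draw = cfg.kinetics[group][sig].draw(rng)
            else:
                draw = {k: min(v, horizon) for k, v in draw.items()}
        kin[sig] = {
            "td": draw["td"], "tau": draw["tau"],
            "mrt": horizon if censored else draw["mrt"],
            "hvt": horizon if censored else draw["hvt"],
        }
        flags[sig] = {"mrt": censored, "hvt": censored}
    return kin, flags


def _draw_covariates(cfg: CohortConfig, rng, group_key: str) -> dict:
    cov = cfg.covariates[group_key]
    return {
        "age": float(np.clip(cov["age"].lognormal(rng), 18, 75)),
        "sex": int(rng.random() < cov["male_prop"]),
        "bmi": float(cov["bmi"].lognormal(rng)),
        "wpeak_per_kg": float(np.clip(
            rng.normal(cov["wpeak_mean"], cov["wpeak_sd"]), 2.0, 9.0)),
        "att": float(np.clip(rng.normal(cov["att_mean"], cov["att_sd"]),
                             1.5, 7.4)),
    }


def _leg_recording_params(cfg: CohortConfig, rng, group_key: str, leg_kin: dict,
                          censored: bool) -> RecordingParams:
    amp = cfg.amplitudes[group_key]
    baseline = float(np.clip(amp["baseline_tsi"].normal(rng), 45, 75))
    d_ex = float(np.clip(amp["delta_exercise"].lognormal(rng), 5, baseline - 5))
    d_rec = 0.0 if censored else float(
        np.clip(amp["delta_recovery"].lognormal(rng), 5,
                (100 - (baseline - d_ex)) - 5))
    return RecordingParams(
        baseline_tsi=baseline, delta_exercise=d_ex, delta_recovery=d_rec,
        tau=max(leg_kin["tsi"]["tau"], 1.0), td=leg_kin["tsi"]["td"],
        cadence_rpm=float(rng.uniform(80, 100)),
        noise_sd=cfg.recording_noise_sd,
        spike_rate_per_min=cfg.recording_spike_rate_per_min,
        exercise_s=float(rng.uniform(480, 720)),
        recovery_s=cfg.censor_horizon_s,
    )


def generate_cohort(config: CohortConfig):
    """Generate the per-leg cohort and (optionally) one recording per leg.

    Returns ``(legs, recordings)``: two healthy legs per healthy subject, an
    affected plus a non-affected leg per unilateral patient, and two affected
    legs per bilateral patient (equal severities for the symmetric group,
    distinct severities for the asymmetric group). ``recordings`` is empty
    unless ``config.include_recordings`` is set; when present it aligns with
    ``legs`` and follows each leg's TSI kinetics.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    legs: list[LegRecord] = []
    recordings: list[NirsRecording] = []

    def add_leg(subject_id, side, label, group, pattern, severity, cov, abi_med):
        censored = bool(rng.random() < cfg.censor_probability[group])
        kin, flags = _draw_kinetics(cfg, rng, group, censored)
        abi = float(np.clip(abi_med.normal(rng), 0.2, 1.3))
        leg = LegRecord(
            subject_id=subject_id, leg_side=side, label=label,
            affected=group == "affected", severity=severity, group=group,
            pattern=pattern, abi_flexed=abi, kinetics=kin, censored=flags,
            **cov)
        legs.append(leg)
        if cfg.include_recordings:
            gkey = "healthy" if label == 0 else "patient"
            params = _leg_recording_params(cfg, rng, gkey, kin, censored)
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec = generate_recording(params, rec_seed)
            rec.meta["subject_id"] = subject_id
            rec.meta["leg_side"] = side
            recordings.append(rec)

    sid = 0
    for _ in range(cfg.n_healthy):
        sid += 1
        subject = f"H{sid:04d}"
        cov = _draw_covariates(cfg, rng, "healthy")
        for side in ("left", "right"):
            add_leg(subject, side, 0, "healthy", "healthy", None, cov,
                    cfg.abi["healthy"])

    patterns = (["unilateral"] * cfg.n_unilateral
                + ["bilateral_symmetric"] * cfg.n_bilateral_symmetric
                + ["bilateral_asymmetric"] * cfg.n_bilateral_asymmetric)
    for pattern in patterns:
        sid += 1
        subject = f"P{sid:04d}"
        cov = _draw_covariates(cfg, rng, "patient")
        if pattern == "unilateral":
            affected_side = "left" if rng.random() < 0.5 else "right"
            for side in ("left", "right"):
                grp = "affected" if side == affected_side else "nonaffected"
                sev = 2 if side == affected_side else 0
                add_leg(subject, side, 1, grp, pattern, sev, cov, cfg.abi[grp])
        else:
            if pattern == "bilateral_symmetric":
                sev_left = sev_right = 2
            else:
                sev_left, sev_right = (2, 1) if rng.random() < 0.5 else (1, 2)
            for side, sev in (("left", sev_left), ("right", sev_right)):
                add_leg(subject, side, 1, "affected", pattern, sev, cov,
                        cfg.abi["affected"])
    return legs, recordings


# ---------------------------------------------------------------------------
# cohort table IO
# ---------------------------------------------------------------------------

def cohort_to_frame(legs) -> pd.DataFrame:
    """Flatten leg records into one row per leg."""
    rows = []
    for leg in legs:
        row = {
            "subject_id": leg.subject_id, "leg_side": leg.leg_side,
            "label": leg.label, "group": leg.group, "pattern": leg.pattern,
            "affected": leg.affected, "severity": leg.severity,
            "age": leg.age, "sex": leg.sex, "bmi": leg.bmi,
            "wpeak_per_kg": leg.wpeak_per_kg, "att": leg.att,
            "abi_flexed": leg.abi_flexed,
        }
        for sig in SIGNALS:
            for var in ("td", "tau", "mrt", "hvt"):
                row[f"{sig}_{var}_s"] = leg.kinetics[sig][var]
            for var in ("mrt", "hvt"):
                row[f"{sig}_{var}_censored"] = leg.censored[sig][var]
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(legs, path, sidecar_path=None, config: CohortConfig = None) -> None:
    """Write the cohort table as delimited text, plus a JSON truth sidecar."""
    cohort_to_frame(legs).to_csv(path, index=False)
    if sidecar_path is not None:
        truth = {"n_legs": len(legs)}
        if config is not None:
            truth["config"] = _config_summary(config)
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2)


def _config_summary(cfg: CohortConfig) -> dict:
    return {
        "n_healthy": cfg.n_healthy, "n_patients": cfg.n_patients,
        "n_unilateral": cfg.n_unilateral,
        "n_bilateral_symmetric": cfg.n_bilateral_symmetric,
        "n_bilateral_asymmetric": cfg.n_bilateral_asymmetric,
        "censor_probability": cfg.censor_probability,
        "censor_horizon_s": cfg.censor_horizon_s,
        "seed": cfg.seed,
        "kinetic_mrt_medians": {
            grp: {sig: cfg.kinetics[grp][sig].mrt.median for sig in SIGNALS}
            for grp in cfg.kinetics
        },
    }


def frame_to_legs(frame: pd.DataFrame) -> list:
    """Rebuild leg records from a cohort table (inverse of cohort_to_frame)."""
    legs = []
    for _, row in frame.iterrows():
        kin = {sig: {var: float(row[f"{sig}_{var}_s"])
                     for var in ("td", "tau", "mrt", "hvt")} for sig in SIGNALS}
        flags = {sig: {var: bool(row[f"{sig}_{var}_censored"])
                       for var in ("mrt", "hvt")} for sig in SIGNALS}
        sev = row["severity"]
        legs.append(LegRecord(
            subject_id=str(row["subject_id"]), leg_side=str(row["leg_side"]),
            label=int(row["label"]), group=str(row["group"]),
            pattern=str(row["pattern"]), affected=bool(row["affected"]),
            severity=None if pd.isna(sev) else int(sev),
            age=float(row["age"]), sex=int(row["sex"]), bmi=float(row["bmi"]),
            wpeak_per_kg=float(row["wpeak_per_kg"]), att=float(row["att"]),
            abi_flexed=float(row["abi_flexed"]), kinetics=kin, censored=flags))
    return legs
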