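"""End-to-end orchestration: simulate -> preprocess -> kinetics -> diagnose.

A run is driven by a JSON-validated :class:`RunConfig`. The master seed
deterministically derives per-stage substreams, every stage logs its
parameters, and a manifest with SHA-256 checksums of all outputs makes reruns
verifiable bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import diagnostics, kinetics, preprocess, synthetic
from .errors import ConfigError
from .recording import SAMPLE_RATE_HZ, SIGNALS

log = logging.getLogger(__name__)

KINETIC_VARS = ("mrt", "hvt")


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hampel_half_window: int = Field(3, ge=1)
    hampel_n_sigmas: float = Field(3.0, gt=0)
    lowpass_order: int = Field(5, ge=1, le=10)
    lowpass_cutoff_hz: float = Field(1.0, gt=0)
    cadence_band_hz: tuple[float, float] = (1.0, 2.0)

    @model_validator(mode="after")
    def _check_nyquist(self):
        ny = SAMPLE_RATE_HZ / 2
        if self.lowpass_cutoff_hz >= ny:
            raise ValueError(f"lowpass_cutoff_hz must be below Nyquist ({ny} Hz)")
        lo, hi = self.cadence_band_hz
        if not 0 < lo < hi < ny:
            raise ValueError("cadence_band_hz must satisfy 0 < lo < hi < Nyquist")
        return self


class KineticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kernel_tau_s: float = Field(10.0, gt=0)
    kernel_len_s: float = Field(60.0, gt=0)
    r2_gate: float = Field(0.85, ge=0, le=1)
    censor_horizon_s: float = Field(300.0, gt=0)
    refine_onset: bool = True


class SimulateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_healthy: int = Field(33, gt=0)
    n_patients: int = Field(201, gt=0)
    n_unilateral: Optional[int] = None
    n_bilateral_symmetric: Optional[int] = None
    n_bilateral_asymmetric: Optional[int] = None
    censor_probability_affected: float = Field(0.07, ge=0, le=1)
    include_recordings: bool = True


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    signal: Literal["tsi", "o2hb", "dhb"] = "dhb"
    kinetic_var: Literal["mrt", "hvt"] = "mrt"
    confounders: list[str] = list(diagnostics.DEFAULT_CONFOUNDERS)
    p_threshold: float = Field(0.10, gt=0, lt=1)
    k_folds: int = Field(10, ge=2)
    select_within_folds: bool = True

    @model_validator(mode="after")
    def _exclusive_kinetic_variable(self):
        # MRT and HVT are nearly collinear (rho ~ 0.98): one per model, ever.
        banned = [c for c in self.confounders
                  if any(c.endswith(f"_{v}_s") or c == v for v in KINETIC_VARS)]
        if banned:
            raise ValueError(
                f"confounders may not contain kinetic variables {banned}; "
                "MRT and HVT enter separate models via 'kinetic_var'")
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["simulate", "analyze", "run_all"] = "run_all"
    outdir: str = "flianirs_run"
    cohort_path: Optional[str] = None       # analyze mode: existing cohort table
    recordings_dir: Optional[str] = None    # analyze mode: existing recordings
    seed: Optional[int] = None
    simulate: SimulateConfig = SimulateConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    kinetics: KineticsConfig = KineticsConfig()
    model: ModelConfig = ModelConfig()

    @model_validator(mode="after")
    def _seed_required_for_simulation(self):
        if self.mode in ("simulate", "run_all") and self.seed is None:
            raise ValueError("seed is mandatory in simulate / run_all mode")
        return self


def validate_config(raw) -> RunConfig:
    """Schema-check a JSON text / dict; defaults filled, unknown keys rejected."""
    if isinstance(raw, (str, bytes)):
        try:
            raw = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors())
        raise ConfigError(f"invalid configuration: {locs}") from exc


# ---------------------------------------------------------------------------
# seeding and manifests
# ---------------------------------------------------------------------------

def _stage_seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(4)
    names = ("cohort", "recordings", "leg_selection", "cv")
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(names, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, outputs: list, config: RunConfig,
                    seeds: dict) -> Path:
    manifest = {
        "config": config.model_dump(),
        "stage_seeds": seeds,
        "outputs": [{"path": p.name, "sha256": _sha256(p)} for p in sorted(outputs)],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path, seeds: dict) -> list:
    sc = config.simulate
    cohort_cfg = synthetic.CohortConfig(
        n_healthy=sc.n_healthy, n_patients=sc.n_patients,
        n_unilateral=sc.n_unilateral,
        n_bilateral_symmetric=sc.n_bilateral_symmetric,
        n_bilateral_asymmetric=sc.n_bilateral_asymmetric,
        censor_probability={"healthy": 0.0,
                            "affected": sc.censor_probability_affected,
                            "nonaffected": 0.0},
        censor_horizon_s=config.kinetics.censor_horizon_s,
        include_recordings=sc.include_recordings,
        seed=seeds["cohort"])
    legs, recordings = synthetic.generate_cohort(cohort_cfg)
    outputs = []
    cohort_path = outdir / "cohort.csv"
    sidecar = outdir / "cohort_truth.json"
    synthetic.write_cohort(legs, cohort_path, sidecar, cohort_cfg)
    outputs += [cohort_path, sidecar]
    if recordings:
        rec_dir = outdir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in recordings:
            p = rec_dir / f"{rec.meta['subject_id']}_{rec.meta['leg_side']}.csv"
            synthetic.write_recording(rec, p)
            outputs.append(p)
    log.info("simulate: %d legs, %d recordings", len(legs), len(recordings))
    return outputs


def stage_features(config: RunConfig, outdir: Path, recordings_dir: Path) -> Path:
    """Preprocess every recording and extract per-leg kinetic features."""
    import warnings
    pc, kc = config.preprocess, config.kinetics
    rows = []
    warnings.filterwarnings("once", message="5-s averaging window truncated")
    for path in sorted(recordings_dir.glob("*.csv")):
        rec = preprocess.read_recording(path)
        subject_id, leg_side = path.stem.rsplit("_", 1)
        rec.meta.update(subject_id=subject_id, leg_side=leg_side)
        rec = preprocess.preprocess_recording(
            rec, hampel_half_window=pc.hampel_half_window,
            hampel_n_sigmas=pc.hampel_n_sigmas,
            lowpass_order=pc.lowpass_order,
            lowpass_cutoff_hz=pc.lowpass_cutoff_hz,
            cadence_band_hz=pc.cadence_band_hz)
        rows.append(kinetics.extract_leg_features(
            rec, kernel_tau_s=kc.kernel_tau_s, kernel_len_s=kc.kernel_len_s,
            r2_gate=kc.r2_gate, horizon_s=kc.censor_horizon_s,
            refine=kc.refine_onset))
    features = pd.DataFrame(rows)
    path = outdir / "features.csv"
    features.to_csv(path, index=False)
    log.info("features: %d legs -> %s", len(rows), path)
    return path


def stage_diagnose(config: RunConfig, outdir: Path, seeds: dict,
                   cohort_path: Path, features_path: Optional[Path]) -> list:
    """Leg selection, Firth model with CV, ROC report."""
    mc = config.model
    frame = pd.read_csv(cohort_path)
    kin_col = f"{mc.signal}_{mc.kinetic_var}_s"
    if features_path is not None:
        feats = pd.read_csv(features_path)
        keep = ["subject_id", "leg_side"] + [
            c for c in feats.columns if c.endswith(("_s", "_censored", "_r2"))]
        frame = frame.drop(
            columns=[c for c in frame.columns
                     if c.endswith("_s") or c.endswith("_censored")]
        ).merge(feats[keep], on=["subject_id", "leg_side"], how="inner")
    legs = synthetic.frame_to_legs(_frame_with_kinetics(frame))
    analysis = diagnostics.select_analysis_leg(legs, seeds["leg_selection"])

    rows = pd.DataFrame([{
        "label": leg.label, kin_col: leg.kinetics[mc.signal][mc.kinetic_var],
        **{c: getattr(leg, c) for c in mc.confounders}} for leg in analysis])
    confounders = [c for c in mc.confounders if rows[c].nunique() > 1]
    dropped = sorted(set(mc.confounders) - set(confounders))
    if dropped:
        log.warning("dropping constant confounder(s) %s", dropped)
    features = confounders + [kin_col]
    X = rows[features].to_numpy(dtype=float)
    y = rows["label"].to_numpy(dtype=int)

    model = diagnostics.backward_select(X, y, features,
                                        p_threshold=mc.p_threshold,
                                        locked=[kin_col])
    cols = [features.index(f) for f in model.feature_names]
    model.apparent_probabilities = model.predict_proba(X[:, cols])
    model.oof_probabilities = diagnostics.cross_validate(
        X, y, k=mc.k_folds, seed=seeds["cv"], feature_names=features,
        select=mc.select_within_folds, p_threshold=mc.p_threshold,
        locked=[kin_col])
    roc = diagnostics.roc_analysis(model.oof_probabilities, y)

    report = {
        "signal": mc.signal, "kinetic_var": mc.kinetic_var,
        "n_analysis_legs": int(len(analysis)),
        "selected_features": model.feature_names,
        "intercept": model.intercept,
        "coefficients": dict(zip(model.feature_names,
                                 model.coefficients.tolist())),
        "p_values": dict(zip(model.feature_names, model.p_values.tolist())),
        "converged": model.converged,
        "cv_auc": roc.auc,
        "operating_points": {
            "youden": vars(roc.youden),
            "max_spec_at_sens95": vars(roc.max_spec_at_sens95),
            "max_sens_at_spec95": vars(roc.max_sens_at_spec95),
        },
    }
    report_path = outdir / "model_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    roc_path = outdir / "roc_coordinates.csv"
    pd.DataFrame({"threshold": roc.thresholds,
                  "sensitivity": roc.sensitivity,
                  "specificity": roc.specificity}).to_csv(roc_path, index=False)
    log.info("diagnose: CV AUC %.3f with features %s", roc.auc,
             model.feature_names)
    return [report_path, roc_path]


def _frame_with_kinetics(frame: pd.DataFrame) -> pd.DataFrame:
    """Ensure every per-signal kinetic/censor column exists (NaN-filled)."""
    frame = frame.copy()
    for sig in SIGNALS:
        for var in ("td", "tau", "mrt", "hvt"):
            frame[f"{sig}_{var}_s"] = frame.get(f"{sig}_{var}_s", np.nan)
        for var in ("mrt", "hvt"):
            col = f"{sig}_{var}_censored"
            frame[col] = frame.get(col, False)
    return frame


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run report.

    Any stage error aborts with the failing stage named; outputs written so
    far are renamed with a ``.partial`` suffix.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed if config.seed is not None else 0)
    outputs: list = []
    stage = "setup"
    try:
        cohort_path = Path(config.cohort_path) if config.cohort_path else None
        recordings_dir = (Path(config.recordings_dir)
                          if config.recordings_dir else None)
        if config.mode in ("simulate", "run_all"):
            stage = "simulate"
            outputs += stage_simulate(config, outdir, seeds)
            cohort_path = outdir / "cohort.csv"
            rec_dir = outdir / "recordings"
            recordings_dir = rec_dir if rec_dir.is_dir() else None
        features_path = None
        if config.mode in ("analyze", "run_all"):
            if cohort_path is None:
                raise ConfigError("analyze mode requires cohort_path")
            if recordings_dir is not None:
                stage = "features"
                features_path = stage_features(config, outdir, recordings_dir)
                outputs.append(features_path)
            stage = "diagnose"
            outputs += stage_diagnose(config, outdir, seeds, cohort_path,
                                      features_path)
        stage = "manifest"
        manifest = _write_manifest(outdir, outputs, config, seeds)
        return {"status": "ok", "stage_seeds": seeds,
                "outputs": [str(p) for p in outputs],
                "manifest": str(manifest)}
    except Exception as exc:
        for p in outputs:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
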