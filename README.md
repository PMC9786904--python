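# flianirs

Muscle-oximetry reoxygenation kinetics and penalized logistic diagnostics for
**sport-related flow limitation in the iliac arteries (FLIA)**.

Endurance athletes can develop an exercise-induced inflow restriction of the
iliac arteries (kinking and/or endofibrotic lesions). The condition is hard to
diagnose: the standard bedside measure — a post-exercise ankle-brachial index
taken in the competitive, hip-flexed posture (ABI_flexed) — misses a large
share of cases. Near-infrared spectroscopy (NIRS) offers a complementary
signal: a flow-limited leg reoxygenates *slowly* after maximal exercise, and
the kinetics of that recovery carry diagnostic information.

This package implements the full analysis chain for that idea, aimed at
exercise physiologists and sports-medicine researchers working with
cycle-ergometer NIRS data:

- **Synthetic cohorts** (`flianirs.synthetic`) — 10 Hz O2Hb/HHb/TSI recordings
  with warm-up, ramp-exercise and recovery phases, cadence-frequency movement
  artifact, noise and spikes; per-leg clinical covariates and group-specific
  kinetic distributions, so the whole pipeline is testable without any
  clinical data.
- **Signal conditioning** (`flianirs.preprocess`) — Hampel outlier
  replacement, zero-lag 5th-order Butterworth low-pass at 1 Hz, TSI and dHb
  derivation, and recovery-start detection from the end of the cadence
  oscillation.
- **Recovery kinetics** (`flianirs.kinetics`) — absolute values and
  amplitudes, then the delayed mono-exponential recovery model

  ```
  Y(t) = Y_min + Y_ΔRecovery · (1 − e^(−t/τ)),   t measured from fit onset
  ```

  with a matched-filter onset (time delay *Td*), a 30-s endpoint rule, the
  mean response time **MRT = Td + τ**, the half value time **HVT**, an
  R² > 0.85 quality gate, and 300-s substitution for values unobservable
  within the recovery window (censoring).
- **Hemodynamic index** (`flianirs.hemodynamics`) —
  `ABI_flexed = (SAP − ΔAB·0.78) / SBP` with the hydrostatic height
  correction and its normal-value rules (≥ 0.54; between-leg ankle pressure
  difference ≤ 23 mmHg).
- **Diagnostic modelling** (`flianirs.diagnostics`) — one analysis leg per
  subject, Firth (Jeffreys-prior) penalized logistic regression that stays
  finite under separation, Wald-based backward selection at p > 0.10,
  stratified 10-fold cross-validation, and ROC analysis with three operating
  points (Youden index, max specificity at sensitivity ≥ 0.95, max
  sensitivity at specificity ≥ 0.95).
- **Pipeline + CLI** (`flianirs.pipeline`, `flianirs` command) — reproducible
  simulate → condition → kinetics → diagnose runs with JSON-validated
  configuration, per-stage seed substreams and a checksummed output manifest.

## Worked example

`examples/diagnostic_model.py` simulates a cohort with the study conditions
the package targets — 33 healthy athletes, 201 patients (95 unilateral /
15 bilateral-symmetric / 91 bilateral-asymmetric), skewed kinetic and ABI
distributions per group, ~7% censored patient legs — and compares the
cross-validated accuracy of the ankle-brachial index alone against the index
combined with the dHb mean response time:

```text
analysis legs: 234 (33 healthy, 201 patients)
Firth coefficients: intercept +3.385, abi_flexed -9.7563, dhb_mrt_s +0.1098
CV AUC, ABI alone      : 0.798
CV AUC, ABI + dHb MRT  : 0.954
Youden point (combined): threshold 0.776, sensitivity 0.90, specificity 0.91
```

The negative ABI coefficient and positive MRT coefficient read exactly as the
physiology says: a lower post-exercise index and a slower reoxygenation both
raise the probability of flow limitation, and adding the kinetic variable
lifts the cross-validated AUC far above the pressure index alone. The other
scripts in `examples/` show single-recording simulation and conditioning,
kinetic fitting against ground truth, the height-corrected index, and the
end-to-end pipeline with its manifest.

The same run from a shell:

```bash
flianirs run-all --seed 11 --outdir demo --signal dhb --kinetic-var mrt
```

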