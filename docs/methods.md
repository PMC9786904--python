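# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `flianirs`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The measurement and the model

During a maximal ramp test on a cycle ergometer, near-infrared spectroscopy
over the vastus lateralis tracks relative concentrations of oxygenated and
deoxygenated heme pigments (O2Hb, HHb, a.u., zero-referenced at the start of
warm-up), the tissue saturation index TSI = 100·O2Hb/(O2Hb+HHb) (%), and the
differential signal dHb = O2Hb − HHb. Oxygenation falls to a nadir (or
plateau) near task failure and then recovers towards a hyperemic maximum.
In a leg with an arterial inflow limitation the recovery is delayed and
slowed.

Recovery is modelled as a *delayed mono-exponential*: the signal stays at
its minimum for a time delay Td, then follows

    Y(t) = Y_min + amp · (1 − exp(−t/τ)),    t re-zeroed at the fit onset.

Derived quantities per signal and leg:

| quantity | definition | units | role |
|---|---|---|---|
| Td | recovery start → mono-exponential onset | s | delay of reoxygenation |
| τ (Tau) | time constant of the fit | s | speed of reoxygenation |
| MRT | Td + τ | s | primary kinetic feature |
| HVT | time from recovery start to half the recovery amplitude | s | model-free companion (= Td + τ·ln 2 on an ideal curve) |
| ΔExercise | baseline − minimal (TSI) or −minimal (O2Hb/dHb) | % or a.u. | deoxygenation depth |
| ΔRecovery | maximal − minimal | % or a.u. | reoxygenation amplitude |

Baseline is the 10-s mean before exercise onset (TSI only); minimal/maximal
are 5-s means centred on the nadir (searched over exercise *and* recovery,
because the minimum can fall just after task failure) and on the
recovery-phase peak. When an extreme is a flat plateau of tied samples, the
averaging window is centred on the middle of the plateau; windows crossing a
recording edge are truncated with a warning.

### Onset, endpoint and fit window

* **Endpoint** — the first recovery sample that is a running maximum, has
  risen at least 25% of the segment's range above its minimum, and is not
  exceeded by any sample in the following 30 s; the fit window ends 30 s
  after it. The 25% rise guard is ours: without it, a noise excursion during
  a delay longer than 30 s satisfies the verbal rule and truncates the
  window before the kinetics begin. A signal still rising at the last sample
  has no confirmable endpoint and is censored; the pipeline then falls back
  to fitting up to the recording end (flagged `endpoint_censored`).
* **Onset (Td)** — a matched filter: a zero-mean, unit-norm kernel
  1 − exp(−t/10 s) of length 60 s slides along the recovery segment and the
  onset is the lag maximizing the normalized cross-correlation. Two
  subtleties, both consequences of the Pearson statistic being scale- and
  offset-invariant: on a clean delayed exponential *every* lag past the true
  onset ties at the maximum (the windowed shape is identical up to scale),
  so the earliest lag within 1e-9 of the peak is taken; and under noise the
  correlation profile is too flat for sharp localization, so the coarse lag
  (together with a second, kernel-normalized projection score that localizes
  sharply but carries a shape-dependent bias) seeds a least-squares
  refinement of a 4-parameter delayed mono-exponential whose delay is free
  within the coarse span ± 5 s. The refinement gives sub-sample delay
  resolution; kernel shape, length and the normalization are fixed defaults
  exposed in configuration, validated by the parameter-recovery tests. A
  segment shorter than the kernel, or one with no positively correlating lag
  (no rising mono-exponential shape, e.g. a monotonically decreasing
  recovery), censors the onset.
* **Fit** — trust-region least squares of (Y_min, amp, τ) over the window,
  τ bounded to (0.1, 300] s (upper bound aligned with the censoring
  horizon), amp > 0; starting values are the window minimum, the window
  range and (time to half-range)/ln 2. R² = 1 − SSE/SST over the window.

### Censoring

Kinetics can be unobservable within the 300-s recovery window: no
reoxygenation at all (severe kinking or occlusion maintained by the posture),
a fit that never converges, or R² ≤ 0.85. Such legs are *not excluded* —
dropping them would remove the most diseased legs and bias the model — but
flagged, and their MRT/HVT set to the horizon itself (300 s exactly). The
substitution is idempotent and order-independent with respect to fitting.

## Signal conditioning

* **Hampel identifier** — window of the sample plus 3 neighbours per side;
  a sample deviating from the window median by more than 3 robust standard
  deviations (1.4826·MAD of the window; the plain SD would be corrupted by
  the outlier itself) is replaced by that median. MAD = 0 gives a zero
  threshold, so any sample off the window median is replaced. Edge windows
  shrink rather than pad. One pass is not a projection — replacing an
  outlier tightens neighbouring windows' MAD and can expose new samples —
  so the identifier is re-applied until the series is a fixed point, making
  the operator idempotent by construction (convergence observed within a
  few passes; capped at 30 with a logged warning).
* **Zero-lag low-pass** — 5th-order Butterworth designed at 1 Hz (10 Hz
  sampling) and applied forward-backward (`filtfilt`): the phase response
  cancels exactly and the magnitude order doubles; "5th order" names the
  design, not the net response. Edge transients are handled by
  reflect-padding of length 3 × order. This removes the 1.3–1.7 Hz cadence
  oscillation while passing recovery kinetics (τ ≥ a few seconds)
  essentially untouched.
* **Recovery start** — the cadence artifact ends when pedalling stops, so
  the conditioned-but-not-lowpassed channel is band-passed over 1–2 Hz and a
  5-s forward-looking RMS envelope is thresholded at 20% of its median over
  the exercise phase; the first crossing sustained for ≥ 5 s marks the
  recovery start. The thresholds are stated conventions, exposed in
  configuration. An explicit phase marker always takes precedence, with the
  detector result logged for comparison.

Conditioning never changes series length or timestamps.

## Ankle-brachial index

ABI_flexed = (SAP − ΔAB·0.78)/SBP, with SAP/SBP systolic ankle/brachial
pressures (mmHg) and ΔAB the ankle-arm height difference (cm; 0.78 mmHg per
cm of blood column). A leg is abnormal when the index is below 0.54 or the
between-leg ankle pressure difference exceeds 23 mmHg; the rule's direction
is not stated in the clinical convention, so the lower-pressure leg is
flagged. No clamping of the index is applied.

## Diagnostic model

One analysis leg per subject keeps observations independent: the affected
leg for unilateral patients, the most symptomatic leg for asymmetric
bilateral patients, a seeded random leg for healthy subjects and symmetric
bilateral patients.

Because censored kinetic values occur almost exclusively in patients, the
substituted 300-s values (quasi-)separate the classes and plain maximum
likelihood diverges. Coefficients therefore maximize the Jeffreys-prior
penalized likelihood ℓ(β) + ½·log det I(β) (Firth bias reduction) via
Fisher scoring on the hat-corrected score U*_j = Σ_i (y_i − p_i +
h_i(½ − p_i)) x_ij with step-halving on the penalized likelihood;
convergence at max |U*| < 1e-6. Estimates are finite under complete
separation; no installed package provides this penalty, so the solver is
implemented here and is checked in the tests against direct numerical
maximization of the penalized likelihood and the add-one-half closed form of
the saturated 2×2 design (slope log 121). Wald p-values use the inverse
observed information at the penalized optimum — standard reporting for
Firth fits — and drive backward elimination (drop the single highest
p > 0.10, refit, repeat), with the kinetic variable under study locked.
MRT and HVT never enter one model together (they are nearly collinear,
ρ ≈ 0.98); configuration validation enforces this.

Validation is stratified 10-fold cross-validation; by default the backward
selection is re-run inside every training fold, which avoids selection
optimism (the alternative — selecting once on all data — is configurable).
k = n degenerates to leave-one-out, where per-class stratification is
trivially satisfied by singleton folds. Out-of-fold probabilities
(inverse logit of the linear predictor) feed the ROC: candidate thresholds
are the midpoints between adjacent distinct scores plus ±∞, a record is
called positive when its score ≥ threshold, and the AUC is the trapezoid
over the resulting staircase (ties count one half, i.e. the Mann-Whitney
concordance). Operating points: maximal Youden index J = sens + spec − 1
(ties towards higher specificity, then lower threshold, so reruns are
bitwise stable); maximal specificity subject to sensitivity ≥ 0.95; maximal
sensitivity subject to specificity ≥ 0.95. Thresholds are reported on the
predicted-probability scale.

## Synthetic data: what it emulates, and what it does not

The generator exists because no clinical recordings are deposited; it
reproduces the *statistical structure* the analysis assumes, not vascular
physiology.

Per recording (defaults in parentheses): flat warm-up baseline (240 s at
~60% TSI); a smooth monotone decline of ΔExercise (20%) reaching the nadir
at 85% of the exercise phase (so the plateau is wider than the 5-s averaging
window; exercise 600 s, drawn 480–720 s in cohorts to mimic the 8–12 min
ramp); recovery (300 s, matching the censoring horizon) flat for Td then
mono-exponential with amplitude ΔRecovery (1.35 × ΔExercise, the overshoot
ratio implied by the reported amplitude tables). A single sinusoid at
cadence/60 Hz (cadence uniform in 80–100 rpm) with amplitude 2 a.u. tapering
over the final 2 s of exercise stands in for the pedalling artifact — the
artifact's true waveform is undocumented, so this is a stated assumption.
Gaussian channel noise (SD 0.35 a.u.) and Poisson-placed single-sample
spikes (2/min, amplitude ±[5, 20] noise SDs — removable by the Hampel
stage) are superimposed. O2Hb/HHb are built around a constant total of
100 a.u., which makes the derived TSI equal the designed trajectory and
dHb = 2·TSI − 100: all three channels share one kinetic trajectory and are
exactly mono-exponential in recovery. Real data have independent
channel dynamics (blood-volume changes) and a coloured noise spectrum;
passing tests therefore demonstrate correctness of the *estimators* on the
assumed signal class, not robustness to every artifact of real optodes.

Per cohort: 33 healthy subjects and 201 patients (95 unilateral /
15 bilateral-symmetric / 91 bilateral-asymmetric) by default. Kinetic
features are drawn per leg group (healthy, affected, non-affected) and per
signal: MRT is log-normal with the group's published median and IQR
(log-normal because the clinical tables report right-skewed median (IQR)
summaries), and Td = f·MRT with f Beta-distributed around the observed
median Td/MRT ratio (concentration 12), so MRT = Td + τ holds exactly per
draw and sampled MRT medians match the configured medians by construction;
HVT = Td + τ·ln 2. ABI and covariates (age, sex, BMI, WPeak/kg, ATT) come
from the published group summaries (normal or log-normal per the shape of
the reported summary; ATT is truncated below the 7.5 mm inclusion
threshold). Censoring is an explicit per-leg event (default probability
0.07 for affected legs, ~the reported share of unobservable patient legs;
0 elsewhere): censored legs carry 300-s values, both flags, and — when
recordings are emitted — a non-reoxygenating recovery; uncensored draws use
the distribution truncated at the horizon, so a zero censor probability
yields a cohort with no flags. Recordings, when emitted, follow each leg's
*TSI* kinetics; the per-signal table values are the ground truth for
feature-level analyses, and the shared-trajectory recording is a deliberate
simplification (see the limitation above).

## Numerical choices and degenerate inputs

* Determinism: every stochastic routine takes an explicit seed; the
  pipeline derives per-stage substreams from the master seed via
  `SeedSequence.spawn`, and manifests carry SHA-256 checksums of all
  outputs.
* TSI from relative channels needs a positive total; undefined samples
  (total ≤ 0) become NaN flags rather than exceptions. Device TSI, when
  present, is conditioned directly instead.
* Constant fit windows have SST = 0; R² is defined as 0 there (no
  explainable variance), which censors the fit.
* A fit window shorter than 10 s or 20 samples, non-convergence, or an
  onset/endpoint that cannot be established all yield censored fits, never
  exceptions; format violations (non-monotone time, missing columns) and
  invalid parameters raise typed errors.
* Rank-deficient designs are rejected naming the collinear columns (the
  later column of each dependent set, so a constant feature is blamed
  rather than the intercept); the pipeline drops constant confounders with
  a logged warning before fitting.
* Time-grid tolerance: timestamps within 1e-6 s of the 0.1 s grid are
  accepted; otherwise the reader resamples by linear interpolation and logs
  it.

## Problem sizes used by the checks

The test suite and the acceptance script run entirely on synthesized data:
a 20-point (τ, Td) grid of noiseless recordings for exactness; 200 noisy
recordings (noise SD = 5% of the recovery amplitude) for parameter-recovery
statistics; 100 cohort draws at the full 33/201 size for the
feature-level diagnostic comparison; and tiny cohorts (≤ 24 subjects,
with per-leg recordings) for end-to-end pipeline checks. These sizes give
stable statistics for every asserted property while keeping a full run in
the minutes range on one core.

## Known limitations

* No correction for adipose tissue thickness beyond using it as a model
  covariate, and no motion-artifact handling beyond the Hampel stage.
* The device-side computation of absolute TSI (spatially resolved
  photon-diffusion processing) is out of scope; TSI here is either taken
  from the device column or formed from channel ratios.
* Only the mono-exponential recovery model is provided — no bi-exponential
  or sigmoidal alternatives.
* Confidence intervals for AUCs and operating points are not computed.
* The endpoint rule's 25% rise guard, the matched-filter kernel
  (shape, 10-s tau, 60-s length), the onset refinement, and the
  recovery-start thresholds (20%, 5 s) are package conventions where the
  underlying verbal descriptions leave the algorithm open; all are exposed
  in configuration and validated against ground truth in the tests.
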