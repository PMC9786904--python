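"""Diagnostic modelling: Firth-penalized logistic regression with ROC analysis.

One analysis leg per subject enters a logistic model of flow-limitation status
on a recovery-kinetics variable (MRT or HVT of one NIRS signal, never both in
one model — they are nearly collinear) plus clinical confounders (age, sex,
BMI, peak workload per kg, adipose tissue thickness, hip-flexed ABI).

Maximum likelihood breaks down under (quasi-)separation — censored kinetic
values occur almost exclusively in patients — so coefficients maximize the
Jeffreys-prior-penalized likelihood

    l*(beta) = l(beta) + 1/2 log det I(beta),

whose estimates are always finite (Firth bias reduction). Models are
validated by stratified k-fold cross-validation; out-of-fold probabilities
feed a ROC analysis with three operating-point rules (Youden index, maximal
specificity at sensitivity >= 0.95, maximal sensitivity at specificity >=
0.95).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError, RankDeficiencyError, SelectionError

log = logging.getLogger(__name__)

DEFAULT_CONFOUNDERS = ("age", "sex", "bmi", "wpeak_per_kg", "att", "abi_flexed")


# ---------------------------------------------------------------------------
# leg records and analysis-leg selection
# ---------------------------------------------------------------------------

@dataclass
class LegRecord:
    """One leg of one subject: label, covariates and kinetic features."""

    subject_id: str
    leg_side: str
    label: int                      # 0 healthy subject, 1 flow-limited patient
    affected: bool
    severity: Optional[int]         # complaint severity for bilateral patients
    group: str                      # healthy / affected / nonaffected
    pattern: str                    # healthy / unilateral / bilateral_*
    age: float
    sex: int
    bmi: float
    wpeak_per_kg: float
    att: float
    abi_flexed: float
    kinetics: dict = field(default_factory=dict)   # signal -> {td,tau,mrt,hvt}
    censored: dict = field(default_factory=dict)   # signal -> {mrt,hvt} flags


def select_analysis_leg(records: Sequence[LegRecord], seed: int) -> list:
    """One analysis leg per subject (independence of observations).

    Healthy subjects and bilateral patients with symmetric complaints get a
    seeded uniformly random leg; asymmetric bilateral patients the leg with
    the most severe complaints; unilateral patients the affected leg.
    """
    rng = np.random.default_rng(seed)
    by_subject: dict = {}
    for leg in records:
        by_subject.setdefault(leg.subject_id, []).append(leg)

    chosen = []
    for subject in sorted(by_subject):
        legs = by_subject[subject]
        if len(legs) == 1:
            chosen.append(legs[0])
            continue
        affected = [l for l in legs if l.affected]
        if len(affected) == 1:                      # unilateral
            pick = affected[0]
        elif len(affected) == 0:                    # healthy subject
            pick = legs[int(rng.integers(len(legs)))]
        else:                                       # bilateral
            sev = [l.severity for l in affected]
            if any(s is None for s in sev):
                raise SelectionError(
                    f"subject {subject}: bilateral legs lack severity annotations")
            if sev[0] == sev[1]:
                pick = affected[int(rng.integers(len(affected)))]
            else:
                pick = max(affected, key=lambda l: l.severity)
        chosen.append(pick)
    return chosen


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticModel:
    """A fitted Firth logistic model with optional validation artifacts."""

    feature_names: list
    intercept: float
    coefficients: np.ndarray
    cov: np.ndarray                  # (p+1)x(p+1), intercept first
    p_values: np.ndarray             # Wald, aligned with feature_names
    converged: bool
    n_iter: int
    loglik_penalized: float
    oof_probabilities: Optional[np.ndarray] = None
    apparent_probabilities: Optional[np.ndarray] = None

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X) -> np.ndarray:
        return expit(self.linear_predictor(X))


def _check_rank(Xd: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # blame the later columns of each dependent set (the intercept comes
        # first, so a constant feature is named rather than the intercept)
        bad, kept = [], []
        for j in range(Xd.shape[1]):
            cand = Xd[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(j)
        raise RankDeficiencyError([names[i] for i in bad])


def _penalized_loglik(Xd, y, beta):
    eta = Xd @ beta
    # log-likelihood written in a numerically safe form
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    w = p * (1.0 - p)
    info = (Xd * w[:, None]).T @ Xd
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic_fit(X, y, feature_names: Optional[Sequence[str]] = None,
                       max_iter: int = 200, tol: float = 1e-6) -> DiagnosticModel:
    """Maximize the Jeffreys-prior-penalized logistic likelihood.

    Newton/Fisher scoring on the Firth-modified score
    ``U*_j = sum_i (y_i - p_i + h_i (1/2 - p_i)) x_ij`` (``h_i`` the hat
    diagonal), with step-halving on the penalized log-likelihood. Convergence:
    max |U*| < ``tol``. Coefficients are finite even under complete
    separation. Raises on a rank-deficient design, naming the columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ParameterError("X and y sizes differ")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ParameterError("y must be binary 0/1")
    if n <= p + 1:
        raise ParameterError("need more observations than parameters")
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ParameterError("feature_names length differs from X columns")
    Xd = np.column_stack([np.ones(n), X])
    _check_rank(Xd, ["(intercept)"] + names)

    beta = np.zeros(p + 1)
    ll = _penalized_loglik(Xd, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        prob = expit(eta)
        w = prob * (1.0 - prob)
        XtW = Xd.T * w
        info = XtW @ Xd
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", Xd, info_inv, Xd) * w
        score = Xd.T @ (y - prob + h * (0.5 - prob))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        lam = 1.0
        for _ in range(25):
            cand = beta + lam * step
            ll_new = _penalized_loglik(Xd, y, cand)
            if ll_new > ll - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        ll = _penalized_loglik(Xd, y, beta)

    eta = Xd @ beta
    prob = expit(eta)
    w = prob * (1.0 - prob)
    cov = np.linalg.inv((Xd.T * w) @ Xd)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p_all = 2.0 * norm.sf(np.abs(z))
    return DiagnosticModel(
        feature_names=names, intercept=float(beta[0]),
        coefficients=beta[1:].copy(), cov=cov, p_values=p_all[1:],
        converged=converged, n_iter=it, loglik_penalized=float(ll))


def backward_select(X, y, feature_names: Sequence[str],
                    p_threshold: float = 0.10,
                    locked: Sequence[str] = ()) -> DiagnosticModel:
    """Stepwise backward elimination on Wald p-values from Firth fits.

    Iteratively refits after removing the single highest-p covariate with
    p > ``p_threshold``; features in ``locked`` (e.g. the kinetic variable
    under study) are never removed. When everything is eliminated an
    intercept-only model is returned with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = list(feature_names)
    locked = set(locked)
    unknown = locked - set(names)
    if unknown:
        raise ParameterError(f"locked feature(s) not in design: {sorted(unknown)}")
    keep = list(range(len(names)))
    while True:
        if not keep:
            log.warning("backward selection removed every covariate; "
                        "returning an intercept-only model")
            return _intercept_only_model(y)
        model = firth_logistic_fit(X[:, keep], y, [names[i] for i in keep])
        removable = [(model.p_values[j], j) for j, i in enumerate(keep)
                     if names[i] not in locked and model.p_values[j] > p_threshold]
        if not removable:
            return model
        _, worst = max(removable)
        del keep[worst]


def _intercept_only_model(y) -> DiagnosticModel:
    y = np.asarray(y, dtype=float)
    n, k = y.size, y.sum()
    # Firth penalty for the intercept-only model = add 1/2 success + failure
    p_hat = (k + 0.5) / (n + 1.0)
    var = 1.0 / (n * p_hat * (1 - p_hat))
    return DiagnosticModel(
        feature_names=[], intercept=float(np.log(p_hat / (1 - p_hat))),
        coefficients=np.empty(0), cov=np.array([[var]]),
        p_values=np.empty(0), converged=True, n_iter=0,
        loglik_penalized=float(k * np.log(p_hat) + (n - k) * np.log(1 - p_hat)
                               + 0.5 * np.log(n * p_hat * (1 - p_hat))))


def predict_probability(model: DiagnosticModel, x: dict) -> float:
    """Inverse-logit probability 1/(1+e^-eta) for one feature row (a mapping)."""
    missing = [f for f in model.feature_names if f not in x]
    if missing:
        raise ParameterError(f"missing feature(s): {missing}")
    row = np.array([float(x[f]) for f in model.feature_names])
    return float(expit(model.intercept + row @ model.coefficients))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(X, y, k: int = 10, seed: int = 0,
                   feature_names: Optional[Sequence[str]] = None,
                   select: bool = False, p_threshold: float = 0.10,
                   locked: Sequence[str] = ()) -> np.ndarray:
    """Out-of-fold inverse-logit probabilities from stratified k-fold CV.

    Folds are stratified to balance the class distribution within splits; with
    ``select`` the backward elimination is re-run inside every training fold
    (avoids selection optimism). ``k == n`` degenerates to leave-one-out.
    Every record receives exactly one out-of-fold probability.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    n = y.size
    names = list(feature_names) if feature_names is not None else [
        f"x{j}" for j in range(X.shape[1])]
    counts = np.bincount(y, minlength=2)
    if k < 2:
        raise ParameterError("k must be at least 2")
    if k == n:
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        if counts.min() < k:
            raise ParameterError(
                f"smallest class has {counts.min()} records < k={k}; "
                "use a smaller k")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))

    oof = np.full(n, np.nan)
    for train, test in folds:
        if select:
            model = backward_select(X[train], y[train], names,
                                    p_threshold=p_threshold, locked=locked)
            cols = [names.index(f) for f in model.feature_names]
        else:
            model = firth_logistic_fit(X[train], y[train], names)
            cols = list(range(X.shape[1]))
        oof[test] = (model.predict_proba(X[test][:, cols]) if cols
                     else expit(model.intercept))
    assert not np.isnan(oof).any()
    return oof


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray          # candidate thresholds, ascending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden: OperatingPoint
    max_spec_at_sens95: OperatingPoint
    max_sens_at_spec95: OperatingPoint


def roc_analysis(probabilities, labels, sens_floor: float = 0.95,
                 spec_floor: float = 0.95) -> RocResult:
    """ROC curve, trapezoid AUC and three diagnostic operating points.

    Candidate thresholds are the midpoints between adjacent distinct scores
    plus -inf/+inf; a record is called positive when its score is >= the
    threshold. The AUC is the trapezoid rule over the resulting staircase
    (ties count one half — it equals the Mann-Whitney concordance). Operating
    points: (a) maximal Youden index J = sens + spec - 1, ties resolved
    towards higher specificity then lower threshold; (b) maximal specificity
    subject to sensitivity >= 0.95; (c) maximal sensitivity subject to
    specificity >= 0.95. An infeasible constraint falls back to the nearest
    feasible sensitivity (resp. specificity) with a warning.
    """
    s = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if s.size != y.size:
        raise ParameterError("scores and labels differ in length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present for ROC analysis")

    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    thr = np.concatenate([[-np.inf], mids, [np.inf]])
    # vectorized confusion counts: positive call iff score >= threshold
    pos_scores = np.sort(s[y == 1])
    neg_scores = np.sort(s[y == 0])
    tp = n_pos - np.searchsorted(pos_scores, thr, side="left")
    fp = n_neg - np.searchsorted(neg_scores, thr, side="left")
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg

    # trapezoid AUC over (FPR, TPR) vertices, ties contribute half; vertices
    # must ascend in TPR within tied FPR for the staircase to be traversed
    fpr = fp / n_neg
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    def best(indices, key):
        idx = max(indices, key=key)
        return OperatingPoint(float(thr[idx]), float(sens[idx]), float(spec[idx]))

    all_idx = range(thr.size)
    youden = best(all_idx, lambda i: (sens[i] + spec[i] - 1.0, spec[i], -thr[i]))

    feas_sens = [i for i in all_idx if sens[i] >= sens_floor]
    if not feas_sens:
        log.warning("sensitivity >= %.2f infeasible; using nearest feasible",
                    sens_floor)
        smax = sens.max()
        feas_sens = [i for i in all_idx if sens[i] >= smax]
    op_sens95 = best(feas_sens, lambda i: (spec[i], sens[i], -thr[i]))

    feas_spec = [i for i in all_idx if spec[i] >= spec_floor]
    if not feas_spec:
        log.warning("specificity >= %.2f infeasible; using nearest feasible",
                    spec_floor)
        pmax = spec.max()
        feas_spec = [i for i in all_idx if spec[i] >= pmax]
    op_spec95 = best(feas_spec, lambda i: (sens[i], spec[i], -thr[i]))

    return RocResult(thresholds=thr, sensitivity=sens, specificity=spec,
                     auc=auc, youden=youden, max_spec_at_sens95=op_sens95,
                     max_sens_at_spec95=op_spec95)
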