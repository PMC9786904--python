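"""Diagnostic modelling: leg selection, Firth-penalized logistic regression,
backward selection, stratified cross-validation and ROC analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

import flianirs as fl
from flianirs.diagnostics import LegRecord
from flianirs.errors import (ParameterError, RankDeficiencyError,
                             SelectionError)


def make_leg(subject, side, label=0, affected=False, severity=None, abi=0.7):
    return LegRecord(subject_id=subject, leg_side=side, label=label,
                     affected=affected, severity=severity,
                     group="affected" if affected else "healthy",
                     pattern="unilateral" if affected else "healthy",
                     age=30.0, sex=1, bmi=22.0, wpeak_per_kg=5.5, att=5.0,
                     abi_flexed=abi)


# ---------------------------------------------------------------------------
# analysis-leg selection
# ---------------------------------------------------------------------------

class TestLegSelection:
    def test_unilateral_patient_gets_affected_leg(self):
        legs = [make_leg("P1", "left", 1, affected=True, severity=2),
                make_leg("P1", "right", 1, affected=False, severity=0)]
        chosen = fl.select_analysis_leg(legs, seed=0)
        assert len(chosen) == 1 and chosen[0].leg_side == "left"

    def test_asymmetric_bilateral_gets_most_severe_leg(self):
        legs = [make_leg("P1", "left", 1, affected=True, severity=1),
                make_leg("P1", "right", 1, affected=True, severity=2)]
        assert fl.select_analysis_leg(legs, seed=0)[0].leg_side == "right"

    def test_healthy_selection_is_seed_deterministic(self):
        legs = [make_leg("H1", "left"), make_leg("H1", "right"),
                make_leg("H2", "left"), make_leg("H2", "right")]
        first = [l.leg_side for l in fl.select_analysis_leg(legs, seed=9)]
        again = [l.leg_side for l in fl.select_analysis_leg(legs, seed=9)]
        assert first == again

    def test_missing_severity_on_bilateral_raises(self):
        legs = [make_leg("P1", "left", 1, affected=True, severity=None),
                make_leg("P1", "right", 1, affected=True, severity=2)]
        with pytest.raises(SelectionError):
            fl.select_analysis_leg(legs, seed=0)

    def test_output_size_equals_subject_count(self):
        cfg = fl.CohortConfig(n_healthy=12, n_patients=20, n_unilateral=10,
                              n_bilateral_symmetric=4,
                              n_bilateral_asymmetric=6, seed=1)
        legs, _ = fl.generate_cohort(cfg)
        assert len(fl.select_analysis_leg(legs, seed=0)) == 32


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

def penalized_loglik_2x2(beta, X, y):
    eta = beta[0] + beta[1] * X[:, 0]
    ll = np.sum(y * eta - np.logaddexp(0, eta))
    p = expit(eta)
    Xd = np.column_stack([np.ones(len(y)), X])
    info = (Xd * (p * (1 - p))[:, None]).T @ Xd
    sign, logdet = np.linalg.slogdet(info)
    return ll + 0.5 * logdet


class TestFirthFit:
    def test_complete_separation_matches_penalized_oracle(self):
        # 2x2 table with 0/5 vs 5/5 events: the saturated-model estimate is
        # the add-one-half odds ratio, slope = log 121
        X = np.array([[0.0]] * 5 + [[1.0]] * 5)
        y = np.array([0] * 5 + [1] * 5)
        model = fl.firth_logistic_fit(X, y)
        assert model.converged
        assert model.coefficients[0] == pytest.approx(np.log(121.0), abs=1e-3)
        # independent oracle: direct maximization of the penalized likelihood
        res = minimize(lambda b: -penalized_loglik_2x2(b, X, y), [0.0, 0.0],
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert model.coefficients[0] == pytest.approx(res.x[1], abs=1e-3)

    def test_coefficients_finite_under_random_separation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            x = rng.normal(size=(n, 1))
            y = (x[:, 0] > rng.normal(0, 0.3)).astype(int)
            if y.min() == y.max():
                continue
            model = fl.firth_logistic_fit(x, y)
            assert np.isfinite(model.intercept)
            assert np.isfinite(model.coefficients).all()

    def test_null_slope_is_unbiased(self):
        # y independent of x: the mean slope over seeds stays near zero
        slopes = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(1000, 1))
            y = rng.integers(0, 2, 1000)
            slopes.append(fl.firth_logistic_fit(x, y).coefficients[0])
        assert abs(np.mean(slopes)) < 0.15

    def test_duplicated_column_raises_naming_it(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 1))
        X = np.column_stack([x, x])
        y = (x[:, 0] + rng.normal(size=50) > 0).astype(int)
        with pytest.raises(RankDeficiencyError) as err:
            fl.firth_logistic_fit(X, y, ["a", "a_copy"])
        assert "a_copy" in str(err.value)

    def test_matches_unpenalized_fit_at_large_n(self):
        # the Jeffreys penalty is O(1/n): at n = 10^4 the Firth and plain
        # maximum-likelihood estimates must agree closely
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10_000, 1))
        y = rng.random(10_000) < expit(-0.5 + 1.2 * x[:, 0])
        firth = fl.firth_logistic_fit(x, y.astype(int))
        mle = sm.Logit(y.astype(int), sm.add_constant(x)).fit(disp=0)
        assert abs(firth.coefficients[0] - mle.params[1]) < 0.05
        assert abs(firth.intercept - mle.params[0]) < 0.05

    def test_probability_prediction(self):
        model = fl.DiagnosticModel(
            feature_names=["x"], intercept=-1.0,
            coefficients=np.array([2.0]), cov=np.eye(2),
            p_values=np.array([0.01]), converged=True, n_iter=3,
            loglik_penalized=0.0)
        assert fl.predict_probability(model, {"x": 1.0}) == \
            pytest.approx(1 / (1 + np.exp(-1.0)))
        assert fl.predict_probability(model, {"x": 0.5}) == pytest.approx(0.5)
        assert fl.predict_probability(model, {"x": 1e4}) == pytest.approx(1.0)
        with pytest.raises(ParameterError):
            fl.predict_probability(model, {"y": 1.0})


# ---------------------------------------------------------------------------
# backward selection
# ---------------------------------------------------------------------------

def _informative_dataset(seed, n=300, noise_features=3, log_or=2.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 1 + noise_features))
    y = (rng.random(n) < expit(log_or * x[:, 0])).astype(int)
    return x, y


class TestBackwardSelection:
    def test_informative_feature_retained(self):
        names = ["signal", "n1", "n2", "n3"]
        kept = 0
        for seed in range(40):
            X, y = _informative_dataset(seed)
            model = fl.backward_select(X, y, names)
            kept += "signal" in model.feature_names
        assert kept >= 36  # expected in >= 95% of draws

    def test_all_noise_usually_reduces_to_intercept_only(self):
        # each null feature is retained with ~p_threshold probability, so a
        # clear majority of draws must end intercept-only
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 3))
            y = rng.integers(0, 2, 200)
            model = fl.backward_select(X, y, ["a", "b", "c"])
            empty += len(model.feature_names) == 0
        assert empty > 50

    def test_locked_feature_survives_any_p_value(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        y = rng.integers(0, 2, 200)
        model = fl.backward_select(X, y, ["locked", "free"],
                                   locked=["locked"])
        assert "locked" in model.feature_names

    def test_unknown_locked_feature_rejected(self):
        X = np.zeros((20, 1)) + np.arange(20)[:, None]
        y = np.array([0, 1] * 10)
        with pytest.raises(ParameterError):
            fl.backward_select(X, y, ["a"], locked=["missing"])


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class TestCrossValidate:
    def test_stratified_fold_proportions(self):
        rng = np.random.default_rng(0)
        n = 234
        y = np.array([0] * 33 + [1] * 201)
        X = rng.normal(size=(n, 2)) + y[:, None]
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=1)
        global_prop = y.mean()
        for _, test in skf.split(X, y):
            # fold class counts deviate from proportionality by < 1 subject
            assert abs(y[test].sum() - global_prop * test.size) < 1.0
        probs = fl.cross_validate(X, y, k=10, seed=1)
        assert probs.shape == (n,) and np.isfinite(probs).all()
        assert ((probs > 0) & (probs < 1)).all()

    def test_leave_one_out_predicts_each_record_once(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 1))
        y = np.array([0, 1] * 6)
        probs = fl.cross_validate(X, y, k=12, seed=0)
        assert np.isfinite(probs).all() and probs.size == 12

    def test_out_of_fold_auc_below_apparent_on_separable_data(self):
        gaps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.sort(rng.normal(size=40))[:, None]
            y = (x[:, 0] > np.median(x)).astype(int)
            model = fl.firth_logistic_fit(x, y)
            apparent = fl.roc_analysis(model.predict_proba(x), y).auc
            oof = fl.roc_analysis(fl.cross_validate(x, y, k=4, seed=seed), y).auc
            gaps.append(apparent - oof)
        assert np.mean(gaps) > 0  # optimism of the apparent AUC

    def test_class_smaller_than_k_rejected(self):
        X = np.arange(20.0)[:, None]
        y = np.array([0] * 3 + [1] * 17)
        with pytest.raises(ParameterError):
            fl.cross_validate(X, y, k=10, seed=0)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

def mann_whitney_auc(scores, labels):
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum())
                 / (pos.size * neg.size))


class TestRocAnalysis:
    def test_worked_concordance_example(self):
        scores = np.array([1, 2, 3, 2.5, 4, 5], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        roc = fl.roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(8 / 9)

    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        roc = fl.roc_analysis(scores, labels)
        assert roc.auc == 1.0
        j = roc.youden.sensitivity + roc.youden.specificity - 1.0
        assert j == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        roc = fl.roc_analysis(np.ones(10), np.array([0, 1] * 5))
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), rng.integers(0, 3))
            roc = fl.roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12)

    def test_operating_points_match_exhaustive_search(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(6, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.normal(size=n)
            roc = fl.roc_analysis(scores, labels)
            sens, spec, thr = roc.sensitivity, roc.specificity, roc.thresholds
            j = sens + spec - 1.0
            assert roc.youden.sensitivity + roc.youden.specificity - 1.0 == \
                pytest.approx(j.max())
            feas = sens >= 0.95
            assert roc.max_spec_at_sens95.specificity == \
                pytest.approx(spec[feas].max())
            feas = spec >= 0.95
            assert roc.max_sens_at_spec95.sensitivity == \
                pytest.approx(sens[feas].max())
            for op in (roc.youden, roc.max_spec_at_sens95,
                       roc.max_sens_at_spec95):
                assert op.threshold in thr

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        for _ in range(25):
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            scores = rng.normal(size=40)
            assert fl.roc_analysis(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5, allow_nan=False),
                              st.integers(0, 1)), min_size=4, max_size=40))
    def test_auc_mann_whitney_property(self, pairs):
        scores = np.array([p[0] for p in pairs])
        labels = np.array([p[1] for p in pairs])
        if labels.min() == labels.max():
            return
        assert fl.roc_analysis(scores, labels).auc == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            fl.roc_analysis(np.arange(5.0), np.ones(5, dtype=int))
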