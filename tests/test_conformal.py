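"""Mondrian ICP: nonconformity, p-values, prediction sets, validity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hazardcp.conformal import (
    ConformalError,
    ConformalResults,
    MondrianConformalClassifier,
    Outcome,
    fit_icp,
    nonconformity,
    p_value,
    prediction_set,
    prediction_sets,
)


def brute_force_p(cal_scores, test_score):
    """Count-and-divide oracle, independent of the implementation path."""
    count = sum(1 for s in cal_scores if s >= test_score)
    return (count + 1) / (len(cal_scores) + 1)


class DummyProb:
    """Stub base classifier returning fixed probabilities."""

    classes_ = np.array([0, 1])

    def __init__(self, proba):
        self.proba = np.asarray(proba, dtype=float)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        return self.proba[: len(X)]


class TestNonconformity:
    @pytest.mark.parametrize("prob,score", [(1.0, 0.0), (0.0, 1.0), (0.75, 0.25)])
    def test_linear_form(self, prob, score):
        assert nonconformity(prob) == pytest.approx(score)

    def test_out_of_range_errors(self):
        with pytest.raises(ConformalError):
            nonconformity(1.5)


class TestPValue:
    def test_count_and_divide_example(self):
        assert p_value([0.9, 0.5, 0.2], 0.6) == pytest.approx(0.5)

    def test_empty_calibration_gives_one(self):
        assert p_value([], 0.7) == 1.0

    def test_max_test_score(self):
        assert p_value([0.1, 0.2, 0.3], 1.0) == pytest.approx(0.25)

    def test_ties_count_toward_numerator(self):
        assert p_value([0.5, 0.5, 0.1], 0.5) == pytest.approx(0.75)

    def test_oracle_equivalence_random_fixtures(self, rng):
        for _ in range(1000):
            cal = rng.uniform(size=rng.integers(0, 30)).round(2)
            t = round(float(rng.uniform()), 2)
            assert p_value(list(cal), t) == pytest.approx(brute_force_p(cal, t))

    @given(st.lists(st.floats(0, 1), max_size=50), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, cal, t):
        p = p_value(cal, t)
        assert 1 / (len(cal) + 1) <= p <= 1.0

    def test_smoothed_seeded_and_bounded(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        cal = [0.5, 0.5, 0.2]
        a = p_value(cal, 0.5, smoothed=True, rng=rng1)
        b = p_value(cal, 0.5, smoothed=True, rng=rng2)
        assert a == b and 0 < a <= 1


class TestPredictionSet:
    @pytest.mark.parametrize(
        "pa,pi,eps,expected",
        [
            (0.5, 0.1, 0.2, Outcome.SINGLE_ACTIVE),
            (0.1, 0.5, 0.2, Outcome.SINGLE_INACTIVE),
            (0.5, 0.5, 0.2, Outcome.BOTH),
            (0.05, 0.15, 0.2, Outcome.EMPTY),
            (0.2, 0.2, 0.2, Outcome.EMPTY),  # strict comparison at the boundary
        ],
    )
    def test_threshold_logic(self, pa, pi, eps, expected):
        assert prediction_set(pa, pi, eps) is expected

    def test_invalid_significance(self):
        with pytest.raises(ConformalError):
            prediction_set(0.5, 0.5, 0.0)

    @given(st.floats(0.001, 1), st.floats(0.001, 1))
    @settings(max_examples=200, deadline=None)
    def test_nesting_across_significance(self, pa, pi):
        # the set can only shrink as epsilon grows
        sizes = []
        for eps in (0.1, 0.15, 0.2, 0.25, 0.3):
            o = prediction_set(pa, pi, eps)
            members = {c for c in (0, 1) if o.contains(c)}
            sizes.append(members)
        for small, large in zip(sizes[1:], sizes):
            assert small <= large

    def test_outcome_contains(self):
        assert Outcome.BOTH.contains(0) and Outcome.BOTH.contains(1)
        assert not Outcome.EMPTY.contains(0)
        assert Outcome.SINGLE_ACTIVE.contains(1) and not Outcome.SINGLE_ACTIVE.contains(0)


class TestFitICP:
    def test_calibration_bookkeeping(self, rng):
        X_tr = rng.normal(size=(80, 5))
        y_tr = rng.integers(0, 2, 80)
        X_cal = rng.normal(size=(20, 5))
        y_cal = np.array([1] * 12 + [0] * 8)
        res = fit_icp(X_tr, y_tr, X_cal, y_cal, seed=0)
        assert res.n_cal_ == {0: 8, 1: 12}
        assert all((0 <= s).all() and (s <= 1).all() for s in res.cal_scores_.values())

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] > 0).astype(int)
        a = fit_icp(X[:70], y[:70], X[70:], y[70:], seed=3)
        b = fit_icp(X[:70], y[:70], X[70:], y[70:], seed=3)
        for cls in (0, 1):
            assert np.array_equal(a.cal_scores_[cls], b.cal_scores_[cls])

    def test_separable_data_low_scores(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, size=(60, 3)), rng.normal(3, 0.3, size=(60, 3))])
        y = np.array([0] * 60 + [1] * 60)
        perm = rng.permutation(120)
        X, y = X[perm], y[perm]
        res = fit_icp(X[:90], y[:90], X[90:], y[90:], seed=0)
        for cls in (0, 1):
            assert np.median(res.cal_scores_[cls]) < 0.5

    def test_single_class_calibration_errors(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, 50)
        with pytest.raises(ConformalError, match="re-split"):
            fit_icp(X[:40], y[:40], X[40:], np.ones(10, dtype=int))

    def test_hand_computed_pvalue_pair(self):
        # 5-point calibration fixture, probabilities controlled by a stub
        cal_p = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.4, 0.6], [0.6, 0.4]])
        y_cal = np.array([0, 0, 1, 1, 0])
        model = MondrianConformalClassifier.__new__(MondrianConformalClassifier)
        model.X_train = np.zeros((1, 2))
        model.y_train = np.array([0, 1])
        model.X_cal = np.zeros((5, 2))
        model.y_cal = y_cal
        model.base = DummyProb(cal_p)
        model.spec = None
        model.seed = 0
        res = model.fit()
        # class-0 scores: 1-0.9, 1-0.8, 1-0.6 = [.1,.2,.4]; class-1: 1-.7,1-.6=[.3,.4]
        assert np.allclose(np.sort(res.cal_scores_[0]), [0.1, 0.2, 0.4])
        assert np.allclose(np.sort(res.cal_scores_[1]), [0.3, 0.4])
        res.base_ = DummyProb(np.array([[0.25, 0.75]]))
        pv = res.predict_p(np.zeros((1, 2)))
        # p_inactive: score .75 -> (0+1)/4; p_active: score .25 -> (2+1)/3
        assert pv[0, 0] == pytest.approx(1 / 4)
        assert pv[0, 1] == pytest.approx(3 / 3)

    def test_symmetric_probabilities_symmetric_pvalues(self):
        cal_p = np.array([[0.7, 0.3], [0.3, 0.7], [0.6, 0.4], [0.4, 0.6]])
        y_cal = np.array([0, 1, 0, 1])
        model = MondrianConformalClassifier.__new__(MondrianConformalClassifier)
        model.X_train, model.y_train = np.zeros((1, 2)), np.array([0, 1])
        model.X_cal, model.y_cal = np.zeros((4, 2)), y_cal
        model.base, model.spec, model.seed = DummyProb(cal_p), None, 0
        res = model.fit()
        res.base_ = DummyProb(np.array([[0.5, 0.5]]))
        pv = res.predict_p(np.zeros((1, 2)))
        assert pv[0, 0] == pytest.approx(pv[0, 1])

    def test_dimension_mismatch_errors(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.tile([0, 1], 30)
        res = fit_icp(X[:40], y[:40], X[40:], y[40:], seed=0)
        with pytest.raises(ConformalError, match="columns"):
            res.predict_p(rng.normal(size=(3, 7)))

    def test_save_load_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        res = fit_icp(X[:40], y[:40], X[40:], y[40:], seed=0)
        path = tmp_path / "model.joblib"
        res.save(path)
        loaded = ConformalResults.load(path)
        X_new = rng.normal(size=(5, 4))
        assert np.allclose(res.predict_p(X_new), loaded.predict_p(X_new))

    def test_summary_mentions_calibration(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        res = fit_icp(X[:40], y[:40], X[40:], y[40:], seed=0)
        text = res.summary()
        assert "cal active" in text and "RandomForestClassifier" in text


class TestStatisticalValidity:
    def test_classwise_error_rate_bounded(self, rng):
        # exchangeable gaussian data with overlap: errors should track epsilon
        n = 1200
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + rng.normal(0, 1.2, n) > 0).astype(int)
        tr, ca, te = np.split(rng.permutation(n), [600, 840])
        res = fit_icp(X[tr], y[tr], X[ca], y[ca], seed=0)
        pv = res.predict_p(X[te])
        for eps in (0.1, 0.2, 0.3):
            outcomes = prediction_sets(pv, eps)
            for cls in (0, 1):
                mask = y[te] == cls
                errors = np.mean([not o.contains(cls) for o in outcomes[mask]])
                se = np.sqrt(eps * (1 - eps) / mask.sum())
                assert errors <= eps + 3 * se, (eps, cls, errors)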