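"""Validity/efficiency, classical metrics and the CV experiment driver."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from hazardcp.conformal import Outcome
from hazardcp.evaluate import (
    compute_metrics,
    efficiency,
    roc_auc_from_pvalue_diff,
    run_cv_experiment,
    single_label_metrics,
    validity,
)

A, I, B, E = (Outcome.SINGLE_ACTIVE, Outcome.SINGLE_INACTIVE,
              Outcome.BOTH, Outcome.EMPTY)


class TestValidity:
    def test_counting_rule(self):
        # actives: correct iff the set contains the active class
        assert validity([A, B, I, E], [1, 1, 1, 1], 1) == pytest.approx(0.5)

    def test_both_always_correct(self):
        assert validity([B, B, B], [1, 0, 1], 1) == 1.0
        assert validity([B, B, B], [1, 0, 1], 0) == 1.0

    def test_empty_always_erroneous(self):
        assert validity([E, E], [1, 1], 1) == 0.0

    def test_absent_class_is_undefined_not_zero(self):
        assert validity([A, A], [1, 1], 0) is None


class TestEfficiency:
    def test_single_label_fraction(self):
        assert efficiency([A, B, I, A], [1, 1, 1, 1], 1) == pytest.approx(0.75)

    def test_all_both_gives_zero(self):
        assert efficiency([B, B], [0, 0], 0) == 0.0

    def test_all_singletons_gives_one(self):
        assert efficiency([A, I, I], [1, 1, 1], 1) == 1.0

    def test_counts_either_single_label(self):
        # a wrong single-label prediction still counts as efficient
        assert efficiency([I, I], [1, 1], 1) == 1.0

    def test_absent_class_undefined(self):
        assert efficiency([A], [1], 0) is None


class TestSingleLabelMetrics:
    def test_two_by_two_arithmetic(self):
        outcomes = [A] * 8 + [I] * 2 + [I] * 5 + [A] * 5
        labels = [1] * 10 + [0] * 10
        m = single_label_metrics(outcomes, labels)
        assert m["se"] == pytest.approx(0.8)
        assert m["sp"] == pytest.approx(0.5)
        assert m["ba"] == pytest.approx(0.65)
        assert m["acc"] == pytest.approx(0.65)

    def test_both_and_empty_excluded(self):
        outcomes = [A, B, E, I]
        labels = [1, 1, 0, 0]
        m = single_label_metrics(outcomes, labels)
        assert m["tp"] + m["tn"] + m["fp"] + m["fn"] == 2
        assert m["acc"] == 1.0

    def test_perfect_predictions_mcc_one(self):
        outcomes = [A] * 5 + [I] * 5
        labels = [1] * 5 + [0] * 5
        assert single_label_metrics(outcomes, labels)["mcc"] == pytest.approx(1.0)

    def test_balanced_independent_mcc_zero(self):
        outcomes = [A, I, A, I]
        labels = [1, 1, 0, 0]
        assert single_label_metrics(outcomes, labels)["mcc"] == pytest.approx(0.0)

    def test_zero_marginal_mcc_zero(self):
        assert single_label_metrics([A, A], [1, 0])["mcc"] == 0.0

    def test_no_singletons_undefined(self):
        assert single_label_metrics([B, E], [1, 0]) is None

    def test_matches_sklearn_on_random_tables(self, rng):
        for _ in range(20):
            outcomes = [[A, I][i] for i in rng.integers(0, 2, 40)]
            labels = rng.integers(0, 2, 40)
            if len(set(labels.tolist())) < 2:
                continue
            m = single_label_metrics(outcomes, labels)
            pred = [1 if o is A else 0 for o in outcomes]
            assert m["mcc"] == pytest.approx(matthews_corrcoef(labels, pred), abs=1e-12)
            assert m["acc"] == pytest.approx(np.mean(pred == labels))


class TestRocAuc:
    def test_perfect_ordering(self):
        pv = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.3]])
        assert roc_auc_from_pvalue_diff(pv, [1, 1, 0, 0]) == 1.0

    def test_all_tied_gives_half(self):
        pv = np.tile([0.5, 0.5], (6, 1))
        assert roc_auc_from_pvalue_diff(pv, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_shuffled_labels_near_half(self, rng):
        pv = rng.uniform(size=(2000, 2))
        labels = rng.integers(0, 2, 2000)
        assert roc_auc_from_pvalue_diff(pv, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_undefined(self):
        assert roc_auc_from_pvalue_diff(np.array([[0.5, 0.5]]), [1]) is None

    def test_matches_sklearn(self, rng):
        pv = rng.uniform(size=(100, 2)).round(1)  # rounding forces ties
        labels = rng.integers(0, 2, 100)
        mine = roc_auc_from_pvalue_diff(pv, labels)
        ref = roc_auc_score(labels, pv[:, 1] - pv[:, 0])
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_brute_force_pair_oracle(self, rng):
        pv = rng.uniform(size=(30, 2)).round(1)
        labels = rng.integers(0, 2, 30)
        scores = pv[:, 1] - pv[:, 0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        expected = np.mean(
            [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        )
        assert roc_auc_from_pvalue_diff(pv, labels) == pytest.approx(expected)


class TestComputeMetrics:
    def test_self_consistency(self, rng):
        outcomes = [[A, I, B, E][i] for i in rng.integers(0, 4, 60)]
        labels = rng.integers(0, 2, 60)
        m = compute_metrics(outcomes, labels)
        # outcome counts conserve the total
        assert (m["n_single_active"] + m["n_single_inactive"]
                + m["n_both"] + m["n_empty"]) == m["n_evaluated"] == 60
        if m["se"] is not None and m["sp"] is not None:
            assert m["ba"] == pytest.approx((m["se"] + m["sp"]) / 2)
        # efficiency * class size equals the recounted singletons
        for cls, key in ((1, "efficiency_active"), (0, "efficiency_inactive")):
            size = int(np.sum(labels == cls))
            singles = sum(
                1 for o, y in zip(outcomes, labels) if y == cls and o.is_single
            )
            assert round(m[key] * size) == singles


@pytest.fixture(scope="module")
def cv(small_dataset):
    records, _ = small_dataset
    return run_cv_experiment(
        records[:160],
        ["ngram_4_hashed_64", "ngram_6_hashed_64"],
        epsilons=(0.1, 0.2, 0.3),
        k=2,
        seed=4,
    )


class TestRunCVExperiment:
    def test_report_fully_populated(self, cv):
        assert set(cv.report["model"]) == {"ngram_4_hashed_64", "ngram_6_hashed_64"}
        assert cv.metric("ngram_4_hashed_64", 0.2, "n_evaluated") == 160
        for name in ("validity_active", "efficiency_inactive", "roc_auc"):
            assert cv.metric("ngram_4_hashed_64", 0.2, name) is not None

    def test_deterministic_given_seed(self, small_dataset):
        records, _ = small_dataset
        kwargs = dict(featurizer_names=["ngram_4_hashed_64"], epsilons=(0.2,), k=2, seed=9)
        a = run_cv_experiment(records[:120], **kwargs)
        b = run_cv_experiment(records[:120], **kwargs)
        assert np.array_equal(a.pvalues["ngram_4_hashed_64"],
                              b.pvalues["ngram_4_hashed_64"])
        assert a.report.equals(b.report)

    def test_predictions_frame_shape(self, cv):
        frame = cv.predictions_frame(0.2)
        assert len(frame) == 160
        assert "p_active[ngram_4_hashed_64]" in frame.columns

    def test_consensus_models_in_report(self, small_dataset):
        from hazardcp.consensus import ConsensusConfig

        records, _ = small_dataset
        cv = run_cv_experiment(
            records[:160],
            ["ngram_4_hashed_64", "ngram_6_hashed_64", "ngram_4_hashed_256"],
            epsilons=(0.2,),
            consensus_configs=[ConsensusConfig(mode="pvals", model_set="all"),
                               ConsensusConfig(mode="cls", model_set="all")],
            k=2,
            seed=4,
        )
        assert cv.metric("consensus_pvals_all", 0.2, "validity_active") is not None
        assert cv.metric("consensus_cls_all", 0.2, "ba") is not None
        outcomes = cv.outcomes("consensus_cls_all", 0.2)
        assert sum(o is not None for o in outcomes) == 160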