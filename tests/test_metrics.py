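"""Term-centric and protein-centric metric behaviour against brute-force
oracles and hand-worked examples."""

import numpy as np
import pytest

from gogcn import metrics

from oracles import (
    pairwise_auc,
    random_eval_instance,
    rankwalk_auprc,
    rankwalk_pr50,
    threshold_fmax,
    threshold_smin,
)


class TestTermAUC:
    def test_hand_example(self):
        # pairs: (0.9,0.8)+, (0.9,0.1)+, (0.7,0.8)-, (0.7,0.1)+ -> 3/4
        assert metrics.term_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert metrics.term_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_negation_flips(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        scores = rng.random(20)
        a = metrics.term_auc(labels, scores)
        assert metrics.term_auc(labels, -scores) == pytest.approx(1 - a)

    def test_ties_count_half(self):
        assert metrics.term_auc([1, 0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            metrics.term_auc([1, 1], [0.2, 0.3])

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 25))
            labels = rng.integers(0, 2, n)
            labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), 2)
            assert metrics.term_auc(labels, scores) == pytest.approx(
                pairwise_auc(labels, scores), abs=1e-12
            )

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        assert metrics.term_auc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestTermAUPRC:
    def test_hand_example(self):
        # positives at ranks 1 and 3: (1/1 + 2/3)/2 = 5/6
        assert metrics.term_auprc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(5 / 6)

    def test_perfect_ranking(self):
        assert metrics.term_auprc([1, 1, 0], [0.9, 0.8, 0.1]) == 1.0

    def test_single_positive_first(self):
        assert metrics.term_auprc([1, 0, 0], [0.9, 0.5, 0.1]) == 1.0

    def test_matches_rankwalk_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            n = int(rng.integers(2, 25))
            labels = rng.integers(0, 2, n)
            labels[0] = 1
            scores = np.round(rng.random(n), 2)
            assert metrics.term_auprc(labels, scores) == pytest.approx(
                rankwalk_auprc(list(labels), list(scores)), abs=1e-12
            )


class TestPR50:
    def test_hand_example_early_crossing(self):
        # 2 positives; rank 1 is a hit -> recall 1/2 at precision 1
        assert metrics.term_pr50([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 1.0

    def test_hand_example_late_crossing(self):
        # single positive ranked second -> recall 0.5 needs rank 2
        assert metrics.term_pr50([0, 1], [0.9, 0.1]) == 0.5

    def test_perfect_ranking(self):
        assert metrics.term_pr50([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_matches_rankwalk_oracle(self):
        rng = np.random.default_rng(44)
        for _ in range(100):
            n = int(rng.integers(2, 25))
            labels = rng.integers(0, 2, n)
            labels[0] = 1
            scores = np.round(rng.random(n), 2)
            assert metrics.term_pr50(labels, scores) == pytest.approx(
                rankwalk_pr50(list(labels), list(scores)), abs=1e-12
            )


class TestFmax:
    def test_perfect_predictions(self):
        truth = np.array([[1, 0], [0, 1]])
        f, theta = metrics.fmax(truth, truth.astype(float))
        assert f == 1.0 and 0 < theta <= 1

    def test_two_protein_hand_case(self):
        # truths P1={t1,t2}, P2={t1}; enumerating the grid gives 6/7,
        # first attained at theta just above 0.3 (and again at 0.61-0.8)
        truth = np.array([[1, 1, 0], [1, 0, 0]])
        scores = np.array([[0.9, 0.6, 0.1], [0.8, 0.7, 0.3]])
        f, theta = metrics.fmax(truth, scores)
        assert f == pytest.approx(6 / 7)

    def test_degenerate_all_zero_scores(self):
        truth = np.array([[1, 0]])
        scores = np.zeros((1, 2))
        f, theta = metrics.fmax(truth, scores, grid=np.arange(0.1, 1.01, 0.1))
        assert np.isnan(f) and np.isnan(theta)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            metrics.fmax(np.ones((1, 1)), np.ones((1, 1)), grid=[])

    def test_monotone_transform_invariance(self):
        # any strictly increasing transform leaves ranks unchanged; taking
        # the grid over the transformed scores preserves the prediction sets
        rng = np.random.default_rng(45)
        truth = (rng.random((6, 5)) < 0.4).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        scores = rng.random((6, 5))
        f1, _ = metrics.fmax(truth, scores, grid=np.unique(scores))
        transformed = scores ** 3
        f2, _ = metrics.fmax(truth, transformed, grid=np.unique(transformed))
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_matches_threshold_oracle(self):
        rng = np.random.default_rng(46)
        for _ in range(100):
            truth, scores = random_eval_instance(rng)
            got, _ = metrics.fmax(truth, scores)
            want, _ = threshold_fmax(truth.tolist(), scores.tolist(), metrics.DEFAULT_GRID)
            assert got == pytest.approx(want, abs=1e-12)

    def test_cafa_recall_matches_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(30):
            truth, scores = random_eval_instance(rng)
            got, _ = metrics.fmax(truth, scores, cafa_recall=True)
            want, _ = threshold_fmax(
                truth.tolist(), scores.tolist(), metrics.DEFAULT_GRID, cafa_recall=True
            )
            assert got == pytest.approx(want, abs=1e-12)


class TestSmin:
    def test_exact_predictions_give_zero(self):
        truth = np.array([[1, 0], [0, 1]])
        s, _ = metrics.smin(truth, truth.astype(float), np.array([0.5, 0.7]))
        assert s == 0.0

    def test_one_protein_hand_case(self):
        # truth {t1}; at theta<=0.4 both predicted: ru=0.3; between:
        # sqrt(0.3^2+0.7^2); above 0.9: mi=0.7 -> minimum 0.3
        truth = np.array([[1, 0]])
        scores = np.array([[0.4, 0.9]])
        ic = np.array([0.7, 0.3])
        s, theta = metrics.smin(truth, scores, ic)
        assert s == pytest.approx(0.3)
        assert theta <= 0.4

    def test_zero_ic_terms_contribute_nothing(self):
        truth = np.array([[1, 0]])
        scores = np.array([[0.0, 1.0]])  # fully wrong
        s, _ = metrics.smin(truth, scores, np.zeros(2))
        assert s == 0.0

    def test_equal_ic_reduces_to_fp_fn_norm(self):
        # with IC = 1 everywhere, Smin is the norm of the mean
        # false-positive and false-negative counts
        rng = np.random.default_rng(48)
        truth, scores = random_eval_instance(rng)
        ic = np.ones(truth.shape[1])
        got, _ = metrics.smin(truth, scores, ic)
        best = np.inf
        for theta in metrics.DEFAULT_GRID:
            pred = scores >= theta
            fp = (pred & (truth == 0)).sum(axis=1).mean()
            fn = (~pred & (truth == 1)).sum(axis=1).mean()
            best = min(best, np.hypot(fp, fn))
        assert got == pytest.approx(best, abs=1e-12)

    def test_matches_threshold_oracle(self):
        rng = np.random.default_rng(49)
        for _ in range(100):
            truth, scores = random_eval_instance(rng)
            ic = np.round(rng.random(truth.shape[1]), 3)
            got, _ = metrics.smin(truth, scores, ic)
            want, _ = threshold_smin(
                truth.tolist(), scores.tolist(), list(ic), metrics.DEFAULT_GRID
            )
            assert got == pytest.approx(want, abs=1e-12)


class TestEvaluatePanel:
    def test_report_fields_and_ranges(self):
        rng = np.random.default_rng(50)
        truth = (rng.random((10, 6)) < 0.4).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        truth[:, 1] = [0, 1] * 5  # guarantee one mixed column
        scores = rng.random((10, 6))
        report = metrics.evaluate(truth, scores, np.full(6, 0.5))
        for value in (report.auc, report.auprc, report.pr50, report.fmax):
            assert 0.0 <= value <= 1.0
        assert report.smin >= 0.0
        assert report.n_proteins == 10 and report.n_terms == 6
        assert "Fmax" in report.summary()

    def test_degenerate_terms_are_skipped(self):
        truth = np.array([[1, 1, 0], [1, 0, 1]])  # first column constant 1
        scores = np.random.default_rng(0).random((2, 3))
        report = metrics.evaluate(truth, scores, np.ones(3))
        assert report.n_terms_scored == 2
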