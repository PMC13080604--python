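"""Screening metrics against brute-force and sklearn oracles."""

import numpy as np
import pytest

from vibroscreen.metrics import (BinaryConfusion, binary_metrics, bootstrap_ci,
                                 combine_or, confusion_from_predictions,
                                 decision_curve, gain_report, macro_f1,
                                 roc_auc)


def pair_counting_auc(scores, labels):
    """O(n²) Mann–Whitney oracle: P(positive outranks negative), ties 1/2."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBinaryMetrics:
    @pytest.mark.parametrize("cm,sens,spec,prec,f1", [
        (BinaryConfusion(70, 24, 3, 1), 0.959, 0.040, 0.745, 0.838),
        (BinaryConfusion(61, 14, 12, 11), 0.836, 0.440, 0.813, 0.824),
        (BinaryConfusion(24, 26, 28, 20), 0.462, 0.435, 0.480, 0.471),
    ])
    def test_reference_matrices(self, cm, sens, spec, prec, f1):
        m = binary_metrics(cm)
        assert round(m["sensitivity"], 3) == sens
        assert round(m["specificity"], 3) == spec
        assert round(m["precision"], 3) == prec
        assert round(m["f1"], 3) == f1

    def test_all_correct_is_one(self):
        m = binary_metrics(BinaryConfusion(10, 0, 0, 10))
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity",
                                         "precision", "f1"))

    def test_zero_denominators_reported_undefined(self):
        m = binary_metrics(BinaryConfusion(tp=0, fp=0, fn=5, tn=5))
        assert m["precision"] is None
        m2 = binary_metrics(BinaryConfusion(tp=5, fp=0, fn=5, tn=0))
        assert m2["specificity"] is None

    def test_f1_is_harmonic_mean_of_own_precision_recall(self, rng):
        for _ in range(25):
            counts = rng.integers(1, 50, size=4)
            m = binary_metrics(BinaryConfusion(*counts))
            hm = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
            assert abs(m["f1"] - hm) < 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            BinaryConfusion(-1, 0, 0, 5)


class TestCombineOr:
    def test_or_identity_with_all_negative(self, rng):
        a = rng.random(30) < 0.5
        assert (combine_or(a, np.zeros(30, bool)) == a).all()

    def test_misaligned_ids_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            combine_or([1, 0], [0, 1], ids_a=["a", "b"], ids_b=["b", "a"])

    def test_dominance_over_random_datasets(self, rng):
        """OR-combination never loses sensitivity nor gains specificity."""
        for _ in range(100):
            n = int(rng.integers(20, 80))
            gold = rng.random(n) < rng.uniform(0.2, 0.8)
            if gold.all() or not gold.any():
                continue
            a = rng.random(n) < rng.uniform(0.2, 0.8)
            b = rng.random(n) < rng.uniform(0.2, 0.8)
            mo = binary_metrics(confusion_from_predictions(combine_or(a, b), gold))
            ma = binary_metrics(confusion_from_predictions(a, gold))
            mb = binary_metrics(confusion_from_predictions(b, gold))
            assert mo["sensitivity"] >= max(ma["sensitivity"], mb["sensitivity"])
            assert mo["specificity"] <= min(ma["specificity"], mb["specificity"])


class TestMacroF1:
    def test_perfect_diagonal(self):
        macro, per_class = macro_f1(np.diag([5, 7, 3]))
        assert macro == 1.0 and (per_class == 1.0).all()

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import f1_score

        for _ in range(20):
            c = rng.integers(0, 8, size=(3, 3))
            if c.sum() == 0 or (c.sum(axis=1) + c.sum(axis=0) == 0).any():
                continue
            y_true = np.repeat(np.arange(9) // 3, c.ravel())
            y_pred = np.repeat(np.arange(9) % 3, c.ravel())
            macro, _ = macro_f1(c)
            assert macro == pytest.approx(
                f1_score(y_true, y_pred, average="macro", zero_division=0))

    def test_absent_class_contributes_zero_with_warning(self):
        c = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="class 2"):
            macro, per_class = macro_f1(c)
        assert per_class[2] == 0.0
        assert macro == pytest.approx(2 / 3)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            macro_f1(np.zeros((3, 3)))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 100))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12)

    def test_null_scores_give_chance_auc(self, rng):
        aucs = [roc_auc(rng.normal(size=500), rng.random(500) < 0.5)
                for _ in range(20)]
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(np.exp(scores), labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestBootstrapCi:
    def test_degenerate_data_zero_width(self):
        x = np.full(30, 0.7)
        low, high, _ = bootstrap_ci(lambda a: a.mean(), (x,), b=200, seed=0)
        assert low == high == pytest.approx(0.7)

    def test_same_seed_identical(self, rng):
        x = rng.normal(size=50)
        a = bootstrap_ci(lambda v: v.mean(), (x,), b=300, seed=4)
        b = bootstrap_ci(lambda v: v.mean(), (x,), b=300, seed=4)
        assert a == b

    def test_interval_covers_true_auc(self, rng):
        """Nested simulation: ~95% interval covers truth in 90–99% of runs."""
        # truth: scores = labels + N(0,1) with d=1 => AUC = Phi(1/sqrt(2))
        from scipy.stats import norm

        true_auc = norm.cdf(1 / np.sqrt(2))
        covered = 0
        n_sets = 200
        for _ in range(n_sets):
            labels = rng.random(80) < 0.5
            scores = labels + rng.normal(size=80)
            low, high, _ = bootstrap_ci(roc_auc, (scores, labels), b=300,
                                        seed=int(rng.integers(2**31 - 1)),
                                        stratify=labels)
            covered += low <= true_auc <= high
        assert 0.90 <= covered / n_sets <= 0.99

    def test_too_few_repetitions_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda a: a.mean(), (np.ones(5),), b=50, seed=0)


class TestDecisionCurve:
    def test_treat_none_is_zero_and_treat_all_closed_form(self, rng):
        probs = rng.random(60)
        labels = rng.random(60) < 0.3
        dc = decision_curve(probs, labels)
        assert (dc["treat_none"] == 0).all()
        prev = labels.mean()
        pt = dc["thresholds"]
        np.testing.assert_allclose(dc["treat_all"],
                                   prev - (1 - prev) * pt / (1 - pt))

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        labels = np.array([0, 0, 1, 1, 1])
        dc = decision_curve(labels.astype(float), labels)
        np.testing.assert_allclose(dc["net_benefit"], labels.mean())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            decision_curve([0.5], [1], pt_grid=[])


class TestGainReport:
    def test_anxiety_recall_gain_is_fifty_percent(self):
        single = binary_metrics(BinaryConfusion(24, 26, 28, 20))
        combined = binary_metrics(BinaryConfusion(36, 34, 16, 12))
        gains = gain_report(single, combined)
        assert gains["recall"] == pytest.approx(50.0)

    def test_depression_recall_gain(self):
        single = binary_metrics(BinaryConfusion(61, 14, 12, 11))
        combined = binary_metrics(BinaryConfusion(72, 25, 1, 0))
        # 61/73 -> 72/73 is a relative gain of 11/61
        assert gain_report(single, combined)["recall"] == pytest.approx(
            11 / 61 * 100)

    def test_identical_metrics_zero_gain(self):
        m = binary_metrics(BinaryConfusion(5, 5, 5, 5))
        assert all(v == 0 for v in gain_report(m, m).values() if v is not None)

    def test_zero_baseline_undefined(self):
        single = binary_metrics(BinaryConfusion(tp=0, fp=3, fn=5, tn=2))
        combined = binary_metrics(BinaryConfusion(tp=2, fp=3, fn=3, tn=2))
        assert gain_report(single, combined)["sensitivity"] is None
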