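import numpy as np
import pytest

import slimscan as ss
from slimscan.evaluation import (
    EvalConfig,
    composition_summary,
    confusion_metrics,
    cross_validate,
    roc_auc,
    select_threshold,
)


def mann_whitney_auc(scores, labels):
    """Brute-force pair-counting AUC oracle (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_low_sensitivity_instance_matcher_arithmetic(self):
        # 20 of 115 positives recovered, no false positives
        m = confusion_metrics(TP=20, TN=425, FP=0, FN=95)
        assert round(m.sensitivity, 4) == 0.1739
        assert m.specificity == 1.0

    def test_perfect_classifier(self):
        m = confusion_metrics(TP=10, TN=10, FP=0, FN=0)
        assert m.accuracy == 1.0 and m.mcc == 1.0

    def test_degenerate_mcc_is_zero(self):
        m = confusion_metrics(TP=10, TN=0, FP=10, FN=0)
        assert m.mcc == 0.0

    def test_undefined_sensitivity_or_specificity_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(TP=0, TN=5, FP=5, FN=0)
        with pytest.raises(ValueError):
            confusion_metrics(TP=5, TN=0, FP=0, FN=5)
        with pytest.raises(ValueError):
            confusion_metrics(TP=-1, TN=5, FP=5, FN=5)

    def test_mcc_symmetric_under_class_and_prediction_swap(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            a = confusion_metrics(int(tp), int(tn), int(fp), int(fn)).mcc
            b = confusion_metrics(int(tn), int(tp), int(fn), int(fp)).mcc
            assert a == pytest.approx(b, abs=1e-12)

    def test_percent_reporting(self):
        d = confusion_metrics(TP=20, TN=425, FP=0, FN=95).as_dict(percent=True)
        assert d["specificity"] == 100.0
        assert d["sensitivity"] == pytest.approx(17.39, abs=0.005)


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([3.0, 2.0, -1.0, -2.0], [1, 1, -1, -1])
        assert r.auc == 1.0

    def test_all_tied_scores(self):
        r = roc_auc([1.0, 1.0, 1.0, 1.0], [1, 1, -1, -1])
        assert r.auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = 50
            scores = rng.normal(size=n).round(1)  # rounding forces ties
            labels = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=80)
        labels = np.where(rng.random(80) < 0.4, 1, -1)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.5, 1, -1)
        r = roc_auc(scores, labels)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


class TestSelectThreshold:
    def test_singleton_grid(self):
        assert select_threshold([1.0, -1.0], [1, -1], [0.3]) == 0.3

    def test_separable_picks_largest_in_gap(self):
        scores = [2.0, 1.5, -1.5, -2.0]
        labels = [1, 1, -1, -1]
        grid = [-1.0, 0.0, 1.0, 1.75]  # all but 1.75 sit in the gap... 1.0 too
        t = select_threshold(scores, labels, grid)
        assert t == 1.0  # accuracy 1.0 attained on [-1.5.. 1.5); largest such

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([1.0], [1], [])

    def test_oracle_recheck(self, rng):
        scores = rng.normal(size=100)
        labels = np.where(rng.random(100) < 0.3, 1, -1)
        grid = np.linspace(-2, 2, 21)
        t = select_threshold(scores, labels, grid)

        def acc(th):
            return np.mean(np.where(scores >= th, 1, -1) == labels)

        assert all(acc(g) <= acc(t) + 1e-12 for g in grid)


class TestCrossValidate:
    def test_every_example_scored_once(self, sh3_bundle):
        r = cross_validate(sh3_bundle, "PSSM", seed=0)
        assert r.metrics.total == sh3_bundle.n_pos + sh3_bundle.n_neg

    def test_same_seed_identical(self, sh3_bundle):
        a = cross_validate(sh3_bundle, "PSSM", seed=4)
        b = cross_validate(sh3_bundle, "PSSM", seed=4)
        assert a.metrics.as_dict() == b.metrics.as_dict()
        assert np.array_equal(a.scores, b.scores)

    def test_binary_methods_have_no_roc(self, sh3_bundle):
        assert cross_validate(sh3_bundle, "RES").roc is None
        assert cross_validate(sh3_bundle, "MIM").roc is None

    def test_unknown_method_rejected(self, sh3_bundle):
        with pytest.raises(ValueError):
            cross_validate(sh3_bundle, "BLAST")

    def test_mim_specificity_perfect_on_disjoint_bundle(self, sh3_bundle):
        r = cross_validate(sh3_bundle, "MIM", seed=0)
        assert r.metrics.specificity == 1.0


class TestCompositionSummary:
    def test_single_proline_peptide(self):
        df = composition_summary({"SH3": ["PPPPPP"]})
        assert df.loc["SH3", "P"] == 100.0

    def test_identical_classes_identical_rows(self):
        df = composition_summary({"a": ["PAYPAY"], "b": ["PAYPAY"]})
        assert np.array_equal(df.loc["a"].values, df.loc["b"].values)

    def test_planted_proline_enrichment_vs_background(self, benchmark_bundles):
        sh3 = benchmark_bundles["SH3"]
        background = [
            e for e in sh3.negatives if e.domain_class == "background"
        ]
        df = composition_summary({"SH3": sh3.positives, "bg": background})
        assert df.loc["SH3", "P"] > df.loc["bg", "P"]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            composition_summary({"a": []})
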