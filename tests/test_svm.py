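import numpy as np
import pytest
from sklearn.svm import SVC

import slimscan as ss
from slimscan.datasets import DatasetBundle, LigandEntry, make_folds
from slimscan.features import scheme_from_positives
from slimscan.predictors.svm import (
    _bundle_matrix,
    _scale,
    load_model,
    save_model,
    svm_decision,
    svm_decision_many,
    svm_train,
    tune_hyperparameters,
)


@pytest.fixture(scope="module")
def separable_bundle():
    """Planted motif at full strength vs uniform background: linearly
    separable in composition space."""
    spec = ss.GeneratorSpec(domain_class="SH3", n_pos=40, signal_strength=1.0, seed=5)
    pos = ss.generate_class(spec)
    records = ss.generate_background_records(n=10, seed=6)
    neg = [
        LigandEntry(e.sequence, "background", e.protein_id, e.start, e.is_c_terminal)
        for e in ss.sample_background(records, 40, 6, seed=7)
    ]
    return DatasetBundle("SH3", pos, neg, balance_mode="balanced")


@pytest.fixture(scope="module")
def scheme(separable_bundle):
    return scheme_from_positives(
        ("AAC", "DPC", "TPC"), (e.sequence for e in separable_bundle.positives)
    )


class TestTrain:
    def test_training_accuracy_on_separable_data(self, separable_bundle, scheme):
        model = svm_train(separable_bundle, scheme, seed=0)
        entries = separable_bundle.entries()
        scores = svm_decision_many(model, [e.sequence for e in entries])
        pred = np.where(scores >= 0.0, 1, -1)
        assert np.mean(pred == separable_bundle.labels()) >= 0.95

    def test_training_positive_scores_positive(self, separable_bundle, scheme):
        model = svm_train(separable_bundle, scheme, seed=0)
        pep = separable_bundle.positives[0]
        assert svm_decision(model, pep.sequence) > 0.0

    def test_retraining_is_deterministic(self, separable_bundle, scheme):
        a = svm_train(separable_bundle, scheme, seed=0)
        b = svm_train(separable_bundle, scheme, seed=0)
        queries = [e.sequence for e in separable_bundle.entries()[:20]]
        assert np.array_equal(
            svm_decision_many(a, queries), svm_decision_many(b, queries)
        )

    def test_single_class_rejected(self, separable_bundle, scheme):
        bad = DatasetBundle("SH3", separable_bundle.positives, [])
        with pytest.raises(ValueError):
            svm_train(bad, scheme)

    def test_unbalanced_cost_factor_defaults_to_class_ratio(self, sh3_bundle):
        sch = scheme_from_positives(
            ("AAC",), (e.sequence for e in sh3_bundle.positives)
        )
        model = svm_train(sh3_bundle, sch, seed=0)
        assert model.cost_factor == pytest.approx(425 / 115)

    def test_length_mismatch_rejected(self, separable_bundle, scheme):
        model = svm_train(separable_bundle, scheme, seed=0)
        with pytest.raises(ValueError):
            svm_decision(model, "PPPP")


class TestThreshold:
    def test_changing_threshold_never_retrains(self, separable_bundle, scheme):
        model = svm_train(separable_bundle, scheme, seed=0)
        strict = model.with_threshold(2.0)
        assert strict.clf is model.clf
        assert strict.threshold == 2.0

    def test_raising_threshold_is_antimonotone_in_calls(
        self, separable_bundle, scheme
    ):
        model = svm_train(separable_bundle, scheme, seed=0)
        queries = [e.sequence for e in separable_bundle.entries()]
        scores = svm_decision_many(model, queries)
        n_calls = [int(np.sum(scores >= t)) for t in (-1.0, 0.0, 0.5, 2.0)]
        assert n_calls == sorted(n_calls, reverse=True)


class TestTune:
    def test_singleton_grid(self, separable_bundle, scheme):
        assert tune_hyperparameters(
            separable_bundle, scheme, grid=[(0.5, 2.0)], n_folds=3
        ) == (0.5, 2.0)

    def test_duplicate_points_keep_first(self, separable_bundle, scheme):
        out = tune_hyperparameters(
            separable_bundle, scheme, grid=[(0.5, 2.0), (0.5, 2.0)], n_folds=3
        )
        assert out == (0.5, 2.0)

    def test_empty_grid_rejected(self, separable_bundle, scheme):
        with pytest.raises(ValueError):
            tune_hyperparameters(separable_bundle, scheme, grid=[])

    def test_selected_point_maximizes_cv_accuracy(self, separable_bundle, scheme):
        """Exhaustive re-evaluation: no grid point beats the winner."""
        grid = [(g, c) for g in (0.125, 0.5) for c in (1.0, 8.0)]
        winner = tune_hyperparameters(
            separable_bundle, scheme, grid=grid, n_folds=3, seed=1
        )
        X, y = _bundle_matrix(separable_bundle, scheme)
        Xs = _scale(X, scheme)
        folds = make_folds(separable_bundle, n_folds=3, seed=1)

        def cv_acc(gamma, C):
            accs = []
            for k in range(3):
                tr, te = folds.train_indices(k), folds.test_indices(k)
                clf = SVC(kernel="rbf", gamma=gamma, C=C,
                          class_weight={1: 1.0, -1: 1.0}, random_state=1)
                clf.fit(Xs[tr], y[tr])
                accs.append(np.mean(
                    np.where(clf.decision_function(Xs[te]) >= 0, 1, -1) == y[te]
                ))
            return np.mean(accs)

        best = cv_acc(*winner)
        assert all(cv_acc(g, c) <= best + 1e-12 for g, c in grid)


class TestModelIO:
    def test_roundtrip_preserves_decisions(self, tmp_path, separable_bundle, scheme):
        model = svm_train(separable_bundle, scheme, seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        queries = [e.sequence for e in separable_bundle.entries()[:10]]
        assert np.array_equal(
            svm_decision_many(model, queries), svm_decision_many(back, queries)
        )
        assert back.scheme == model.scheme
        assert back.threshold == model.threshold
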