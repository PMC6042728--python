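"""RBF-kernel support vector machine over compositional features.

The classifier is a standard soft-margin SVM with a radial basis
function kernel, trained on the percentage-composition encoding of the
peptides (AAC/DPC/TPC blocks plus the PDZ C-terminal flag).  Before the
kernel is applied the percentage blocks are rescaled from [0, 100] to
[0, 1] — the customary normalization for RBF kernels, which puts the
default hyperparameter grid (kernel width gamma in 2^-7..2^3,
regularization C in 2^-3..2^7) on a useful scale.  The binary CTERM
flag is left as is.

Class imbalance (the unbalanced union negative sets are roughly 2-4x
the positives) is handled with a cost factor on the positive class
proportional to n_neg / n_pos.

The decision threshold is a free post-hoc parameter (default 0.00: any
positive margin is a call); changing it never retrains the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from ..datasets import DatasetBundle, make_folds
from ..features import FeatureScheme, encode, encode_many

#: Default hyperparameter grid: (kernel width gamma, regularization C).
DEFAULT_GRID: tuple[tuple[float, float], ...] = tuple(
    (2.0**g, 2.0**c) for g in range(-7, 4) for c in range(-3, 8)
)

_DEFAULT_GAMMA = 2.0**-2
_DEFAULT_C = 2.0**3


@dataclass
class SVMModel:
    """A trained RBF-kernel SVM for one domain class."""

    domain_class: str
    scheme: FeatureScheme
    gamma: float
    C: float
    cost_factor: float
    threshold: float
    n_pos: int
    n_neg: int
    clf: SVC

    def with_threshold(self, threshold: float) -> "SVMModel":
        """Same trained model at a different operating threshold."""
        return replace(self, threshold=threshold)


def _scale(X: np.ndarray, scheme: FeatureScheme) -> np.ndarray:
    X = np.asarray(X, dtype=float) / 100.0
    if "CTERM" in scheme.components:
        sl = scheme.block_slices()["CTERM"]
        X = X.copy()
        X[:, sl] *= 100.0
    return X


def _bundle_matrix(bundle: DatasetBundle, scheme: FeatureScheme):
    entries = bundle.entries()
    X = encode_many(
        [e.sequence for e in entries], scheme, [e.is_c_terminal for e in entries]
    )
    return X, bundle.labels()


def svm_train(
    bundle: DatasetBundle,
    scheme: FeatureScheme,
    gamma: float = _DEFAULT_GAMMA,
    C: float = _DEFAULT_C,
    cost_factor: float | None = None,
    threshold: float = 0.0,
    seed: int = 0,
) -> SVMModel:
    """Fit an RBF-kernel SVM on a dataset bundle.

    ``cost_factor`` weights positive-class errors; by default it is
    ``n_neg / n_pos`` for unbalanced bundles and 1 for balanced ones.
    Training is deterministic for fixed data order and seed.
    """
    if bundle.n_pos == 0 or bundle.n_neg == 0:
        raise ValueError("training requires examples of both classes")
    if cost_factor is None:
        cost_factor = (
            bundle.n_neg / bundle.n_pos if bundle.balance_mode == "unbalanced" else 1.0
        )
    X, y = _bundle_matrix(bundle, scheme)
    clf = SVC(
        kernel="rbf",
        gamma=gamma,
        C=C,
        class_weight={1: cost_factor, -1: 1.0},
        random_state=seed,
    )
    clf.fit(_scale(X, scheme), y)
    return SVMModel(
        domain_class=bundle.domain_class,
        scheme=scheme,
        gamma=gamma,
        C=C,
        cost_factor=cost_factor,
        threshold=threshold,
        n_pos=bundle.n_pos,
        n_neg=bundle.n_neg,
        clf=clf,
    )


def _check_window_length(model: SVMModel, peptides: Sequence[str]) -> None:
    from ..domains import DOMAINS

    spec = DOMAINS.get(model.domain_class)
    if spec is None:
        return
    for pep in peptides:
        if len(pep) != spec.window_length:
            raise ValueError(
                f"peptide {pep!r} has length {len(pep)}; the {spec.name} "
                f"model expects {spec.window_length}-mers"
            )


def svm_decision(model: SVMModel, peptide: str, is_c_terminal: bool = False) -> float:
    """Real-valued margin score for one peptide; classification is
    ``score >= model.threshold`` (boundary inclusive)."""
    _check_window_length(model, [peptide])
    x = encode(peptide, model.scheme, is_c_terminal)[None, :]
    return float(model.clf.decision_function(_scale(x, model.scheme))[0])


def svm_decision_many(
    model: SVMModel,
    peptides: Sequence[str],
    is_c_terminal: Sequence[bool] | None = None,
) -> np.ndarray:
    """Margin scores for a batch of peptides."""
    _check_window_length(model, peptides)
    X = encode_many(peptides, model.scheme, is_c_terminal)
    return model.clf.decision_function(_scale(X, model.scheme))


def svm_classify(model: SVMModel, peptide: str, is_c_terminal: bool = False) -> bool:
    return svm_decision(model, peptide, is_c_terminal) >= model.threshold


def tune_hyperparameters(
    bundle: DatasetBundle,
    scheme: FeatureScheme,
    grid: Iterable[tuple[float, float]] = DEFAULT_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Pick the (gamma, C) grid point maximizing mean cross-validated
    accuracy at threshold 0.  Ties break toward smaller C, then smaller
    gamma; exact duplicates keep the first in iteration order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X, y = _bundle_matrix(bundle, scheme)
    Xs = _scale(X, scheme)
    folds = make_folds(bundle, n_folds=n_folds, seed=seed)
    cost = bundle.n_neg / bundle.n_pos if bundle.balance_mode == "unbalanced" else 1.0

    best: tuple[float, float] | None = None
    best_acc = -np.inf
    for gamma, C in grid:
        accs = []
        for k in range(n_folds):
            tr, te = folds.train_indices(k), folds.test_indices(k)
            clf = SVC(
                kernel="rbf", gamma=gamma, C=C,
                class_weight={1: cost, -1: 1.0}, random_state=seed,
            )
            clf.fit(Xs[tr], y[tr])
            pred = np.where(clf.decision_function(Xs[te]) >= 0.0, 1, -1)
            accs.append(float(np.mean(pred == y[te])))
        acc = float(np.mean(accs))
        if (
            best is None
            or acc > best_acc
            or (acc == best_acc and (C, gamma) < (best[1], best[0]))
        ):
            best, best_acc = (gamma, C), acc
    assert best is not None
    return best


def save_model(model: SVMModel, path: str | Path) -> None:
    """Serialize a model bundle (scheme, tripeptide list, kernel
    parameters, fitted classifier, threshold) to one portable file."""
    joblib.dump(
        {
            "format": "slimscan-svm-1",
            "domain_class": model.domain_class,
            "components": model.scheme.components,
            "tripeptides": model.scheme.tripeptides,
            "gamma": model.gamma,
            "C": model.C,
            "cost_factor": model.cost_factor,
            "threshold": model.threshold,
            "n_pos": model.n_pos,
            "n_neg": model.n_neg,
            "clf": model.clf,
        },
        path,
    )


def load_model(path: str | Path) -> SVMModel:
    blob = joblib.load(path)
    if blob.get("format") != "slimscan-svm-1":
        raise ValueError(f"{path} is not a recognized model bundle")
    return SVMModel(
        domain_class=blob["domain_class"],
        scheme=FeatureScheme(
            components=tuple(blob["components"]),
            tripeptides=tuple(blob["tripeptides"]),
        ),
        gamma=blob["gamma"],
        C=blob["C"],
        cost_factor=blob["cost_factor"],
        threshold=blob["threshold"],
        n_pos=blob["n_pos"],
        n_neg=blob["n_neg"],
        clf=blob["clf"],
    )
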