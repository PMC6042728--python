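"""Performance evaluation: confusion-matrix metrics, ROC/AUC, operating
threshold selection, the five-fold cross-validation harness, and
per-class composition summaries.

Metrics follow the standard definitions: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy (TP+TN)/total, and the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

on [-1, 1], with MCC defined as 0 whenever a denominator factor is 0.
Cross-validation pools (micro-averages) the confusion counts of the
five test folds; continuous methods (SVM, PSSM) additionally yield a
pooled ROC curve and its trapezoidal AUC.  Everything learned from
data — the SVM model, the tripeptide selection behind its TPC block,
and the PSSM counts — is recomputed inside each training fold, so test
peptides never influence the feature space or the matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .alphabet import AMINO_ACIDS
from .datasets import DatasetBundle, LigandEntry, make_folds
from .domains import get_domain
from .features import aac, scheme_from_positives, FeatureScheme
from .predictors import (
    InstanceLibrary,
    RegexLibrary,
    build_pssm,
    default_regex_library,
    mim_classify,
    pssm_score,
    res_classify,
)
from .predictors.svm import svm_decision_many, svm_train


@dataclass
class MetricsReport:
    """Confusion counts and the derived threshold metrics."""

    TP: int
    TN: int
    FP: int
    FN: int
    threshold: float | None = None

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.total

    @property
    def mcc(self) -> float:
        tp, tn, fp, fn = self.TP, self.TN, self.FP, self.FN
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            return 0.0
        return (tp * tn - fp * fn) / math.sqrt(denom)

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        d = {
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "sensitivity": self.sensitivity * scale,
            "specificity": self.specificity * scale,
            "accuracy": self.accuracy * scale,
            "MCC": self.mcc,
        }
        if self.threshold is not None:
            d["threshold"] = self.threshold
        return d


@dataclass
class ROCResult:
    """A ROC curve (FPR/TPR points over all score thresholds) and its
    trapezoidal AUC, which equals the probability that a random positive
    outscores a random negative, ties counting one half."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class CVResult:
    """Pooled five-fold cross-validation output for one method."""

    method: str
    metrics: MetricsReport
    roc: ROCResult | None
    scores: np.ndarray
    labels: np.ndarray


def confusion_metrics(
    TP: int, TN: int, FP: int, FN: int, threshold: float | None = None
) -> MetricsReport:
    """Validate counts and wrap them in a :class:`MetricsReport`.

    Requires at least one actual positive and one actual negative, since
    sensitivity and specificity are otherwise undefined.
    """
    for name, v in (("TP", TP), ("TN", TN), ("FP", FP), ("FN", FN)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if TP + FN == 0:
        raise ValueError("no actual positives: sensitivity undefined")
    if TN + FP == 0:
        raise ValueError("no actual negatives: specificity undefined")
    return MetricsReport(TP=TP, TN=TN, FP=FP, FN=FN, threshold=threshold)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve and trapezoidal AUC from continuous scores and ±1 labels."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(np.sign(labels).tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(labels, scores, pos_label=1)
    return ROCResult(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def select_threshold(
    scores: Sequence[float], labels: Sequence[int], grid: Sequence[float]
) -> float:
    """Grid value maximizing accuracy of ``score >= t``; ties break toward
    higher specificity, then toward the larger threshold."""
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best_t = None
    best_key = None
    for t in grid:
        pred = np.where(scores >= t, 1, -1)
        acc = float(np.mean(pred == labels))
        neg = labels == -1
        spec = float(np.mean(pred[neg] == -1)) if neg.any() else 0.0
        key = (acc, spec, t)
        if best_key is None or key > best_key:
            best_key, best_t = key, t
    return float(best_t)


@dataclass
class EvalConfig:
    """Per-method settings for :func:`cross_validate`.

    ``scheme_components`` names the SVM feature blocks (domain default if
    ``None``); the TPC selection itself is always refit per training
    fold.  ``instance_library=None`` makes MIM use each training fold's
    positives as its library, mirroring how the known-instance list and
    the training set derive from the same collection.
    """

    scheme_components: tuple[str, ...] | None = None
    gamma: float | None = None
    C: float | None = None
    svm_threshold: float = 0.0
    pssm_mode: str = "background_odds"
    pssm_threshold: float | None = None
    regex_library: RegexLibrary | None = None
    instance_library: InstanceLibrary | None = None


def _counts(pred: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == -1) & (y == -1)))
    fp = int(np.sum((pred == 1) & (y == -1)))
    fn = int(np.sum((pred == -1) & (y == 1)))
    return tp, tn, fp, fn


def cross_validate(
    bundle: DatasetBundle,
    method: str,
    config: EvalConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Five-fold cross-validation of one method on one bundle.

    Each example is scored exactly once, as a member of its test fold;
    confusion counts are pooled across folds.  SVM and PSSM return a
    pooled ROC as well; RES and MIM are binary (match / no match) and
    produce none.
    """
    if method not in ("SVM", "PSSM", "RES", "MIM"):
        raise ValueError(f"unknown method {method!r}")
    config = config or EvalConfig()
    spec = get_domain(bundle.domain_class)
    entries = bundle.entries()
    y = bundle.labels()
    folds = make_folds(bundle, n_folds=n_folds, seed=seed)

    scores = np.zeros(len(entries))
    preds = np.zeros(len(entries), dtype=int)
    threshold: float | None

    if method == "SVM":
        threshold = config.svm_threshold
        components = config.scheme_components or spec.feature_components
        for k in range(n_folds):
            tr, te = folds.train_indices(k), folds.test_indices(k)
            train_pos = [entries[i] for i in tr if y[i] == 1]
            scheme = scheme_from_positives(components, (e.sequence for e in train_pos))
            sub = DatasetBundle(
                domain_class=bundle.domain_class,
                positives=[entries[i] for i in tr if y[i] == 1],
                negatives=[entries[i] for i in tr if y[i] == -1],
                balance_mode=bundle.balance_mode,
            )
            kwargs = {}
            if config.gamma is not None:
                kwargs["gamma"] = config.gamma
            if config.C is not None:
                kwargs["C"] = config.C
            model = svm_train(sub, scheme, seed=seed, **kwargs)
            s = svm_decision_many(
                model,
                [entries[i].sequence for i in te],
                [entries[i].is_c_terminal for i in te],
            )
            scores[te] = s
            preds[te] = np.where(s >= threshold, 1, -1)
    elif method == "PSSM":
        threshold = (
            config.pssm_threshold
            if config.pssm_threshold is not None
            else spec.pssm_threshold
        )
        for k in range(n_folds):
            tr, te = folds.train_indices(k), folds.test_indices(k)
            matrix = build_pssm(
                [entries[i].sequence for i in tr if y[i] == 1],
                L=spec.window_length,
                mode=config.pssm_mode,
                domain_class=spec.name,
            )
            s = np.array([pssm_score(matrix, entries[i].sequence) for i in te])
            scores[te] = s
            preds[te] = np.where(s >= threshold, 1, -1)
    elif method == "RES":
        threshold = None
        library = config.regex_library or default_regex_library(spec.name)
        for i, e in enumerate(entries):
            hit = res_classify(e.sequence, library, is_c_terminal=e.is_c_terminal)
            preds[i] = 1 if hit else -1
            scores[i] = 1.0 if hit else 0.0
    else:  # MIM
        threshold = None
        if config.instance_library is not None:
            for i, e in enumerate(entries):
                hit = mim_classify(e.sequence, config.instance_library)
                preds[i] = 1 if hit else -1
                scores[i] = 1.0 if hit else 0.0
        else:
            for k in range(n_folds):
                tr, te = folds.train_indices(k), folds.test_indices(k)
                library = InstanceLibrary(
                    domain_class=spec.name,
                    instances=frozenset(
                        entries[i].sequence for i in tr if y[i] == 1
                    ),
                )
                for i in te:
                    hit = mim_classify(entries[i].sequence, library)
                    preds[i] = 1 if hit else -1
                    scores[i] = 1.0 if hit else 0.0

    metrics = confusion_metrics(*_counts(preds, y), threshold=threshold)
    roc = roc_auc(scores, y) if method in ("SVM", "PSSM") else None
    return CVResult(method=method, metrics=metrics, roc=roc, scores=scores, labels=y)


def composition_summary(
    class_sets: Mapping[str, Sequence[str | LigandEntry]]
) -> pd.DataFrame:
    """Mean amino-acid composition per peptide class.

    Returns a DataFrame with one row per class and one column per
    residue (alphabetical), entries in percent.  SH3/WW ligand classes
    show up as proline-enriched rows, PDZ as S/T/V/E-enriched, relative
    to a uniform background class.
    """
    if not class_sets:
        raise ValueError("no classes given")
    rows = {}
    for name, peptides in class_sets.items():
        if len(peptides) == 0:
            raise ValueError(f"class {name!r} is empty")
        seqs = [p.sequence if isinstance(p, LigandEntry) else p for p in peptides]
        rows[name] = np.mean([aac(s) for s in seqs], axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(AMINO_ACIDS))
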