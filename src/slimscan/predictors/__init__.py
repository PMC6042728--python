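"""The four prediction strategies for domain-binding peptides.

- :mod:`.svm` — RBF-kernel support vector machine over compositional
  features (continuous decision score).
- :mod:`.pssm` — frequency position-specific scoring matrix scoring
  (continuous score, product of per-position frequencies).
- :mod:`.matchers` — regular-expression scanning (RES) and exact
  motif-instance matching (MIM), both binary.
"""

from __future__ import annotations

from dataclasses import dataclass

METHODS = ("SVM", "PSSM", "RES", "MIM")


@dataclass(frozen=True)
class PredictionHit:
    """One positive call by one method.

    ``score`` is present for the continuous methods (SVM, PSSM);
    ``matched`` carries the regex text (RES) or the matched known
    instance (MIM).  Coordinates are 1-based inclusive in the parent.
    """

    method: str
    parent_id: str
    start: int
    end: int
    sequence: str
    score: float | None = None
    matched: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if (self.score is not None) != (self.method in ("SVM", "PSSM")):
            raise ValueError("score must be present iff method is SVM or PSSM")


from .pssm import PSSMatrix, build_pssm, pssm_classify, pssm_score  # noqa: E402
from .matchers import (  # noqa: E402
    InstanceLibrary,
    RegexLibrary,
    default_regex_library,
    load_instance_library,
    load_regex_library,
    mim_classify,
    mim_match,
    res_classify,
    res_scan,
)
from .svm import (  # noqa: E402
    SVMModel,
    load_model,
    save_model,
    svm_decision,
    svm_train,
    tune_hyperparameters,
)

__all__ = [
    "METHODS",
    "PredictionHit",
    "PSSMatrix",
    "build_pssm",
    "pssm_score",
    "pssm_classify",
    "RegexLibrary",
    "InstanceLibrary",
    "default_regex_library",
    "load_regex_library",
    "load_instance_library",
    "res_scan",
    "res_classify",
    "mim_match",
    "mim_classify",
    "SVMModel",
    "svm_train",
    "svm_decision",
    "tune_hyperparameters",
    "save_model",
    "load_model",
]
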