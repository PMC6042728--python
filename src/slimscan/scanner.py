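"""End-to-end protein scanning: window extraction, per-method
prediction, union combination, and the tabular output.

A query is cut into all contiguous windows of the domain's length
(6 for SH3/WW, 4 for PDZ).  Each selected method evaluates every
window: SVM and PSSM score the window directly; regex and instance
matches anywhere in the sequence are attributed to every window that
fully contains them.  A window appears in the output if *any* selected
method calls it (union semantics), with per-method score/match columns
and the count of agreeing methods — agreement of three or more methods
on the same region is a strong indication of a true binding peptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .domains import get_domain
from .predictors import (
    InstanceLibrary,
    RegexLibrary,
    default_regex_library,
    mim_match,
    pssm_score,
    res_scan,
)
from .predictors.pssm import PSSMatrix
from .predictors.svm import SVMModel, svm_decision_many
from .seqio import HitRow, SequenceRecord, windows


@dataclass
class ScanConfig:
    """Which methods to run, with their resources and thresholds."""

    domain_class: str
    methods: tuple[str, ...] = ("SVM", "PSSM", "RES", "MIM")
    svm_model: SVMModel | None = None
    pssm: PSSMatrix | None = None
    regex_library: RegexLibrary | None = None
    instance_library: InstanceLibrary | None = None
    svm_threshold: float | None = None  # None: use the model's threshold
    pssm_threshold: float | None = None  # None: use the domain default

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method must be selected")
        for m in self.methods:
            if m not in ("SVM", "PSSM", "RES", "MIM"):
                raise ValueError(f"unknown method {m!r}")
        if "SVM" in self.methods and self.svm_model is None:
            raise ValueError("SVM selected but no model provided")
        if "PSSM" in self.methods and self.pssm is None:
            raise ValueError("PSSM selected but no matrix provided")
        if "MIM" in self.methods and self.instance_library is None:
            raise ValueError("MIM selected but no instance library provided")
        if "RES" in self.methods and self.regex_library is None:
            self.regex_library = default_regex_library(self.domain_class)


def scan(records: Sequence[SequenceRecord], config: ScanConfig) -> list[HitRow]:
    """Scan query records with the selected methods; returns the union
    hit table ordered by query (input order) then window position.

    Records shorter than the domain window are skipped with a warning.
    The PDZ C-terminal flag is set only on each record's terminal
    window.
    """
    spec = get_domain(config.domain_class)
    L = spec.window_length
    svm_thr = (
        config.svm_threshold
        if config.svm_threshold is not None
        else (config.svm_model.threshold if config.svm_model else 0.0)
    )
    pssm_thr = (
        config.pssm_threshold
        if config.pssm_threshold is not None
        else spec.pssm_threshold
    )

    rows: list[HitRow] = []
    for record in records:
        if not record.valid:
            warnings.warn(
                f"record {record.id!r} contains non-standard residues "
                f"{record.invalid_chars!r}; skipped",
                stacklevel=2,
            )
            continue
        wins = windows(record, L)
        if not wins:
            warnings.warn(
                f"record {record.id!r} is shorter than the {L}-residue "
                "window; skipped",
                stacklevel=2,
            )
            continue

        cand: dict[int, HitRow] = {}  # window start -> row

        def row_for(w) -> HitRow:
            if w.start not in cand:
                cand[w.start] = HitRow(
                    query_id=record.id, start=w.start, end=w.end, sequence=w.sequence
                )
            return cand[w.start]

        if "SVM" in config.methods:
            scores = svm_decision_many(
                config.svm_model,
                [w.sequence for w in wins],
                [w.is_c_terminal for w in wins],
            )
            for w, s in zip(wins, scores):
                if s >= svm_thr:
                    row_for(w).svm_score = float(s)
        if "PSSM" in config.methods:
            for w in wins:
                s = pssm_score(config.pssm, w.sequence)
                if s >= pssm_thr:
                    row_for(w).pssm_score = s
        if "RES" in config.methods:
            for hit in res_scan(record, config.regex_library, L):
                for w in wins:
                    if w.start <= hit.start and hit.end <= w.end:
                        row = row_for(w)
                        if row.res_pattern is None:
                            row.res_pattern = hit.matched
        if "MIM" in config.methods:
            for hit in mim_match(record, config.instance_library):
                for w in wins:
                    if w.start <= hit.start and hit.end <= w.end:
                        row = row_for(w)
                        if row.mim_instance is None:
                            row.mim_instance = hit.matched

        rows.extend(cand[s] for s in sorted(cand))
    return rows


def peptide_level_call(record: SequenceRecord, config: ScanConfig) -> bool:
    """True iff any selected method calls at least one window of the
    record (the any-window union rule used for variable-length
    peptides)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return len(scan([record], config)) > 0
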