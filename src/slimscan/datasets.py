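"""Training-set construction and cross-validation folds.

Positive sets are non-redundant ligand peptides for one domain class.
The negative set for a domain is the union of the other two domains'
positive sets plus random background peptides — so a model learns to
separate true binders of its domain from other motif-containing peptides
as well as from random sequence.  Both the unbalanced union (roughly
1:4 / 1:3 / 1:2 positive:negative for SH3 / WW / PDZ at the reference
class sizes) and seeded 1:1 balanced subsamples are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .domains import DOMAIN_NAMES, get_domain
from .seqio import SequenceRecord

#: Reference positive-class sizes (number of non-redundant ligand peptides).
CLASS_SIZES: dict[str, int] = {"SH3": 115, "WW": 140, "PDZ": 165}

#: Reference background-set size (random peptides from unrelated proteins).
BACKGROUND_SIZE: int = 120

#: Balanced-mode subsampling quotas: per target domain, how many negatives
#: to draw from each of the other two classes and from the background.
BALANCED_QUOTAS: dict[str, dict[str, int]] = {
    "SH3": {"WW": 30, "PDZ": 30, "background": 55},
    "WW": {"SH3": 45, "PDZ": 45, "background": 50},
    "PDZ": {"SH3": 50, "WW": 50, "background": 65},
}


@dataclass(frozen=True)
class LigandEntry:
    """A labeled fixed-length peptide window with provenance.

    ``start`` is the 1-based position of the window in its source
    protein and may be ``None`` for synthetic or context-free peptides.
    """

    sequence: str
    domain_class: str
    protein_id: str = "unknown"
    start: int | None = None
    is_c_terminal: bool = False

    @property
    def key(self) -> tuple[str, str, int | None]:
        return (self.sequence, self.protein_id, self.start)


@dataclass
class DatasetBundle:
    """Positive and negative peptides for one domain class."""

    domain_class: str
    positives: list[LigandEntry]
    negatives: list[LigandEntry]
    balance_mode: str = "unbalanced"

    def __post_init__(self) -> None:
        if self.balance_mode not in ("unbalanced", "balanced"):
            raise ValueError(f"unknown balance_mode {self.balance_mode!r}")
        overlap = {e.key for e in self.positives} & {e.key for e in self.negatives}
        if overlap:
            raise ValueError(
                f"positives and negatives share {len(overlap)} identical "
                "(sequence, protein, start) entries"
            )

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def entries(self) -> list[LigandEntry]:
        """Positives followed by negatives (the canonical example order)."""
        return list(self.positives) + list(self.negatives)

    def labels(self) -> np.ndarray:
        """+1 for positives, -1 for negatives, aligned with :meth:`entries`."""
        return np.concatenate(
            [np.ones(self.n_pos, dtype=int), -np.ones(self.n_neg, dtype=int)]
        )


@dataclass
class FoldAssignment:
    """A stratified k-fold partition of a bundle's examples.

    ``assignment[i]`` is the test-fold index of example ``i`` in the
    bundle's canonical order (positives then negatives).
    """

    n_folds: int
    assignment: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def collapse_redundant(entries: Sequence[LigandEntry]) -> list[LigandEntry]:
    """Collapse entries identical in (sequence, protein, start) to one.

    Identical peptide sequences reported from a different protein, a
    different isoform, or a different position are all retained — only
    exact duplicates of the same motif occurrence collapse.  Idempotent.
    """
    seen: set[tuple[str, str, int | None]] = set()
    out: list[LigandEntry] = []
    for e in entries:
        if e.key not in seen:
            seen.add(e.key)
            out.append(e)
    return out


def _fit_length(
    entry: LigandEntry, L: int, target_domain: str, rng: np.random.Generator,
    pad_alphabet: str,
) -> LigandEntry:
    """Adapt a cross-class positive to the target domain's window length.

    Longer peptides are trimmed to their last ``L`` residues (the
    C-terminal side, where PDZ specificity lives); shorter ones are
    padded on the N-terminal side with residues drawn uniformly from
    ``pad_alphabet`` (a C-terminal peptide's natural context extends
    N-terminally).
    """
    seq = entry.sequence
    if len(seq) == L:
        new_seq = seq
    elif len(seq) > L:
        new_seq = seq[-L:]
    else:
        pad = "".join(rng.choice(list(pad_alphabet), size=L - len(seq)))
        new_seq = pad + seq
    return LigandEntry(
        sequence=new_seq,
        domain_class=entry.domain_class,
        protein_id=entry.protein_id,
        start=entry.start,
        is_c_terminal=entry.is_c_terminal,
    )


def assemble_negatives(
    domain: str,
    class_sets: Mapping[str, Sequence[LigandEntry]],
    background: Sequence[LigandEntry],
    balance_mode: str = "unbalanced",
    quotas: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> list[LigandEntry]:
    """Build the negative set for ``domain``.

    Unbalanced mode returns the union of the other two domains' full
    positive sets and the full background set, so at the reference class
    sizes (115/140/165 positives, 120 background) SH3 gets exactly
    140 + 165 + 120 = 425 negatives, WW 400 and PDZ 375.  Balanced mode
    subsamples each source uniformly without replacement according to
    ``quotas`` (defaults to :data:`BALANCED_QUOTAS`) under ``seed``.

    Cross-class positives whose length differs from the target window
    are trimmed to their C-terminal ``L`` residues or N-terminally
    padded (see :func:`_fit_length`).
    """
    spec = get_domain(domain)
    L = spec.window_length
    rng = np.random.default_rng(seed)
    from .alphabet import AMINO_ACIDS

    others = [d for d in DOMAIN_NAMES if d != spec.name]
    pools: dict[str, list[LigandEntry]] = {}
    for other in others:
        if other not in class_sets:
            raise KeyError(f"class_sets is missing positives for {other}")
        pools[other] = [
            _fit_length(e, L, spec.name, rng, AMINO_ACIDS) for e in class_sets[other]
        ]
    for e in background:
        if len(e.sequence) != L:
            raise ValueError(
                f"background peptide {e.sequence!r} is not length {L}; "
                "background must be pre-cut to the target window length"
            )
    pools["background"] = list(background)

    if balance_mode == "unbalanced":
        return pools[others[0]] + pools[others[1]] + pools["background"]
    if balance_mode != "balanced":
        raise ValueError(f"unknown balance_mode {balance_mode!r}")

    quotas = dict(quotas) if quotas is not None else dict(BALANCED_QUOTAS[spec.name])
    out: list[LigandEntry] = []
    for source in others + ["background"]:
        n = quotas.get(source, 0)
        pool = pools[source]
        if n > len(pool):
            raise ValueError(
                f"balanced quota {n} for source {source!r} exceeds its pool "
                f"size {len(pool)}"
            )
        idx = rng.choice(len(pool), size=n, replace=False)
        out.extend(pool[i] for i in sorted(idx))
    return out


def sample_background(
    records: Sequence[SequenceRecord],
    n: int,
    L: int,
    seed: int | None = None,
) -> list[LigandEntry]:
    """Draw ``n`` length-``L`` peptides from random positions of ``records``.

    A source record and then a start position within it are drawn
    uniformly for each peptide (with replacement across draws);
    reproducible under ``seed``.
    """
    if n <= 0:
        raise ValueError(f"number of background peptides must be positive, got {n}")
    eligible = [r for r in records if r.length >= L]
    if not eligible:
        raise ValueError(f"no source record is at least {L} residues long")
    rng = np.random.default_rng(seed)
    out: list[LigandEntry] = []
    for _ in range(n):
        rec = eligible[rng.integers(len(eligible))]
        start = int(rng.integers(1, rec.length - L + 2))
        out.append(
            LigandEntry(
                sequence=rec.sequence[start - 1 : start + L - 1],
                domain_class="background",
                protein_id=rec.id,
                start=start,
                is_c_terminal=(start + L - 1 == rec.length),
            )
        )
    return out


def make_folds(
    bundle: DatasetBundle, n_folds: int = 5, seed: int = 0
) -> FoldAssignment:
    """Stratified k-fold assignment of a bundle's examples.

    Positives and negatives are partitioned separately so every fold
    keeps the bundle's class ratio (fold sizes within a stratum differ
    by at most one).  Deterministic under ``seed``.
    """
    if bundle.n_pos < n_folds or bundle.n_neg < n_folds:
        raise ValueError(
            f"need at least {n_folds} examples per class, got "
            f"{bundle.n_pos} positives / {bundle.n_neg} negatives"
        )
    labels = bundle.labels()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return FoldAssignment(n_folds=n_folds, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# Labeled-peptide TSV interchange

_TSV_COLUMNS = ["sequence", "domain_class", "label", "protein_id", "start", "is_c_terminal"]


def write_dataset(bundle: DatasetBundle, path: str | Path) -> None:
    """Write a bundle as a labeled-peptide TSV (label +1/-1)."""
    rows = []
    for label, entries in ((1, bundle.positives), (-1, bundle.negatives)):
        for e in entries:
            rows.append(
                {
                    "sequence": e.sequence,
                    "domain_class": e.domain_class,
                    "label": label,
                    "protein_id": e.protein_id,
                    "start": "" if e.start is None else e.start,
                    "is_c_terminal": int(e.is_c_terminal),
                }
            )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path, domain_class: str) -> DatasetBundle:
    """Read a labeled-peptide TSV back into a :class:`DatasetBundle`."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "protein_id": str})
    positives: list[LigandEntry] = []
    negatives: list[LigandEntry] = []
    for row in df.itertuples(index=False):
        start = None if pd.isna(row.start) or row.start == "" else int(row.start)
        entry = LigandEntry(
            sequence=row.sequence,
            domain_class=row.domain_class,
            protein_id=row.protein_id,
            start=start,
            is_c_terminal=bool(int(row.is_c_terminal)),
        )
        (positives if int(row.label) > 0 else negatives).append(entry)
    return DatasetBundle(
        domain_class=domain_class, positives=positives, negatives=negatives
    )
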