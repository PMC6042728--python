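"""Compositional feature encoding for peptides.

Three percentage-composition blocks are supported — amino-acid (AAC,
20 features), dipeptide (DPC, 400 features) and over-represented
tripeptide composition (TPC, one feature per selected tripeptide) —
plus a binary C-terminal-location flag (CTERM) used for PDZ ligands,
whose binding sites lie predominantly at protein C-termini.

AAC entries are ``count / length * 100``; DPC uses overlapping
dipeptides with denominator ``length - 1``; TPC uses overlapping
tripeptides with denominator ``length - 2``.  The TPC block is
restricted to tripeptides found in at least two distinct positive
peptides of a ligand class, which keeps the dimensionality of the input
vector in check for short training peptides.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, DIPEPTIDE_INDEX, invalid_residues

_VALID_COMPONENTS = ("AAC", "DPC", "TPC", "CTERM")

_BLOCK_LENGTHS = {"AAC": 20, "DPC": 400, "CTERM": 1}


@dataclass(frozen=True)
class FeatureScheme:
    """An ordered combination of feature blocks.

    ``tripeptides`` fixes the TPC block's feature order (must be set iff
    TPC is among the components).  The scheme fully determines the
    encoding, so serialized models can reproduce their feature space.
    """

    components: tuple[str, ...]
    tripeptides: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for c in self.components:
            if c not in _VALID_COMPONENTS:
                raise ValueError(f"unknown feature component {c!r}")
        if len(set(self.components)) != len(self.components):
            raise ValueError("duplicate feature components")
        if "TPC" in self.components and not self.tripeptides:
            raise ValueError("TPC component requires a selected tripeptide list")

    @property
    def total_length(self) -> int:
        n = 0
        for c in self.components:
            n += _BLOCK_LENGTHS.get(c, len(self.tripeptides))
        return n

    def block_slices(self) -> dict[str, slice]:
        """Start/stop of each component block within the encoded vector."""
        out: dict[str, slice] = {}
        offset = 0
        for c in self.components:
            width = _BLOCK_LENGTHS.get(c, len(self.tripeptides))
            out[c] = slice(offset, offset + width)
            offset += width
        return out


def _check_peptide(peptide: str, min_length: int, what: str) -> None:
    bad = invalid_residues(peptide)
    if bad:
        raise ValueError(f"peptide {peptide!r} contains non-standard residues {bad!r}")
    if len(peptide) < min_length:
        raise ValueError(f"{what} requires length >= {min_length}, got {peptide!r}")


def aac(peptide: str) -> np.ndarray:
    """Amino-acid composition: percentage of each of the 20 residues,
    in fixed alphabetical order.  Entries sum to 100."""
    _check_peptide(peptide, 1, "amino-acid composition")
    v = np.zeros(20)
    for ch in peptide:
        v[AA_INDEX[ch]] += 1
    return v / len(peptide) * 100.0


def dpc(peptide: str) -> np.ndarray:
    """Dipeptide composition over all 400 ordered pairs (lexicographic
    order), counting overlapping dipeptides; denominator ``L - 1``."""
    _check_peptide(peptide, 2, "dipeptide composition")
    v = np.zeros(400)
    for i in range(len(peptide) - 1):
        v[DIPEPTIDE_INDEX[peptide[i : i + 2]]] += 1
    return v / (len(peptide) - 1) * 100.0


def select_overrepresented_tripeptides(positives: Iterable[str]) -> list[str]:
    """Tripeptides present in at least two distinct positive peptides.

    Presence is per peptide (a tripeptide repeated within one peptide
    counts once), matching the notion of a motif fragment shared by more
    than one ligand.  The result is sorted lexicographically for a
    stable feature order.
    """
    npep: Counter[str] = Counter()
    for pep in positives:
        seen = {pep[i : i + 3] for i in range(len(pep) - 2)}
        npep.update(seen)
    return sorted(t for t, c in npep.items() if c >= 2)


def tpc(peptide: str, selected: Sequence[str]) -> np.ndarray:
    """Composition of the selected tripeptides only, counting overlapping
    occurrences; denominator ``L - 2``.  Sums to at most 100."""
    _check_peptide(peptide, 3, "tripeptide composition")
    counts = Counter(peptide[i : i + 3] for i in range(len(peptide) - 2))
    v = np.array([counts.get(t, 0) for t in selected], dtype=float)
    return v / (len(peptide) - 2) * 100.0


def encode(peptide: str, scheme: FeatureScheme, is_c_terminal: bool = False) -> np.ndarray:
    """Encode one peptide under ``scheme``: the component blocks
    concatenated in scheme order, the CTERM block being 1.0 iff the
    peptide ends at its parent protein's C-terminus."""
    blocks: list[np.ndarray] = []
    for c in scheme.components:
        if c == "AAC":
            blocks.append(aac(peptide))
        elif c == "DPC":
            blocks.append(dpc(peptide))
        elif c == "TPC":
            blocks.append(tpc(peptide, scheme.tripeptides))
        else:  # CTERM
            blocks.append(np.array([1.0 if is_c_terminal else 0.0]))
    return np.concatenate(blocks)


def scheme_from_positives(
    components: Sequence[str], positives: Iterable[str]
) -> FeatureScheme:
    """Build a scheme whose TPC block (if any) is selected from the given
    positive peptides.  Use the *training* positives only — recomputing
    the selection inside each cross-validation training fold keeps test
    peptides from leaking into the feature space."""
    components = tuple(components)
    tripeptides: tuple[str, ...] = ()
    if "TPC" in components:
        tripeptides = tuple(select_overrepresented_tripeptides(positives))
    return FeatureScheme(components=components, tripeptides=tripeptides)


def encode_many(
    peptides: Sequence[str],
    scheme: FeatureScheme,
    is_c_terminal: Sequence[bool] | None = None,
) -> np.ndarray:
    """Encode a batch of peptides into an ``(n, scheme.total_length)`` matrix."""
    if is_c_terminal is None:
        is_c_terminal = [False] * len(peptides)
    return np.array(
        [encode(p, scheme, ct) for p, ct in zip(peptides, is_c_terminal)]
    ).reshape(len(peptides), scheme.total_length)
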