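"""The 20-letter amino-acid alphabet and fixed feature orderings.

Every compositional feature block in this package uses one canonical
ordering — alphabetical one-letter codes for residues and lexicographic
products for k-mers — so that serialized models and feature vectors are
portable across sessions.
"""

from __future__ import annotations

from itertools import product

#: Standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: All 400 dipeptides in lexicographic order.
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a, b in product(AMINO_ACIDS, repeat=2))

DIPEPTIDE_INDEX: dict[str, int] = {d: i for i, d in enumerate(DIPEPTIDES)}


def invalid_residues(sequence: str) -> str:
    """Return the non-standard characters in ``sequence``, in order of
    first appearance (empty string if the sequence is fully standard).

    Ambiguity and rare codes (B, J, O, U, X, Z) and ``*`` are all
    non-standard here.
    """
    seen: list[str] = []
    for ch in sequence:
        if ch not in AA_INDEX and ch not in seen:
            seen.append(ch)
    return "".join(seen)


def is_valid(sequence: str) -> bool:
    """True iff every character is one of the 20 standard residues."""
    return all(ch in AA_INDEX for ch in sequence)
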