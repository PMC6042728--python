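"""Frequency position-specific scoring matrices (PSSMs).

A PSSM for a ligand class is a 20 x L matrix of positional residue
frequencies: ``PS(i, p) = n(i, p) / N`` where ``n(i, p)`` is the number
of training peptides with residue ``i`` at position ``p`` and ``N`` the
training-set size.  A query of length L is scored by multiplying its
per-position entries.

Two scoring modes are offered.  ``raw`` multiplies the frequencies
directly, giving a score in [0, 1] that is 1 only for a unanimous
consensus and shrinks geometrically with L.  ``background_odds``
(the default) divides each position score by the uniform background
1/20 before multiplying, so a score of 1 means "as likely as uniform
random sequence" and thresholds near 1 are meaningful operating points.
A residue never seen at a position zeroes the score in both modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ..alphabet import AA_INDEX, AMINO_ACIDS, invalid_residues

MODES = ("raw", "background_odds")


@dataclass
class PSSMatrix:
    """Positional frequency matrix for one ligand class.

    ``scores[i, p]`` is the frequency of amino acid ``i`` (alphabetical
    order) at position ``p`` (0-based column for 1-based peptide
    position p+1); each column sums to 1 for fully standard-alphabet
    training data.  ``N`` is the number of training peptides.
    """

    domain_class: str
    L: int
    scores: np.ndarray
    N: int
    mode: str = "background_odds"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (20, self.L):
            raise ValueError(
                f"scores must be 20 x {self.L}, got {self.scores.shape}"
            )
        if self.mode not in MODES:
            raise ValueError(f"unknown scoring mode {self.mode!r}")


def build_pssm(
    positives: Sequence[str],
    L: int,
    mode: str = "background_odds",
    domain_class: str = "",
) -> PSSMatrix:
    """Count positional residue frequencies over ``positives``.

    All peptides must have length ``L``; the matrix entry is the
    fraction of peptides carrying each residue at each position.
    """
    if not positives:
        raise ValueError("cannot build a PSSM from an empty training set")
    counts = np.zeros((20, L))
    for pep in positives:
        if len(pep) != L:
            raise ValueError(f"training peptide {pep!r} is not length {L}")
        bad = invalid_residues(pep)
        if bad:
            raise ValueError(f"peptide {pep!r} has non-standard residues {bad!r}")
        for p, ch in enumerate(pep):
            counts[AA_INDEX[ch], p] += 1
    return PSSMatrix(
        domain_class=domain_class,
        L=L,
        scores=counts / len(positives),
        N=len(positives),
        mode=mode,
    )


def pssm_score(matrix: PSSMatrix, peptide: str) -> float:
    """Score a length-L query by multiplying its position scores.

    In ``background_odds`` mode each positional frequency is divided by
    the uniform background 1/20 before multiplying.  Any residue with
    zero training frequency at its position gives a score of 0.
    """
    if len(peptide) != matrix.L:
        raise ValueError(
            f"query {peptide!r} has length {len(peptide)}, matrix expects {matrix.L}"
        )
    bad = invalid_residues(peptide)
    if bad:
        raise ValueError(f"query {peptide!r} has non-standard residues {bad!r}")
    score = 1.0
    for p, ch in enumerate(peptide):
        ps = matrix.scores[AA_INDEX[ch], p]
        if matrix.mode == "background_odds":
            ps = ps / (1.0 / 20.0)
        score *= ps
    return float(score)


def pssm_classify(matrix: PSSMatrix, peptide: str, threshold: float) -> bool:
    """True iff the PSSM score reaches ``threshold`` (boundary inclusive)."""
    return pssm_score(matrix, peptide) >= threshold


def save_pssm(matrix: PSSMatrix, path: str | Path) -> None:
    """Write a matrix as tab-separated text (rows = residues, columns =
    positions), with metadata in ``#`` header lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#domain_class\t{matrix.domain_class}\n")
        fh.write(f"#L\t{matrix.L}\n")
        fh.write(f"#N\t{matrix.N}\n")
        fh.write(f"#mode\t{matrix.mode}\n")
        fh.write("residue\t" + "\t".join(str(p + 1) for p in range(matrix.L)) + "\n")
        for i, a in enumerate(AMINO_ACIDS):
            fh.write(
                a + "\t" + "\t".join(repr(float(x)) for x in matrix.scores[i]) + "\n"
            )


def load_pssm(path: str | Path) -> PSSMatrix:
    """Read a matrix written by :func:`save_pssm`."""
    meta: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key] = value
            elif not line.startswith("residue\t"):
                parts = line.split("\t")
                rows[parts[0]] = [float(x) for x in parts[1:]]
    L = int(meta["L"])
    scores = np.array([rows[a] for a in AMINO_ACIDS])
    return PSSMatrix(
        domain_class=meta.get("domain_class", ""),
        L=L,
        scores=scores,
        N=int(meta["N"]),
        mode=meta.get("mode", "background_odds"),
    )
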