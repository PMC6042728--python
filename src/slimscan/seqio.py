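"""Sequence input/output: FASTA reading and writing, alphabet validation,
sliding-window extraction, and the combined tab-separated hit table.

Coordinates are 1-based inclusive throughout, the convention biologists
see in sequence viewers and motif-server output tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .alphabet import invalid_residues

#: Placeholder printed in a method column when that method did not call the row.
ABSENT = "—"  # em dash

HIT_TABLE_COLUMNS = (
    "query_id",
    "start",
    "end",
    "sequence",
    "svm_score",
    "pssm_score",
    "mim_instance",
    "res_pattern",
    "n_methods_agreeing",
)


@dataclass
class SequenceRecord:
    """One protein or peptide sequence.

    Sequences are uppercased on ingest.  A record containing characters
    outside the 20 standard one-letter codes is flagged invalid (never
    silently altered); the offending characters are kept in
    ``invalid_chars``.
    """

    id: str
    sequence: str
    invalid_chars: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.invalid_chars = invalid_residues(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def valid(self) -> bool:
        return self.length >= 1 and not self.invalid_chars


@dataclass(frozen=True)
class Window:
    """A fixed-length peptide window with provenance coordinates.

    ``start``/``end`` are 1-based inclusive positions in the parent
    sequence; ``is_c_terminal`` is true iff the window ends at the
    parent's last residue.
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    is_c_terminal: bool = False


@dataclass
class HitRow:
    """One row of the combined scan output: a called peptide region and
    the per-method evidence (scores or matched strings) behind the call."""

    query_id: str
    start: int
    end: int
    sequence: str
    svm_score: float | None = None
    pssm_score: float | None = None
    mim_instance: str | None = None
    res_pattern: str | None = None

    @property
    def n_methods_agreeing(self) -> int:
        return sum(
            v is not None
            for v in (self.svm_score, self.pssm_score, self.mim_instance, self.res_pattern)
        )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Entry order is preserved and sequences are uppercased; lowercase
    input is accepted.  Records with non-standard residues come back
    with ``valid`` false and the offending characters recorded.  An
    empty file yields an empty list with a warning.
    """
    path = Path(path)
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to a FASTA file (ids and sequences round-trip exactly)."""
    bio = [
        _BioSeqRecord(Seq(rec.sequence), id=rec.id, description="")
        for rec in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def windows(record: SequenceRecord, L: int) -> list[Window]:
    """All contiguous length-``L`` windows of ``record``, in order.

    Returns ``record.length - L + 1`` windows (an empty list if the
    sequence is shorter than ``L``); exactly the last window carries
    ``is_c_terminal=True``.
    """
    if L < 1:
        raise ValueError(f"window length must be >= 1, got {L}")
    n = record.length
    return [
        Window(
            parent_id=record.id,
            start=s,
            end=s + L - 1,
            sequence=record.sequence[s - 1 : s + L - 1],
            is_c_terminal=(s + L - 1 == n),
        )
        for s in range(1, n - L + 2)
    ]


def _fmt_score(value: float | None, precision: int | None) -> str:
    if value is None:
        return ABSENT
    if precision is None:
        return repr(float(value))
    return f"{value:.{precision}f}"


def write_hits_table(
    hits: Sequence[HitRow],
    path: str | Path,
    precision: int | None = 4,
) -> None:
    """Write the combined prediction table as tab-separated text.

    One row per called peptide region; method columns show the SVM and
    PSSM scores, the matched known instance, and the matched regular
    expression, with an em dash for methods that did not call the row.
    ``precision`` fixes score formatting (default 4 decimals; ``None``
    writes full precision).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(HIT_TABLE_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.query_id,
                        str(h.start),
                        str(h.end),
                        h.sequence,
                        _fmt_score(h.svm_score, precision),
                        _fmt_score(h.pssm_score, precision),
                        h.mim_instance if h.mim_instance is not None else ABSENT,
                        h.res_pattern if h.res_pattern is not None else ABSENT,
                        str(h.n_methods_agreeing),
                    )
                )
                + "\n"
            )
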