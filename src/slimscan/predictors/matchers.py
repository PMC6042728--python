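"""String-matching predictors: regular-expression scanning (RES) and
exact motif-instance matching (MIM).

RES maps a library of linear-motif regular expressions onto query
sequences; every (possibly overlapping) match is a positive call
reporting the matching pattern.  ``$``-anchored patterns describe
C-terminal motifs (PDZ) and only ever match at a sequence terminus.

MIM searches queries for exact substring occurrences of known binder
peptides.  It cannot call a peptide differing by even one residue from
a known instance, so its sensitivity is low but its false-positive rate
on sequences sharing no instance is exactly zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ..domains import get_domain
from ..seqio import SequenceRecord
from . import PredictionHit


@dataclass
class RegexLibrary:
    """Ordered list of motif regular expressions for one domain class."""

    domain_class: str
    patterns: tuple[str, ...]
    _compiled: list[re.Pattern] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._compiled = []
        for pat in self.patterns:
            try:
                # lookahead wrapper exposes overlapping matches
                self._compiled.append(re.compile(f"(?=({pat}))"))
            except re.error as exc:
                raise ValueError(f"invalid motif pattern {pat!r}: {exc}") from exc

    def finditer(self, sequence: str):
        """Yield (pattern_text, start0, end0) for every match of every
        pattern, overlapping matches included (0-based half-open span)."""
        for pat, rx in zip(self.patterns, self._compiled):
            for m in rx.finditer(sequence):
                yield pat, m.start(1), m.end(1)


@dataclass
class InstanceLibrary:
    """Known binder peptides for one domain class (exact-match library)."""

    domain_class: str
    instances: frozenset[str]

    def __post_init__(self) -> None:
        self.instances = frozenset(s.upper() for s in self.instances)


def default_regex_library(domain: str) -> RegexLibrary:
    """The shipped default pattern list for a domain class: canonical
    literature motifs, intended as replaceable placeholders for a
    curated list."""
    spec = get_domain(domain)
    return RegexLibrary(domain_class=spec.name, patterns=spec.regex_patterns)


def load_regex_library(path: str | Path, domain_class: str = "") -> RegexLibrary:
    """Load patterns from a plain-text file, one per line; ``#`` starts a
    comment.  An uncompilable pattern raises an error naming it."""
    patterns: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(line)
    return RegexLibrary(domain_class=domain_class, patterns=tuple(patterns))


def load_instance_library(path: str | Path, domain_class: str = "") -> InstanceLibrary:
    """Load known instances from a plain-text list (one peptide per line)
    or a FASTA file (auto-detected by a leading ``>``)."""
    text = Path(path).read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith(">"):
        from ..seqio import read_fasta

        instances = {rec.sequence for rec in read_fasta(path)}
    else:
        instances = {
            line.strip().upper()
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        }
    if not instances:
        raise ValueError(f"instance library {path} is empty")
    return InstanceLibrary(domain_class=domain_class, instances=frozenset(instances))


def res_scan(
    record: SequenceRecord, library: RegexLibrary, L: int | None = None
) -> list[PredictionHit]:
    """All (overlapping) pattern matches in ``record``, as hits carrying
    the matched span and pattern text.  ``$``-anchored patterns can by
    construction only fire at the sequence terminus."""
    hits = [
        PredictionHit(
            method="RES",
            parent_id=record.id,
            start=s0 + 1,
            end=e0,
            sequence=record.sequence[s0:e0],
            matched=pat,
        )
        for pat, s0, e0 in library.finditer(record.sequence)
    ]
    hits.sort(key=lambda h: (h.start, h.end, h.matched or ""))
    return hits


def res_classify(
    peptide: str, library: RegexLibrary, is_c_terminal: bool = True
) -> str | None:
    """Classify a fixed-length peptide: the first matching pattern, or
    ``None``.  Anchored patterns only apply when the peptide sits at its
    parent protein's C-terminus (a context-free peptide's own end is
    treated as a terminus, hence the default)."""
    for pat, rx in zip(library.patterns, library._compiled):
        if pat.rstrip().endswith("$") and not is_c_terminal:
            continue
        if rx.search(peptide):
            return pat
    return None


def mim_match(record: SequenceRecord, library: InstanceLibrary) -> list[PredictionHit]:
    """Every exact substring occurrence of any library instance in
    ``record`` (overlapping and repeated occurrences all reported)."""
    if not library.instances:
        raise ValueError("instance library is empty")
    hits: list[PredictionHit] = []
    seq = record.sequence
    for inst in library.instances:
        pos = seq.find(inst)
        while pos != -1:
            hits.append(
                PredictionHit(
                    method="MIM",
                    parent_id=record.id,
                    start=pos + 1,
                    end=pos + len(inst),
                    sequence=inst,
                    matched=inst,
                )
            )
            pos = seq.find(inst, pos + 1)
    hits.sort(key=lambda h: (h.start, h.end, h.matched or ""))
    return hits


def mim_classify(peptide: str, library: InstanceLibrary) -> str | None:
    """Classify a query peptide: the first known instance occurring as an
    exact substring (full equality when lengths agree), else ``None``."""
    for inst in sorted(library.instances):
        if inst in peptide:
            return inst
    return None
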