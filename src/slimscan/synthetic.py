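"""Synthetic peptide and protein generation with planted motif signal.

The generator emulates the statistical structure of curated
domain-ligand collections: SH3 positives are proline/arginine-biased
6-mers drawn from an "RxPxxP"-style positional template, WW positives
are "xPPxY"-style 6-mers, and PDZ positives are 4-mers with an
"x[ST]x[VIL]" C-terminal template, predominantly flagged as C-terminal
windows.  Background peptides are cut from uniform-random protein
sequences.  ``signal_strength`` is the probability mass a template
position places on its template residues (the rest is spread uniformly
over the 20-letter alphabet), so 1.0 plants the motif deterministically
and values near 0.05 approach uniform noise.

Everything is reproducible under a seed, and the bundle generator can
guarantee (by rejection) that no negative peptide is an exact string
match to a same-domain positive — the property that makes exact
instance matching a zero-false-positive classifier by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS
from .datasets import (
    BACKGROUND_SIZE,
    CLASS_SIZES,
    DatasetBundle,
    LigandEntry,
    assemble_negatives,
)
from .domains import DOMAIN_NAMES, get_domain
from .seqio import SequenceRecord

#: Positional motif templates: position (1-based) -> preferred residues.
DEFAULT_TEMPLATES: dict[str, dict[int, str]] = {
    "SH3": {1: "RK", 3: "P", 6: "P"},
    "WW": {2: "P", 3: "P", 5: "Y"},
    "PDZ": {2: "ST", 4: "VIL"},
}


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic positive class.

    ``motif_template`` maps 1-based positions to the residues favored
    there; unlisted positions are uniform.  ``c_terminal_prob`` is the
    probability a PDZ peptide carries the C-terminal flag (PDZ binding
    sites are predominantly C-terminal; ignored for SH3/WW, which get
    internal windows).
    """

    domain_class: str
    n_pos: int
    motif_template: Mapping[int, str] | None = None
    signal_strength: float = 0.8
    c_terminal_prob: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        get_domain(self.domain_class)
        if not (0.05 < self.signal_strength <= 1.0):
            raise ValueError(
                f"signal_strength must be in (0.05, 1], got {self.signal_strength}"
            )
        if self.n_pos <= 0:
            raise ValueError(f"n_pos must be positive, got {self.n_pos}")

    def position_distributions(self) -> np.ndarray:
        """(L, 20) per-position residue probabilities (each row sums to 1)."""
        spec = get_domain(self.domain_class)
        L = spec.window_length
        template = (
            dict(self.motif_template)
            if self.motif_template is not None
            else DEFAULT_TEMPLATES[spec.name]
        )
        dists = np.full((L, 20), 1.0 / 20.0)
        for pos, residues in template.items():
            if not (1 <= pos <= L):
                raise ValueError(f"template position {pos} outside 1..{L}")
            if not residues:
                raise ValueError(f"template position {pos} lists no residues")
            row = np.full(20, (1.0 - self.signal_strength) / 20.0)
            for r in residues:
                row[AMINO_ACIDS.index(r)] += self.signal_strength / len(residues)
            dists[pos - 1] = row
        return dists


def generate_class(spec: GeneratorSpec) -> list[LigandEntry]:
    """Draw ``spec.n_pos`` template-distributed peptides for one class."""
    domain = get_domain(spec.domain_class)
    rng = np.random.default_rng(spec.seed)
    dists = spec.position_distributions()
    letters = np.array(list(AMINO_ACIDS))
    out: list[LigandEntry] = []
    for i in range(spec.n_pos):
        seq = "".join(
            letters[rng.choice(20, p=dists[p])] for p in range(domain.window_length)
        )
        if domain.name == "PDZ":
            is_ct = bool(rng.random() < spec.c_terminal_prob)
        else:
            is_ct = False
        out.append(
            LigandEntry(
                sequence=seq,
                domain_class=domain.name,
                protein_id=f"syn_{domain.name}_{i + 1}",
                start=None,
                is_c_terminal=is_ct,
            )
        )
    return out


def generate_background_records(
    n: int = 40,
    length_range: tuple[int, int] = (80, 300),
    seed: int | None = None,
) -> list[SequenceRecord]:
    """Uniform-random protein records to cut background peptides from."""
    rng = np.random.default_rng(seed)
    letters = list(AMINO_ACIDS)
    lo, hi = length_range
    return [
        SequenceRecord(
            id=f"bg_{i + 1}",
            sequence="".join(rng.choice(letters, size=int(rng.integers(lo, hi + 1)))),
        )
        for i in range(n)
    ]


def _sample_disjoint_background(
    records: Sequence[SequenceRecord],
    n: int,
    L: int,
    forbidden: set[str],
    rng: np.random.Generator,
    max_tries: int = 100_000,
) -> list[LigandEntry]:
    """Background peptides avoiding exact matches to ``forbidden``."""
    eligible = [r for r in records if r.length >= L]
    if not eligible:
        raise ValueError(f"no source record is at least {L} residues long")
    out: list[LigandEntry] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "background rejection sampling exceeded its bound; the "
                "forbidden set covers too much of sequence space"
            )
        rec = eligible[rng.integers(len(eligible))]
        start = int(rng.integers(1, rec.length - L + 2))
        seq = rec.sequence[start - 1 : start + L - 1]
        if seq in forbidden:
            continue
        out.append(
            LigandEntry(
                sequence=seq,
                domain_class="background",
                protein_id=rec.id,
                start=start,
                is_c_terminal=(start + L - 1 == rec.length),
            )
        )
    return out


def generate_bundle(
    specs: Mapping[str, GeneratorSpec] | None = None,
    reference_sizes: bool = True,
    seed: int = 0,
    balance_mode: str = "unbalanced",
    disjoint: bool = True,
    signal_strength: float = 0.8,
    n_background: int = BACKGROUND_SIZE,
    max_attempts: int = 50,
) -> dict[str, DatasetBundle]:
    """Generate complete per-domain dataset bundles.

    With ``reference_sizes`` the positive classes have 115 (SH3), 140 (WW)
    and 165 (PDZ) members and the background 120, reproducing the
    reference unbalanced negative-set sizes 425/400/375.  With
    ``disjoint`` (default) no negative is an exact string match to a
    same-domain positive: background peptides are rejection-resampled,
    and the rare collision through a trimmed/padded cross-class
    negative triggers a bounded regeneration of the whole draw under a
    derived seed.
    """
    for attempt in range(max_attempts):
        base = (seed * 1_000_003 + attempt * 7_919) % (2**31 - 1)
        rng = np.random.default_rng(base)

        class_specs: dict[str, GeneratorSpec] = {}
        for d in DOMAIN_NAMES:
            if specs is not None and d in specs:
                s = specs[d]
                if reference_sizes:
                    s = GeneratorSpec(
                        domain_class=d,
                        n_pos=CLASS_SIZES[d],
                        motif_template=s.motif_template,
                        signal_strength=s.signal_strength,
                        c_terminal_prob=s.c_terminal_prob,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                else:
                    s = GeneratorSpec(
                        domain_class=d,
                        n_pos=s.n_pos,
                        motif_template=s.motif_template,
                        signal_strength=s.signal_strength,
                        c_terminal_prob=s.c_terminal_prob,
                        seed=int(rng.integers(2**31 - 1)),
                    )
            else:
                s = GeneratorSpec(
                    domain_class=d,
                    n_pos=CLASS_SIZES[d],
                    signal_strength=signal_strength,
                    seed=int(rng.integers(2**31 - 1)),
                )
            class_specs[d] = s

        positives = {d: generate_class(class_specs[d]) for d in DOMAIN_NAMES}
        pos_strings = {d: {e.sequence for e in positives[d]} for d in DOMAIN_NAMES}

        records = generate_background_records(seed=int(rng.integers(2**31 - 1)))
        if disjoint:
            bg6 = _sample_disjoint_background(
                records, n_background, 6,
                pos_strings["SH3"] | pos_strings["WW"], rng,
            )
            bg4 = _sample_disjoint_background(
                records, n_background, 4, pos_strings["PDZ"], rng,
            )
        else:
            from .datasets import sample_background

            bg6 = sample_background(records, n_background, 6,
                                    seed=int(rng.integers(2**31 - 1)))
            bg4 = sample_background(records, n_background, 4,
                                    seed=int(rng.integers(2**31 - 1)))

        bundles: dict[str, DatasetBundle] = {}
        collision = False
        for d in DOMAIN_NAMES:
            L = get_domain(d).window_length
            negatives = assemble_negatives(
                d,
                class_sets=positives,
                background=bg6 if L == 6 else bg4,
                balance_mode=balance_mode,
                seed=int(rng.integers(2**31 - 1)),
            )
            if disjoint and any(n.sequence in pos_strings[d] for n in negatives):
                collision = True
                break
            bundles[d] = DatasetBundle(
                domain_class=d,
                positives=positives[d],
                negatives=negatives,
                balance_mode=balance_mode,
            )
        if not collision:
            return bundles
    raise RuntimeError(
        f"could not build a disjoint bundle in {max_attempts} attempts"
    )


def generate_proteins(
    n: int,
    length_range: tuple[int, int],
    embedded: Sequence[tuple[str, str]] = (),
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Uniform-random proteins with the given peptides planted in them.

    ``embedded`` is a list of ``(peptide, domain_class)`` pairs,
    distributed round-robin over the proteins; PDZ peptides are planted
    at the C-terminus, others at random non-overlapping internal
    offsets.  Returns the records and the ground-truth coordinates
    (1-based inclusive) of every planted peptide.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    letters = list(AMINO_ACIDS)
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n)]

    per_protein: list[list[tuple[str, str]]] = [[] for _ in range(n)]
    for j, item in enumerate(embedded):
        per_protein[j % n].append(item)

    records: list[SequenceRecord] = []
    truth: list[dict] = []
    for i in range(n):
        plen = lengths[i]
        seq = list(rng.choice(letters, size=plen))
        occupied: list[tuple[int, int]] = []  # 0-based half-open
        if sum(len(p) for p, _ in per_protein[i]) > plen:
            raise ValueError(f"embedded peptides do not fit in protein of length {plen}")
        for pep, cls in per_protein[i]:
            if cls == "PDZ":
                s0 = plen - len(pep)
                if any(s0 < e and s0 + len(pep) > s for s, e in occupied):
                    raise ValueError("C-terminal slot already occupied")
            else:
                for _ in range(10_000):
                    s0 = int(rng.integers(0, plen - len(pep) + 1))
                    if not any(s0 < e and s0 + len(pep) > s for s, e in occupied):
                        break
                else:
                    raise ValueError("could not place embedded peptide without overlap")
            seq[s0 : s0 + len(pep)] = list(pep)
            occupied.append((s0, s0 + len(pep)))
            truth.append(
                {
                    "protein_id": f"prot_{i + 1}",
                    "start": s0 + 1,
                    "end": s0 + len(pep),
                    "sequence": pep,
                    "domain_class": cls,
                }
            )
        records.append(SequenceRecord(id=f"prot_{i + 1}", sequence="".join(seq)))
    return records, truth
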