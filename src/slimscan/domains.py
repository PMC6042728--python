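"""Per-domain configuration for the three peptide-recognition modules.

SH3 and WW domains bind proline-rich internal peptides and are scanned
with 6-residue windows; PDZ domains recognize predominantly C-terminal
motifs and are scanned with 4-residue windows.  Each :class:`DomainSpec`
carries the window length, the composition feature scheme its classifier
uses, default decision thresholds, and a replaceable default library of
literature motif patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DomainSpec:
    """Configuration bundle for one peptide-recognition module class.

    Attributes
    ----------
    name:
        Domain class name (``"SH3"``, ``"WW"`` or ``"PDZ"``).
    window_length:
        Peptide window length used for training and scanning.
    feature_components:
        Composition blocks of the domain's SVM feature scheme, in order.
        ``CTERM`` is the binary C-terminal-location flag used for PDZ.
    svm_threshold:
        Default SVM decision threshold (0.00: any positive margin calls
        a binder).
    svm_operating_threshold:
        The cross-validation operating point at which the best accuracy
        was obtained for this class (a free post-hoc parameter).
    pssm_threshold:
        Default threshold on the background-odds PSSM score.
    regex_patterns:
        Default regular-expression motif library: canonical literature
        motifs, intended to be replaced by a user-supplied list.
        ``$``-anchored patterns are evaluated only at a sequence terminus.
    """

    name: str
    window_length: int
    feature_components: tuple[str, ...]
    svm_threshold: float = 0.0
    svm_operating_threshold: float = 0.0
    pssm_threshold: float = 1.0
    regex_patterns: tuple[str, ...] = field(default_factory=tuple)


DOMAINS: dict[str, DomainSpec] = {
    "SH3": DomainSpec(
        name="SH3",
        window_length=6,
        feature_components=("AAC", "DPC", "TPC"),
        svm_operating_threshold=-0.25,
        pssm_threshold=1.00,
        regex_patterns=("P..P", "[RK]..P..P", "P..P.[RK]"),
    ),
    "WW": DomainSpec(
        name="WW",
        window_length=6,
        feature_components=("AAC", "DPC", "TPC"),
        svm_operating_threshold=-0.05,
        pssm_threshold=0.50,
        regex_patterns=("PP.Y", "PPLP"),
    ),
    "PDZ": DomainSpec(
        name="PDZ",
        window_length=4,
        feature_components=("AAC", "TPC", "CTERM"),
        svm_operating_threshold=-0.10,
        pssm_threshold=0.60,
        regex_patterns=("[ST].[VIL]$", "[FYV].[VIL]$"),
    ),
}

DOMAIN_NAMES: tuple[str, ...] = ("SH3", "WW", "PDZ")


def get_domain(name: str) -> DomainSpec:
    """Look up a :class:`DomainSpec` by (case-insensitive) name."""
    key = name.upper()
    if key not in DOMAINS:
        raise KeyError(f"unknown domain class {name!r}; expected one of {DOMAIN_NAMES}")
    return DOMAINS[key]
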