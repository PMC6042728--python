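# Methods

## Problem setting

SH3, WW and PDZ domains recognize short linear peptide ligands: proline-rich
internal motifs for SH3 (canonical core `PxxP`, often flanked by R/K) and WW
(`PPxY`-like), and predominantly C-terminal motifs for PDZ
(`[ST]x[VIL]-COOH`-like). `slimscan` treats prediction as classification of
fixed-length windows: 6-mers for SH3 and WW, 4-mers for PDZ — the lengths at
which short ligand peptides are most abundant and at which compositional
classifiers behave best. Coordinates are 1-based inclusive everywhere, and a
window is "C-terminal" iff it ends at its parent's last residue.

## Dataset construction

Positives for a domain class are non-redundant ligand windows: entries
identical in (sequence, source protein, start) collapse to one; the same
sequence from a different protein, isoform or position is retained, since it
is genuinely independent evidence.

Negatives for a domain are the union of the *other two* classes' positives
and a set of random background peptides cut from unrelated protein sequence.
Including other classes' ligands forces the classifier to separate true
binders from motif-containing non-binders, not merely from random sequence.
At the reference class sizes (115 SH3 / 140 WW / 165 PDZ positives, 120
background) the unbalanced sets are exactly 425/400/375 negatives
(~1:4/1:3/1:2); balanced 1:1 sets subsample each source uniformly without
replacement under an explicit seed, with quotas (30,30,55)/(45,45,50)/
(50,50,65) per target domain.

**Window-length reconciliation.** Cross-class negatives whose length differs
from the target window are adapted deterministically where possible: 6-mer
SH3/WW positives used as PDZ negatives are trimmed to their last 4 residues
(the C-terminal side, where PDZ specificity lives). The reverse direction —
4-mer PDZ positives as SH3/WW negatives — has no unique natural answer; we
pad on the N-terminal side with seeded uniform-random residues, on the
reasoning that a C-terminal peptide's real sequence context extends
N-terminally. This is a design choice of this package.

## Features

Peptides are encoded as percentage compositions with fixed alphabetical
(residues) and lexicographic (pairs/triples) feature order:

- **AAC** (20): `count_i / L × 100`.
- **DPC** (400): overlapping dipeptides, denominator `L − 1`.
- **TPC**: overlapping tripeptides restricted to those *present in at least
  two distinct positive peptides* of the class (a tripeptide repeated within
  one peptide counts once); denominator `L − 2`. Restricting to shared
  tripeptides keeps the dimensionality sensible for 4–6-mers. The selection
  is part of the learned model and is recomputed inside each
  cross-validation training fold.
- **CTERM** (1): binary C-terminal-location flag, used in the PDZ scheme. A
  context-free query peptide defaults to C-terminal (its own end is a
  terminus); windows inside a protein get the flag only on the terminal
  window.

Default schemes: AAC+DPC+TPC for SH3 and WW; AAC+TPC+CTERM for PDZ.

## Classifiers

**SVM.** Soft-margin SVM with RBF kernel (scikit-learn `SVC`). Percentage
blocks are rescaled to [0, 1] before the kernel — the customary
normalization, which places the hyperparameter grid (γ ∈ 2⁻⁷..2³,
C ∈ 2⁻³..2⁷) on a useful scale; the CTERM flag stays binary. Class imbalance
is handled with a positive-class cost factor defaulting to `n_neg/n_pos` on
unbalanced data. Grid selection maximizes mean cross-validated accuracy at
threshold 0, ties broken toward smaller C then smaller γ; defaults without
tuning are γ = 2⁻², C = 2³. The decision threshold is post-hoc (default
0.00, boundary inclusive; raising it trades sensitivity for specificity and
never retrains).

**PSSM.** `PS(i,p) = n(i,p)/N` over the training positives; query score is
the product of position entries; a residue unseen at a position zeroes the
score. Raw frequency products shrink geometrically with L and can only reach
1 for a unanimous column, which makes operating thresholds near 1
unreachable; the default `background_odds` mode therefore divides each
position entry by the uniform background 1/20, so score ≥ 1 reads "more
likely than random sequence". Raw mode is retained for fidelity to the plain
frequency-product definition. Default thresholds per domain: 1.00 (SH3),
0.50 (WW), 0.60 (PDZ).

**RES.** A pattern library is mapped over the query; all overlapping matches
of all patterns are reported (implemented with look-ahead group capture).
`$`-anchored patterns describe C-terminal motifs and can only fire at a
sequence terminus; in peptide classification they are skipped for
non-terminal peptides. The shipped default lists (`P..P`, `[RK]..P..P`,
`P..P.[RK]`; `PP.Y`, `PPLP`; `[ST].[VIL]$`, `[FYV].[VIL]$`) are canonical
literature motifs intended as replaceable placeholders for a curated
library.

**MIM.** Exact substring matching against known binder instances. By
construction it cannot call a peptide differing by one residue from every
known instance, so sensitivity is low; on negatives sharing no exact string
with the library its specificity is exactly 1.

## Scanning and combination

A query protein is cut into all windows of the domain length; each selected
method evaluates every window (regex/instance matches anywhere in the
sequence are attributed to each window fully containing them). The output
table is the union: a window appears if any method calls it, with per-method
columns (score, score, matched instance, matched pattern; em dash when
silent) and the count of agreeing methods. Overlapping positive windows stay
separate rows. For variable-length peptide queries the peptide-level call is
the any-window union rule. Scores print at 4 decimals by default (full
precision on request), making repeated runs byte-identical.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy, and the standard
rooted Matthews correlation coefficient on [−1, 1], defined as 0 when any
denominator factor vanishes. Metrics require at least one actual positive
and negative. ROC curves and trapezoidal AUC come from all score thresholds;
the AUC equals the Mann–Whitney probability that a random positive outscores
a random negative (ties ½) — the test suite checks this against a
brute-force pair-counting oracle. Cross-validation is stratified five-fold
(positives and negatives partitioned separately, seeded); confusion counts
are pooled (micro-averaged) across the test folds rather than averaging
per-fold metrics — a choice, stated here because both conventions exist.
Everything learned from data (SVM, its TPC selection, PSSM counts, the
per-fold MIM instance library) is recomputed inside each training fold; a
label-shuffle test confirms pooled AUC collapses to 0.5 when the signal is
destroyed.

Operating-point selection on a score grid maximizes accuracy, ties broken
toward higher specificity then the larger threshold.

## Synthetic data generator

The generator emulates curated ligand collections with positional templates:
SH3 `{1:[RK], 3:P, 6:P}`, WW `{2:P, 3:P, 5:Y}`, PDZ `{2:[ST], 4:[VIL]}`.
`signal_strength` (default 0.8) is the probability mass on the template
residues at a template position, the remainder spread uniformly over the 20
residues; non-template positions are uniform. PDZ peptides carry the
C-terminal flag with probability 0.9. Background peptides are cut from
uniform-random "proteins" (40 records of 80–300 residues by default; 120
peptides at each window length). Reference sizes (115/140/165 positives, 120
background) are the defaults so the dataset arithmetic above is exercised
literally.

The **disjointness guarantee** (default on) ensures no negative equals a
same-domain positive string: background peptides are rejection-resampled,
and the rare collision through a deterministically trimmed/padded
cross-class negative triggers a bounded regeneration of the whole draw under
a derived seed (deterministic given the top-level seed). This is what forces
MIM specificity to exactly 100% on generated bundles.

What the generator does **not** emulate: real amino-acid background
composition (true background proteomes are biased, not uniform), correlated
positions within motifs, domain-subtype specificities, disorder context, and
homology structure between peptides. Passing tests therefore demonstrate the
machinery is correct and the methods rank as expected on clean planted
signal; they do not certify performance levels on curated biological data.

## Numerical and operational choices

- Benchmark problem sizes: the bundled benchmarks and tests run at the
  reference class sizes (540–600 examples per domain), where the full
  five-fold evaluation of all four methods completes in seconds.
- Benchmark seed 20180712; hypothesis-based property tests run
  derandomized.
- All classification thresholds are boundary-inclusive (`score ≥ t`).
- Records with non-standard residues (B, J, O, U, X, Z, `*`) are flagged
  invalid on ingest and skipped with a warning when scanning; they are never
  silently altered. Ambiguity handling finer than whole-record rejection is
  not implemented.
- The interactive-use quota (≤10 sequences of ≥6 residues) is a UI
  constraint, not a method constraint: the library never enforces it and the
  CLI only under `--server-limits`.
- Model bundles serialize with joblib (scheme, tripeptide list, kernel
  parameters, fitted coefficients, threshold); PSSMs serialize as plain TSV.

## Limitations

Models are generalized per domain class, not per domain subtype (curated
instances are too few for subtype models). The default regex libraries are
minimal placeholders; results with them are illustrative. MCC and AUC on
synthetic benchmarks depend on `signal_strength` and are not comparable to
values obtained on curated interaction databases.
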