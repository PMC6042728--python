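import numpy as np
import pytest

import slimscan as ss
from slimscan.datasets import (
    BALANCED_QUOTAS,
    DatasetBundle,
    LigandEntry,
    assemble_negatives,
    collapse_redundant,
    make_folds,
    read_dataset,
    sample_background,
    write_dataset,
)
from slimscan.seqio import SequenceRecord


def _entry(seq, domain="SH3", protein="prot1", start=1):
    return LigandEntry(sequence=seq, domain_class=domain, protein_id=protein, start=start)


class TestCollapseRedundant:
    def test_same_motif_same_position_collapses(self):
        out = collapse_redundant([_entry("PPPPPP"), _entry("PPPPPP")])
        assert len(out) == 1

    def test_same_sequence_different_protein_kept(self):
        out = collapse_redundant(
            [_entry("PPPPPP", protein="a"), _entry("PPPPPP", protein="b")]
        )
        assert len(out) == 2

    def test_same_sequence_different_position_kept(self):
        out = collapse_redundant([_entry("PPPPPP", start=1), _entry("PPPPPP", start=7)])
        assert len(out) == 2

    def test_empty_and_idempotent(self):
        assert collapse_redundant([]) == []
        entries = [_entry("PPPPPP"), _entry("PPPPPP"), _entry("AAAAAA")]
        once = collapse_redundant(entries)
        assert collapse_redundant(once) == once


@pytest.fixture(scope="module")
def class_sets():
    """Reference-size positive sets (115 SH3 / 140 WW / 165 PDZ) and
    120 background peptides at each window length."""
    bundles = {}
    for d, n in ss.CLASS_SIZES.items():
        spec = ss.GeneratorSpec(domain_class=d, n_pos=n, seed=42)
        bundles[d] = ss.generate_class(spec)
    records = ss.generate_background_records(seed=43)
    bg6 = sample_background(records, 120, 6, seed=44)
    bg4 = sample_background(records, 120, 4, seed=44)
    return bundles, bg6, bg4


class TestAssembleNegatives:
    @pytest.mark.parametrize(
        "domain,expected", [("SH3", 425), ("WW", 400), ("PDZ", 375)]
    )
    def test_unbalanced_union_counts(self, class_sets, domain, expected):
        positives, bg6, bg4 = class_sets
        bg = bg6 if domain in ("SH3", "WW") else bg4
        neg = assemble_negatives(domain, positives, bg, seed=0)
        assert len(neg) == expected
        others = [d for d in ("SH3", "WW", "PDZ") if d != domain]
        assert len(neg) == sum(len(positives[d]) for d in others) + len(bg)

    @pytest.mark.parametrize("domain", ["SH3", "WW", "PDZ"])
    def test_balanced_is_one_to_one(self, class_sets, domain):
        positives, bg6, bg4 = class_sets
        bg = bg6 if domain in ("SH3", "WW") else bg4
        neg = assemble_negatives(domain, positives, bg, balance_mode="balanced", seed=0)
        assert len(neg) == len(positives[domain])
        assert sum(BALANCED_QUOTAS[domain].values()) == len(positives[domain])

    def test_cross_class_negatives_fit_window_length(self, class_sets):
        positives, bg6, bg4 = class_sets
        for domain, L in (("SH3", 6), ("WW", 6), ("PDZ", 4)):
            bg = bg6 if L == 6 else bg4
            neg = assemble_negatives(domain, positives, bg, seed=0)
            assert all(len(e.sequence) == L for e in neg)

    def test_pdz_negatives_are_c_terminal_trims(self, class_sets):
        positives, _, bg4 = class_sets
        neg = assemble_negatives("PDZ", positives, bg4, seed=0)
        sh3_derived = [e for e in neg if e.domain_class == "SH3"]
        originals = {e.protein_id: e.sequence for e in positives["SH3"]}
        assert all(
            e.sequence == originals[e.protein_id][-4:] for e in sh3_derived
        )

    def test_quota_exceeding_pool_names_source(self, class_sets):
        positives, bg6, _ = class_sets
        with pytest.raises(ValueError, match="background"):
            assemble_negatives(
                "SH3", positives, bg6, balance_mode="balanced",
                quotas={"WW": 1, "PDZ": 1, "background": 10_000}, seed=0,
            )

    def test_wrong_background_length_rejected(self, class_sets):
        positives, _, bg4 = class_sets
        with pytest.raises(ValueError, match="length 6"):
            assemble_negatives("SH3", positives, bg4, seed=0)


class TestSampleBackground:
    def test_seeded_determinism(self):
        records = ss.generate_background_records(n=5, seed=7)
        a = sample_background(records, 120, 6, seed=11)
        b = sample_background(records, 120, 6, seed=11)
        assert [e.key for e in a] == [e.key for e in b]

    def test_nonpositive_count_rejected(self):
        records = ss.generate_background_records(n=2, seed=7)
        with pytest.raises(ValueError):
            sample_background(records, 0, 6, seed=0)

    def test_all_records_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_background([SequenceRecord(id="s", sequence="PPP")], 5, 6)

    def test_single_window_forced_outcome(self):
        rec = SequenceRecord(id="only", sequence="ACDEFG")
        out = sample_background([rec], 3, 6, seed=0)
        assert [e.sequence for e in out] == ["ACDEFG"] * 3
        assert all(e.start == 1 and e.is_c_terminal for e in out)


def _toy_bundle(n_pos=10, n_neg=10):
    pos = [_entry(f"PPPPP{a}", protein=f"p{i}") for i, a in enumerate("ACDEFGHIKL"[:n_pos])]
    neg = [_entry(f"AAAAA{a}", protein=f"n{i}") for i, a in enumerate("ACDEFGHIKL"[:n_neg])]
    return DatasetBundle(domain_class="SH3", positives=pos, negatives=neg)


class TestMakeFolds:
    def test_stratified_small(self):
        folds = make_folds(_toy_bundle(), n_folds=5, seed=0)
        labels = _toy_bundle().labels()
        for k in range(5):
            te = folds.test_indices(k)
            assert len(te) == 4
            assert np.sum(labels[te] == 1) == 2
            assert np.sum(labels[te] == -1) == 2

    def test_partition_invariants(self, sh3_bundle):
        folds = make_folds(sh3_bundle, seed=3)
        n = sh3_bundle.n_pos + sh3_bundle.n_neg
        all_test = np.concatenate([folds.test_indices(k) for k in range(5)])
        assert sorted(all_test.tolist()) == list(range(n))
        sizes = [len(folds.test_indices(k)) for k in range(5)]
        assert max(sizes) - min(sizes) <= 2  # at most 1 per stratum

    def test_fold_sizes_divide_evenly(self):
        # 540 examples over 5 folds -> 108 each
        pos = [_entry("PPPPPP", protein=f"p{i}", start=i) for i in range(115)]
        neg = [_entry("AAAAAA", protein=f"n{i}", start=i) for i in range(425)]
        bundle = DatasetBundle("SH3", pos, neg)
        folds = make_folds(bundle, seed=0)
        assert all(len(folds.test_indices(k)) == 108 for k in range(5))

    def test_same_seed_identical(self, sh3_bundle):
        a = make_folds(sh3_bundle, seed=5).assignment
        b = make_folds(sh3_bundle, seed=5).assignment
        assert np.array_equal(a, b)

    def test_too_few_examples(self):
        with pytest.raises(ValueError):
            make_folds(_toy_bundle(n_pos=3, n_neg=10), n_folds=5)


class TestBundleAndTSV:
    def test_overlap_rejected(self):
        e = _entry("PPPPPP")
        with pytest.raises(ValueError, match="share"):
            DatasetBundle("SH3", [e], [e])

    def test_tsv_roundtrip(self, tmp_path, sh3_bundle):
        path = tmp_path / "sh3.tsv"
        write_dataset(sh3_bundle, path)
        back = read_dataset(path, "SH3")
        assert [e.sequence for e in back.positives] == [
            e.sequence for e in sh3_bundle.positives
        ]
        assert back.n_neg == sh3_bundle.n_neg
        assert [e.is_c_terminal for e in back.negatives] == [
            e.is_c_terminal for e in sh3_bundle.negatives
        ]
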