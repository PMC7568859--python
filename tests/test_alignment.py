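"""Alignment container, gap masking, concatenation, dataset derivation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plastosig as ps
from plastosig.alignment import Locus, PartitionMap
from plastosig.errors import DataError

def toy_loci():
    return [
        ("lA", "coding", ps.Alignment(["s1", "s2"], ["ACGTACGTAC",
                                                     "ACGTACGTAG"])),
        ("lB", "igs", ps.Alignment(["s1", "s3"], ["TTTTTTTTTTTTTTTTTTTT",
                                                  "TTTTTTTTTTTTTTTTTTTA"])),
    ]


class TestMasking:
    def test_gap_free_alignment_unchanged(self):
        aln = ps.Alignment(["a", "b"], ["ACGT", "ACGA"])
        for threshold in (0.0, 0.5, 1.0):
            assert ps.mask_gap_columns(aln, threshold) == aln

    def test_threshold_semantics_on_toy(self):
        # per-column gap fractions: 0, 0.25, 0.5, 0.75
        aln = ps.Alignment(list("wxyz"), ["ACGT", "ACG-", "AC--", "A---"])
        masked = ps.mask_gap_columns(aln, 0.5)
        assert masked.n_sites == 3
        assert ps.mask_gap_columns(aln, 0.0).n_sites == 1

    def test_all_columns_removed_is_an_error(self):
        aln = ps.Alignment(["a", "b"], ["A-", "-A"])
        with pytest.raises(DataError, match="empty alignment"):
            ps.mask_gap_columns(aln, 0.2)

    def test_partition_remapped_to_survivors(self):
        aln = ps.Alignment(["a", "b"], ["AC-GT-", "ACCG--"])
        part = PartitionMap([Locus("x", "coding", ((0, 3),)),
                             Locus("y", "igs", ((3, 6),))])
        # gap fractions per column: 0, 0, .5, 0, .5, 1
        masked, remapped = ps.mask_gap_columns(aln, 0.25, part)
        assert masked.n_sites == 3
        assert remapped.get("x").ranges == ((0, 2),)
        assert remapped.get("y").ranges == ((2, 3),)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1), st.floats(0, 1), st.floats(0, 1))
    def test_masking_idempotent_and_monotone(self, seed, t1, t2):
        rng = np.random.default_rng(seed)
        mat = rng.choice(list("ACGT-"), size=(4, 30), p=[.2, .2, .2, .2, .2])
        aln = ps.Alignment(list("abcd"), ["".join(r) for r in mat])
        lo, hi = sorted((t1, t2))
        try:
            masked_hi = ps.mask_gap_columns(aln, hi)
        except DataError:
            return  # everything gappy enough to vanish
        assert ps.mask_gap_columns(masked_hi, hi) == masked_hi
        try:
            masked_lo = ps.mask_gap_columns(aln, lo)
        except DataError:
            return
        assert masked_lo.n_sites <= masked_hi.n_sites


class TestConcatenation:
    def test_ranges_and_total_columns(self):
        aln, part = ps.concatenate_loci(toy_loci())
        assert aln.n_sites == 30
        assert part.get("lA").ranges == ((0, 10),)
        assert part.get("lB").ranges == ((10, 30),)

    def test_missing_taxon_padded_with_gaps(self):
        aln, part = ps.concatenate_loci(toy_loci())
        assert aln.sequence("s3")[:10] == "-" * 10
        assert aln.sequence("s2")[10:] == "-" * 20

    def test_split_round_trip(self):
        loci = toy_loci()
        aln, part = ps.concatenate_loci(loci)
        back = ps.split_by_partition(aln, part)
        for name, _, original in loci:
            sub = back[name]
            for taxon in original.taxa:
                assert sub.sequence(taxon) == original.sequence(taxon)

    def test_duplicate_locus_name_rejected(self):
        loci = toy_loci() + [("lA", "igs",
                              ps.Alignment(["s1", "s2"], ["AA", "AA"]))]
        with pytest.raises(DataError, match="duplicate"):
            ps.concatenate_loci(loci)


class TestDeriveDataset:
    def setup_method(self):
        self.aln, self.part = ps.concatenate_loci(
            toy_loci() + [("lC", "coding",
                           ps.Alignment(["s1", "s2"], ["GGGGG", "GGGGA"]))])

    def test_identity_selection(self):
        sub, part = ps.derive_dataset(self.aln, self.part, "all")
        assert sub == self.aln
        assert part.names == self.part.names

    def test_cds_only(self):
        sub, part = ps.derive_dataset(self.aln, self.part, "cds_only")
        assert part.names == ["lA", "lC"]
        assert sub.n_sites == 15

    def test_noncds_only(self):
        sub, part = ps.derive_dataset(self.aln, self.part, "noncds_only")
        assert part.names == ["lB"]
        assert sub.n_sites == 20

    def test_exclusion_and_unknown_name(self):
        sub, part = ps.derive_dataset(self.aln, self.part, "all",
                                      exclude=["lB"])
        assert part.names == ["lA", "lC"]
        with pytest.raises(DataError, match="nope"):
            ps.derive_dataset(self.aln, self.part, "all", exclude=["nope"])


class TestPartitionIO:
    def test_tsv_round_trip(self, tmp_path):
        _, part = ps.concatenate_loci(toy_loci())
        path = tmp_path / "p.tsv"
        part.to_tsv(path)
        again = PartitionMap.from_tsv(path)
        assert again.names == part.names
        assert [l.ranges for l in again] == [l.ranges for l in part]

    def test_raxml_format(self, tmp_path):
        _, part = ps.concatenate_loci(toy_loci())
        path = tmp_path / "p.part"
        part.to_raxml(path)
        text = path.read_text()
        assert "DNA, lA = 1-10" in text
        assert "DNA, lB = 11-30" in text

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(DataError, match="overlap"):
            PartitionMap([Locus("x", "coding", ((0, 5),)),
                          Locus("y", "igs", ((4, 8),))])
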