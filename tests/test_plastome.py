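"""Plastome structure detection, statistics and locus extraction."""

import numpy as np
import pytest

import plastosig as ps
from plastosig.errors import DataError, StructureError
from plastosig.plastome import (Feature, PlastomeRecord, revcomp,
                                rotate_sequence, normalize_rotation)

from oracles import longest_inverted_repeat_bruteforce

MINI_GENBANK = """\
LOCUS       MINI0001                 100 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  handcrafted miniature record.
ACCESSION   MINI0001
VERSION     MINI0001.1
FEATURES             Location/Qualifiers
     source          1..100
                     /organism="synthetic construct"
     CDS             11..40
                     /gene="matK"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def plant_ir(rng, n, ir_len, gap_frac=0.35):
    """Random sequence with one planted inverted repeat; returns
    (sequence, a_start, b_start)."""
    a_start = n // 10
    b_start = a_start + ir_len + int(n * gap_frac)
    seq = list(random_seq(rng, n))
    core = random_seq(rng, ir_len)
    seq[a_start:a_start + ir_len] = core
    seq[b_start:b_start + ir_len] = revcomp(core)
    comp = dict(zip("ACGT", "TGCA"))
    # block chance extension at all four boundaries
    seq[a_start - 1] = "A" if comp[seq[b_start + ir_len]] != "A" else "C"
    seq[a_start + ir_len] = "A" if comp[seq[b_start - 1]] != "A" else "C"
    return "".join(seq), a_start, b_start


class TestGenBankIO:
    def test_minimal_handcrafted_record(self, tmp_path):
        path = tmp_path / "mini.gb"
        path.write_text(MINI_GENBANK)
        record = ps.read_plastome_record(path)
        assert record.length == 100
        assert len(record.features) == 1
        feat = record.features[0]
        assert feat.name == "matK"
        assert feat.intervals == ((10, 40),)

    def test_synthetic_record_round_trip(self, tmp_path, synth_plastome):
        record, _ = synth_plastome
        path = tmp_path / "synth.gb"
        ps.write_genbank(record, path)
        again = ps.read_plastome_record(path)
        assert again.length == record.length
        assert again.sequence == record.sequence
        key = lambda f: (f.span, f.name, f.kind)
        for a, b in zip(sorted(record.features, key=key),
                        sorted(again.features, key=key)):
            assert (a.name, a.kind, a.strand) == (b.name, b.kind, b.strand)
            assert sorted(a.intervals) == sorted(b.intervals)

    def test_feature_outside_sequence_rejected(self):
        with pytest.raises(DataError, match="outside"):
            PlastomeRecord(id="x", sequence="ACGT" * 10,
                           features=[Feature("g", "CDS", ((30, 50),))])


class TestQuadripartiteDetection:
    def test_planted_exact_recovery(self, synth_plastome):
        record, truth = synth_plastome
        found = ps.detect_quadripartite(record.sequence)
        assert found.regions() == truth.regions()

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(12):
            n = int(rng.integers(3000, 6000))
            ir_len = int(rng.integers(200, 600))
            seq, a_start, b_start = plant_ir(rng, n, ir_len)
            want_len, want_a, want_b = \
                longest_inverted_repeat_bruteforce(seq)
            got = ps.detect_quadripartite(seq, min_ir_length=150)
            starts = sorted((got.ira.start, got.irb.start))
            assert got.ir_length == want_len
            assert starts == [want_a, want_b]

    def test_no_repeat_is_an_error(self):
        rng = np.random.default_rng(22)
        with pytest.raises(StructureError, match="no quadripartite"):
            ps.detect_quadripartite(random_seq(rng, 5000), min_ir_length=300)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(StructureError):
            ps.detect_quadripartite("ACGT" * 100, min_ir_length=1000)


class TestRegionStats:
    def test_all_gc_sequence(self):
        rng = np.random.default_rng(23)
        core = "".join(rng.choice(["G", "C"], size=400))
        seq, a, b = plant_ir(rng, 4000, 300)
        # build a fully-GC genome with a planted GC inverted repeat
        gc = "".join(np.random.default_rng(24).choice(["G", "C"], size=4000))
        gc = gc[:500] + core + gc[800:2500] + revcomp(core) + gc[2800:]
        record = PlastomeRecord(id="gc", sequence=gc)
        structure = ps.detect_quadripartite(gc, min_ir_length=200)
        stats = ps.region_stats(record, structure)
        assert (stats.total_gc, stats.lsc_gc, stats.ir_gc,
                stats.ssc_gc) == (100.0, 100.0, 100.0, 100.0)

    def test_length_identity_and_plastome_gc_profile(self, synth_plastome):
        record, truth = synth_plastome
        stats = ps.region_stats(record, truth)
        assert stats.lsc_bp + stats.ssc_bp + 2 * stats.ir_bp \
            == stats.total_bp == record.length
        # plastome GC ordering: IR > LSC > SSC
        assert stats.ir_gc > stats.lsc_gc > stats.ssc_gc

    def test_rotation_changes_coordinates_not_lengths_or_gc(
            self, synth_plastome):
        record, truth = synth_plastome
        rotated = rotate_sequence(record.sequence, 47_001)
        structure = ps.detect_quadripartite(rotated)
        assert structure.ir_length == truth.ir_length
        assert {structure.lsc.length, structure.ssc.length} \
            == {truth.lsc.length, truth.ssc.length}
        stats = ps.region_stats(PlastomeRecord(id="r", sequence=rotated),
                                structure)
        want = ps.region_stats(record, truth)
        assert stats == want

    def test_normalize_rotation_puts_lsc_at_zero(self, synth_plastome):
        record, truth = synth_plastome
        rec2, st2 = normalize_rotation(record, truth)
        assert st2.lsc.start == 0
        assert ps.count_genes(rec2, st2) == ps.count_genes(record, truth)


class TestGeneCounts:
    def test_single_cds_record(self):
        record = PlastomeRecord(id="x", sequence="ACGT" * 30,
                                features=[Feature("matK", "CDS", ((0, 30),))])
        counts = ps.count_genes(record)
        assert counts.unique_genes == 1
        assert counts.unique_cds == 1
        assert counts.total_genes == 1

    def test_synthetic_inventory_counts(self, synth_plastome):
        record, truth = synth_plastome
        counts = ps.count_genes(record, truth)
        assert counts.unique_genes == 112
        assert counts.unique_cds == 78
        assert counts.unique_trna == 30
        assert counts.unique_rrna == 4
        assert counts.ir_duplicated == 13
        assert counts.total_genes == 125


class TestLocusExtraction:
    def toy_record(self):
        seq = "A" * 400
        feats = [Feature("geneA", "CDS", ((50, 110),)),
                 Feature("geneB", "CDS", ((160, 220),))]
        return PlastomeRecord(id="toy", sequence=seq, features=feats)

    def test_igs_between_adjacent_genes(self):
        loci = ps.extract_loci([self.toy_record()], ir_policy="keep_both")
        by_name = {l.name: l for l in loci}
        igs = by_name["genea-geneb"]
        assert igs.kind == "igs"
        assert len(igs.sequences["toy"]) == 50

    def test_two_exon_gene_yields_coding_plus_intron(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), 500))
        feats = [Feature("geneC", "CDS", ((100, 160), (220, 280)))]
        record = PlastomeRecord(id="t2", sequence=seq, features=feats)
        by_name = {l.name: l for l in
                   ps.extract_loci([record], ir_policy="keep_both")}
        assert len(by_name["genec"].sequences["t2"]) == 120
        intron = by_name["genec_intron"]
        assert intron.kind == "intron"
        assert intron.sequences["t2"] == seq[160:220]

    def test_coverage_identity_on_synthetic_record(self, synth_plastome):
        """With IRb dropped and non-overlapping features, extracted loci
        tile the genome minus one IR copy exactly."""
        record, truth = synth_plastome
        loci = ps.extract_loci([record], structures={record.id: truth})
        total = sum(len(s) for l in loci for s in l.sequences.values())
        assert total == record.length - truth.ir_length

    def test_min_records_drops_rare_loci(self):
        rec1 = self.toy_record()
        rec2 = PlastomeRecord(id="toy2", sequence="A" * 400,
                              features=[Feature("geneA", "CDS", ((50, 110),))])
        loci = ps.extract_loci([rec1, rec2], ir_policy="keep_both",
                               min_records=2)
        names = {l.name for l in loci}
        assert "genea" in names
        assert "geneb" not in names

    def test_conflicting_duplicate_gene_rejected(self, synth_plastome):
        record, truth = synth_plastome
        bad = PlastomeRecord(
            id="dup", sequence=record.sequence,
            features=list(record.features)
            + [Feature(record.features[0].name, record.features[0].kind,
                       ((1000, 1300),))])
        with pytest.raises(DataError, match="conflicting duplicate"):
            ps.extract_loci([bad], structures={"dup": truth})

    def test_trans_spliced_gene_excluded_by_default(self):
        seq = "C" * 600
        feats = [Feature("rps12", "CDS", ((10, 70),)),
                 Feature("geneA", "CDS", ((100, 160),)),
                 Feature("geneB", "CDS", ((200, 260),))]
        record = PlastomeRecord(id="ts", sequence=seq, features=feats)
        names = {l.name for l in
                 ps.extract_loci([record], ir_policy="keep_both")}
        assert "rps12" not in names
        assert {"genea", "geneb"} <= names
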