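"""Sequence simulation: expectations, determinism, conflict bookkeeping."""

import logging

import numpy as np
import pytest

import plastosig as ps
from plastosig.errors import DataError
from plastosig.likelihood import TreeLikelihood
from plastosig.synthdata import three_subclade_newick, RESOLUTIONS


class TestSimulateAlignment:
    def test_zero_branch_lengths_give_identical_rows(self):
        tree = ps.PhyloTree.from_newick("((a:0,b:0):0,c:0,d:0);")
        aln = ps.simulate_alignment(tree, ps.plastome_like_model(), 200,
                                    seed=0)
        rows = {aln.sequence(t) for t in aln.taxa}
        assert len(rows) == 1

    def test_two_taxon_jc_expected_p_distance(self, jc_model):
        """At t=0.3 total the expected mismatch fraction is
        3/4 (1 - exp(-0.4))."""
        tree = ps.PhyloTree.from_newick("(a:0.15,b:0.15);")
        n = 100_000
        aln = ps.simulate_alignment(tree, jc_model, n, seed=1)
        mism = np.mean(np.frombuffer(aln.sequence("a").encode(), "S1")
                       != np.frombuffer(aln.sequence("b").encode(), "S1"))
        expect = 0.75 * (1 - np.exp(-0.4))
        sigma = np.sqrt(expect * (1 - expect) / n)
        assert abs(mism - expect) < 3 * sigma

    def test_seeded_determinism(self):
        tree = ps.PhyloTree.from_newick("((a:0.1,b:0.1):0.05,c:0.1,d:0.2);")
        model = ps.plastome_like_model()
        a = ps.simulate_alignment(tree, model, 500, seed=42)
        b = ps.simulate_alignment(tree, model, 500, seed=42)
        assert a == b

    def test_base_composition_converges_to_stationary(self):
        model = ps.plastome_like_model()
        tree = ps.PhyloTree.from_newick("(a:0.4,b:0.4);")
        n = 50_000
        aln = ps.simulate_alignment(tree, model, n, seed=3)
        counts = np.array([aln.sequence("a").count(c) for c in "ACGT"])
        for obs, pi in zip(counts, model.freqs):
            sigma = np.sqrt(n * pi * (1 - pi))
            assert abs(obs - n * pi) < 3 * sigma


class TestConflictDataset:
    def test_bookkeeping_and_truth_labels(self):
        cfg = ps.default_conflict_config(seed=2, preset="reduced")
        aln, part, truth = ps.simulate_conflict_dataset(cfg)
        assert aln.n_sites == truth["length"].sum()
        assert len(part) == cfg.n_loci == len(truth)
        assert (truth["source"] == "minority").sum() == 6
        planted = truth.loc[truth.source == "minority", "length"]
        assert planted.between(700, 900).all()

    def test_zero_conflict_fraction_all_majority(self, caplog):
        cfg = ps.ConflictSimConfig(
            majority_tree=three_subclade_newick(RESOLUTIONS["T1"]),
            minority_tree=three_subclade_newick(RESOLUTIONS["T2"]),
            n_loci=5, conflict=0, locus_length=(50, 80), seed=1)
        with caplog.at_level(logging.WARNING):
            _, _, truth = ps.simulate_conflict_dataset(cfg)
        assert (truth["source"] == "majority").all()
        assert any("0 loci" in r.message for r in caplog.records)

    def test_explicit_conflict_indices(self):
        cfg = ps.ConflictSimConfig(
            majority_tree=three_subclade_newick(RESOLUTIONS["T1"]),
            minority_tree=three_subclade_newick(RESOLUTIONS["T2"]),
            n_loci=8, conflict=[1, 4], locus_length=(50, 80), seed=1)
        _, _, truth = ps.simulate_conflict_dataset(cfg)
        assert list(truth.loc[truth.source == "minority"].index) == [1, 4]

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(DataError, match="share leaves"):
            ps.ConflictSimConfig(
                majority_tree="((a:1,b:1):1,c:1,d:1);",
                minority_tree="((a:1,x:1):1,c:1,d:1);")

    def test_focal_branch_length_drives_planted_signal(self):
        """Median |delta-lnL| of planted loci grows with the length of
        the minority tree's focal edge (scored on the true trees)."""
        model = ps.plastome_like_model()
        majority = ps.PhyloTree.from_newick(
            three_subclade_newick(RESOLUTIONS["T1"], focal_length=0.001))
        medians = []
        for focal in (0.005, 0.03):
            minority = ps.PhyloTree.from_newick(
                three_subclade_newick(RESOLUTIONS["T2"],
                                      focal_length=focal))
            rng_deltas = []
            for seed in range(4):
                aln = ps.simulate_alignment(minority, model, 800,
                                            seed=100 + seed)
                la = TreeLikelihood(aln, majority,
                                    model).total_log_likelihood()
                lb = TreeLikelihood(aln, minority,
                                    model).total_log_likelihood()
                rng_deltas.append(abs(la - lb))
            medians.append(np.median(rng_deltas))
        assert medians[1] > medians[0]


class TestSyntheticPlastome:
    def test_inventory_must_fit(self):
        with pytest.raises(DataError):
            ps.synth_plastome_record(total_bp=50_000, ir_bp=20_000,
                                     ssc_bp=5_000, seed=0)
        with pytest.raises(DataError, match="smaller than total"):
            ps.synth_plastome_record(total_bp=30_000, ir_bp=14_000,
                                     ssc_bp=4_000, seed=0)

    def test_deterministic_by_seed(self):
        a, _ = ps.synth_plastome_record(seed=9)
        b, _ = ps.synth_plastome_record(seed=9)
        assert a.sequence == b.sequence
        assert [f.intervals for f in a.features] \
            == [f.intervals for f in b.features]
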