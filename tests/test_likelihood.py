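"""Pruning engine against closed forms, enumeration, and invariances."""

import dendropy
import numpy as np
import pytest

import plastosig as ps
from plastosig.errors import DataError

from oracles import enumeration_site_loglik, jc_site_loglik
from test_substmodel import random_model


def random_instance(n_taxa, n_sites, rng, p_inv=None):
    """Random tree + model + unrelated random data (worst-case patterns)."""
    names = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{n}:{rng.uniform(0.01, 0.4):.4f}" for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        pair = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.01, 0.4):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [pair]
    tree = ps.PhyloTree.from_newick("(" + ",".join(nodes) + ");")
    model = random_model(rng, p_inv=p_inv)
    mat = rng.choice(list("ACGT"), size=(n_taxa, n_sites))
    aln = ps.Alignment(names, ["".join(r) for r in mat])
    return aln, tree, model


class TestClosedForms:
    def test_two_taxon_jukes_cantor(self, jc_model):
        tree = ps.PhyloTree.from_newick("(A:0.15,B:0.15);")
        aln = ps.Alignment(["A", "B"], ["ACGTAC", "ACGTAG"])
        site = ps.TreeLikelihood(aln, tree, jc_model).site_log_likelihoods()
        for i in range(5):
            assert site[i] == pytest.approx(jc_site_loglik(0.3, True),
                                            abs=1e-10)
        assert site[5] == pytest.approx(jc_site_loglik(0.3, False), abs=1e-10)

    def test_zero_branches_identical_sequences(self, jc_model):
        tree = ps.PhyloTree.from_newick("((A:0,B:0):0,C:0,D:0);")
        aln = ps.Alignment(list("ABCD"), ["ACGT"] * 4)
        site = ps.TreeLikelihood(aln, tree, jc_model).site_log_likelihoods()
        assert np.allclose(site, np.log(0.25), atol=1e-12)


class TestEnumerationOracle:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(6):
            aln, tree, model = random_instance(int(rng.integers(4, 7)), 40,
                                               rng)
            tl = ps.TreeLikelihood(aln, tree, model)
            want = enumeration_site_loglik(aln, tree, model)
            assert np.abs(tl.site_log_likelihoods() - want).max() < 1e-10


class TestInvariances:
    def test_sum_of_sites_equals_total(self):
        rng = np.random.default_rng(3)
        aln, tree, model = random_instance(6, 80, rng)
        tl = ps.TreeLikelihood(aln, tree, model)
        assert tl.total_log_likelihood() == pytest.approx(
            tl.site_log_likelihoods().sum(), abs=1e-9)

    def test_root_placement_invariance(self):
        """Pulley principle: rerooting a reversible-model tree changes
        no site log-likelihood."""
        rng = np.random.default_rng(4)
        aln, tree, model = random_instance(6, 60, rng)
        base = ps.TreeLikelihood(aln, tree, model).site_log_likelihoods()
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                               preserve_underscores=True)
        for edge in list(dt.preorder_edge_iter())[3:6]:
            if edge.head_node is dt.seed_node or edge.length is None:
                continue
            dt.reroot_at_edge(edge, length1=edge.length / 2,
                              length2=edge.length / 2,
                              update_bipartitions=False)
            rerooted = ps.PhyloTree.from_dendropy(dt)
            got = ps.TreeLikelihood(aln, rerooted,
                                    model).site_log_likelihoods()
            assert np.abs(got - base).max() < 1e-10

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(5)
        aln, tree, model = random_instance(5, 50, rng)
        perm = list(rng.permutation(aln.n_taxa))
        shuffled = ps.Alignment([aln.taxa[i] for i in perm],
                                aln.matrix[perm])
        a = ps.TreeLikelihood(aln, tree, model).total_log_likelihood()
        b = ps.TreeLikelihood(shuffled, tree, model).total_log_likelihood()
        assert a == pytest.approx(b, abs=1e-9)


class TestMissingData:
    def test_gaps_and_ambiguities_partial_likelihood(self, jc_model):
        """A fully ambiguous taxon contributes likelihood one: the site
        lnL equals that of the remaining pair."""
        tree3 = ps.PhyloTree.from_newick("(A:0.1,B:0.1,C:0.7);")
        aln3 = ps.Alignment(list("ABC"), ["AC", "AG", "--"])
        pair = ps.PhyloTree.from_newick("(A:0.1,B:0.1);")
        aln2 = ps.Alignment(list("AB"), ["AC", "AG"])
        got = ps.TreeLikelihood(aln3, tree3, jc_model).site_log_likelihoods()
        want = ps.TreeLikelihood(aln2, pair, jc_model).site_log_likelihoods()
        assert np.allclose(got, want, atol=1e-10)
        # R = A or G: site with A,R is a mixture of match and mismatch
        alnr = ps.Alignment(list("AB"), ["A", "R"])
        site = ps.TreeLikelihood(alnr, pair, jc_model).site_log_likelihoods()
        from oracles import jc_site_loglik
        expect = np.logaddexp(jc_site_loglik(0.2, True),
                              jc_site_loglik(0.2, False))
        assert site[0] == pytest.approx(expect, abs=1e-10)

    def test_all_gap_site_contributes_zero(self, jc_model):
        tree = ps.PhyloTree.from_newick("(A:0.1,B:0.2);")
        aln = ps.Alignment(["A", "B"], ["A-", "A-"])
        site = ps.TreeLikelihood(aln, tree, jc_model).site_log_likelihoods()
        assert site[1] == pytest.approx(0.0, abs=1e-12)

    def test_taxon_mismatch_rejected(self, jc_model):
        tree = ps.PhyloTree.from_newick("(A:0.1,B:0.2);")
        aln = ps.Alignment(["A", "X"], ["AC", "AG"])
        with pytest.raises(DataError, match="do not match"):
            ps.TreeLikelihood(aln, tree, jc_model)
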