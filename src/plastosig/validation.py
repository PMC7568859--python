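"""Reference oracles and validation experiments.

Everything here recomputes quantities by routes independent of the main
implementation — exhaustive enumeration over ancestral states, truncated
series, numerical quadrature, closed forms — or runs seeded end-to-end
experiments (planted-conflict recovery, test calibration) whose expected
outcomes are known by construction.  The functions return plain dicts of
numbers so they can back both the test suite and a validation script.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from .alignment import Alignment
from .fit import FreeParams, optimize_fixed_topology
from .phylotree import PhyloTree
from .signal import (SiteLnLMatrix, fit_topologies, locuswise_delta,
                     removal_experiment, sorted_by_magnitude)
from .substmodel import (GTRTransition, SubstitutionModel,
                         discrete_gamma_rates, gtr_rate_matrix)
from .synthdata import candidate_topologies, default_conflict_config, \
    simulate_conflict_dataset
from .likelihood import TreeLikelihood
from .topotests import au_test, kh_test, sh_test

# ------------------------------------------------------------- oracles


def series_matrix_exponential(q: np.ndarray, t: float,
                              terms: int = 60) -> np.ndarray:
    """Truncated power series sum_k (Qt)^k / k!."""
    acc = np.eye(4)
    term = np.eye(4)
    qt = q * t
    for k in range(1, terms + 1):
        term = term @ qt / k
        acc = acc + term
    return acc


def gamma_rates_by_quadrature(alpha: float, k: int) -> np.ndarray:
    """Mean-category discrete-gamma rates via adaptive integration."""
    edges = gamma_dist.ppf(np.arange(0, k + 1) / k, alpha, scale=1.0 / alpha)
    edges[0], edges[-1] = 0.0, np.inf
    rates = []
    for lo, hi in zip(edges, edges[1:]):
        val, _ = quad(lambda x: x * gamma_dist.pdf(x, alpha,
                                                   scale=1.0 / alpha),
                      lo, hi, limit=200)
        rates.append(val * k)
    return np.asarray(rates)


def jc_site_loglik(t: float, match: bool) -> float:
    """Two-taxon Jukes-Cantor per-site log-likelihood."""
    e = np.exp(-4.0 * t / 3.0)
    if match:
        return float(np.log(0.25 * (0.25 + 0.75 * e)))
    return float(np.log(0.25 * (0.25 - 0.25 * e)))


def jc_distance(k_mismatch: int, n_sites: int) -> float:
    """Closed-form Jukes-Cantor ML distance."""
    p = k_mismatch / n_sites
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))


def enumeration_site_loglik(aln: Alignment, tree: PhyloTree,
                            model: SubstitutionModel) -> np.ndarray:
    """Site lnL by brute-force summation over all internal-state
    assignments (viable only for a handful of taxa)."""
    trans = GTRTransition(model)
    rates = model.category_rates()
    codes = np.array([["ACGT".index(c) for c in aln.sequence(t)]
                      for t in tree.leaf_names])
    n_sites = codes.shape[1]
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    leaf_row = {node: i for i, node in enumerate(tree.leaf_indices)}
    like = np.zeros((len(rates), n_sites))
    for k, r in enumerate(rates):
        pmat = {i: trans.probability(float(tree.lengths[i]), r)
                for i in tree.edge_nodes}
        total = np.zeros(n_sites)
        for assign in itertools.product(range(4), repeat=len(internal)):
            state = dict(zip(internal, assign))
            vec = np.full(n_sites, model.freqs[state[tree.root]])
            for i in tree.edge_nodes:
                p_state = state[tree.parent[i]]
                if i in leaf_row:
                    vec = vec * pmat[i][p_state, codes[leaf_row[i]]]
                else:
                    vec = vec * pmat[i][p_state, state[i]]
            total += vec
        like[k] = total
    compat = np.ones((n_sites, 4), dtype=bool)
    for i, node in enumerate(tree.leaf_indices):
        compat &= np.arange(4)[None, :] == codes[i][:, None]
    invariant = compat @ model.freqs
    mixture = model.p_inv * invariant + (1 - model.p_inv) * like.mean(axis=0)
    return np.log(mixture)


def random_model(rng: np.random.Generator,
                 p_inv: float | None = None) -> SubstitutionModel:
    rates = rng.uniform(0.3, 3.0, 6)
    rates[5] = 1.0
    return SubstitutionModel(
        rates=rates, freqs=rng.dirichlet(np.ones(4) * 8),
        alpha=rng.uniform(0.2, 2.0), n_categories=4,
        p_inv=rng.uniform(0.0, 0.4) if p_inv is None else p_inv)


def random_likelihood_instance(rng: np.random.Generator, n_taxa: int,
                               n_sites: int):
    """Random unrooted tree, GTR+I+Gamma model, and random site data."""
    names = [f"t{i}" for i in range(n_taxa)]
    nodes = [f"{n}:{rng.uniform(0.01, 0.4):.4f}" for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        pair = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.01, 0.4):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [pair]
    tree = PhyloTree.from_newick("(" + ",".join(nodes) + ");")
    model = random_model(rng)
    mat = rng.choice(list("ACGT"), size=(n_taxa, n_sites))
    aln = Alignment(names, ["".join(r) for r in mat])
    return aln, tree, model


def _derive_seed(seed: int, i: int) -> int:
    """Stable sub-stream seed, kept within the 31-bit range."""
    return int((seed * 100_003 + i) % (2 ** 31 - 1))


# --------------------------------------------------------- experiments


def pruning_vs_enumeration(n_instances: int = 100, max_sites: int = 200,
                           seed: int = 0) -> dict:
    """Worst absolute site-lnL deviation of pruning from enumeration."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_taxa = int(rng.integers(4, 7))
        n_sites = int(rng.integers(20, max_sites + 1))
        aln, tree, model = random_likelihood_instance(rng, n_taxa, n_sites)
        got = TreeLikelihood(aln, tree, model).site_log_likelihoods()
        want = enumeration_site_loglik(aln, tree, model)
        worst = max(worst, float(np.abs(got - want).max()))
    return {"value": worst, "n": n_instances}


def closed_form_checks(seed: int = 0) -> dict:
    """Closed-form errors: two-taxon JC lnL, JC ML distance, discrete
    gamma vs quadrature, P(t) vs truncated series."""
    rng = np.random.default_rng(seed)
    jc = SubstitutionModel(n_categories=1)
    # per-site lnL at a random total distance
    t = float(rng.uniform(0.05, 1.0))
    tree = PhyloTree.from_newick(f"(A:{t / 2},B:{t / 2});")
    aln = Alignment(["A", "B"], ["ACGTA", "ACGTC"])
    site = TreeLikelihood(aln, tree, jc).site_log_likelihoods()
    lnl_err = max(abs(site[0] - jc_site_loglik(t, True)),
                  abs(site[4] - jc_site_loglik(t, False)))
    # ML distance for a random mismatch count
    n, k = 200, int(rng.integers(10, 60))
    aln2 = Alignment(["A", "B"], ["A" * n, "A" * (n - k) + "C" * k])
    fit = optimize_fixed_topology(
        aln2, PhyloTree.from_newick("(A:0.1,B:0.1);"), model=jc,
        free=FreeParams(branch_lengths=True, alpha=False, p_inv=False))
    dist_err = abs(fit.tree.total_length() - jc_distance(k, n))
    gamma_err = 0.0
    for alpha in (0.1, 0.5, 1.0, 3.7):
        gamma_err = max(gamma_err, float(np.abs(
            discrete_gamma_rates(alpha, 4)
            - gamma_rates_by_quadrature(alpha, 4)).max()))
    pt_err = 0.0
    for _ in range(5):
        model = random_model(rng)
        q = gtr_rate_matrix(model)
        trans = GTRTransition(model)
        for tt in (0.05, 0.3, 1.2):
            pt_err = max(pt_err, float(np.abs(
                trans.probability(tt)
                - series_matrix_exponential(q, tt)).max()))
    return {"jc_site_lnl_max_abs_err": lnl_err,
            "jc_ml_distance_max_abs_err": dist_err,
            "gamma_rates_max_abs_err": gamma_err,
            "transition_matrix_max_abs_err": pt_err}


@dataclass
class ConflictTrial:
    winner: str
    runner: str
    precision_top6: float
    n_strong_winner: int
    flipped: bool
    post_removal_winner: str
    table: object
    truth: object


def conflict_trial(seed: int, preset: str = "reduced") -> ConflictTrial:
    """One planted-conflict dataset through the full dissection.

    Fits all three resolutions, ranks loci by |delta-lnL| between the
    two best, removes the strong supporters of the winner and re-ranks.
    """
    cfg = default_conflict_config(seed=seed, preset=preset)
    aln, partition, truth = simulate_conflict_dataset(cfg)
    free = FreeParams(branch_lengths=True, alpha=False, p_inv=False)
    topologies = candidate_topologies()
    matrix, _ = fit_topologies(aln, topologies, model=cfg.model, free=free)
    totals = matrix.totals().sort_values(ascending=False)
    winner, runner = totals.index[0], totals.index[1]
    table = locuswise_delta(matrix, winner, runner, partition)
    planted = set(truth.loc[truth.source == "minority", "locus"])
    top6 = set(sorted_by_magnitude(table).head(6)["locus"])
    precision = len(top6 & planted) / 6.0
    strong = [x for x in table.loc[table.support == "strong_A", "locus"]
              if x != "_unpartitioned"]
    ranking = removal_experiment(aln, partition, topologies,
                                 model=cfg.model, exclude=strong, free=free)
    post = ranking.iloc[0]["topology"]
    return ConflictTrial(winner=winner, runner=runner,
                         precision_top6=precision,
                         n_strong_winner=len(strong),
                         flipped=post != winner, post_removal_winner=post,
                         table=table, truth=truth)


def planted_conflict_experiment(n_seeds: int = 20,
                                base_seed: int = 0) -> dict:
    precisions, flips, strong_counts = [], [], []
    for i in range(n_seeds):
        trial = conflict_trial(seed=_derive_seed(base_seed, i))
        precisions.append(trial.precision_top6)
        flips.append(trial.flipped)
        strong_counts.append(trial.n_strong_winner)
    return {"precision_mean": float(np.mean(precisions)),
            "flip_rate": float(np.mean(flips)),
            "strong_locus_count_mean": float(np.mean(strong_counts)),
            "n": n_seeds}


def _null_matrix(rng, n_sites: int = 400,
                 delta_sd: float = 0.15) -> SiteLnLMatrix:
    """Two topologies whose site-lnL differences are i.i.d. symmetric."""
    base = -np.abs(rng.normal(2.0, 0.7, n_sites))
    delta = rng.normal(0.0, delta_sd, n_sites)
    return SiteLnLMatrix(["a", "b"], np.vstack([base + delta, base]))


def kh_type1_error(n_trials: int = 500, n_sites: int = 1500,
                   n_replicates: int = 1500, alpha: float = 0.05,
                   seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    rejections = 0
    for i in range(n_trials):
        m = _null_matrix(rng, n_sites)
        p = kh_test(m, "a", "b", n_replicates,
                    seed=_derive_seed(seed, i))
        rejections += p < alpha
    return {"value": rejections / n_trials, "n": n_trials}


def sh_vs_kh_conservatism(n_trials: int = 200, n_sites: int = 300,
                          n_replicates: int = 500, seed: int = 0) -> dict:
    """Fraction of random instances with SH p >= one-sided KH p for the
    weaker of three topologies."""
    rng = np.random.default_rng(seed)
    wins = 0
    for i in range(n_trials):
        base = -np.abs(rng.normal(2.0, 0.7, n_sites))
        rows = [base + rng.normal(0.0, 0.3, n_sites) for _ in range(3)]
        m = SiteLnLMatrix(["T1", "T2", "T3"], np.vstack(rows))
        totals = m.matrix.sum(axis=1)
        best = m.labels[int(np.argmax(totals))]
        worst = m.labels[int(np.argmin(totals))]
        trial_seed = _derive_seed(seed, i)
        p_kh = kh_test(m, best, worst, n_replicates, seed=trial_seed,
                       two_sided=False)
        p_sh = sh_test(m, n_replicates, seed=trial_seed)[worst]
        wins += p_sh >= p_kh
    return {"value": wins / n_trials, "n": n_trials}


def au_vs_kh_null_rejection(n_trials: int = 200, n_sites: int = 400,
                            n_replicates: int = 1000, alpha: float = 0.05,
                            seed: int = 0) -> dict:
    """Null rejection rates of AU and KH on the same near-null matrices
    (the weaker topology is tested)."""
    rng = np.random.default_rng(seed)
    rej_au = rej_kh = 0
    for i in range(n_trials):
        m = _null_matrix(rng, n_sites)
        worse = m.labels[int(np.argmin(m.matrix.sum(axis=1)))]
        trial_seed = _derive_seed(seed, i)
        p_au = au_test(m, n_replicates=n_replicates, seed=trial_seed)[worse]
        p_kh = kh_test(m, "a", "b", n_replicates, seed=trial_seed)
        rej_au += p_au < alpha
        rej_kh += p_kh < alpha
    return {"au_rejection_rate": rej_au / n_trials,
            "kh_rejection_rate": rej_kh / n_trials,
            "n": n_trials}
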