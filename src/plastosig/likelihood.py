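"""Felsenstein pruning under GTR+I+Gamma with per-site log-likelihoods.

The engine compresses alignment columns into unique site patterns, runs the
pruning recursion per gamma category with per-pattern log scaling, and
mixes in the invariant-sites class:

    L(site) = p_inv * I(site) + (1 - p_inv) * (1/K) * sum_k L_k(site)

where ``I(site)`` is the summed stationary frequency of the states
compatible with every taxon at the site (zero if the site cannot be
constant) and ``L_k`` is the pruning likelihood at gamma rate k.

Besides plain evaluation the class exposes directed "message" caches
(conditional likelihoods looking into each edge from both sides), which
make single-branch likelihood curves cheap for the branch-length
optimiser.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment import Alignment
from .errors import DataError
from .phylotree import PhyloTree
from .substmodel import GTRTransition, SubstitutionModel

log = logging.getLogger(__name__)

_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "X": "ACGT", "?": "ACGT", "-": "ACGT",
}
_CODE_CHARS = list(_AMBIG)
#: partial-likelihood row per character code
PARTIALS = np.zeros((len(_CODE_CHARS), 4))
for _i, _c in enumerate(_CODE_CHARS):
    for _b in _AMBIG[_c]:
        PARTIALS[_i, "ACGT".index(_b)] = 1.0
_GAPLIKE = {_i for _i, _c in enumerate(_CODE_CHARS) if _c in "NX?-"}

_BYTE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_CODE_CHARS):
    _BYTE_TO_CODE[ord(_c)] = _i
    _BYTE_TO_CODE[ord(_c.lower())] = _i

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 100.0
_TINY = 1e-300


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Map an alignment to integer character codes (taxa x sites)."""
    codes = _BYTE_TO_CODE[aln.matrix.view(np.uint8)]
    if np.any(codes == 255):
        bad = np.unique(aln.matrix[codes == 255])
        raise DataError(f"unrecognised characters in alignment: {bad}")
    return codes


class TreeLikelihood:
    """Site log-likelihoods of an alignment on a fixed tree.

    Parameters
    ----------
    aln:
        Alignment whose taxa exactly match the tree's leaf labels.
    tree:
        :class:`PhyloTree` with branch lengths on every edge.
    model:
        GTR+I+Gamma parameters.
    compress:
        Collapse identical site patterns (weighted likelihoods); the
        per-site vector is re-expanded on demand.
    """

    def __init__(self, aln: Alignment, tree: PhyloTree,
                 model: SubstitutionModel, compress: bool = True):
        if set(aln.taxa) != set(tree.leaf_names):
            raise DataError("alignment taxa and tree leaves do not match: "
                            f"{sorted(set(aln.taxa) ^ set(tree.leaf_names))}")
        self.tree = tree.copy()
        idx = self.tree.edge_nodes
        if np.any(np.isnan(self.tree.lengths[idx])):
            raise DataError("tree is missing branch lengths")
        self.n_sites = aln.n_sites

        codes = encode_alignment(aln)
        order = [aln.taxa.index(name) for name in self.tree.leaf_names]
        codes = codes[order]
        if compress:
            patterns, inverse, counts = np.unique(
                codes, axis=1, return_inverse=True, return_counts=True)
            self._patterns = patterns
            self._inverse = inverse.ravel()
            self.weights = counts.astype(float)
        else:
            self._patterns = codes
            self._inverse = np.arange(codes.shape[1])
            self.weights = np.ones(codes.shape[1])
        self.n_patterns = self._patterns.shape[1]

        leaf_nodes = self.tree.leaf_indices
        self._tip = {node: PARTIALS[self._patterns[i]]
                     for i, node in enumerate(leaf_nodes)}
        compat = np.ones((self.n_patterns, 4), dtype=bool)
        for i, _ in enumerate(leaf_nodes):
            compat &= PARTIALS[self._patterns[i]] > 0
        all_gap = np.all(np.isin(self._patterns, list(_GAPLIKE)), axis=0)
        if np.any(all_gap):
            log.warning("%d all-gap/ambiguous site pattern(s); they "
                        "contribute log-likelihood 0", int(all_gap.sum()))
        self._compat = compat

        self.update_model(model)

    # ----------------------------------------------------------- model

    def update_model(self, model: SubstitutionModel) -> None:
        self.model = model
        self.trans = GTRTransition(model)
        self.rates = model.category_rates()
        self.K = len(self.rates)
        self._inv_like = self._compat @ model.freqs
        self._pmats = None
        self._stale = True

    def set_branch_length(self, node: int, t: float) -> None:
        self.tree.lengths[node] = t
        if self._pmats is not None:
            self._pmats[node] = self.trans.probabilities(
                np.array([t]), self.rates)[0]
        self._stale = True

    def _ensure_pmats(self) -> None:
        if self._pmats is None:
            lengths = np.where(np.isnan(self.tree.lengths), 0.0,
                               self.tree.lengths)
            self._pmats = self.trans.probabilities(lengths, self.rates)

    # -------------------------------------------------------- messages

    def _refresh(self) -> None:
        """Recompute all directed messages for current lengths/model."""
        if not self._stale:
            return
        self._ensure_pmats()
        K, npat = self.K, self.n_patterns
        n = self.tree.n_nodes
        self._W = np.empty((n, K, npat, 4))
        self._Wsc = np.zeros((n, K, npat))
        self._D = np.empty((n, K, npat, 4))
        self._Dsc = np.zeros((n, K, npat))
        root = self.tree.root
        for i in self.tree.postorder():
            kids = self.tree.children[i]
            if not kids:
                self._W[i] = self._tip[i][None, :, :]
                self._Wsc[i] = 0.0
            else:
                w = np.ones((K, npat, 4))
                sc = np.zeros((K, npat))
                for c in kids:
                    w = w * self._D[c]
                    sc = sc + self._Dsc[c]
                m = np.maximum(w.max(axis=-1), _TINY)
                w /= m[..., None]
                sc += np.log(m)
                self._W[i] = w
                self._Wsc[i] = sc
            if i != root:
                # D[i][x_parent] = sum_x P[x_parent, x] W[i][x]
                self._D[i] = np.einsum("kpb,kab->kpa", self._W[i],
                                       self._pmats[i])
                self._Dsc[i] = self._Wsc[i]

        # above-partials: A[c] = (pi at root | U[parent]) * prod(sibling D)
        self._A = np.empty((n, K, npat, 4))
        self._Asc = np.zeros((n, K, npat))
        self._U = np.empty((n, K, npat, 4))
        self._Usc = np.zeros((n, K, npat))
        pi = self.model.freqs
        for p in self.tree.preorder():
            kids = self.tree.children[p]
            for c in kids:
                if p == root:
                    a = np.broadcast_to(pi, (K, npat, 4)).copy()
                    sc = np.zeros((K, npat))
                else:
                    a = self._U[p].copy()
                    sc = self._Usc[p].copy()
                for s in kids:
                    if s != c:
                        a *= self._D[s]
                        sc += self._Dsc[s]
                m = np.maximum(a.max(axis=-1), _TINY)
                a /= m[..., None]
                sc += np.log(m)
                self._A[c] = a
                self._Asc[c] = sc
                # U[c][y] = sum_x A[c][x] P_c[x, y]
                self._U[c] = np.einsum("kpa,kab->kpb", a, self._pmats[c])
                self._Usc[c] = sc
        self._stale = False

    # ------------------------------------------------------ evaluation

    def _mix_site_loglik(self, log_lk: np.ndarray) -> np.ndarray:
        """Combine per-category logs (K, npat) with the invariant class."""
        m = self.model
        parts = [log_lk + np.log((1.0 - m.p_inv) / self.K)]
        if m.p_inv > 0.0:
            with np.errstate(divide="ignore"):
                inv = np.log(self._inv_like) + np.log(m.p_inv)
            parts.append(inv[None, :])
        stacked = np.concatenate(parts, axis=0)
        return logsumexp(stacked, axis=0)

    def pattern_log_likelihoods(self) -> np.ndarray:
        self._refresh()
        root = self.tree.root
        core = self._W[root] @ self.model.freqs          # (K, npat)
        log_lk = np.log(np.maximum(core, _TINY)) + self._Wsc[root]
        return self._mix_site_loglik(log_lk)

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-site natural-log likelihoods (length = alignment sites)."""
        return self.pattern_log_likelihoods()[self._inverse]

    def total_log_likelihood(self) -> float:
        return float(self.weights @ self.pattern_log_likelihoods())

    # ------------------------------------------------- branch optimiser

    def _edge_loglik_fn(self, node: int):
        """Log-likelihood of the data as a function of one branch length."""
        self._refresh()
        a, asc = self._A[node], self._Asc[node]
        w, wsc = self._W[node], self._Wsc[node]
        scale = asc + wsc
        weights = self.weights

        def loglik(t: float) -> float:
            p = self.trans.probabilities(np.array([t]), self.rates)[0]
            core = np.einsum("kpa,kab,kpb->kp", a, p, w)
            log_lk = np.log(np.maximum(core, _TINY)) + scale
            return float(weights @ self._mix_site_loglik(log_lk))

        return loglik

    def optimize_branch_lengths(self, xatol: float = 1e-4) -> float:
        """One coordinate-descent pass over all branches; returns lnL."""
        lo, hi = np.log(MIN_BRANCH_LENGTH), np.log(MAX_BRANCH_LENGTH)
        for node in self.tree.edge_nodes:
            self._stale = True
            fn = self._edge_loglik_fn(node)
            t0 = float(self.tree.lengths[node])
            base = fn(t0)
            res = minimize_scalar(lambda x: -fn(np.exp(x)),
                                  bounds=(lo, hi), method="bounded",
                                  options={"xatol": xatol})
            if -res.fun > base:
                self.set_branch_length(node, float(np.exp(res.x)))
        self._stale = True
        return self.total_log_likelihood()
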