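"""Fixed-topology maximum-likelihood fitting.

Coordinate-wise optimisation: alternate single-branch Brent passes with
1-D optimisation of the gamma shape and the invariant proportion (and,
optionally, joint quasi-Newton optimisation of the exchangeabilities)
until the total log-likelihood improves by less than ``tol``.  The
topology itself is never changed; tree search is out of scope by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment
from .errors import DataError
from .likelihood import TreeLikelihood
from .phylotree import PhyloTree
from .substmodel import SubstitutionModel

log = logging.getLogger(__name__)

_ALPHA_BOUNDS = (np.log(0.02), np.log(100.0))
_PINV_MAX = 0.95


@dataclass
class FreeParams:
    """Which parameter groups the optimiser may move."""

    branch_lengths: bool = True
    alpha: bool = True
    p_inv: bool = True
    exchangeabilities: bool = False


@dataclass
class FitResult:
    tree: PhyloTree
    model: SubstitutionModel
    log_likelihood: float
    site_log_likelihoods: np.ndarray
    n_passes: int = 0
    converged: bool = True
    history: list = field(default_factory=list)


def empirical_base_freqs(aln: Alignment) -> np.ndarray:
    """Observed A/C/G/T proportions (ambiguities ignored, +1 pseudocount)."""
    counts = np.array([np.count_nonzero(aln.matrix == b)
                       for b in (b"A", b"C", b"G", b"T")], dtype=float)
    counts += 1.0
    return counts / counts.sum()


def default_start_model(aln: Alignment, n_categories: int = 4) -> SubstitutionModel:
    return SubstitutionModel(rates=np.ones(6), freqs=empirical_base_freqs(aln),
                             alpha=0.5, n_categories=n_categories, p_inv=0.1)


def _optimize_scalar(tl: TreeLikelihood, setter, x0: float, bounds,
                     current: float) -> float:
    """Maximise lnL over one transformed scalar; keep the better point."""
    def neg(x: float) -> float:
        setter(x)
        return -tl.total_log_likelihood()

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    if -res.fun > current:
        setter(float(res.x))
        return -res.fun
    setter(x0)
    return current


def optimize_fixed_topology(aln: Alignment, tree: PhyloTree,
                            model: SubstitutionModel | None = None,
                            free: FreeParams | None = None,
                            tol: float = 1e-4, max_passes: int = 200,
                            init_branch_length: float = 0.05) -> FitResult:
    """Fit branch lengths and model parameters on a fixed topology.

    Parameters
    ----------
    aln, tree:
        Data and the (fixed) topology; missing branch lengths are
        initialised to ``init_branch_length``.
    model:
        Starting model; by default empirical base frequencies with
        exchangeabilities 1, alpha 0.5, p_inv 0.1.
    free:
        Parameter groups to optimise (:class:`FreeParams`).  With
        everything frozen the call just scores the tree.
    tol:
        Convergence tolerance in log-likelihood units per outer pass.
    """
    if aln.n_sites < 1:
        raise DataError("empty alignment")
    free = free or FreeParams()
    model = model or default_start_model(aln)
    work = tree.fill_missing_lengths(init_branch_length)
    tl = TreeLikelihood(aln, work, model)
    lnl = tl.total_log_likelihood()
    history = [lnl]
    converged = False
    n_passes = 0

    for n_passes in range(1, max_passes + 1):
        prev = lnl
        if free.branch_lengths:
            lnl = tl.optimize_branch_lengths()
        if free.alpha:
            m0 = tl.model
            lnl = _optimize_scalar(
                tl, lambda x: tl.update_model(tl.model.with_(alpha=float(np.exp(x)))),
                np.log(m0.alpha), _ALPHA_BOUNDS, lnl)
        if free.p_inv:
            m0 = tl.model
            lnl = _optimize_scalar(
                tl, lambda x: tl.update_model(tl.model.with_(p_inv=float(x))),
                m0.p_inv, (0.0, _PINV_MAX), lnl)
        if free.exchangeabilities:
            lnl = _optimize_exchangeabilities(tl, lnl)
        history.append(lnl)
        if lnl - prev < tol:
            converged = True
            break

    if not converged:
        log.warning("fixed-topology fit did not converge in %d passes "
                    "(last improvement %.3g)", max_passes,
                    history[-1] - history[-2])
    return FitResult(tree=tl.tree.copy(), model=tl.model,
                     log_likelihood=lnl,
                     site_log_likelihoods=tl.site_log_likelihoods(),
                     n_passes=n_passes, converged=converged, history=history)


def _optimize_exchangeabilities(tl: TreeLikelihood, current: float) -> float:
    """L-BFGS-B over the five free log-exchangeabilities (GT fixed at 1)."""
    start = np.log(tl.model.rates[:5] / tl.model.rates[5])

    def neg(x: np.ndarray) -> float:
        rates = np.append(np.exp(x), 1.0)
        tl.update_model(tl.model.with_(rates=rates))
        return -tl.total_log_likelihood()

    res = minimize(neg, start, method="L-BFGS-B",
                   bounds=[(-7.0, 7.0)] * 5,
                   options={"maxiter": 30, "ftol": 1e-8})
    if -res.fun > current:
        neg(res.x)
        return float(-res.fun)
    neg(start)
    return current
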