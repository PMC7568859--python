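"""GTR+I+Gamma substitution model: rate matrix, discrete-gamma rates, P(t).

The general time-reversible (GTR) model is parameterised by six symmetric
exchangeabilities r_xy (one of which is redundant and conventionally fixed
to 1) and four stationary base frequencies pi.  Rate heterogeneity across
sites is modelled as a mixture of a proportion ``p_inv`` of invariant sites
and ``n_categories`` discrete gamma rate classes with shape ``alpha``
(mean-category discretisation).

The instantaneous rate matrix is scaled so that the *expected* substitution
rate over the whole mixture equals one, i.e. branch lengths are measured in
expected substitutions per site:  the gamma classes have mean rate 1, the
invariant class rate 0, so Q is scaled such that
``-sum_i pi_i q_ii = 1 / (1 - p_inv)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as _gamma

from .errors import DataError

#: order of the exchangeability parameters
RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
BASES = "ACGT"

_RATE_INDEX = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class SubstitutionModel:
    """GTR+I+Gamma parameter bundle.

    Parameters
    ----------
    rates:
        Six exchangeabilities in the order AC, AG, AT, CG, CT, GT.  The
        GT rate acts as the reference and is conventionally 1.
    freqs:
        Stationary base frequencies in the order A, C, G, T.
    alpha:
        Gamma shape for among-site rate variation.
    n_categories:
        Number of discrete gamma categories (K >= 1).
    p_inv:
        Proportion of invariant sites, in [0, 1).
    """

    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    n_categories: int = 4
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise DataError("GTR requires six strictly positive exchangeabilities")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise DataError("base frequencies must be four positive numbers")
        if abs(self.freqs.sum() - 1.0) > 1e-6:
            raise DataError("base frequencies must sum to 1")
        self.freqs = self.freqs / self.freqs.sum()
        if not self.alpha > 0:
            raise DataError("gamma shape alpha must be positive")
        if self.n_categories < 1:
            raise DataError("n_categories must be >= 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise DataError("p_inv must lie in [0, 1)")

    def with_(self, **kwargs) -> "SubstitutionModel":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)


def gtr_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Build the normalised 4x4 GTR rate matrix Q.

    Off-diagonals are ``q_ij = r_ij * pi_j``; the diagonal makes rows sum
    to zero; the matrix is scaled so that the mean rate over the full
    invariant+gamma mixture is one substitution per unit branch length:
    ``-sum_i pi_i q_ii = 1 / (1 - p_inv)``.
    """
    pi = model.freqs
    q = np.zeros((4, 4))
    for r, (i, j) in zip(model.rates, _RATE_INDEX):
        q[i, j] = r * pi[j]
        q[j, i] = r * pi[i]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    target = 1.0 / (1.0 - model.p_inv)
    return q * (target / mu)


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of K equal-probability slabs of a Gamma(alpha, alpha) law.

    This is the classical mean-category discretisation: cut the Gamma
    distribution (shape ``alpha``, mean 1) at its i/K quantiles and take
    the conditional mean of each slab.  The truncated first moment of a
    Gamma(a, scale 1/a) is ``F_{a+1}(x)`` where F is the CDF with shape
    a+1, which gives the category means in closed form.  The returned
    rates are nondecreasing with mean exactly 1 (up to float rounding).
    """
    if n_categories < 1:
        raise DataError("number of gamma categories must be >= 1")
    if not alpha > 0:
        raise DataError("gamma shape alpha must be positive")
    k = int(n_categories)
    if k == 1:
        return np.ones(1)
    bounds = _gamma.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    upper = _gamma.cdf(bounds, alpha + 1.0, scale=1.0 / alpha)
    cum = np.concatenate([[0.0], upper, [1.0]])
    rates = k * np.diff(cum)
    return rates


class GTRTransition:
    """Eigen-decomposed GTR generator yielding P(t) cheaply for many t.

    Uses the similarity transform ``B = D Q D^{-1}`` with
    ``D = diag(sqrt(pi))``; B is symmetric for a reversible Q, so an
    orthogonal eigendecomposition gives
    ``P(t) = D^{-1} U exp(L t) U' D`` with real eigenvalues L.
    """

    def __init__(self, model: SubstitutionModel):
        self.model = model
        q = gtr_rate_matrix(model)
        sp = np.sqrt(model.freqs)
        b = (q * sp[:, None]) / sp[None, :]
        b = 0.5 * (b + b.T)  # symmetrise away float noise
        lam, u = np.linalg.eigh(b)
        self.eigvals = lam
        self._left = u / sp[:, None]       # D^{-1} U  (4x4)
        self._right = u.T * sp[None, :]    # U' D      (4x4)

    def probability(self, t: float, rate: float = 1.0) -> np.ndarray:
        """Transition matrix P(t * rate)."""
        e = np.exp(self.eigvals * (t * rate))
        p = (self._left * e[None, :]) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p

    def probabilities(self, lengths: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """Array of transition matrices, shape (n_edges, n_rates, 4, 4)."""
        lengths = np.asarray(lengths, dtype=float)
        rates = np.asarray(rates, dtype=float)
        scale = lengths[:, None] * rates[None, :]              # (E, K)
        e = np.exp(self.eigvals[None, None, :] * scale[:, :, None])  # (E, K, 4)
        p = np.einsum("ab,ekb,bc->ekac", self._left, e, self._right)
        np.clip(p, 0.0, None, out=p)
        return p
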