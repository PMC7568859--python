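"""RELL resampling and KH / SH / AU topology tests.

All three tests work from a fixed topologies-x-sites matrix of site
log-likelihoods (no refitting): bootstrap replicates of the total
log-likelihood are formed by resampling site columns with replacement —
the RELL approximation.

* KH (Kishino-Hasegawa): two-sided test of one pair of topologies using
  the centred bootstrap distribution of their log-likelihood difference.
* SH (Shimodaira-Hasegawa): simultaneous test of many topologies against
  the maximum, centring each topology's replicates and comparing the
  observed deficit to the null distribution of ``max_j - lnL_t``.
* AU (approximately unbiased): multiscale bootstrap; the bootstrap
  proportion of each topology is tracked across resample sizes
  ``round(r * n_sites)``, the normal-quantile transform is regressed on
  ``d*sqrt(r) + c/sqrt(r)`` by weighted least squares, and
  ``p = 1 - Phi(d - c)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError
from .signal import SiteLnLMatrix

log = logging.getLogger(__name__)

DEFAULT_REPLICATES = 10_000
#: CONSEL-conventional multiscale bootstrap factors
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))
_CHUNK = 500


def _bootstrap_totals(matrix: np.ndarray, n_draw: int, n_replicates: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Replicates x topologies totals of ``n_draw`` site draws (RELL).

    Equal-weight resampling with replacement.  For small matrices the
    multinomial sampler is vectorised over replicates; for long
    alignments per-replicate index draws with bincount are much faster
    than a multinomial over hundreds of thousands of categories.
    """
    n_topo, n_sites = matrix.shape
    out = np.empty((n_replicates, n_topo))
    if n_sites <= 2048:
        p = np.full(n_sites, 1.0 / n_sites)
        done = 0
        while done < n_replicates:
            k = min(_CHUNK, n_replicates - done)
            counts = rng.multinomial(n_draw, p, size=k)
            out[done:done + k] = counts @ matrix.T
            done += k
    else:
        mt = matrix.T
        for i in range(n_replicates):
            idx = rng.integers(0, n_sites, n_draw)
            counts = np.bincount(idx, minlength=n_sites).astype(float)
            out[i] = counts @ mt
    return out


def rell_replicates(m: SiteLnLMatrix, n_replicates: int = DEFAULT_REPLICATES,
                    seed: int = 0) -> np.ndarray:
    """Equal-weight RELL bootstrap of the total lnL per topology.

    Returns an (n_replicates x n_topologies) array; reproducible for a
    fixed seed.
    """
    if n_replicates < 1:
        raise DataError("need at least one RELL replicate")
    rng = np.random.default_rng(seed)
    return _bootstrap_totals(m.matrix, m.n_sites, n_replicates, rng)


def kh_test(m: SiteLnLMatrix, a: str, b: str,
            n_replicates: int = DEFAULT_REPLICATES, seed: int = 0,
            two_sided: bool = True) -> float:
    """KH test p-value for topologies ``a`` vs ``b``.

    The default is the two-sided test (symmetric in its arguments),
    appropriate when neither topology is pre-specified as the null.  The
    one-sided variant (``two_sided=False``) asks whether ``a`` beats
    ``b`` more than resampling noise allows and is the quantity the SH
    test is conservative against.
    """
    delta = m.row(a) - m.row(b)
    obs = float(delta.sum())
    rng = np.random.default_rng(seed)
    reps = _bootstrap_totals(delta[None, :], delta.size, n_replicates, rng)[:, 0]
    centred = reps - reps.mean()
    if two_sided:
        return float(np.mean(np.abs(centred) >= abs(obs)))
    return float(np.mean(centred >= obs))


def sh_test(m: SiteLnLMatrix, n_replicates: int = DEFAULT_REPLICATES,
            seed: int = 0) -> pd.Series:
    """SH test p-value per topology (conservative, simultaneous)."""
    if len(m.labels) < 2:
        raise DataError("SH test needs at least two topologies")
    totals = m.matrix.sum(axis=1)
    obs = totals.max() - totals
    reps = rell_replicates(m, n_replicates, seed)
    centred = reps - reps.mean(axis=0)
    null = centred.max(axis=1)[:, None] - centred
    p = (null >= obs[None, :]).mean(axis=0)
    return pd.Series(p, index=m.labels)


def au_test(m: SiteLnLMatrix, scales=DEFAULT_SCALES,
            n_replicates: int = DEFAULT_REPLICATES,
            seed: int = 0) -> pd.Series:
    """AU test p-value per topology via the multiscale bootstrap."""
    scales = np.asarray(list(scales), dtype=float)
    if scales.size < 2 or not (scales.min() < 1.0 < scales.max()):
        raise DataError("AU needs >= 2 scale factors spanning 1.0")
    if np.any(scales <= 0):
        raise DataError("scale factors must be positive")
    rng = np.random.default_rng(seed)
    n_topo = len(m.labels)
    bp = np.empty((scales.size, n_topo))
    for si, r in enumerate(scales):
        n_draw = max(1, int(round(r * m.n_sites)))
        reps = _bootstrap_totals(m.matrix, n_draw, n_replicates, rng)
        best = reps.max(axis=1)
        bp[si] = (reps >= best[:, None] - 1e-12).mean(axis=0)

    p = np.empty(n_topo)
    eps = 1.0 / (n_replicates + 1)
    for t in range(n_topo):
        bpt = bp[:, t]
        if np.all(bpt >= 1.0 - eps):
            p[t] = 1.0
            continue
        if np.all(bpt <= eps):
            p[t] = 0.0
            log.warning("AU: bootstrap proportions all ~0 for %s; p clamped",
                        m.labels[t])
            continue
        bpc = np.clip(bpt, eps, 1.0 - eps)
        z = norm.ppf(1.0 - bpc)
        # weights from the binomial variance via the delta method
        w = n_replicates * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
        x = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
        wx = x * w[:, None]
        beta = np.linalg.solve(x.T @ wx, wx.T @ z)
        d, c = beta
        p[t] = float(np.clip(1.0 - norm.cdf(d - c), 0.0, 1.0))
    return pd.Series(p, index=m.labels)


def topology_test_table(m: SiteLnLMatrix,
                        n_replicates: int = DEFAULT_REPLICATES,
                        seed: int = 0, scales=DEFAULT_SCALES) -> pd.DataFrame:
    """KH/SH/AU summary per topology (deltaL from the best topology).

    KH compares each topology against the maximum-likelihood one; the
    best topology's own KH entry is 1 by convention.
    """
    totals = m.totals()
    best = totals.idxmax()
    rows = []
    for label in m.labels:
        p_kh = 1.0 if label == best else kh_test(m, best, label,
                                                n_replicates, seed)
        rows.append((label, float(totals[best] - totals[label]), p_kh))
    df = pd.DataFrame(rows, columns=["topology", "deltaL", "p_kh"])
    df["p_sh"] = sh_test(m, n_replicates, seed).to_numpy()
    df["p_au"] = au_test(m, scales, n_replicates, seed).to_numpy()
    df.attrs["n_replicates"] = n_replicates
    df.attrs["seed"] = seed
    return df
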