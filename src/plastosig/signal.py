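"""Per-locus phylogenetic-signal dissection between competing topologies.

Site log-likelihoods computed under two or more candidate topologies are
aggregated into locus-wise log-likelihood differences (delta-lnL).  A
locus with |delta-lnL| > 2 is classed a *strong* supporter of whichever
topology it favours and 1 < |delta-lnL| <= 2 a *moderate* supporter; the
conventions follow the widespread use of 2 lnL units as the significance
yardstick for gene-wise signal.  The sign is always first-label minus
second-label, so positive values support the first topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, PartitionMap, derive_dataset
from .errors import DataError
from .fit import FitResult, FreeParams, optimize_fixed_topology
from .phylotree import PhyloTree
from .substmodel import SubstitutionModel

log = logging.getLogger(__name__)

STRONG_DEFAULT = 2.0
MODERATE_DEFAULT = 1.0
UNPARTITIONED = "_unpartitioned"


@dataclass
class SiteLnLMatrix:
    """Topologies x sites matrix of per-site log-likelihoods."""

    labels: list
    matrix: np.ndarray  # (n_topologies, n_sites)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = list(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise DataError("topology labels must be unique")
        if self.matrix.shape[0] != len(self.labels):
            raise DataError("label count does not match matrix rows")
        if self.matrix.shape[1] < 1:
            raise DataError("site log-likelihood matrix is empty")

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, label: str) -> np.ndarray:
        try:
            return self.matrix[self.labels.index(label)]
        except ValueError:
            raise DataError(f"unknown topology label {label!r}") from None

    def totals(self) -> pd.Series:
        return pd.Series(self.matrix.sum(axis=1), index=self.labels)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix.T, columns=self.labels)
        df.insert(0, "site", np.arange(self.n_sites))
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SiteLnLMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = [c for c in df.columns if c != "site"]
        return cls(labels, df[labels].to_numpy().T)


def locuswise_delta(m: SiteLnLMatrix, a: str, b: str,
                    partition: PartitionMap,
                    strong: float = STRONG_DEFAULT,
                    moderate: float = MODERATE_DEFAULT) -> pd.DataFrame:
    """Per-locus delta-lnL table between topologies ``a`` and ``b``.

    delta(locus) = sum over the locus's columns of (lnL_a - lnL_b);
    positive supports ``a``.  Columns outside every locus are aggregated
    into a pseudo-locus ``_unpartitioned`` so the table sums exactly to
    the total log-likelihood difference.
    """
    site_delta = m.row(a) - m.row(b)
    n = site_delta.size
    seen = np.zeros(n, dtype=bool)
    rows = []
    for locus in partition:
        cols = locus.columns()
        if cols.size and cols.max() >= n:
            raise DataError(f"locus {locus.name} extends past the matrix")
        if np.any(seen[cols]):
            raise DataError(f"locus {locus.name} overlaps another locus")
        seen[cols] = True
        if locus.length == 0:
            log.warning("locus %s has zero aligned length; delta-lnL = 0",
                        locus.name)
        rows.append((locus.name, locus.kind, locus.length,
                     float(site_delta[cols].sum())))
    rest = ~seen
    if np.any(rest):
        rows.append((UNPARTITIONED, "igs", int(rest.sum()),
                     float(site_delta[rest].sum())))
    df = pd.DataFrame(rows, columns=["locus", "kind", "length", "delta_lnl"])
    df.attrs["labels"] = (a, b)
    return classify_support(df, strong=strong, moderate=moderate)


def classify_support(table: pd.DataFrame, strong: float = STRONG_DEFAULT,
                     moderate: float = MODERATE_DEFAULT) -> pd.DataFrame:
    """Attach support classes by |delta-lnL| thresholds (strict >).

    |delta| > strong       -> strong_A / strong_B
    moderate < |delta| <= strong -> moderate_A / moderate_B
    otherwise              -> weak
    """
    if not strong > moderate > 0:
        raise DataError("thresholds must satisfy strong > moderate > 0")
    d = table["delta_lnl"].to_numpy()
    cls = np.full(d.size, "weak", dtype=object)
    cls[(d > moderate) & (d <= strong)] = "moderate_A"
    cls[d > strong] = "strong_A"
    cls[(d < -moderate) & (d >= -strong)] = "moderate_B"
    cls[d < -strong] = "strong_B"
    out = table.copy()
    out["support"] = cls
    out.attrs.update(table.attrs)
    out.attrs["thresholds"] = (strong, moderate)
    return out


def summarize_comparison(table: pd.DataFrame) -> dict:
    """Sum of positive / negative delta-lnL with supporting-locus counts."""
    if table.empty:
        raise DataError("empty delta-lnL table")
    d = table["delta_lnl"].to_numpy()
    pos, neg = d[d > 0], d[d < 0]
    return {
        "sum_positive": float(pos.sum()),
        "n_positive": int(pos.size),
        "sum_negative": float(neg.sum()),
        "n_negative": int(neg.size),
        "net": float(d.sum()),
    }


def sorted_by_magnitude(table: pd.DataFrame) -> pd.DataFrame:
    """Bar-plot-ready view: loci sorted by |delta-lnL| descending."""
    named = table[table["locus"] != UNPARTITIONED]
    order = named["delta_lnl"].abs().sort_values(ascending=False).index
    return named.loc[order].reset_index(drop=True)


def fit_topologies(aln: Alignment, topologies: dict,
                   model: SubstitutionModel | None = None,
                   free: FreeParams | None = None) -> tuple:
    """Fit every candidate topology to one alignment.

    Returns ``(SiteLnLMatrix, {label: FitResult})``; rows follow the
    insertion order of ``topologies`` (label -> PhyloTree or newick).
    """
    if len(topologies) < 2:
        raise DataError("need at least two candidate topologies")
    fits: dict = {}
    rows = []
    for label, topo in topologies.items():
        tree = topo if isinstance(topo, PhyloTree) else PhyloTree.from_newick(topo)
        fit = optimize_fixed_topology(aln, tree, model=model, free=free)
        fits[label] = fit
        rows.append(fit.site_log_likelihoods)
    return SiteLnLMatrix(list(topologies), np.vstack(rows)), fits


def removal_experiment(aln: Alignment, partition: PartitionMap,
                       topologies: dict, model: SubstitutionModel | None = None,
                       exclude=(), free: FreeParams | None = None) -> pd.DataFrame:
    """Rank candidate topologies by refitted lnL after dropping loci.

    Each candidate is re-optimised (branch lengths and any free model
    parameters) on the alignment with the ``exclude`` loci removed; the
    result is a deterministic ranking by total log-likelihood.  Note the
    candidates are re-scored, not re-searched.
    """
    if len(topologies) < 2:
        raise DataError("need at least two candidate topologies")
    reduced, _ = derive_dataset(aln, partition, "all", exclude=list(exclude))
    matrix, fits = fit_topologies(reduced, topologies, model=model, free=free)
    df = pd.DataFrame({
        "topology": list(topologies),
        "log_likelihood": [fits[t].log_likelihood for t in topologies],
    }).sort_values("log_likelihood", ascending=False,
                   kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
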