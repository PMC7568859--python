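"""Synthetic data: sequence simulation on trees and planted-conflict sets.

Two generators back the whole test surface:

* forward simulation of alignments under GTR+I+Gamma on a fixed tree
  (root states drawn from the stationary frequencies, a single rate
  category per site shared across the whole tree);
* multi-locus datasets in which a small minority of loci is evolved on an
  alternative resolution of a focal trichotomy — the planted analogue of
  a plastome in which a handful of loci carry a conflicting history
  (e.g. via heteroplasmic recombination or introgression) while the bulk
  of loci reflect a rapid radiation with a very short internal branch;
* annotated synthetic plastome records with an exact planted inverted
  repeat and a realistic gene inventory, for exercising structure
  detection, statistics and locus extraction.

Everything is seeded and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, concatenate_loci
from .errors import DataError
from .phylotree import PhyloTree
from .plastome import (Feature, PlastomeRecord, QuadripartiteStructure,
                       Region, revcomp)
from .substmodel import GTRTransition, SubstitutionModel

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: three subclades of a focal trichotomy plus an outgroup
SUBCLADES = ("I", "II", "III")
OUTGROUP = "OUT"
#: the three resolutions, named as sister pairs
RESOLUTIONS = {"T1": ("I", "II"), "T2": ("II", "III"), "T3": ("I", "III")}


def plastome_like_model() -> SubstitutionModel:
    """GTR+I+Gamma parameters in the range typical for plant plastomes:
    AT-rich stationary frequencies (~38% GC), transition bias, strong
    among-site rate variation."""
    return SubstitutionModel(
        rates=np.array([1.4, 2.6, 0.5, 1.1, 2.8, 1.0]),
        freqs=np.array([0.31, 0.19, 0.19, 0.31]),
        alpha=0.5, n_categories=4, p_inv=0.2)


def three_subclade_newick(sister=("I", "II"), focal_length: float = 0.002,
                          terminal: float = 0.004, stem: float = 0.003,
                          outgroup_length: float = 0.02,
                          taxa_per_subclade: int = 2) -> str:
    """Newick for one resolution of the focal trichotomy.

    The two ``sister`` subclades are joined by the focal internal branch
    of length ``focal_length``; each subclade is a rake of
    ``taxa_per_subclade`` leaves on ``terminal`` branches over a ``stem``.
    """
    a, b = sister
    if a not in SUBCLADES or b not in SUBCLADES or a == b:
        raise DataError(f"sister pair must be two distinct subclades, "
                        f"got {sister}")
    (c,) = [s for s in SUBCLADES if s not in (a, b)]

    def clade(s: str) -> str:
        tips = ",".join(f"{s}{i + 1}:{terminal}"
                        for i in range(taxa_per_subclade))
        return f"({tips}):{stem}"

    return (f"(({clade(a)},{clade(b)}):{focal_length},"
            f"{clade(c)},{OUTGROUP}:{outgroup_length});")


def candidate_topologies(taxa_per_subclade: int = 2) -> dict:
    """The three resolutions as bare topologies (lengths left to refit)."""
    out = {}
    for label, sister in RESOLUTIONS.items():
        newick = three_subclade_newick(sister,
                                       taxa_per_subclade=taxa_per_subclade)
        tree = PhyloTree.from_newick(newick)
        tree.lengths[:] = np.nan
        out[label] = tree
    return out


# ----------------------------------------------------------- simulation


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel,
                       n_sites: int, seed: int | None = None,
                       rng: np.random.Generator | None = None) -> Alignment:
    """Evolve ``n_sites`` down ``tree`` under GTR+I+Gamma.

    Each site draws one rate class (invariant with probability p_inv,
    otherwise one of the K gamma categories) that applies on every
    branch; root states follow the stationary frequencies.
    """
    if n_sites < 1:
        raise DataError("n_sites must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    work = tree.copy()
    if np.any(np.isnan(work.lengths[work.edge_nodes])):
        raise DataError("simulation tree is missing branch lengths")
    rates = model.category_rates()
    site_rate = np.where(rng.random(n_sites) < model.p_inv, 0.0,
                         rates[rng.integers(0, len(rates), n_sites)])
    trans = GTRTransition(model)
    states = np.empty((work.n_nodes, n_sites), dtype=np.int64)
    states[work.root] = rng.choice(4, size=n_sites, p=model.freqs)
    unique_rates = np.unique(site_rate)
    for node in work.preorder():
        if node == work.root:
            continue
        t = float(work.lengths[node])
        parent = states[work.parent[node]]
        child = parent.copy()
        for r in unique_rates:
            if r == 0.0 or t == 0.0:
                continue
            mask = site_rate == r
            if not mask.any():
                continue
            p = trans.probability(t, r)
            cum = np.cumsum(p, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(int(mask.sum()))
            child[mask] = (u[:, None] > cum[parent[mask]]).sum(axis=1)
        states[node] = child
    rows = _BASES[states[work.leaf_indices]]
    return Alignment(work.leaf_names, rows)


@dataclass
class ConflictSimConfig:
    """Planted-conflict multi-locus simulation settings.

    ``majority_tree`` and ``minority_tree`` must share a leaf set and
    differ in the resolution of the focal trichotomy.  ``conflict``
    selects the planted loci: an integer count, a fraction in (0, 1), or
    an explicit list of locus indices.  Locus lengths are drawn
    log-uniformly from ``locus_length`` (planted loci from
    ``conflict_locus_length`` when given).
    """

    majority_tree: PhyloTree
    minority_tree: PhyloTree
    n_loci: int = 243
    conflict: object = 6
    locus_length: tuple = (100, 3000)
    conflict_locus_length: tuple | None = (500, 2000)
    length_distribution: str = "loguniform"
    model: SubstitutionModel = field(default_factory=plastome_like_model)
    seed: int = 0

    def __post_init__(self):
        for name in ("majority_tree", "minority_tree"):
            val = getattr(self, name)
            if isinstance(val, str):
                setattr(self, name, PhyloTree.from_newick(val))
        if set(self.majority_tree.leaf_names) \
                != set(self.minority_tree.leaf_names):
            raise DataError("majority and minority trees must share leaves")
        if self.n_loci < 1:
            raise DataError("n_loci must be >= 1")
        lo, hi = self.locus_length
        if not 0 < lo <= hi:
            raise DataError("invalid locus length range")
        if self.length_distribution not in ("loguniform", "uniform"):
            raise DataError("length_distribution must be loguniform|uniform")

    def conflict_indices(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.conflict, (list, tuple, np.ndarray)):
            idx = np.asarray(self.conflict, dtype=int)
        else:
            if isinstance(self.conflict, float):
                count = int(round(self.conflict * self.n_loci))
            else:
                count = int(self.conflict)
            idx = np.sort(rng.choice(self.n_loci, size=count, replace=False))
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_loci):
            raise DataError("conflict locus indices out of range")
        return idx


_KIND_PROBS = (("coding", 0.40), ("igs", 0.30), ("intron", 0.15),
               ("trna", 0.10), ("rrna", 0.05))


def _draw_lengths(rng, n, bounds, how):
    lo, hi = bounds
    if how == "uniform" or lo == hi:
        return rng.integers(lo, hi + 1, size=n)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)


def simulate_conflict_dataset(cfg: ConflictSimConfig):
    """Simulate a multi-locus alignment with planted conflicting loci.

    Returns ``(alignment, partition_map, truth)`` where ``truth`` is a
    data frame with the source tree (majority / minority) per locus.
    """
    rng = np.random.default_rng(cfg.seed)
    planted = set(int(i) for i in cfg.conflict_indices(rng))
    if not planted:
        log.warning("conflict configuration plants 0 loci; all loci follow "
                    "the majority tree")
    lengths = _draw_lengths(rng, cfg.n_loci, cfg.locus_length,
                            cfg.length_distribution)
    if planted and cfg.conflict_locus_length is not None:
        planted_lengths = _draw_lengths(rng, len(planted),
                                        cfg.conflict_locus_length,
                                        cfg.length_distribution)
        for j, i in enumerate(sorted(planted)):
            lengths[i] = planted_lengths[j]
    kinds, cut = [], np.cumsum([p for _, p in _KIND_PROBS])
    draws = rng.random(cfg.n_loci)
    for u in draws:
        kinds.append(_KIND_PROBS[int(np.searchsorted(cut, u))][0])

    loci, truth_rows = [], []
    for i in range(cfg.n_loci):
        source = "minority" if i in planted else "majority"
        tree = cfg.minority_tree if source == "minority" else cfg.majority_tree
        aln = simulate_alignment(tree, cfg.model, int(lengths[i]), rng=rng)
        name = f"locus{i:03d}"
        loci.append((name, kinds[i], aln))
        truth_rows.append((name, kinds[i], int(lengths[i]), source))
    alignment, partition = concatenate_loci(loci)
    truth = pd.DataFrame(truth_rows,
                         columns=["locus", "kind", "length", "source"])
    return alignment, partition, truth


def default_conflict_config(seed: int = 0,
                            preset: str = "laureae-like") -> ConflictSimConfig:
    """Named presets for planted-conflict simulations.

    ``laureae-like``: 243 loci with log-uniform lengths 100-3000 bp, six
    planted loci, a very short majority focal branch (rapid-radiation
    regime) and a long minority focal branch (concentrated conflicting
    signal).  ``reduced``: the same geometry at 240 loci with shorter
    majority loci, sized for quick desk-scale experiments.
    """
    if preset == "laureae-like":
        return ConflictSimConfig(
            majority_tree=three_subclade_newick(RESOLUTIONS["T1"],
                                                focal_length=0.002),
            minority_tree=three_subclade_newick(RESOLUTIONS["T2"],
                                                focal_length=0.03),
            n_loci=243, conflict=6, locus_length=(100, 3000),
            conflict_locus_length=(500, 2000),
            length_distribution="loguniform", seed=seed)
    if preset == "reduced":
        return ConflictSimConfig(
            majority_tree=three_subclade_newick(RESOLUTIONS["T1"],
                                                focal_length=0.001),
            minority_tree=three_subclade_newick(RESOLUTIONS["T2"],
                                                focal_length=0.03),
            n_loci=240, conflict=6, locus_length=(200, 400),
            conflict_locus_length=(700, 900),
            length_distribution="uniform", seed=seed)
    raise DataError(f"unknown preset {preset!r}")


# ------------------------------------------------- synthetic plastomes


def _random_dna(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


@dataclass
class GeneSpec:
    name: str
    kind: str          # CDS | tRNA | rRNA
    length: int        # summed exon length
    intron_lengths: tuple = ()
    strand: str = "+"

    @property
    def footprint(self) -> int:
        return self.length + sum(self.intron_lengths)


def _default_inventory(rng) -> dict:
    """Plastome-shaped gene inventory: 78 CDS + 30 tRNA + 4 rRNA unique
    genes, 13 of them duplicated in the IR, 16 genes with one intron and
    2 with two."""
    def cds_len():
        return int(rng.integers(100, 500)) * 3

    lsc, idx = [], 0
    for i in range(57):
        idx += 1
        introns = ()
        if i < 14:
            introns = (int(rng.integers(400, 900)),)
        elif i < 16:
            introns = (int(rng.integers(300, 700)), int(rng.integers(300, 700)))
        lsc.append(GeneSpec(f"cds{idx:02d}", "CDS", cds_len(), introns,
                            "+" if rng.random() < 0.5 else "-"))
    for i in range(26):
        lsc.append(GeneSpec(f"trn{i + 1:02d}", "tRNA",
                            int(rng.integers(72, 89))))
    ssc = []
    for i in range(16):
        idx += 1
        introns = (int(rng.integers(400, 900)),) if i < 2 else ()
        ssc.append(GeneSpec(f"cds{idx:02d}", "CDS", cds_len(), introns,
                            "+" if rng.random() < 0.5 else "-"))
    ir = []
    for i in range(5):
        idx += 1
        ir.append(GeneSpec(f"cds{idx:02d}", "CDS", cds_len()))
    for i in range(4):
        ir.append(GeneSpec(f"trn{27 + i:02d}", "tRNA",
                           int(rng.integers(72, 89))))
    for i, ln in enumerate((1500, 2900, 150, 280)):
        ir.append(GeneSpec(f"rrn{i + 1}", "rRNA", ln))
    return {"lsc": lsc, "ssc": ssc, "ir": ir}


def _layout_region(rng, genes, region_start: int, region_length: int):
    """Place genes sequentially with random spacer gaps; exact tiling."""
    used = sum(g.footprint for g in genes)
    free = region_length - used
    if free < 0:
        raise DataError(f"gene inventory does not fit: needs {used} bp in a "
                        f"{region_length} bp region")
    weights = rng.random(len(genes) + 1)
    gaps = np.floor(free * weights / weights.sum()).astype(int)
    gaps[-1] += free - gaps.sum()
    features = []
    pos = region_start
    for g, gap in zip(genes, gaps[:-1]):
        pos += int(gap)
        exons = []
        if g.intron_lengths:
            n_exons = len(g.intron_lengths) + 1
            cuts = np.sort(rng.choice(np.arange(60, g.length - 60),
                                      size=n_exons - 1, replace=False))
            exon_lens = np.diff(np.concatenate([[0], cuts, [g.length]]))
            p = pos
            for exon_len, intron_len in zip(
                    exon_lens, list(g.intron_lengths) + [0]):
                exons.append((p, p + int(exon_len)))
                p += int(exon_len) + int(intron_len)
        else:
            exons.append((pos, pos + g.length))
        intervals = tuple(exons if g.strand == "+" else list(reversed(exons)))
        features.append(Feature(g.name, g.kind, intervals, g.strand))
        pos += g.footprint
    return features


def _mirror_into_irb(feature: Feature, ira: Region, irb: Region) -> Feature:
    flipped = []
    for s, e in feature.intervals:
        flipped.append((irb.start + (ira.end - e), irb.start + (ira.end - s)))
    strand = "-" if feature.strand == "+" else "+"
    return Feature(feature.name, feature.kind,
                   tuple(sorted(flipped, reverse=(strand == "-"))), strand)


def synth_plastome_record(total_bp: int = 152_000, ir_bp: int = 20_000,
                          ssc_bp: int = 18_500, seed: int = 0,
                          record_id: str = "SYNPL001",
                          inventory: dict | None = None):
    """Random annotated plastome with an exact planted inverted repeat.

    Returns ``(record, structure)``; the structure is the ground truth
    for testing detection.  Region GC contents follow the plastome norm
    (IR richest, SSC poorest).
    """
    if 2 * ir_bp + ssc_bp >= total_bp:
        raise DataError("2*ir_bp + ssc_bp must be smaller than total_bp")
    rng = np.random.default_rng(seed)
    lsc_bp = total_bp - 2 * ir_bp - ssc_bp
    lsc_seq = _random_dna(rng, lsc_bp, 0.379)
    ira_seq = _random_dna(rng, ir_bp, 0.444)
    ssc_seq = _random_dna(rng, ssc_bp, 0.339)
    # pin the repeat boundaries: the base flanking each IR end must not
    # complement its mirror, or chance matches would extend the repeat
    comp = dict(zip("ACGT", "TGCA"))
    if lsc_seq[-1] == comp[lsc_seq[0]]:
        lsc_seq = lsc_seq[:-1] + ("A" if comp[lsc_seq[0]] != "A" else "C")
    if ssc_seq[0] == comp[ssc_seq[-1]]:
        repl = "A" if comp[ssc_seq[-1]] != "A" else "C"
        ssc_seq = repl + ssc_seq[1:]
    sequence = lsc_seq + ira_seq + ssc_seq + revcomp(ira_seq)
    structure = QuadripartiteStructure(
        lsc=Region(0, lsc_bp),
        ira=Region(lsc_bp, ir_bp),
        ssc=Region(lsc_bp + ir_bp, ssc_bp),
        irb=Region(lsc_bp + ir_bp + ssc_bp, ir_bp),
        total=total_bp)
    inventory = inventory or _default_inventory(rng)
    features = []
    features += _layout_region(rng, inventory["lsc"], 0, lsc_bp)
    features += _layout_region(rng, inventory["ir"], lsc_bp, ir_bp)
    features += _layout_region(rng, inventory["ssc"], lsc_bp + ir_bp, ssc_bp)
    for f in list(features):
        mid = (f.span[0] + f.span[1]) // 2
        if structure.contains(structure.ira, mid):
            features.append(_mirror_into_irb(f, structure.ira, structure.irb))
    record = PlastomeRecord(id=record_id, sequence=sequence,
                            features=features)
    return record, structure
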