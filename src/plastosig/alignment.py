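"""Alignment container, partition bookkeeping, masking and dataset derivation.

An :class:`Alignment` is a taxa-by-sites character matrix over the DNA
alphabet plus IUPAC ambiguity codes; ``-`` is the only gap character and
``?`` is normalised to ``N`` on input.  A :class:`PartitionMap` names
disjoint column ranges (loci) of an alignment; its union may be a proper
subset of the columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import DataError

log = logging.getLogger(__name__)

GAP = b"-"
#: locus kinds recognised throughout the package
KINDS = ("coding", "intron", "trna", "rrna", "igs")
_CODING_KINDS = ("coding",)


class Alignment:
    """Immutable-ish multiple sequence alignment.

    Parameters
    ----------
    taxa:
        Ordered unique taxon labels.
    matrix:
        2-D array (n_taxa x n_sites) of single bytes; strings are accepted
        and encoded.  ``?`` is treated as ``N``; lowercase is upcased.
    """

    def __init__(self, taxa: Sequence[str], matrix):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise DataError("duplicate taxon labels in alignment")
        if isinstance(matrix, np.ndarray) and matrix.dtype == np.dtype("S1"):
            m = matrix.copy()
        else:
            rows = ["".join(r) if not isinstance(r, str) else r for r in matrix]
            if len({len(r) for r in rows}) > 1:
                raise DataError("alignment rows differ in length")
            m = np.frombuffer("".join(rows).upper().encode(),
                              dtype="S1").reshape(len(rows), -1).copy()
        m = np.char.upper(m)
        m[m == b"?"] = b"N"
        if m.ndim != 2 or m.shape[0] != len(self.taxa):
            raise DataError("matrix shape does not match taxon list")
        if len(self.taxa) < 2 or m.shape[1] < 1:
            raise DataError("alignment needs >= 2 taxa and >= 1 site")
        self.matrix = m

    # ------------------------------------------------------------ basics

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.matrix.shape[1])

    def sequence(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return self.matrix[i].tobytes().decode()

    def take_columns(self, cols) -> "Alignment":
        cols = np.asarray(cols, dtype=int)
        if cols.size == 0:
            raise DataError("cannot build an alignment with zero columns")
        return Alignment(self.taxa, self.matrix[:, cols])

    def __eq__(self, other) -> bool:
        return (isinstance(other, Alignment) and self.taxa == other.taxa
                and self.matrix.shape == other.matrix.shape
                and bool(np.all(self.matrix == other.matrix)))

    def __repr__(self) -> str:
        return f"Alignment({self.n_taxa} taxa x {self.n_sites} sites)"

    # ---------------------------------------------------------------- io

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise DataError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.taxa):
                fh.write(f">{t}\n{self.matrix[i].tobytes().decode()}\n")


@dataclass(frozen=True)
class Locus:
    """A named, typed set of columns of an alignment."""

    name: str
    kind: str
    ranges: tuple  # tuple of (start, end), 0-based half-open

    def __post_init__(self):
        if self.kind not in KINDS:
            raise DataError(f"unknown locus kind {self.kind!r}")
        for s, e in self.ranges:
            if e <= s:
                raise DataError(f"empty range in locus {self.name}")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.ranges)

    def columns(self) -> np.ndarray:
        return np.concatenate([np.arange(s, e) for s, e in self.ranges])


@dataclass
class PartitionMap:
    """Disjoint named column ranges over an alignment."""

    loci: list = field(default_factory=list)

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise DataError("duplicate locus names in partition map")
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        spans = sorted((s, e, l.name) for l in self.loci for s, e in l.ranges)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise DataError(f"overlapping partition ranges: {n1} and {n2}")

    def __iter__(self):
        return iter(self.loci)

    def __len__(self):
        return len(self.loci)

    @property
    def names(self) -> list:
        return [l.name for l in self.loci]

    def get(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def covered_columns(self) -> np.ndarray:
        if not self.loci:
            return np.empty(0, dtype=int)
        return np.concatenate([l.columns() for l in self.loci])

    def select(self, names: Iterable[str]) -> "PartitionMap":
        wanted = list(names)
        missing = [n for n in wanted if n not in self.names]
        if missing:
            raise DataError(f"unknown locus name(s): {', '.join(missing)}")
        return PartitionMap([l for l in self.loci if l.name in set(wanted)])

    def remap(self, kept_columns: np.ndarray) -> "PartitionMap":
        """Re-express ranges after a column subset ``kept_columns`` (sorted)."""
        kept = np.asarray(kept_columns, dtype=int)
        new_index = -np.ones(int(kept.max()) + 2 if kept.size else 1, dtype=int)
        new_index[kept] = np.arange(kept.size)
        out = []
        for l in self.loci:
            cols = l.columns()
            cols = cols[np.isin(cols, kept)]
            if cols.size == 0:
                continue
            newcols = new_index[cols]
            breaks = np.flatnonzero(np.diff(newcols) != 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [newcols.size - 1]])
            ranges = tuple((int(newcols[s]), int(newcols[e]) + 1)
                           for s, e in zip(starts, ends))
            out.append(Locus(l.name, l.kind, ranges))
        return PartitionMap(out)

    # ---------------------------------------------------------------- io

    def to_raxml(self, path) -> None:
        """RAxML-style plain-text partition file (1-based inclusive)."""
        with open(path, "w") as fh:
            for l in self.loci:
                parts = ",".join(f"{s + 1}-{e}" for s, e in l.ranges)
                fh.write(f"DNA, {l.name} = {parts}\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("locus\tkind\tranges\n")
            for l in self.loci:
                parts = ",".join(f"{s}-{e}" for s, e in l.ranges)
                fh.write(f"{l.name}\t{l.kind}\t{parts}\n")

    @classmethod
    def from_tsv(cls, path) -> "PartitionMap":
        loci = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("locus"):
                raise DataError("partition TSV must have a 'locus' header line")
            for line in fh:
                if not line.strip():
                    continue
                name, kind, parts = line.rstrip("\n").split("\t")
                ranges = tuple(tuple(int(x) for x in p.split("-"))
                               for p in parts.split(","))
                loci.append(Locus(name, kind, ranges))
        return cls(loci)


# ---------------------------------------------------------------- operations


def mask_gap_columns(aln: Alignment, threshold: float,
                     partition: PartitionMap | None = None):
    """Strip columns whose gap fraction exceeds ``threshold``.

    ``threshold`` is a fraction in [0, 1]; a threshold of 0 removes every
    column containing any gap.  Ambiguity codes (including N) count as
    non-gap because they still carry partial information.  Returns the
    masked alignment, or ``(alignment, remapped_partition)`` when a
    partition map is supplied.
    """
    if not 0.0 <= threshold <= 1.0:
        raise DataError("gap threshold must lie in [0, 1]")
    gap_frac = (aln.matrix == GAP).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= threshold + 1e-12)
    if keep.size == 0:
        raise DataError("empty alignment after masking")
    masked = aln.take_columns(keep)
    if partition is None:
        return masked
    return masked, partition.remap(keep)


def concatenate_loci(loci, taxa: Sequence[str] | None = None):
    """Concatenate per-locus alignments into one matrix plus a partition map.

    ``loci`` is an iterable of ``(name, kind, Alignment)``.  Taxa missing
    from a locus are padded with gaps over that locus's columns.
    """
    loci = list(loci)
    if not loci:
        raise DataError("no loci to concatenate")
    names = [n for n, _, _ in loci]
    if len(set(names)) != len(names):
        raise DataError("duplicate locus name in concatenation")
    if taxa is None:
        taxa = []
        for _, _, a in loci:
            for t in a.taxa:
                if t not in taxa:
                    taxa.append(t)
    for n, _, a in loci:
        extra = set(a.taxa) - set(taxa)
        if extra:
            raise DataError(f"locus {n} has taxa outside the master set: {extra}")
    blocks, parts, offset = [], [], 0
    for name, kind, a in loci:
        block = np.full((len(taxa), a.n_sites), GAP, dtype="S1")
        for i, t in enumerate(a.taxa):
            block[taxa.index(t)] = a.matrix[i]
        blocks.append(block)
        parts.append(Locus(name, kind, ((offset, offset + a.n_sites),)))
        offset += a.n_sites
    return Alignment(taxa, np.concatenate(blocks, axis=1)), PartitionMap(parts)


def split_by_partition(aln: Alignment, partition: PartitionMap) -> dict:
    """Inverse of concatenation: per-locus sub-alignments keyed by name."""
    return {l.name: aln.take_columns(l.columns()) for l in partition}


def derive_dataset(aln: Alignment, partition: PartitionMap, selector="all",
                   exclude: Sequence[str] = ()):
    """Column subset of an alignment by locus selection.

    ``selector`` is one of ``all``, ``cds_only``, ``noncds_only``; on top of
    that, ``exclude`` drops the named loci.  Columns keep their original
    order and the partition is remapped onto the subset.
    """
    if selector not in ("all", "cds_only", "noncds_only"):
        raise DataError(f"unknown selector {selector!r}")
    unknown = [n for n in exclude if n not in partition.names]
    if unknown:
        raise DataError(f"unknown locus name(s) in exclude: {', '.join(unknown)}")
    chosen = []
    for l in partition:
        if l.name in set(exclude):
            continue
        if selector == "cds_only" and l.kind not in _CODING_KINDS:
            continue
        if selector == "noncds_only" and l.kind in _CODING_KINDS:
            continue
        chosen.append(l)
    sub = PartitionMap(chosen)
    cols = np.sort(sub.covered_columns())
    if cols.size == 0:
        raise DataError("selection leaves no columns")
    return aln.take_columns(cols), sub.remap(cols)
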