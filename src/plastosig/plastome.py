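"""Plastome records: quadripartite structure, summary statistics, loci.

A plastome is a circular DNA molecule with the classical quadripartite
architecture: a large single-copy region (LSC) and a small single-copy
region (SSC) separated by two identical inverted repeats (IRa / IRb).
This module reads annotated records from GenBank flat files, locates the
repeat structure directly from the sequence (seed-and-extend search for
the longest pair of reverse-complement-identical repeats), computes
region statistics (lengths, GC, gene counts) and extracts typed loci:
coding regions, introns, tRNAs, rRNAs and intergenic spacers.

Internal coordinates are 0-based half-open; GenBank's 1-based inclusive
convention applies only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import DataError, StructureError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
MIN_IR_LENGTH = 1000
_FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "intron")
#: genes whose dispersed (trans-spliced) pieces are skipped by default
DEFAULT_EXCLUDED_GENES = ("rps12",)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_gene_name(name: str) -> str:
    """Case-insensitive gene identity; copy suffixes like '-1'/'_2' stripped."""
    base = name.strip()
    for suffix in ("-1", "-2", "_1", "_2"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    return base.lower()


# --------------------------------------------------------------- datatypes


@dataclass
class Feature:
    """One annotated gene copy (possibly multi-exon)."""

    name: str
    kind: str  # CDS | tRNA | rRNA | intron
    intervals: tuple  # ((start, end), ...) 0-based half-open, strand order
    strand: str = "+"

    def __post_init__(self):
        if self.kind not in _FEATURE_KINDS:
            raise DataError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise DataError("strand must be '+' or '-'")
        self.intervals = tuple((int(s), int(e)) for s, e in self.intervals)
        if not self.intervals:
            raise DataError(f"feature {self.name} has no intervals")

    @property
    def span(self) -> tuple:
        return (min(s for s, _ in self.intervals),
                max(e for _, e in self.intervals))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def genomic_intervals(self) -> list:
        return sorted(self.intervals)


@dataclass
class PlastomeRecord:
    """Annotated circular plastome sequence."""

    id: str
    sequence: str
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        if n == 0:
            raise DataError(f"record {self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise DataError(f"record {self.id}: unexpected characters {bad}")
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= n):
                    raise DataError(
                        f"record {self.id}: feature {f.name} interval "
                        f"[{s},{e}) outside sequence of length {n}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subsequence(self, start: int, length: int) -> str:
        """Circular slice starting at ``start`` (may wrap the origin)."""
        n = self.length
        start %= n
        if start + length <= n:
            return self.sequence[start:start + length]
        return self.sequence[start:] + self.sequence[:(start + length) - n]


@dataclass(frozen=True)
class Region:
    """Arc of the circle: start position and length (may wrap)."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class QuadripartiteStructure:
    """LSC / IRa / SSC / IRb arcs; IRa is the repeat copy after the LSC."""

    lsc: Region
    ira: Region
    ssc: Region
    irb: Region
    total: int

    def __post_init__(self):
        if self.ira.length != self.irb.length:
            raise DataError("IR copies differ in length")
        covered = (self.lsc.length + self.ssc.length
                   + self.ira.length + self.irb.length)
        if covered != self.total:
            raise DataError("quadripartite regions do not tile the sequence")

    @property
    def ir_length(self) -> int:
        return self.ira.length

    def regions(self) -> dict:
        return {"lsc": self.lsc, "ira": self.ira,
                "ssc": self.ssc, "irb": self.irb}

    def contains(self, region: Region, pos: int) -> bool:
        off = (pos - region.start) % self.total
        return off < region.length


@dataclass
class RegionStats:
    total_bp: int
    lsc_bp: int
    ssc_bp: int
    ir_bp: int
    total_gc: float
    lsc_gc: float
    ir_gc: float
    ssc_gc: float

    def __post_init__(self):
        if self.lsc_bp + self.ssc_bp + 2 * self.ir_bp != self.total_bp:
            raise DataError("region lengths do not sum to the total")


@dataclass
class GeneCounts:
    total_genes: int
    unique_genes: int
    unique_cds: int
    unique_trna: int
    unique_rrna: int
    ir_duplicated: int

    def __post_init__(self):
        if self.unique_cds + self.unique_trna + self.unique_rrna \
                != self.unique_genes:
            raise DataError("unique gene counts are inconsistent")


@dataclass
class LocusSet:
    """One locus (by name) with its unaligned sequence per record."""

    name: str
    kind: str  # coding | intron | trna | rrna | igs
    sequences: dict = field(default_factory=dict)  # record id -> str

    def __len__(self):
        return len(self.sequences)


# ----------------------------------------------------------------- file io


def read_plastome_record(path) -> PlastomeRecord:
    """Read a single annotated GenBank record (CDS / tRNA / rRNA features)."""
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) <= {"N"}:
        raise DataError(f"record {record.id}: missing sequence")
    features = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or ["?"])[0]
        strand = "-" if (feat.location.strand or 1) < 0 else "+"
        parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
        if strand == "-":
            parts = sorted(parts, key=lambda p: -p[0])
        for s, e in parts:
            if not (0 <= s < e <= len(seq)):
                raise DataError(f"record {record.id}: feature {name} "
                                f"outside sequence bounds")
        features.append(Feature(name=name, kind=feat.type,
                                intervals=tuple(parts), strand=strand))
    return PlastomeRecord(id=record.id or record.name, sequence=seq,
                          features=features)


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a record back to a GenBank flat file (round-trip safe)."""
    seq_record = SeqRecord(Seq(record.sequence), id=record.id,
                           name=record.id[:16].replace(".", "_"),
                           description="synthetic plastome")
    seq_record.annotations["molecule_type"] = "DNA"
    seq_record.annotations["topology"] = "circular"
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in f.intervals]
        if strand < 0:
            locs = list(reversed(locs))
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        seq_record.features.append(
            SeqFeature(location, type=f.kind,
                       qualifiers={"gene": [f.name]}))
    SeqIO.write([seq_record], str(path), "genbank")


# ------------------------------------------------- quadripartite detection


def _extend_pair(s2: str, rc_ok, pa: int, pe: int, qa: int, qe: int,
                 limit: int, budget: int):
    """Greedy outward extension of a reverse-complement match pair."""
    # grow left end of A together with right end of B
    miss = 0
    while pa > 0 and qe < limit and (pe - pa) < limit // 2:
        ok = rc_ok(s2[pa - 1], s2[qe])
        if not ok:
            if miss >= budget:
                break
            miss += 1
        pa -= 1
        qe += 1
    # trim trailing mismatches
    while miss and not rc_ok(s2[pa], s2[qe - 1]):
        pa += 1
        qe -= 1
        miss -= 1
    budget -= miss
    miss = 0
    while qa > 0 and pe < limit and (pe - pa) < limit // 2:
        ok = rc_ok(s2[pe], s2[qa - 1])
        if not ok:
            if miss >= budget:
                break
            miss += 1
        pe += 1
        qa -= 1
    while miss and not rc_ok(s2[pe - 1], s2[qa]):
        pe -= 1
        qa += 1
        miss -= 1
    return pa, pe, qa, qe


def detect_quadripartite(sequence: str, min_ir_length: int = MIN_IR_LENGTH,
                         max_mismatch: int = 0,
                         seed_length: int = 25) -> QuadripartiteStructure:
    """Locate the quadripartite structure of a circular sequence.

    Seed-and-extend search for the maximal pair of reverse-complement-
    identical repeats of length >= ``min_ir_length``; the two gaps between
    the repeat copies are the single-copy regions and the longer one is
    the LSC.  Deterministic for a fixed rotation of the input.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 4 * min_ir_length:
        raise StructureError("sequence shorter than four minimum IR lengths")
    k = min(seed_length, min_ir_length)
    s2 = seq + seq
    comp = dict(zip("ACGTN", "TGCAN"))

    def rc_ok(x: str, y: str) -> bool:
        return comp.get(x, "?") == y

    positions: dict = {}
    for p in range(n):
        positions.setdefault(s2[p:p + k], []).append(p)

    best = None  # (length, a_start, b_start)
    seen_diag: set = set()
    limit = 2 * n
    for q in range(n):
        window = s2[q:q + k]
        key = revcomp(window)
        hits = positions.get(key)
        if not hits:
            continue
        for p in hits:
            d = p + q
            if d in seen_diag:
                continue
            seen_diag.add(d)
            pa, pe, qa, qe = _extend_pair(s2, rc_ok, p, p + k, q, q + k,
                                          limit, max_mismatch)
            length = pe - pa
            if length < min_ir_length:
                continue
            a_start, b_start = pa % n, qa % n
            if a_start == b_start:
                continue  # a palindrome matching itself
            gap_ab = (b_start - (a_start + length)) % n
            gap_ba = (a_start - (b_start + length)) % n
            if gap_ab + gap_ba + 2 * length != n:
                continue  # overlapping arms
            cand = (length, min(a_start, b_start), max(a_start, b_start))
            if best is None or cand[0] > best[0] or \
                    (cand[0] == best[0] and cand[1:] < best[1:]):
                best = cand
    if best is None:
        raise StructureError("no quadripartite structure: no inverted "
                             f"repeat of length >= {min_ir_length}")
    length, c1, c2 = best
    gap12 = (c2 - (c1 + length)) % n
    gap21 = (c1 - (c2 + length)) % n
    if gap12 >= gap21:
        lsc = Region(c1 + length, gap12)
        ira, ssc, irb = Region(c2, length), Region((c2 + length) % n, gap21), \
            Region(c1, length)
    else:
        lsc = Region(c2 + length, gap21)
        ira, ssc, irb = Region(c1, length), Region((c1 + length) % n, gap12), \
            Region(c2, length)
    lsc = Region(lsc.start % n, lsc.length)
    return QuadripartiteStructure(lsc=lsc, ira=ira, ssc=ssc, irb=irb, total=n)


# -------------------------------------------------------------- statistics


def _gc_percent(seq: str, label: str) -> float:
    unambiguous = sum(seq.count(b) for b in "ACGT")
    if unambiguous == 0:
        raise DataError(f"region {label} has no unambiguous bases")
    gc = seq.count("G") + seq.count("C")
    return round(100.0 * gc / unambiguous, 1)


def region_stats(record: PlastomeRecord,
                 structure: QuadripartiteStructure) -> RegionStats:
    """Region lengths and GC percentages (to one decimal)."""
    if structure.total != record.length:
        raise DataError("structure does not cover the record")
    seqs = {name: record.subsequence(r.start, r.length)
            for name, r in structure.regions().items()}
    ir_seq = seqs["ira"] + seqs["irb"]
    return RegionStats(
        total_bp=record.length,
        lsc_bp=structure.lsc.length,
        ssc_bp=structure.ssc.length,
        ir_bp=structure.ir_length,
        total_gc=_gc_percent(record.sequence, "total"),
        lsc_gc=_gc_percent(seqs["lsc"], "lsc"),
        ir_gc=_gc_percent(ir_seq, "ir"),
        ssc_gc=_gc_percent(seqs["ssc"], "ssc"),
    )


_KIND_TO_UNIQUE = {"CDS": "cds", "tRNA": "trna", "rRNA": "rrna"}


def count_genes(record: PlastomeRecord,
                structure: QuadripartiteStructure | None = None) -> GeneCounts:
    """Gene copy / unique-gene counts; IR-duplicated genes counted once."""
    by_name: dict = {}
    for f in record.features:
        if f.kind not in _KIND_TO_UNIQUE:
            continue
        by_name.setdefault(normalize_gene_name(f.name), []).append(f)
    unique = {"cds": 0, "trna": 0, "rrna": 0}
    total = 0
    ir_duplicated = 0
    for name, feats in by_name.items():
        unique[_KIND_TO_UNIQUE[feats[0].kind]] += 1
        total += len(feats)
        if structure is not None and len(feats) >= 2:
            mids = [(f.span[0] + f.span[1]) // 2 for f in feats]
            in_a = any(structure.contains(structure.ira, m) for m in mids)
            in_b = any(structure.contains(structure.irb, m) for m in mids)
            if in_a and in_b:
                ir_duplicated += 1
    return GeneCounts(total_genes=total,
                      unique_genes=sum(unique.values()),
                      unique_cds=unique["cds"], unique_trna=unique["trna"],
                      unique_rrna=unique["rrna"],
                      ir_duplicated=ir_duplicated)


# ---------------------------------------------------------------- rotation


def rotate_sequence(seq: str, offset: int) -> str:
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def normalize_rotation(record: PlastomeRecord,
                       structure: QuadripartiteStructure):
    """Rotate so the LSC starts at position 0 (reproducible coordinates)."""
    off = structure.lsc.start % record.length
    n = record.length

    def shift_interval(s, e):
        s2, e2 = (s - off) % n, (e - off) % n
        if e2 == 0:
            e2 = n
        if s2 < e2:
            return [(s2, e2)]
        return [(s2, n), (0, e2)]  # interval wraps after rotation

    feats = []
    for f in record.features:
        intervals = []
        for s, e in f.intervals:
            intervals.extend(shift_interval(s, e))
        feats.append(Feature(f.name, f.kind, tuple(intervals), f.strand))
    new_record = PlastomeRecord(id=record.id,
                                sequence=rotate_sequence(record.sequence, off),
                                features=feats)
    regions = {k: Region((r.start - off) % n, r.length)
               for k, r in structure.regions().items()}
    new_structure = QuadripartiteStructure(total=n, **regions)
    return new_record, new_structure


# ---------------------------------------------------------- locus extraction


def _record_loci(record: PlastomeRecord,
                 structure: QuadripartiteStructure | None,
                 ir_policy: str, excluded) -> dict:
    """Extract {name: (kind, sequence)} for one record."""
    n = record.length
    out: dict = {}

    def fetch(s: int, e: int) -> str:
        return record.sequence[s:e]

    drop_irb = ir_policy == "drop_one_copy" and structure is not None

    def in_irb(span) -> bool:
        if not drop_irb:
            return False
        mid = (span[0] + span[1]) // 2
        return structure.contains(structure.irb, mid)

    # group features into gene copies; reject genuinely conflicting copies
    kept: list = []
    seen_spans: dict = {}
    for f in record.features:
        name = normalize_gene_name(f.name)
        if name in {normalize_gene_name(g) for g in excluded}:
            log.info("record %s: skipping excluded gene %s", record.id, f.name)
            continue
        key = (name, f.kind)
        span = f.span
        if key in seen_spans:
            previous = seen_spans[key]
            duplicate_ok = in_irb(span) != in_irb(previous) or span == previous
            if not duplicate_ok and structure is not None:
                raise DataError(f"record {record.id}: gene {f.name} has "
                                "conflicting duplicate coordinates")
        seen_spans.setdefault(key, span)
        if in_irb(span):
            continue
        kept.append((name, f))

    for name, f in kept:
        exons = f.genomic_intervals()
        if f.strand == "-":
            seq = revcomp("".join(fetch(s, e) for s, e in exons))
        else:
            seq = "".join(fetch(s, e) for s, e in exons)
        kind = {"CDS": "coding", "tRNA": "trna", "rRNA": "rrna"}[f.kind]
        if name in out:
            continue  # identical IR copy already captured
        out[name] = (kind, seq)
        if len(exons) > 1:
            introns = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])
                       if s2 > e1]
            for i, (s, e) in enumerate(introns, start=1):
                label = f"{name}_intron" if len(introns) == 1 \
                    else f"{name}_intron{i}"
                iseq = fetch(s, e)
                out[label] = ("intron", revcomp(iseq)
                              if f.strand == "-" else iseq)

    # intergenic spacers between adjacent gene-level spans
    spans = sorted({(f.span, name) for name, f in kept})
    if spans:
        if drop_irb:
            arc_start = (structure.irb.start + structure.irb.length) % n
            arc_len = n - structure.irb.length
            ordered = sorted(spans,
                             key=lambda it: (it[0][0] - arc_start) % n)
            bounds = [((sp[0] - arc_start) % n, (sp[1] - arc_start) % n, nm)
                      for sp, nm in ordered]
            prev_end, prev_name = 0, None
            for s, e, nm in bounds:
                if prev_name is not None and s > prev_end:
                    igs = record.subsequence((arc_start + prev_end) % n,
                                             s - prev_end)
                    out.setdefault(f"{prev_name}-{nm}", ("igs", igs))
                prev_end, prev_name = max(prev_end, e), nm
            # junction spacer: last gene -> (IRb excised) -> first gene,
            # i.e. the tail and head gaps of the arc form one locus
            head = bounds[0][0]
            tail = arc_len - prev_end
            if prev_name is not None and head + tail > 0:
                igs = (record.subsequence((arc_start + prev_end) % n, tail)
                       + record.subsequence(arc_start, head))
                first = bounds[0][2]
                out.setdefault(f"{prev_name}-{first}", ("igs", igs))
        else:
            ordered = sorted(spans)
            for (sp1, n1), (sp2, n2) in zip(ordered, ordered[1:]):
                if sp2[0] > sp1[1]:
                    out.setdefault(f"{n1}-{n2}",
                                   ("igs", fetch(sp1[1], sp2[0])))
            (sp_last, n_last), (sp_first, n_first) = ordered[-1], ordered[0]
            wrap = (sp_first[0] - sp_last[1]) % n
            if wrap > 0:
                out.setdefault(f"{n_last}-{n_first}",
                               ("igs", record.subsequence(sp_last[1], wrap)))
    return out


def extract_loci(records, ir_policy: str = "drop_one_copy",
                 structures: dict | None = None, min_records: int = 1,
                 excluded_genes=DEFAULT_EXCLUDED_GENES,
                 min_ir_length: int = MIN_IR_LENGTH) -> list:
    """Extract all typed loci shared across records.

    Coding loci are exon concatenations per gene, introns are the
    within-gene gaps between consecutive exons, and intergenic spacers
    (``geneA-geneB``, A upstream) are the maximal regions between
    adjacent gene spans.  With ``ir_policy='drop_one_copy'`` the IRb copy
    of the repeat is removed before spacer construction and IR genes are
    kept once.  Loci found in fewer than ``min_records`` records are
    dropped with a warning.
    """
    if ir_policy not in ("drop_one_copy", "keep_both"):
        raise DataError(f"unknown ir_policy {ir_policy!r}")
    records = list(records)
    loci: dict = {}
    for record in records:
        structure = (structures or {}).get(record.id)
        if structure is None and ir_policy == "drop_one_copy":
            try:
                structure = detect_quadripartite(record.sequence,
                                                 min_ir_length=min_ir_length)
            except StructureError:
                log.warning("record %s: no quadripartite structure; "
                            "treating as single-copy", record.id)
        per = _record_loci(record, structure, ir_policy, excluded_genes)
        for name, (kind, seq) in per.items():
            entry = loci.setdefault(name, LocusSet(name=name, kind=kind))
            if entry.kind != kind:
                log.warning("locus %s: kind differs across records "
                            "(%s vs %s)", name, entry.kind, kind)
            entry.sequences[record.id] = seq
    kept = []
    for name in sorted(loci):
        entry = loci[name]
        if len(entry) < min_records:
            log.warning("dropping locus %s: present in %d < %d records",
                        name, len(entry), min_records)
            continue
        kept.append(entry)
    return kept


def write_locus_fastas(loci, out_dir) -> list:
    """One unaligned FASTA per locus, named <locus>.fasta."""
    import os

    paths = []
    os.makedirs(out_dir, exist_ok=True)
    for locus in loci:
        path = os.path.join(out_dir, f"{locus.name}.fasta")
        with open(path, "w") as fh:
            for rid, seq in locus.sequences.items():
                fh.write(f">{rid}\n{seq}\n")
        paths.append(path)
    return paths
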