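"""Quadripartite structure: inverted-repeat detection, canonical orientation
and IR/SC junction characterisation.

A plastome is organised as LSC + IRb + SSC + IRa on a circle, the two IRs
being reverse complements of each other.  Detection searches the raw circular
sequence for the maximal pair of disjoint reverse-complementary repeats
(k-mer seeding, greedy extension), labels the longer single-copy region LSC,
and derives the four junctions JLB (LSC/IRb), JSB (IRb/SSC), JSA (SSC/IRa)
and JLA (IRa/LSC).  IR expansion and contraction across accessions show up as
junction shifts: genes slide across borders and per-accession IR lengths
deviate from the set median.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .genbank_io import (GENE_KINDS, Feature, PlastidKitError, PlastomeRecord,
                         revcomp)

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class NoInvertedRepeatError(PlastidKitError):
    pass


@dataclass
class QuadripartitePartition:
    """Region spans as (start, length) on the circle; starts in [0, genome).

    ``lsc``, ``irb``, ``ssc``, ``ira`` follow each other around the circle in
    that order (possibly wrapping the origin).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    ir_identity: float = 1.0

    def __post_init__(self) -> None:
        total = self.lsc[1] + self.irb[1] + self.ssc[1] + self.ira[1]
        if total != self.genome_length:
            raise ValueError(
                f"region lengths {total} != genome length {self.genome_length}")
        if self.irb[1] != self.ira[1]:
            raise ValueError("IR copies differ in length")
        if self.lsc[1] <= self.ssc[1]:
            raise ValueError("LSC must be longer than SSC")

    @property
    def lengths(self) -> dict[str, int]:
        return {"LSC": self.lsc[1], "IRb": self.irb[1], "SSC": self.ssc[1],
                "IRa": self.ira[1]}

    @property
    def ir_length(self) -> int:
        return self.ira[1]

    def region_sequence(self, record: PlastomeRecord, region: str) -> str:
        start, length = getattr(self, region.lower())
        return record.slice(start, start + length)


def _extend_pair(seq: str, a: int, b: int, m: int, g1: int, g2: int):
    """Greedily extend an exact reverse-complementary seed pair.

    Segment A = [a, a+m), B = [b, b+m) circularly, with S[A] == revcomp(S[B]).
    g1 = gap from A-end to B-start, g2 = gap from B-end to A-start.
    """
    L = len(seq)
    # grow A-right / B-left (consumes g1, two bases per step)
    while g1 >= 2 and _COMP.get(seq[(a + m) % L]) == seq[(b - 1) % L]:
        b = (b - 1) % L
        m += 1
        g1 -= 2
    # grow A-left / B-right (consumes g2)
    while g2 >= 2 and _COMP.get(seq[(a - 1) % L]) == seq[(b + m) % L]:
        a = (a - 1) % L
        m += 1
        g2 -= 2
    return a, b, m, g1, g2


def detect_quadripartite(record: PlastomeRecord, min_ir_len: int = 1000,
                         max_mismatch_frac: float = 0.0,
                         k: int = 25) -> QuadripartitePartition:
    """Find the maximal pair of disjoint reverse-complementary repeats and the
    induced single-copy regions; the longer single-copy region is LSC.

    Exact matching when ``max_mismatch_frac`` is 0 (the default).  A small
    tolerance re-scores the detected IR pair and only relaxes the identity
    invariant, for real records whose IRs differ by a handful of sites.
    """
    seq = record.sequence
    L = len(seq)
    if L <= 2 * min_ir_len:
        raise NoInvertedRepeatError(
            f"genome ({L} bp) shorter than twice min_ir_len")
    doubled = seq + seq[:k - 1]
    index: dict[str, list[int]] = {}
    for p in range(L):
        index.setdefault(doubled[p:p + k], []).append(p)

    stride = max(1, (min_ir_len - k) // 2)
    best = None  # (m, a, b, g1, g2)
    for p1 in range(0, L, stride):
        if best is not None:
            # skip seeds already inside the best pair
            m, a, b = best[0], best[1], best[2]
            if (p1 - a) % L < m or (p1 - b) % L < m:
                continue
        hits = index.get(revcomp(doubled[p1:p1 + k]))
        if not hits:
            continue
        for p2 in hits:
            if p2 == p1:
                continue
            g1 = (p2 - (p1 + k)) % L
            g2 = (p1 - (p2 + k)) % L
            if g1 + g2 + 2 * k != L:  # seeds overlap circularly
                continue
            a, b, m, g1, g2 = _extend_pair(seq, p1, p2, k, g1, g2)
            if best is None or m > best[0] or (m == best[0]
                                               and min(a, b) < min(best[1], best[2])):
                best = (m, a, b, g1, g2)

    if best is None or best[0] < min_ir_len:
        raise NoInvertedRepeatError(
            f"no reverse-complementary repeat >= {min_ir_len} bp")
    m, a, b, g1, g2 = best
    if g1 == 0 or g2 == 0:
        raise PlastidKitError("degenerate genome: repeats are adjacent, "
                              "no single-copy region between them")
    # gap1 follows copy A, gap2 follows copy B
    if g1 >= g2:
        lsc = ((a + m) % L, g1)
        irb, ssc, ira = ((b, m), ((b + m) % L, g2), (a, m))
    else:
        lsc = ((b + m) % L, g2)
        irb, ssc, ira = ((a, m), ((a + m) % L, g1), (b, m))

    ira_seq = seq[ira[0]:ira[0] + m] if ira[0] + m <= L else \
        seq[ira[0]:] + seq[:(ira[0] + m) % L]
    irb_seq = seq[irb[0]:irb[0] + m] if irb[0] + m <= L else \
        seq[irb[0]:] + seq[:(irb[0] + m) % L]
    rc = revcomp(irb_seq)
    identity = sum(x == y for x, y in zip(ira_seq, rc)) / m
    if identity < 1.0 - max_mismatch_frac - 1e-12:
        raise NoInvertedRepeatError(
            f"IR identity {identity:.4f} below tolerance")
    return QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira,
                                  genome_length=L, ir_identity=identity)


# ---------------------------------------------------------------------------
# canonical orientation
# ---------------------------------------------------------------------------

def _rotate_feature(f: Feature, shift: int, L: int) -> Feature:
    segs = []
    for s, e in f.intervals:
        s2 = (s - shift) % L
        e2 = s2 + (e - s)
        if e2 <= L:
            segs.append((s2, e2))
        else:
            segs.append((s2, L))
            segs.append((0, e2 - L))
    segs = _merge_adjacent(segs)
    return replace(f, intervals=segs)


def _reflect_feature(f: Feature, L: int) -> Feature:
    segs = [(L - e, L - s) for s, e in f.intervals][::-1]
    strand = "-" if f.strand == "+" else "+"
    return replace(f, intervals=segs, strand=strand)


def _merge_adjacent(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge segments split only by the origin (exactly abutting)."""
    if len(segs) < 2:
        return segs
    out = [segs[0]]
    for s, e in segs[1:]:
        if out[-1][1] == s:
            out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    if len(out) > 1 and out[-1][1] == out[0][0] == 0:
        pass  # wrap-around stays as two segments
    return out


def canonicalize(record: PlastomeRecord,
                 partition: QuadripartitePartition
                 ) -> tuple[PlastomeRecord, QuadripartitePartition]:
    """Rotate/orient to LSC,IRb,SSC,IRa with position 0 at the JLA junction.

    Between the two strand orientations (which both present an LSC-first
    reading of the circle) the one with the lexicographically smaller
    canonical sequence wins, making the result invariant to rotation and to
    reverse complementation of the input.  Applying canonicalize twice is the
    identity.
    """
    seq = record.sequence
    L = len(seq)
    r_f = partition.lsc[0]
    fwd = seq[r_f:] + seq[:r_f]
    # in the reverse complement, old IRa becomes the copy following LSC
    lsc_end = (partition.lsc[0] + partition.lsc[1]) % L
    r_r = (L - lsc_end) % L
    rc = revcomp(seq)
    rev = rc[r_r:] + rc[:r_r]

    if fwd <= rev:
        feats = [_rotate_feature(f, r_f, L) for f in record.features]
        new_seq = fwd
    else:
        feats = [_rotate_feature(_reflect_feature(f, L), r_r, L)
                 for f in record.features]
        new_seq = rev
    feats.sort(key=lambda f: (f.start, f.end, f.name, f.kind))
    new_rec = PlastomeRecord(accession=record.accession, species=record.species,
                             sequence=new_seq, circular=record.circular,
                             features=feats)
    lengths = partition.lengths
    lsc = (0, lengths["LSC"])
    irb = (lengths["LSC"], lengths["IRb"])
    ssc = (irb[0] + irb[1], lengths["SSC"])
    ira = (ssc[0] + ssc[1], lengths["IRa"])
    new_part = QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira,
                                      genome_length=L,
                                      ir_identity=partition.ir_identity)
    return new_rec, new_part


def detect_and_canonicalize(record: PlastomeRecord, **kw):
    part = detect_quadripartite(record, **kw)
    return canonicalize(record, part)


# ---------------------------------------------------------------------------
# junction reports
# ---------------------------------------------------------------------------

@dataclass
class JunctionEntry:
    junction: str
    position: int  # coordinate of the first base of the downstream region
    spanning_gene: tuple[str, int, int] | None  # (name, bp left, bp right)
    left_gene: str | None
    left_dist: int | None
    right_gene: str | None
    right_dist: int | None


@dataclass
class JunctionReport:
    accession: str
    entries: dict[str, JunctionEntry]
    ir_length: int

    def __post_init__(self) -> None:
        if set(self.entries) != set(JUNCTIONS):
            raise ValueError("need exactly one entry per junction")


def _feature_extent(f: Feature, L: int) -> tuple[int, int]:
    """(start, end) with end possibly > L for origin-wrapping features."""
    s, e = f.intervals[0][0], f.intervals[-1][1]
    if len(f.intervals) > 1 and f.intervals[-1][1] <= f.intervals[0][0]:
        return s, f.intervals[-1][1] + L  # wraps the origin
    return s, e


def junction_report(record: PlastomeRecord,
                    partition: QuadripartitePartition) -> JunctionReport:
    """Per-junction spanning gene or nearest flanking genes with distances.

    Expects the canonical orientation (LSC starting at 0); only gene-like
    features (gene/tRNA/rRNA/pseudogene) are considered.
    """
    feats = [f for f in record.features if f.kind in GENE_KINDS]
    if not feats:
        raise PlastidKitError(
            "record has no gene annotations; annotate it or skip the "
            "junction report")
    L = partition.genome_length
    jpos = {"JLB": partition.irb[0], "JSB": partition.ssc[0],
            "JSA": partition.ira[0], "JLA": 0}
    extents = [(f, *_feature_extent(f, L)) for f in feats]
    entries = {}
    for j, p in jpos.items():
        spanning = None
        for f, fs, fe in extents:
            for pp in (p, p + L):
                if fs < pp < fe:
                    spanning = (f.name, pp - fs, fe - pp)
                    break
            if spanning:
                break
        left = right = None
        left_d = right_d = None
        for f, fs, fe in extents:
            if spanning and f.name == spanning[0]:
                continue
            dl = (p - fe) % L
            dr = (fs - p) % L
            if left_d is None or dl < left_d:
                left, left_d = f.name, dl
            if right_d is None or dr < right_d:
                right, right_d = f.name, dr
        entries[j] = JunctionEntry(junction=j, position=p,
                                   spanning_gene=spanning,
                                   left_gene=left, left_dist=left_d,
                                   right_gene=right, right_dist=right_d)
    return JunctionReport(accession=record.accession, entries=entries,
                          ir_length=partition.ir_length)


def compare_junctions(reports: list[JunctionReport]) -> pd.DataFrame:
    """Multi-accession border table: one row per accession x junction, plus
    the accession's IR-length delta against the set median (positive =
    expansion, negative = contraction)."""
    if len(reports) < 2:
        raise ValueError("need at least two junction reports to compare")
    ir = pd.Series({r.accession: r.ir_length for r in reports})
    median = ir.median()
    rows = []
    for r in reports:
        for j in JUNCTIONS:
            e = r.entries[j]
            rows.append({
                "accession": r.accession, "junction": j, "position": e.position,
                "spanning_gene": e.spanning_gene[0] if e.spanning_gene else "",
                "into_left_bp": e.spanning_gene[1] if e.spanning_gene else 0,
                "into_right_bp": e.spanning_gene[2] if e.spanning_gene else 0,
                "left_gene": e.left_gene, "left_dist": e.left_dist,
                "right_gene": e.right_gene, "right_dist": e.right_dist,
                "ir_length": r.ir_length,
                "ir_delta_vs_median": int(r.ir_length - median),
            })
    return pd.DataFrame(rows)


def partition_to_bed(partition: QuadripartitePartition,
                     accession: str) -> str:
    """BED (0-based half-open) lines for the four regions; wrapping regions
    are split at the origin."""
    lines = []
    for name in ("LSC", "IRb", "SSC", "IRa"):
        start, length = getattr(partition, name.lower())
        end = start + length
        if end <= partition.genome_length:
            lines.append(f"{accession}\t{start}\t{end}\t{name}")
        else:
            lines.append(f"{accession}\t{start}\t{partition.genome_length}\t{name}")
            lines.append(f"{accession}\t0\t{end - partition.genome_length}\t{name}")
    return "\n".join(lines) + "\n"
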