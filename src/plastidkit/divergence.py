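"""Sequence divergence along the plastome.

Implements the DnaSP-style sliding-window nucleotide diversity (π) with the
600 bp window / 200 bp step used for plastome hotspot screens, hotspot naming
against a reference annotation, mVISTA-style percent-identity profiles with a
coding/non-coding split, per-sequence GC content, and the Welch t-test
contrasting inter- against intra-specific size variation of the whole genome
and of each quadripartite region.

π in a window is the average pairwise per-site difference:
``π = Σ_{i<j} d_ij / C(n,2)`` where ``d_ij`` is the mismatch fraction over
the window's retained columns at which both rows carry unambiguous bases.
Under the default *complete* deletion policy any column containing a gap in
any row is removed from the window first; ambiguity codes (including N) are
always treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genbank_io import GENE_KINDS, PlastomeRecord

_GAP = 4
_MISSING = 5


def _encode(rows: dict[str, str]) -> np.ndarray:
    lut = np.full(256, _MISSING, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    for c in "-.~":
        lut[ord(c)] = _GAP
    return np.vstack([lut[np.frombuffer(s.encode(), dtype=np.uint8)]
                      for s in rows.values()])


@dataclass
class MultipleAlignment:
    """Equal-length rows over {A,C,G,T,-,N and other IUPAC codes}; the
    reference row's ungapped coordinates anchor window positions."""

    rows: dict[str, str]
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")
        if self.reference is None:
            self.reference = next(iter(self.rows))
        if self.reference not in self.rows:
            raise ValueError(f"reference {self.reference!r} not in rows")

    @property
    def n_cols(self) -> int:
        return len(self.rows[self.reference])

    def column_map(self) -> np.ndarray:
        """Alignment column -> reference ungapped coordinate (-1 at reference
        gaps)."""
        ref = self.rows[self.reference]
        out = np.full(len(ref), -1, dtype=np.int64)
        pos = 0
        for i, c in enumerate(ref):
            if c not in "-.~":
                out[i] = pos
                pos += 1
        return out


def read_alignment(path, reference: str | None = None) -> MultipleAlignment:
    from Bio import SeqIO
    rows = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    return MultipleAlignment(rows=rows, reference=reference)


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from both counts."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    counts = {c: s.count(c) for c in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases")
    return (counts["G"] + counts["C"]) / total


# ---------------------------------------------------------------------------
# sliding-window nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityWindow:
    start: int
    end: int
    ref_start: int
    ref_end: int
    pi: float  # NaN when no usable columns
    n_sites_used: int
    region_name: str = ""


@dataclass
class DiversityProfile:
    windows: list[DiversityWindow]
    parameters: dict
    scope: str = "interspecific"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "win_start": w.start, "win_end": w.end,
            "ref_start": w.ref_start, "ref_end": w.ref_end,
            "n_sites": w.n_sites_used, "pi": w.pi,
            "region_name": w.region_name} for w in self.windows])

    def mean_pi(self) -> float:
        vals = [w.pi for w in self.windows if not np.isnan(w.pi)]
        return float(np.mean(vals)) if vals else float("nan")


def _window_pi(sub: np.ndarray, deletion: str) -> tuple[float, int]:
    """π and retained-column count for one window (encoded rows x cols)."""
    if deletion == "complete":
        sub = sub[:, ~(sub == _GAP).any(axis=0)]
    n_used = sub.shape[1]
    if n_used == 0:
        return float("nan"), 0
    n = sub.shape[0]
    ok = sub < 4
    total = 0.0
    npairs = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            nb = int(both.sum())
            if nb:
                total += float((sub[i, both] != sub[j, both]).sum()) / nb
    return total / npairs, n_used


def sliding_window_pi(alignment: MultipleAlignment, window: int = 600,
                      step: int = 200, deletion: str = "complete",
                      scope: str = "interspecific") -> DiversityProfile:
    """Sliding-window π anchored in alignment columns (the DnaSP convention);
    reference coordinates are carried along for region naming."""
    if len(alignment.rows) < 2:
        raise ValueError("π undefined for a single sequence")
    if deletion not in {"complete", "pairwise"}:
        raise ValueError(f"unknown deletion policy {deletion!r}")
    mat = _encode(alignment.rows)
    cmap = alignment.column_map()
    ncols = mat.shape[1]
    windows = []
    for start in range(0, ncols, step):
        end = min(start + window, ncols)
        pi, n_used = _window_pi(mat[:, start:end], deletion)
        refs = cmap[start:end]
        refs = refs[refs >= 0]
        ref_start = int(refs[0]) if refs.size else -1
        ref_end = int(refs[-1]) + 1 if refs.size else -1
        windows.append(DiversityWindow(start=start, end=end,
                                       ref_start=ref_start, ref_end=ref_end,
                                       pi=pi, n_sites_used=n_used))
        if end == ncols:
            break
    return DiversityProfile(windows=windows, scope=scope,
                            parameters={"window": window, "step": step,
                                        "deletion": deletion})


# ---------------------------------------------------------------------------
# hotspot naming
# ---------------------------------------------------------------------------

def name_region(record: PlastomeRecord, ref_start: int, ref_end: int) -> str:
    """Annotation label for a reference interval: the overlapped gene-like
    feature name(s), or "geneA-geneB" for a spacer between consecutive
    features."""
    feats = [f for f in record.features if f.kind in GENE_KINDS]
    if not feats:
        return f"{ref_start}-{ref_end}"
    hit = sorted({f.name: f.start for f in feats
                  if f.start < ref_end and f.end > ref_start}.items(),
                 key=lambda kv: kv[1])
    if hit:
        return "-".join(name for name, _ in hit)
    n = len(record)
    left = min(feats, key=lambda f: (ref_start - f.end) % n)
    right = min(feats, key=lambda f: (f.start - ref_end) % n)
    return f"{left.name}-{right.name}"


@dataclass
class HotspotRegion:
    name: str
    ref_start: int
    ref_end: int
    peak_pi: float
    col_start: int = 0
    col_end: int = 0


def top_k_regions(profile: DiversityProfile, record: PlastomeRecord,
                  k: int = 5) -> list[HotspotRegion]:
    """Top-k π hotspots: windows are taken in decreasing π order, overlapping
    or abutting windows merge into regions, and merging stops as soon as k
    regions exist; regions come back ranked by peak π."""
    import logging
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted((w for w in profile.windows if not np.isnan(w.pi)),
                    key=lambda w: (-w.pi, w.start))
    regions: list[list] = []  # [col_start, col_end, peak]
    for w in ranked:
        merged = None
        for r in regions:
            if w.start <= r[1] and w.end >= r[0]:
                r[0] = min(r[0], w.start)
                r[1] = max(r[1], w.end)
                r[2] = max(r[2], w.pi)
                merged = r
                break
        if merged is None:
            regions.append([w.start, w.end, w.pi])
            if len(regions) >= k:
                break
        # re-merge regions that may now touch
        regions.sort(key=lambda r: r[0])
        out = [regions[0]]
        for r in regions[1:]:
            if r[0] <= out[-1][1]:
                out[-1][1] = max(out[-1][1], r[1])
                out[-1][2] = max(out[-1][2], r[2])
            else:
                out.append(r)
        regions = out
        if len(regions) >= k and merged is None:
            break
    if len(regions) < k:
        logging.getLogger("plastidkit").warning(
            "only %d merged regions available (requested %d)",
            len(regions), k)
    cmap = None
    result = []
    for col_start, col_end, peak in regions:
        ws = [w for w in profile.windows
              if w.start >= col_start and w.end <= col_end]
        ref_start = min(w.ref_start for w in ws if w.ref_start >= 0)
        ref_end = max(w.ref_end for w in ws)
        result.append(HotspotRegion(
            name=name_region(record, ref_start, ref_end),
            ref_start=ref_start, ref_end=ref_end, peak_pi=peak,
            col_start=col_start, col_end=col_end))
    result.sort(key=lambda r: (-r.peak_pi, r.name))
    return result[:k]


def annotate_profile(profile: DiversityProfile,
                     record: PlastomeRecord) -> DiversityProfile:
    for w in profile.windows:
        if w.ref_start >= 0:
            w.region_name = name_region(record, w.ref_start, w.ref_end)
    return profile


# ---------------------------------------------------------------------------
# identity profile (mVISTA-style)
# ---------------------------------------------------------------------------

def identity_profile(alignment: MultipleAlignment, window: int = 100,
                     step: int = 40, record: PlastomeRecord | None = None
                     ) -> tuple[pd.DataFrame, dict]:
    """Per-row percent identity against the reference in sliding windows.

    Gap-vs-base counts as a mismatch, gap-vs-gap is skipped, ambiguity codes
    are skipped.  With a reference annotation, each window is labeled coding
    when most of its reference bases fall inside CDS/tRNA/rRNA features, and
    the summary reports mean identity for coding vs non-coding windows.
    """
    mat = _encode(alignment.rows)
    names = list(alignment.rows)
    ref_i = names.index(alignment.reference)
    cmap = alignment.column_map()
    coding_mask = None
    if record is not None:
        coding_mask = np.zeros(len(record), dtype=bool)
        for f in record.features:
            if f.kind in {"CDS", "tRNA", "rRNA"}:
                for s, e in f.intervals:
                    coding_mask[s:e] = True
    ncols = mat.shape[1]
    rows_out = []
    for start in range(0, ncols, step):
        end = min(start + window, ncols)
        ref = mat[ref_i, start:end]
        label = ""
        if coding_mask is not None:
            refs = cmap[start:end]
            refs = refs[refs >= 0]
            if refs.size:
                label = ("coding" if coding_mask[refs].mean() > 0.5
                         else "noncoding")
        for i, name in enumerate(names):
            row = mat[i, start:end]
            skip = ((row == _GAP) & (ref == _GAP)) | (row == _MISSING) | \
                (ref == _MISSING)
            compared = int((~skip).sum())
            if compared:
                ident = float((row[~skip] == ref[~skip]).sum()) / compared
            else:
                ident = float("nan")
            rows_out.append({"accession": name, "win_start": start,
                             "win_end": end, "identity": ident,
                             "label": label})
        if end == ncols:
            break
    df = pd.DataFrame(rows_out)
    summary = {}
    others = df[df.accession != alignment.reference]
    if coding_mask is not None and len(others):
        for lab in ("coding", "noncoding"):
            sel = others[others.label == lab].identity.dropna()
            summary[f"mean_identity_{lab}"] = (float(sel.mean())
                                               if len(sel) else float("nan"))
    return df, summary


# ---------------------------------------------------------------------------
# inter- vs intra-specific size variation
# ---------------------------------------------------------------------------

@dataclass
class SizeVariationResult:
    region: str
    interspecific: list[float] = field(default_factory=list)
    intraspecific: list[float] = field(default_factory=list)
    mean_inter: float = float("nan")
    mean_intra: float = float("nan")
    t_statistic: float = float("nan")
    p_value: float = float("nan")


def _pair_abs_diffs(values: list[float]) -> list[float]:
    return [abs(values[i] - values[j]) for i in range(len(values))
            for j in range(i + 1, len(values))]


def size_variation_test(records: list[PlastomeRecord],
                        partitions: list) -> dict[str, SizeVariationResult]:
    """Welch two-sided t-test of interspecific vs intraspecific absolute
    length differences, for the whole genome and each region.

    The intraspecific sample pools all within-species accession pairs; the
    interspecific sample takes every between-species accession pair.
    Species assignment comes from ``record.species``.
    """
    if len(records) != len(partitions):
        raise ValueError("records and partitions must match")
    by_species: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_species.setdefault(r.species, []).append(i)
    if len(by_species) < 2:
        raise ValueError("need at least two species")
    if not any(len(v) >= 2 for v in by_species.values()):
        raise ValueError("intraspecific sample empty: no species with >= 2 "
                         "accessions")

    def region_lengths(region: str) -> list[float]:
        if region == "whole":
            return [float(len(r)) for r in records]
        key = {"LSC": "lsc", "SSC": "ssc", "IR": "ira"}[region]
        return [float(getattr(p, key)[1]) for p in partitions]

    results = {}
    species_list = list(by_species)
    for region in ("whole", "LSC", "SSC", "IR"):
        lengths = region_lengths(region)
        intra: list[float] = []
        for idxs in by_species.values():
            intra.extend(_pair_abs_diffs([lengths[i] for i in idxs]))
        inter: list[float] = []
        for a in range(len(species_list)):
            for b in range(a + 1, len(species_list)):
                for i in by_species[species_list[a]]:
                    for j in by_species[species_list[b]]:
                        inter.append(abs(lengths[i] - lengths[j]))
        res = SizeVariationResult(region=region, interspecific=inter,
                                  intraspecific=intra,
                                  mean_inter=float(np.mean(inter)),
                                  mean_intra=float(np.mean(intra)))
        t, p = stats.ttest_ind(inter, intra, equal_var=False)
        if np.isnan(p):  # degenerate: both samples constant
            t, p = 0.0, 1.0
        res.t_statistic, res.p_value = float(t), float(p)
        results[region] = res
    return results


def size_variation_frame(results: dict[str, SizeVariationResult]
                         ) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": r.region, "n_inter": len(r.interspecific),
        "n_intra": len(r.intraspecific), "mean_inter": r.mean_inter,
        "mean_intra": r.mean_intra, "t": r.t_statistic, "p": r.p_value}
        for r in results.values()])
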