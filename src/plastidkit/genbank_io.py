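"""Reading, writing and slicing annotated plastome records.

The universal input of the package is a :class:`PlastomeRecord`: one circular
chloroplast genome with its feature table.  Records are read from and written
to GenBank flat files or FASTA via Biopython; internally every coordinate is
0-based half-open on the forward strand, and GenBank's 1-based inclusive
convention exists only at the file boundary.

Locus extraction across a set of accessions produces a :class:`LocusMatrix`
(one unaligned sequence per accession); accessions lacking the locus are
reported in ``dropped`` rather than failing the whole extraction, mirroring
how per-locus phylogenetic analyses exclude accessions with missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("plastidkit")

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = set("ACGT")
#: feature kinds treated as "gene-like" when looking for junction neighbours
#: or intergenic flanks
GENE_KINDS = ("gene", "tRNA", "rRNA", "pseudogene")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastidKitError(Exception):
    """Base class for all package errors."""


class ParseError(PlastidKitError):
    pass


class LocusNotFoundError(PlastidKitError):
    pass


@dataclass
class Feature:
    """One annotated feature.

    ``intervals`` is an ordered list of 0-based half-open ``(start, end)``
    segments; multiple segments encode joins, including features spanning the
    origin of a circular genome (stored as a tail segment followed by a head
    segment).
    """

    name: str
    kind: str  # gene | CDS | tRNA | rRNA | pseudogene
    strand: str  # '+' | '-'
    intervals: list[tuple[int, int]]
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in {"gene", "CDS", "tRNA", "rRNA", "pseudogene"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty segment ({s}, {e}) in {self.name}")

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def key(self) -> tuple:
        return (self.name, self.kind, self.strand, tuple(self.intervals))


@dataclass
class PlastomeRecord:
    accession: str
    species: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < n and 0 < e <= n):
                    raise ValueError(
                        f"feature {f.name} segment ({s},{e}) outside genome [0,{n})")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Circular slice on the forward strand; ``end`` may wrap past the origin."""
        n = len(self.sequence)
        if end <= n and start <= end:
            return self.sequence[start:end]
        start %= n
        end %= n
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]

    def feature_sequence(self, feat: Feature) -> str:
        """Spliced, strand-oriented sequence of a feature."""
        s = "".join(self.sequence[a:b] for a, b in feat.intervals)
        return revcomp(s) if feat.strand == "-" else s


# ---------------------------------------------------------------------------
# locus name normalization
# ---------------------------------------------------------------------------

# GenBank annotation dialects disagree on capitalisation and on whether tRNA
# names carry their anticodon; normalisation is deliberately lossy so that
# "trnH" and "trnH-GUG" address the same marker.
_SYNONYMS = {
    "ycf15": "ycf15",
    "pbf1": "psbn",  # psbN was renamed pbf1 in some recent annotations
}


def normalize_locus_name(name: str) -> str:
    n = name.strip().lower()
    if n.startswith("trn"):
        n = n.split("(")[0]
        # strip an anticodon suffix ("trnH-GUG" == "trnH") but leave spacer
        # labels like "trnK-trnQ" intact
        head, _, tail = n.rpartition("-")
        if head and len(tail) == 3 and set(tail) <= set("acgu"):
            n = head
    return _SYNONYMS.get(n, n)


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_KIND_TO_GB = {"gene": "gene", "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "pseudogene": "gene"}


def _feature_from_seqfeature(sf: SeqFeature) -> Feature | None:
    if sf.type not in {"gene", "CDS", "tRNA", "rRNA"}:
        return None
    name = (sf.qualifiers.get("gene") or sf.qualifiers.get("locus_tag")
            or sf.qualifiers.get("product") or ["?"])[0]
    kind = sf.type
    if sf.type == "gene" and "pseudo" in sf.qualifiers:
        kind = "pseudogene"
    strand = "-" if sf.location.strand == -1 else "+"
    parts = sf.location.parts
    if strand == "-":
        # Biopython lists complement-join parts in transcription order;
        # store them in genome order.
        parts = sorted(parts, key=lambda p: int(p.start))
    intervals = [(int(p.start), int(p.end)) for p in parts]
    quals = {k: v[0] for k, v in sf.qualifiers.items()
             if k not in {"gene", "pseudo", "translation"}}
    return Feature(name=name, kind=kind, strand=strand, intervals=intervals,
                   qualifiers=quals)


def read_plastome(path, format: str = "genbank") -> PlastomeRecord:
    """Read one plastome record from a GenBank flat file or FASTA."""
    if format not in {"genbank", "fasta"}:
        raise ValueError(f"unknown format {format!r}")
    try:
        rec = next(SeqIO.parse(str(path), format))
    except StopIteration:
        raise ParseError(f"{path}: no record found")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq:
        raise ParseError(f"{path}: empty sequence")
    if format == "fasta":
        species = " ".join(rec.description.split()[1:]) or rec.id
        return PlastomeRecord(accession=rec.id, species=species, sequence=seq,
                              circular=True, features=[])
    circular = rec.annotations.get("topology", "circular") == "circular"
    species = rec.annotations.get("organism", "") or rec.description
    feats = []
    for sf in rec.features:
        f = _feature_from_seqfeature(sf)
        if f is not None:
            feats.append(f)
    return PlastomeRecord(accession=rec.id.split(".")[0] or rec.name,
                          species=species, sequence=seq, circular=circular,
                          features=feats)


def read_plastomes(paths, format: str = "genbank") -> list[PlastomeRecord]:
    return [read_plastome(p, format=format) for p in paths]


def _seqfeature_from_feature(f: Feature) -> SeqFeature:
    strand = -1 if f.strand == "-" else 1
    locs = [SimpleLocation(s, e, strand=strand) for s, e in f.intervals]
    if strand == -1 and len(locs) > 1:
        locs = locs[::-1]  # transcription order for complement joins
    loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    quals: dict = {"gene": [f.name]}
    if f.kind == "pseudogene":
        quals["pseudo"] = [""]
    for k, v in sorted(f.qualifiers.items()):
        quals[k] = [v]
    return SeqFeature(location=loc, type=_KIND_TO_GB[f.kind], qualifiers=quals)


def write_record(record: PlastomeRecord, path, format: str = "genbank") -> None:
    """Write a record; the emitted file re-reads to an equivalent record."""
    if format == "fasta":
        rec = SeqRecord(Seq(record.sequence), id=record.accession,
                        description=record.species)
        SeqIO.write([rec], str(path), "fasta")
        return
    if format != "genbank":
        raise ValueError(f"unknown format {format!r}")
    rec = SeqRecord(Seq(record.sequence), id=record.accession,
                    name=record.accession[:16], description=record.species)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    rec.annotations["organism"] = record.species
    rec.features = [_seqfeature_from_feature(f) for f in record.features]
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# feature accounting (Table-1-style)
# ---------------------------------------------------------------------------

def feature_counts(record: PlastomeRecord) -> dict[str, int]:
    """Counts by category; every annotated occurrence counts once, so genes
    duplicated in the two IRs count twice.  Pseudogenes are included in both
    the gene and the CDS tallies (standard plastome-table convention)."""
    by_kind = {"gene": 0, "CDS": 0, "tRNA": 0, "rRNA": 0, "pseudogene": 0}
    for f in record.features:
        by_kind[f.kind] += 1
    return {
        "genes": by_kind["gene"] + by_kind["pseudogene"],
        "CDS": by_kind["CDS"] + by_kind["pseudogene"],
        "tRNA": by_kind["tRNA"],
        "rRNA": by_kind["rRNA"],
        "pseudogenes": by_kind["pseudogene"],
    }


def feature_counts_table(records: list[PlastomeRecord]):
    """Per-accession feature-count table (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for r in records:
        c = feature_counts(r)
        rows.append({"accession": r.accession, "species": r.species,
                     "length_bp": len(r), **c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# locus extraction
# ---------------------------------------------------------------------------

@dataclass
class LocusMatrix:
    locus: str
    rows: dict[str, str]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("LocusMatrix with no rows")
        overlap = set(self.dropped) & set(self.rows)
        if overlap:
            raise ValueError(f"accessions both present and dropped: {overlap}")


def _locus_features(record: PlastomeRecord, locus: str,
                    kinds=GENE_KINDS) -> list[Feature]:
    want = normalize_locus_name(locus)
    return [f for f in record.features
            if f.kind in kinds and normalize_locus_name(f.name) == want]


def _extract_feature_mode(record: PlastomeRecord, locus: str,
                          both_copies: bool = False) -> str | list[str] | None:
    # prefer the spliced CDS when one is annotated, else the gene-like feature
    feats = _locus_features(record, locus, kinds=("CDS",))
    if not feats:
        feats = _locus_features(record, locus)
    if not feats:
        return None
    feats = sorted(feats, key=lambda f: f.start)
    if both_copies:
        return [record.feature_sequence(f) for f in feats]
    return record.feature_sequence(feats[0])


def _extract_intergenic(record: PlastomeRecord, name_a: str,
                        name_b: str) -> str | None:
    fa = _locus_features(record, name_a)
    fb = _locus_features(record, name_b)
    if not fa or not fb:
        return None
    n = len(record)
    best = None  # (gap, start, end)
    for a in fa:
        for b in fb:
            for left, right in ((a, b), (b, a)):
                gap = (right.start - left.end) % n
                if best is None or gap < best[0]:
                    best = (gap, left.end, left.end + gap)
    if best is None or best[0] == 0:
        return ""
    return record.slice(best[1], best[2])


def parse_locus_request(name: str, records: list[PlastomeRecord]):
    """Resolve a locus name into (mode, args).

    A name is a feature if any record annotates it; otherwise, a name
    containing '-' is tried as an intergenic spacer "geneA-geneB" at every
    split point (tRNA anticodons also use '-', e.g. "ndhF-trnL-UAG" splits as
    ndhF | trnL-UAG).
    """
    for r in records:
        if _locus_features(r, name) or _locus_features(r, name, kinds=("CDS",)):
            return ("feature", (name,))
    parts = name.split("-")
    for i in range(1, len(parts)):
        a, b = "-".join(parts[:i]), "-".join(parts[i:])
        for r in records:
            if _locus_features(r, a) and _locus_features(r, b):
                return ("intergenic", (a, b))
    # region label listing several features ("geneA-geneB-geneC"): fall back
    # to the span between the outermost recognised flanks
    for i in range(1, len(parts)):
        for j in range(i, len(parts)):
            a, b = "-".join(parts[:i]), "-".join(parts[j:])
            for r in records:
                if _locus_features(r, a) and _locus_features(r, b):
                    return ("intergenic", (a, b))
    raise LocusNotFoundError(f"locus unknown: {name!r}")


def extract_locus(records: list[PlastomeRecord], locus: str,
                  region: str | tuple = "feature") -> LocusMatrix:
    """Extract one locus across accessions.

    ``region`` is "feature", "auto" (feature, falling back to spacer parsing),
    or a tuple ``("intergenic", (nameA, nameB))``.
    """
    if not records:
        raise ValueError("no records")
    if region == "auto":
        mode, args = parse_locus_request(locus, records)
    elif region == "feature":
        mode, args = "feature", (locus,)
    elif isinstance(region, tuple) and region[0] == "intergenic":
        mode, args = "intergenic", tuple(region[1])
    else:
        raise ValueError(f"unknown region spec {region!r}")

    rows: dict[str, str] = {}
    dropped: list[str] = []
    for r in records:
        if mode == "feature":
            seq = _extract_feature_mode(r, args[0])
        else:
            seq = _extract_intergenic(r, *args)
        if seq:
            rows[r.accession] = seq
        else:
            dropped.append(r.accession)
            logger.warning("accession %s lacks locus %s; excluded",
                           r.accession, locus)
    if not rows:
        raise LocusNotFoundError(f"locus unknown in all accessions: {locus!r}")
    return LocusMatrix(locus=locus, rows=rows, dropped=dropped)
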