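"""Synthetic annotated plastomes with known ground truth.

The generator emulates the phenomena a comparative plastome study measures:
a known species tree (pure-birth, unit depth) optionally carrying several
accessions per species with much shallower within-species divergence;
per-locus substitution-rate multipliers (fast intergenic spacers, conserved
CDSs, one or more planted high-rate marker genes); a circular quadripartite
genome whose two inverted repeats are kept exactly identical (full concerted
evolution: IR loci evolve once and are copied); lineage-specific IR
expansion/contraction implemented as junction boundary moves that duplicate
or remove sequence in both IR copies; and geometric-length indels restricted
to intergenic spacers.

Every emitted record satisfies the package's record invariants and the
emitted :class:`SyntheticTruth` (true tree, multipliers, per-accession
partitions, event log) is verifiable with ``detect_quadripartite``.  A base
adjacent to a single-copy junction is adjusted when it would extend the
reverse-complementary repeat past the true boundary, so the true partition
is exactly the maximal one the detector recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genbank_io import Feature, PlastomeRecord, revcomp
from .phylo import GTRModel, Node, PhyloTree
from .quadripartite import QuadripartitePartition

NUC = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome templates
# ---------------------------------------------------------------------------

@dataclass
class LocusSpec:
    name: str
    kind: str  # gene | tRNA | rRNA | pseudogene | spacer
    strand: str
    length: int


@dataclass
class GenomeTemplate:
    """Ordered locus maps for LSC, SSC and IRa; IRb is the reverse-complement
    mirror of IRa and is derived, never specified."""

    lsc: list[LocusSpec]
    ssc: list[LocusSpec]
    ira: list[LocusSpec]

    def __post_init__(self) -> None:
        if self.region_length("lsc") <= self.region_length("ssc"):
            raise ValueError("template LSC must be longer than SSC")
        names = [s.name for s in self.loci()]
        if len(names) != len(set(names)):
            raise ValueError("duplicate locus names in template")

    def region_length(self, region: str) -> int:
        return sum(s.length for s in getattr(self, region))

    @property
    def genome_length(self) -> int:
        return (self.region_length("lsc") + self.region_length("ssc")
                + 2 * self.region_length("ira"))

    def loci(self) -> list[LocusSpec]:
        """Evolving loci (IR loci once)."""
        return list(self.lsc) + list(self.ssc) + list(self.ira)


def _with_spacers(entries, default_spacer: int):
    """Interleave (name, kind, strand, length) gene tuples with named
    spacers; an int entry is an explicit spacer length."""
    out: list[LocusSpec] = []
    prev_gene = None
    pending_spacer = None
    for e in entries:
        if isinstance(e, int):
            pending_spacer = e
            continue
        name, kind, strand, length = e
        if prev_gene is not None:
            w = pending_spacer if pending_spacer is not None else default_spacer
            if w > 0:
                out.append(LocusSpec(name=f"{prev_gene}-{name}-igs",
                                     kind="spacer", strand="+", length=w))
        out.append(LocusSpec(name=name, kind=kind, strand=strand,
                             length=length))
        prev_gene = name
        pending_spacer = None
    return out


def _pad_to(loci: list[LocusSpec], target: int, name: str) -> list[LocusSpec]:
    total = sum(s.length for s in loci)
    if total > target:
        raise ValueError(f"template loci exceed target ({total} > {target})")
    if total < target:
        loci = list(loci)
        # keep the pad away from the region edge used by junction events
        loci.insert(len(loci) - 1,
                    LocusSpec(name=name, kind="spacer", strand="+",
                              length=target - total))
    return loci


def default_template(scale: str = "toy") -> GenomeTemplate:
    """Quadripartite template echoing the canonical plastome gene roster.

    ``toy`` is a ~25 kb genome for fast tests; ``realistic`` has region
    lengths of real plastome magnitude (~160 kb genome).
    """
    if scale == "toy":
        g, sp = 1.0, 1.0
        targets = {"lsc": 11000, "ssc": 5200, "ira": 4900}
    elif scale == "realistic":
        g, sp = 2.6, 9.0
        targets = {"lsc": 91000, "ssc": 18200, "ira": 26500}
    else:
        raise ValueError(f"unknown scale {scale!r}")

    def L(x):
        return int(x * g)

    def S(x):
        return int(x * sp)

    lsc = _with_spacers([
        ("trnH", "tRNA", "-", 80),
        S(150), ("psbA", "gene", "-", L(600)),
        S(150), ("trnK", "tRNA", "-", 80),
        S(420), ("trnQ", "tRNA", "-", 80),
        S(150), ("matK", "gene", "-", L(700)),
        S(150), ("psbI", "gene", "+", L(200)),
        S(320), ("atpA", "gene", "+", L(900)),
        S(150), ("rpoB", "gene", "+", L(1100)),
        S(150), ("rpoC1", "gene", "+", L(900)),
        S(150), ("rpoC2", "gene", "+", L(1300)),
        S(150), ("accD", "gene", "+", L(700)),
        S(260), ("psaI", "gene", "+", L(120)),
        S(150), ("clpP", "gene", "+", L(600)),
        S(150), ("rpl22", "gene", "+", L(400)),
        S(150), ("rps19", "gene", "+", L(280)),
    ], S(150))
    ssc = _with_spacers([
        ("ndhF", "gene", "-", L(1100)),
        S(360), ("trnL", "tRNA", "-", 80),
        S(150), ("ndhD", "gene", "-", L(800)),
        S(150), ("ccsA", "gene", "+", L(600)),
        S(150), ("ycf1", "gene", "+", L(1500)),
    ], S(150))
    ira = _with_spacers([
        ("rrn16", "rRNA", "+", L(600)),
        S(100), ("trnI", "tRNA", "+", 75),
        S(100), ("trnA", "tRNA", "+", 75),
        S(100), ("rrn23", "rRNA", "+", L(800)),
        S(60), ("rrn4.5", "rRNA", "+", 60),
        S(60), ("rrn5", "rRNA", "+", 60),
        S(100), ("ycf2", "gene", "-", L(900)),
    ], S(100))
    # spacer margins at the IRa edges keep junction events inside unannotated
    # sequence (except cuts deliberately planted inside genes)
    ira = ([LocusSpec("ira-head-igs", "spacer", "+", 900)] + ira
           + [LocusSpec("ira-tail-igs", "spacer", "+", 900)])
    lsc = _pad_to(lsc, targets["lsc"], "lsc-pad-igs")
    ssc = _pad_to(ssc, targets["ssc"], "ssc-pad-igs")
    ira = _pad_to(ira, targets["ira"], "ira-pad-igs")
    return GenomeTemplate(lsc=lsc, ssc=ssc, ira=ira)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Defaults emulate a nine-species comparison with 18 accessions (four for
    one species, three for another, two for four, one for three), shallow
    within-species divergence, spacers evolving faster than CDSs, one
    planted high-rate marker gene (rpoB), and IR contractions of 550 and
    700 bp in two single-accession lineages.
    """

    template: GenomeTemplate = None
    tree: str | None = None  # newick species tree; simulated when None
    n_species: int = 9
    accessions_per_species: tuple = (4, 3, 2, 2, 2, 2, 1, 1, 1)
    birth_rate: float = 1.0
    min_internal_edge: float = 0.0  # species-tree resolvability floor
    subs_per_site: float = 0.016  # root-to-tip expected subs at multiplier 1
    intraspecific_depth: float = 0.01  # within-species depth, tree-depth units
    kappa: float = 2.0
    base_freqs: tuple = (0.31, 0.19, 0.19, 0.31)
    gamma_alpha: float = 1.0
    rate_multipliers: dict = field(default_factory=lambda: {"rpoB": 5.0})
    spacer_multiplier: float = 3.0
    ir_rate_factor: float = 0.3  # IRs evolve several-fold slower than SC
    indel_rate: float = 1e-3  # per spacer site per unit branch length
    indel_mean_len: float = 3.0
    junction_shifts: list = field(default_factory=lambda: [
        ("sp08", "JLB", -550), ("sp09", "JLB", -700)])
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.template is None:
            self.template = default_template("toy")
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")

    def multiplier(self, spec: LocusSpec) -> float:
        if spec.name in self.rate_multipliers:
            return self.rate_multipliers[spec.name]
        base = self.spacer_multiplier if spec.kind == "spacer" else 1.0
        if spec.name in {s.name for s in self.template.ira}:
            base *= self.ir_rate_factor
        return base


def default_params(scenario: str = "paperlike", **overrides
                   ) -> SimulationParams:
    """Shipped scenarios: ``paperlike`` (see :class:`SimulationParams`) and
    ``markers`` (12 single-accession species, no indels or junction events;
    the clean condition for end-to-end marker selection)."""
    if scenario == "paperlike":
        p = SimulationParams()
    elif scenario == "markers":
        # shallow CDS-level divergence: the regime where single-locus trees
        # are informative but imperfect, so congruence ranking discriminates
        p = SimulationParams(n_species=12,
                             accessions_per_species=tuple([1] * 12),
                             subs_per_site=0.002, min_internal_edge=0.05,
                             spacer_multiplier=2.5,
                             indel_rate=0.0, junction_shifts=[])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return replace(p, **overrides) if overrides else p


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth_rate: float = 1.0,
                  seed: int | None = None,
                  min_internal: float = 0.0) -> PhyloTree:
    """Pure-birth (Yule) tree rescaled to unit root-to-tip depth.

    ``min_internal`` rejects realizations whose shortest internal edge falls
    below that fraction of the depth, redrawing until one qualifies — the
    condition for a resolvable radiation (a marker benchmark on a tree with
    effectively zero-length edges measures only noise).  Deterministic given
    ``seed``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    for _ in range(10000):
        tree = _yule_tree(n_taxa, birth_rate, rng)
        if min_internal <= 0:
            return tree
        internal = [n.length for n in tree.postorder()
                    if not n.is_leaf() and n.length is not None]
        if not internal or min(internal) >= min_internal:
            return tree
    raise RuntimeError("no tree satisfied min_internal; lower it")


def _yule_tree(n_taxa: int, birth_rate: float, rng) -> PhyloTree:
    t = 0.0
    root = Node()
    active = [(root, 0.0)]
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.length = (t - born) if node is not root else None
        kids = [Node(), Node()]
        node.children = kids
        active.extend((k, t) for k in kids)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    # shuffle label assignment so tip numbering carries no topological signal
    order = rng.permutation(n_taxa)
    for (node, born), k in zip(active, order):
        node.label = f"sp{k + 1:02d}"
        node.length = t - born
    tree = PhyloTree(root)
    return tree.rescale_to_unit_depth()


def _expand_accessions(tree: PhyloTree, counts: dict[str, int],
                       depth: float, rng) -> tuple[PhyloTree, dict[str, str]]:
    """Attach per-accession tips below species tips; returns the accession
    tree and accession -> species map."""
    tree = tree.copy()
    acc_species = {}
    for leaf in list(tree.leaves()):
        sp = leaf.label
        m = counts.get(sp, 1)
        if m == 1:
            acc = f"{sp}_1"
            leaf.label = acc
            acc_species[acc] = sp
            continue
        leaf.label = None
        for i in range(m):
            acc = f"{sp}_{i + 1}"
            bl = depth * rng.uniform(0.5, 1.5)
            leaf.children.append(Node(label=acc, length=bl))
            acc_species[acc] = sp
    return tree, acc_species


# ---------------------------------------------------------------------------
# sequence evolution (HKY + gamma site rates, locus multipliers)
# ---------------------------------------------------------------------------

class _Evolver:
    def __init__(self, params: SimulationParams, rng):
        self.p = params
        self.rng = rng
        kappa = params.kappa
        model = GTRModel(exch=np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0]),
                         freqs=np.asarray(params.base_freqs, dtype=float),
                         alpha=1.0, ncat=1)
        self.freqs = model.freqs
        self.w, self.u, self.uinv = model.eigensystem()

    def root_locus(self, spec: LocusSpec):
        n = spec.length
        bases = self.rng.choice(4, size=n, p=self.freqs).astype(np.uint8)
        rates = self.rng.gamma(self.p.gamma_alpha,
                               1.0 / self.p.gamma_alpha, size=n)
        return bases, rates

    def _substitute(self, bases, rates, dist):
        t = dist * rates
        ew = np.exp(np.outer(t, self.w))
        probs = np.einsum("ik,sk,kj->sij", self.u, ew, self.uinv)
        probs = np.clip(probs, 0.0, None)
        row = probs[np.arange(bases.size), bases, :]
        row /= row.sum(axis=1, keepdims=True)
        u = self.rng.random(bases.size)
        return (u[:, None] > np.cumsum(row, axis=1)).sum(axis=1
                                                         ).astype(np.uint8)

    def _indels(self, bases, rates, branch_len, locus_len0):
        lam = self.p.indel_rate * locus_len0 * branch_len
        n_events = self.rng.poisson(lam) if lam > 0 else 0
        for _ in range(n_events):
            size = int(self.rng.geometric(1.0 / self.p.indel_mean_len))
            if self.rng.random() < 0.5 and bases.size - size >= 10:
                pos = int(self.rng.integers(0, bases.size - size + 1))
                bases = np.delete(bases, slice(pos, pos + size))
                rates = np.delete(rates, slice(pos, pos + size))
            else:
                pos = int(self.rng.integers(0, bases.size + 1))
                ins_b = self.rng.choice(4, size=size, p=self.freqs
                                        ).astype(np.uint8)
                ins_r = self.rng.gamma(self.p.gamma_alpha,
                                       1.0 / self.p.gamma_alpha, size=size)
                bases = np.insert(bases, pos, ins_b)
                rates = np.insert(rates, pos, ins_r)
        return bases, rates

    def evolve_branch(self, spec: LocusSpec, bases, rates, branch_len):
        mult = self.p.multiplier(spec)
        dist = branch_len * self.p.subs_per_site * mult
        if dist > 0:
            bases = self._substitute(bases, rates, dist)
        if spec.kind == "spacer" and self.p.indel_rate > 0:
            bases, rates = self._indels(bases, rates, branch_len, spec.length)
        return bases, rates


def evolve_sequences(template: GenomeTemplate, tree: PhyloTree,
                     params: SimulationParams, rng=None
                     ) -> dict[str, dict[str, np.ndarray]]:
    """Per-taxon, per-locus base arrays (uint8 over ACGT), evolved down the
    tree; IR loci evolve once (both IR copies stay identical)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ev = _Evolver(params, rng)
    out: dict[str, dict[str, np.ndarray]] = {}
    specs = template.loci()
    root_state = {s.name: ev.root_locus(s) for s in specs}

    def walk(node, state):
        if node.length:
            state = {s.name: ev.evolve_branch(s, *state[s.name], node.length)
                     for s in specs}
        if node.is_leaf():
            out[node.label] = {name: b for name, (b, _) in state.items()}
        for c in node.children:
            walk(c, state)

    walk(tree.root, root_state)
    return out


# ---------------------------------------------------------------------------
# assembly: regions, annotations, junction events
# ---------------------------------------------------------------------------

def _decode(bases: np.ndarray) -> str:
    return NUC[bases].tobytes().decode()


def _region_string(specs, seqs) -> tuple[str, list[tuple[LocusSpec, int, int]]]:
    parts, layout = [], []
    pos = 0
    for s in specs:
        seq = _decode(seqs[s.name])
        parts.append(seq)
        layout.append((s, pos, pos + len(seq)))
        pos += len(seq)
    return "".join(parts), layout


def _features_for(spec: LocusSpec, start: int, end: int) -> list[Feature]:
    if spec.kind == "spacer":
        return []
    iv = [(start, end)]
    if spec.kind == "gene":
        return [Feature(spec.name, "gene", spec.strand, list(iv)),
                Feature(spec.name, "CDS", spec.strand, list(iv))]
    if spec.kind == "pseudogene":
        return [Feature(spec.name, "pseudogene", spec.strand, list(iv))]
    return [Feature(spec.name, "gene", spec.strand, list(iv)),
            Feature(spec.name, spec.kind, spec.strand, list(iv))]


def _splice_features(features: list[Feature], pos: int, delta: int
                     ) -> list[Feature]:
    """Remap absolute feature coordinates after inserting (delta > 0) or
    deleting (delta < 0) |delta| bases at ``pos``; features falling entirely
    inside a deletion are dropped, partial overlaps are truncated."""
    out = []
    for f in features:
        segs = []
        for s, e in f.intervals:
            if delta > 0:
                if s >= pos:
                    segs.append((s + delta, e + delta))
                elif e > pos:  # spanning the insertion point
                    segs.append((s, e + delta))
                else:
                    segs.append((s, e))
            else:
                d = -delta
                lo, hi = pos, pos + d
                ns = s - d if s >= hi else min(s, lo)
                ne = e - d if e >= hi else min(e, lo)
                if ne > ns:
                    segs.append((ns, ne))
        if segs:
            out.append(replace(f, intervals=segs))
    return out


_EVENTS = {
    # junction -> (region losing/gaining, description); implemented as a
    # single genome splice plus bookkeeping of the true region lengths
    "JLB": "LSC/IRb", "JSB": "IRb/SSC", "JSA": "SSC/IRa",
}


def apply_junction_shift(genome: str, features: list[Feature],
                         lengths: dict[str, int], junction: str, delta: int
                         ) -> tuple[str, list[Feature], dict[str, int]]:
    """Move the ``junction`` border by ``delta`` bp (positive = IR expansion
    into the single-copy side, negative = contraction), keeping the two IRs
    exact reverse complements.  Supported junctions: JLB, JSB, JSA.
    """
    if junction not in _EVENTS:
        raise ValueError(f"unsupported junction {junction!r}")
    if delta == 0:
        return genome, features, dict(lengths)
    d = abs(delta)
    l, s, ir = lengths["LSC"], lengths["SSC"], lengths["IR"]
    n = len(genome)
    expanding = delta > 0
    if junction == "JLB":
        if expanding:  # last d of LSC duplicated (revcomp) at IRa end
            chunk = genome[l - d:l]
            genome2 = genome + revcomp(chunk)
            pos, change = n, d
            l2, s2, ir2 = l - d, s, ir + d
        else:  # first d of IRb become LSC; IRa loses its last d
            genome2 = genome[:n - d]
            pos, change = n - d, -d
            l2, s2, ir2 = l + d, s, ir - d
    elif junction == "JSB":
        if expanding:  # first d of SSC join IRb; revcomp copy at IRa start
            chunk = genome[l + ir:l + ir + d]
            pos = l + ir + s
            genome2 = genome[:pos] + revcomp(chunk) + genome[pos:]
            change = d
            l2, s2, ir2 = l, s - d, ir + d
        else:  # last d of IRb become SSC; IRa loses its first d
            pos = l + ir + s
            genome2 = genome[:pos] + genome[pos + d:]
            change = -d
            l2, s2, ir2 = l, s + d, ir - d
    else:  # JSA
        if expanding:  # last d of SSC join IRa; revcomp copy at IRb end
            chunk = genome[l + ir + s - d:l + ir + s]
            pos = l + ir
            genome2 = genome[:pos] + revcomp(chunk) + genome[pos:]
            change = d
            l2, s2, ir2 = l, s - d, ir + d
        else:  # first d of IRa become SSC; IRb loses its last d
            pos = l + ir - d
            genome2 = genome[:pos] + genome[pos + d:]
            change = -d
            l2, s2, ir2 = l, s + d, ir - d
    if min(l2, s2, ir2) <= 0:
        raise ValueError(f"junction shift {junction} {delta:+d} leaves a "
                         "non-positive region")
    feats2 = _splice_features(features, pos, change)
    return genome2, feats2, {"LSC": l2, "SSC": s2, "IR": ir2}


def _block_boundary_extension(genome: str, lengths: dict[str, int]) -> str:
    """Substitute at most two junction-adjacent bases so the true IR pair is
    exactly maximal (no chance reverse-complementary extension across the
    single-copy regions)."""
    l, s, ir = lengths["LSC"], lengths["SSC"], lengths["IR"]
    g = list(genome)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if comp[g[l - 1]] == g[0]:
        g[l - 1] = g[0]
    if comp[g[l + ir]] == g[l + ir + s - 1]:
        g[l + ir + s - 1] = g[l + ir]
    return "".join(g)


def assemble_plastome(taxon: str, species: str,
                      seqs: dict[str, np.ndarray],
                      template: GenomeTemplate,
                      shifts: list[tuple[str, int]] | None = None
                      ) -> tuple[PlastomeRecord, QuadripartitePartition, list]:
    """One circular annotated genome (LSC|IRb|SSC|IRa) plus its true
    partition; ``shifts`` is a list of (junction, delta) for this lineage."""
    lsc_str, lsc_layout = _region_string(template.lsc, seqs)
    ssc_str, ssc_layout = _region_string(template.ssc, seqs)
    ira_str, ira_layout = _region_string(template.ira, seqs)
    irb_str = revcomp(ira_str)
    l, s, ir = len(lsc_str), len(ssc_str), len(ira_str)
    genome = lsc_str + irb_str + ssc_str + ira_str

    features: list[Feature] = []
    for spec, a, b in lsc_layout:
        features.extend(_features_for(spec, a, b))
    for spec, a, b in ssc_layout:
        features.extend(_features_for(spec, l + ir + a, l + ir + b))
    ira_off = l + ir + s
    for spec, a, b in ira_layout:
        features.extend(_features_for(spec, ira_off + a, ira_off + b))
        # mirrored IRb copy, reverse-complemented
        mirrored = replace(spec, strand="-" if spec.strand == "+" else "+")
        features.extend(_features_for(mirrored, l + (ir - b), l + (ir - a)))

    lengths = {"LSC": l, "SSC": s, "IR": ir}
    log = []
    for junction, delta in (shifts or []):
        genome, features, lengths = apply_junction_shift(
            genome, features, lengths, junction, delta)
        log.append({"taxon": taxon, "junction": junction, "delta": delta})
    genome = _block_boundary_extension(genome, lengths)

    l2, s2, ir2 = lengths["LSC"], lengths["SSC"], lengths["IR"]
    part = QuadripartitePartition(
        lsc=(0, l2), irb=(l2, ir2), ssc=(l2 + ir2, s2),
        ira=(l2 + ir2 + s2, ir2), genome_length=len(genome))
    features.sort(key=lambda f: (f.start, f.end, f.name, f.kind))
    rec = PlastomeRecord(accession=taxon, species=species, sequence=genome,
                         circular=True, features=features)
    return rec, part, log


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    tree: str  # accession tree, newick
    species_tree: str
    multipliers: dict[str, float]
    partitions: dict[str, QuadripartitePartition]
    events: list
    accession_species: dict[str, str]


def simulate_dataset(params: SimulationParams
                     ) -> tuple[list[PlastomeRecord], SyntheticTruth]:
    """One call producing the full synthetic study: records plus truth."""
    rng = np.random.default_rng(params.seed)
    if params.tree is not None:
        sp_tree = PhyloTree.from_newick(params.tree).rescale_to_unit_depth()
    else:
        sp_tree = simulate_tree(params.n_species, params.birth_rate,
                                seed=int(rng.integers(2 ** 31)),
                                min_internal=params.min_internal_edge)
    sp_names = sorted(sp_tree.taxa())
    counts = {sp: (params.accessions_per_species[i]
                   if i < len(params.accessions_per_species) else 1)
              for i, sp in enumerate(sp_names)}
    acc_tree, acc_species = _expand_accessions(
        sp_tree, counts, params.intraspecific_depth, rng)
    seqs = evolve_sequences(params.template, acc_tree, params, rng)

    shift_by_lineage: dict[str, list] = {}
    for lineage, junction, delta in params.junction_shifts:
        shift_by_lineage.setdefault(lineage, []).append((junction, delta))

    records, partitions, events = [], {}, []
    for acc in sorted(seqs):
        sp = acc_species[acc]
        shifts = shift_by_lineage.get(acc, []) + shift_by_lineage.get(sp, [])
        rec, part, log = assemble_plastome(acc, sp, seqs[acc],
                                           params.template, shifts)
        records.append(rec)
        partitions[acc] = part
        events.extend(log)

    multipliers = {spec.name: params.multiplier(spec)
                   for spec in params.template.loci()}
    truth = SyntheticTruth(tree=acc_tree.to_newick(),
                           species_tree=sp_tree.to_newick(),
                           multipliers=multipliers, partitions=partitions,
                           events=events, accession_species=acc_species)
    return records, truth
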