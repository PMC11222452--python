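# Methods

plastidkit reimplements, as one tested pipeline, the comparative analyses a
chloroplast-genome (plastome) study performs when it asks: *which single
locus, or small combination of loci, recovers the same phylogeny as the
whole plastome?*  This note documents the models, the conventions, the
synthetic study conditions, and the choices made where the design was
genuinely open.

## Coordinates and records

All internal coordinates are 0-based half-open on the forward strand;
GenBank's 1-based inclusive convention exists only at the file boundary
(Biopython handles the conversion).  A `PlastomeRecord` is one circular
genome with an ordered feature table; features may span the origin (stored
as two abutting segments).  Ambiguity codes other than the four bases are
preserved on read but treated as missing in every downstream statistic,
because the π and likelihood definitions below are over {A,C,G,T}.  Locus
names are normalised case-insensitively and tRNA anticodon suffixes are
optional ("trnH-GUG" ≡ "trnH"); a label that is not itself a feature is
interpreted as an intergenic spacer "geneA-geneB", and a label listing
several features falls back to the span between the outermost recognised
flanks.

## Quadripartite structure and junctions

The detector searches the raw circular sequence for the maximal pair of
disjoint reverse-complementary repeats: k-mer seeds (k = 25, strided so any
repeat of at least `min_ir_len` is guaranteed a seed) matched against the
reverse complement on the doubled sequence, then greedy exact extension in
both directions; the longer induced single-copy region is labelled LSC, per
universal plastome convention.  Matching is exact by default; a tolerance
only relaxes the IR-identity invariant (real IRs occasionally differ by a
handful of sites).  Junction positions are reported as the first base of
the downstream region, which fixes the off-by-one convention for
distance-0 cases: a gene ending exactly at a junction is the nearest left
gene at distance 0, never a spanning gene.

Canonical orientation: the genome is rotated so the LSC starts at
position 0 in the order LSC, IRb, SSC, IRa.  Between the two strand
orientations (both of which present an LSC-first reading) the one whose
canonical sequence is lexicographically smaller wins.  This makes
canonicalisation deterministic, idempotent, and invariant to rotation and
reverse complementation of the input — at the price that reports may
describe the reverse complement of the submitted strand.

IR expansion/contraction across accessions is summarised per junction and
as each accession's IR-length delta against the set median, so a single
shifted lineage among unshifted relatives reads out the shift exactly.

## Nucleotide diversity and identity profiles

Sliding-window π follows the DnaSP convention: windows are anchored in
alignment columns (default 600 bp window, 200 bp step), and per window

π = Σ_{i<j} d_ij / C(n,2),

where d_ij is the mismatch fraction over the window's retained columns at
which both rows carry unambiguous bases.  The default *complete* deletion
policy removes any column containing a gap in any row before computing
d_ij; a *pairwise* mode is available for sensitivity checks, and the policy
is recorded in the profile.  No n/(n−1) correction is applied (the direct
mean-pairwise estimator).  Hotspots are the top-k windows after merging
overlapping/abutting windows in decreasing π order, stopping as soon as k
regions exist; each merged region is named by the gene-like features it
overlaps, or by its flanking features when it lies in a spacer.

Identity profiles (mVISTA-style) report per-row percent identity against a
reference in 100 bp / 40 bp windows; gap-vs-base counts as mismatch,
gap-vs-gap and ambiguity codes are skipped, and windows are labelled coding
when most of their reference bases fall inside CDS/tRNA/rRNA features.

Size variation: the intraspecific sample pools |Δlength| over all
within-species accession pairs, the interspecific sample takes every
between-species accession pair, and a Welch two-sided t-test compares the
two, for the whole genome and for each region.  The pairwise-|Δ|
construction is this package's stated definition of "variation", chosen
because it uses every accession symmetrically; degenerate all-equal input
reports p = 1.

## Site rates and phylogenetic informativeness

Per-site informativeness uses the quartet form ρ(t; λ) = 16 λ² t e^(−4λt),
which peaks at t = 1/(4λ) and obeys ρ(t; cλ) = c·ρ(ct; λ); the constant 16
is immaterial to ranking.  Site rates λ_i are estimated on a guide tree
rescaled to unit root-to-tip depth, normalised to mean 1 over the locus,
with invariant sites fixed at 0:

- `fitch_norm` (default): λ_i proportional to the parsimony step count of
  site i, computed with Hartigan's generalisation of the Fitch algorithm
  (exact on multifurcating trees, so consensus guide trees work; branch
  lengths are not required).
- `ml_jc`: λ_i maximises the one-site Jukes–Cantor pruning likelihood with
  branch lengths scaled by λ.  Slower; requires branch lengths.  Parameter
  recovery is well identified when the tree carries substantial length and
  rate heterogeneity is moderate; under strong heterogeneity many sites are
  invariant and tie at rate 0, capping rank correlations.

Net PI sums ρ over a locus's sites (so longer loci legitimately score
higher, matching the net-informativeness convention), profiles are reported
on t ∈ [0, 1] in units of guide-tree depth, and loci are ranked by the
trapezoid area of the net profile on that interval — an integral over the
whole depth rather than an arbitrary single epoch.

## Tree inference and comparison

Distances: p, JC69, K2P with pairwise deletion; JC saturation (p ≥ 3/4)
raises an error by default (an optional cap is available, because silent
caps distort NJ).  Neighbor joining is the classic Saitou–Nei algorithm
with negative branch lengths clamped to zero and ties broken on the
smallest active index pair, making it deterministic given input order.

The ML engine is a compact GTR+Γ hill-climber, not a RAxML
reimplementation: Felsenstein pruning over site patterns with per-node
scaling; four discrete-gamma categories with mean-of-bin rates; empirical
base frequencies; α optimised by bounded one-dimensional search on
[0.05, 10]; branch lengths by per-edge Brent; NNI moves accepted when they
improve the log-likelihood by more than 1e-4, restarting the sweep after
each accepted move so the edge list is never stale.  An external-provider
hook (command template producing newick from FASTA) allows substituting
RAxML or similar for exact replication.

Bootstrap: columns resampled with replacement per replicate (deterministic
given the seed), one tree per replicate, majority-rule consensus retaining
splits above the threshold (default 50%) annotated with percentage support.

Tree distances are computed on the shared tip set after pruning (mirroring
per-locus accession exclusions).  Classic RF is the symmetric difference of
non-trivial split sets, normalised by |S1| + |S2|.  Generalized RF pairs
splits by maximum-weight bipartite matching (Hungarian algorithm) where a
pair's weight is its mutual clustering information in bits; with H_k the
summed clustering entropies of tree k's splits and M the matching score,
the distance is (H1 + H2 − 2M)/(H1 + H2) ∈ [0, 1], zero exactly when the
split sets coincide.  This is the clustering-information variant; other
generalized-RF flavours (phylogenetic information, matching split) would
give similar but not identical values.

## The marker-selection pipeline

Stages: whole-genome alignment → reference tree (bootstrap majority-rule
consensus; distances are taken against it directly, polytomies being
handled natively by the split-based distances) → interspecific π profile →
top-5 hotspot regions → per-CDS site rates and net PI → top-10 loci →
union with provenance (shared loci tagged "both") → one tree per candidate
with generalized-RF congruence → all 2^m − 1 combinations of the top-m
singletons (concatenation over the intersection of accessions holding
every locus in the set).  Accessions missing a locus are excluded from
that locus's analysis and reported.

Two deliberate robustness choices:

- Per-locus trees collapse internal edges supported by fewer than 0.5
  expected substitutions across the alignment (`collapse_min_subs`).  A
  distance-tree edge of essentially zero length is a tie-break artifact,
  not evidence; leaving such edges resolved lets a signal-free locus reach
  perfect congruence by luck.  Collapsing converts guesses into polytomies,
  which the generalized-RF distance penalises less than wrong splits but
  never credits as agreement.
- The reference tree and the candidate trees can use different inference
  methods (`reference_tree_method`): the whole-genome reference is
  signal-rich and NJ-based bootstrap is accurate there, while the built-in
  ML search measured no better than NJ for weak single loci at toy scale
  and costs an order of magnitude more, so NJ is the default for both.

Ties in the ranking break by fewer loci, then alphabetically.

## Synthetic plastomes: what they emulate, and what they do not

The generator produces circular annotated genomes with full ground truth:
a pure-birth species tree rescaled to unit depth (optionally conditioned on
a minimum internal edge length — a resolvability floor, because a marker
benchmark on a tree with effectively zero-length edges measures only
noise); optional multi-accession species whose within-species branch
lengths are two orders of magnitude shallower; HKY substitution (κ = 2,
AT-rich frequencies 0.31/0.19/0.19/0.31) with per-site gamma rates (α = 1)
times a per-locus multiplier; intergenic spacers faster than CDSs; IR loci
evolved once and copied (full concerted evolution — the strongest form,
guaranteeing the detector's exact-match assumption) and additionally slowed
by `ir_rate_factor` = 0.3, reflecting the several-fold lower substitution
rate of real IRs; geometric-length indels (mean 3 bp) restricted to
spacers, so CDS alignments stay gap-free as in real plastome CDSs; and
lineage-specific junction shifts implemented as boundary moves that
duplicate or remove sequence in both IR copies at JLB, JSB or JSA (JLA
would relocate the linear origin and is not supported — the same
signatures are available at the other borders).  A shift cutting inside a
gene leaves that gene spanning the border, the signature by which IR
expansion is read in real junction plots.

Two details exist purely so the truth is exactly recoverable.  Tip labels
are assigned by a seeded random permutation, because assigning them in
birth order correlates label indices with topology and lets deterministic
NJ tie-breaks "recover" trees from signal-free data.  And after assembly,
at most two junction-adjacent bases are substituted when they would extend
the reverse-complementary repeat past the true border by chance; without
this, exact partition recovery would fail for about one genome in four per
border.

Shipped scenarios (their defaults are the study conditions; they are not
tuned per run):

- `paperlike`: nine species, 18 accessions (4+3+2+2+2+2+1+1+1),
  subs_per_site = 0.016 at multiplier 1 — calibrated once so the mean
  interspecific sliding-window π over the whole genome is ≈ 0.028, the
  level typical of congeneric plastome comparisons; intraspecific depth
  0.01; indel rate 1e-3 per spacer site per unit branch; IR contractions
  of 550 and 700 bp planted in two single-accession lineages.
- `markers`: twelve single-accession species on a resolvable radiation
  (minimum internal edge 0.05 of depth), shallow CDS-level divergence
  (subs_per_site = 0.002), spacer multiplier 2.5, no indels or junction
  events, and one planted high-rate, tree-concordant marker gene (rpoB at
  5×).  This is the regime in which single-locus trees are informative but
  imperfect, so congruence ranking genuinely discriminates.

What the generator does **not** emulate: annotation errors and dialect
inconsistencies of public records, codon structure and selection,
recombination, heteroplasmy, within-IR divergence, base-composition
heterogeneity along the genome, and alignment error (CDS loci are
simulated indel-free, so their "alignments" are exact).  Passing tests on
this generator therefore demonstrate correctness of the statistics and the
recovery machinery under the stated model, not robustness to the
annotation and alignment pathologies of real GenBank records — the
normalisation table and the MAFFT provider address those, but are only
exercised lightly here.

## Problem sizes and numerical choices

The default test suite runs at toy scale: ~26 kb genomes, 12–18 accessions,
600–1500 bp loci; the exhaustive oracles run on ≤6-tip trees and 5-leaf
topology sets; ML topology recovery is exercised at 6 taxa × 1200 sites.
Likelihood agreement with brute-force state enumeration is asserted to
1e-10, π against its brute-force oracle to 1e-12, and the ρ scaling
identity to 1e-12.  Degenerate inputs are defined rather than left to
chance: empty windows give missing π, all-equal size samples give p = 1,
all-invariant loci give zero rates and zero PI with a warning, trees with
fewer than four taxa skip the NNI search, and a generalized-RF comparison
of two star trees is 0.

## Known limitations

- The built-in ML search is a local NNI hill-climber from an NJ start; it
  can stop at local optima that SPR-capable tools escape.
- The junction-shift model moves one border per event and does not model
  partial duplications that leave diverged pseudo-copies.
- `detect_quadripartite`'s tolerant mode re-scores the exact maximal pair;
  genomes whose IRs differ enough to break exact k-mer seeds within the
  stride are reported as having no IR rather than approximately located.
- Generalized-RF values depend on the variant; comparisons with numbers
  produced by other implementations should expect variant-level, not
  digit-level, agreement.
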