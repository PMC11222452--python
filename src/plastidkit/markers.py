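"""End-to-end marker selection.

The procedure mirrors how single-locus surrogates for whole-plastome
phylogenies are chosen: build the reference tree from the whole-genome
alignment (bootstrap majority-rule consensus); screen for candidate loci as
the union of the top-π sliding-window hotspots and the top net-PI coding
loci; infer one tree per candidate locus (accessions missing the locus are
excluded from that analysis); rank candidates by generalized Robinson–Foulds
distance to the reference; and finally evaluate every combination of the
top-m singleton loci by concatenation.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import divergence, informativeness
from .divergence import MultipleAlignment
from .genbank_io import (PlastidKitError, PlastomeRecord, extract_locus,
                         normalize_locus_name)
from .phylo import (PhyloTree, TreeDistance, bootstrap_consensus, nj_tree,
                    optimize_tree, pairwise_distances, tree_distance)

logger = logging.getLogger("plastidkit")


class PipelineError(PlastidKitError):
    pass


@dataclass
class PipelineConfig:
    window: int = 600
    step: int = 200
    deletion: str = "complete"
    k_pi: int = 5
    k_PI: int = 10
    top_m: int = 3
    tree_method: str = "nj"  # nj | ml | external
    reference_tree_method: str | None = None  # None -> same as tree_method
    external_tree_cmd: str | None = None  # template with {fasta} and {out}
    bootstrap_B: int = 100
    consensus_threshold: float = 0.5
    rate_method: str = "fitch_norm"
    alignment: str = "auto"  # asis | mafft | auto
    distance_method: str = "gen_rf_matching"
    locus_tree_consensus: bool = False  # best tree by default
    # collapse locus-tree edges supported by fewer than this many expected
    # substitutions across the alignment (0 disables)
    collapse_min_subs: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.k_pi, self.k_PI, self.top_m) < 1:
            raise ValueError("k_pi, k_PI and top_m must all be >= 1")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")


@dataclass
class MarkerEvaluation:
    loci: tuple[str, ...]
    accessions: tuple[str, ...]
    excluded: tuple[str, ...]
    tree: PhyloTree
    distance: TreeDistance
    rank: int | None = None

    @property
    def key(self):
        return (self.distance.normalized, len(self.loci),
                tuple(sorted(self.loci)))


@dataclass
class PipelineReport:
    candidates: list[dict]
    evaluations: list[MarkerEvaluation]
    combination_evaluations: list[MarkerEvaluation]
    best_single: MarkerEvaluation
    best_combination: MarkerEvaluation
    reference_tree: PhyloTree
    hotspots: list
    pi_ranking: list

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.evaluations + self.combination_evaluations:
            rows.append({"loci": "+".join(ev.loci), "n_loci": len(ev.loci),
                         "n_accessions": len(ev.accessions),
                         "distance": ev.distance.normalized,
                         "rank": ev.rank})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alignment providers
# ---------------------------------------------------------------------------

def align_rows(rows: dict[str, str], how: str = "auto",
               reference: str | None = None) -> MultipleAlignment:
    """Turn unaligned per-accession sequences into a MultipleAlignment.

    ``asis`` requires equal lengths (pre-aligned or indel-free input);
    ``mafft`` shells out to a MAFFT-compatible aligner; ``auto`` picks asis
    when lengths already agree.
    """
    lengths = {len(s) for s in rows.values()}
    if how == "auto":
        how = "asis" if len(lengths) == 1 else "mafft"
    if how == "asis":
        if len(lengths) != 1:
            raise PipelineError(
                "asis alignment requires equal-length sequences; "
                "use the mafft provider")
        return MultipleAlignment(rows=dict(rows), reference=reference)
    if how != "mafft":
        raise ValueError(f"unknown alignment provider {how!r}")
    exe = shutil.which("mafft")
    if exe is None:
        raise PipelineError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        fin = os.path.join(td, "in.fasta")
        with open(fin, "w") as fh:
            for name, seq in rows.items():
                fh.write(f">{name}\n{seq}\n")
        out = subprocess.run([exe, "--auto", "--quiet", fin],
                             capture_output=True, text=True, check=True)
    aligned: dict[str, str] = {}
    name = None
    for line in out.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            aligned[name] = []
        elif name:
            aligned[name].append(line.strip())
    rows2 = {n: "".join(parts).upper() for n, parts in aligned.items()}
    return MultipleAlignment(rows=rows2, reference=reference)


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def select_candidate_loci(top_pi_regions: list, top_pi_loci: list
                          ) -> list[dict]:
    """Union of π hotspots and high-PI loci with provenance tags; ordered by
    the best rank either source assigns."""
    if not top_pi_regions or not top_pi_loci:
        raise ValueError("both candidate lists must be non-empty")

    def name_of(x):
        return getattr(x, "name", None) or getattr(x, "locus", None) or str(x)

    cands: dict[str, dict] = {}
    for rank, item in enumerate(top_pi_regions, start=1):
        key = name_of(item).lower()
        cands[key] = {"locus": name_of(item), "provenance": "pi",
                      "best_rank": rank}
    for rank, item in enumerate(top_pi_loci, start=1):
        key = name_of(item).lower()
        if key in cands:
            cands[key]["provenance"] = "both"
            cands[key]["best_rank"] = min(cands[key]["best_rank"], rank)
        else:
            cands[key] = {"locus": name_of(item), "provenance": "PI",
                          "best_rank": rank}
    return sorted(cands.values(), key=lambda c: (c["best_rank"], c["locus"]))


# ---------------------------------------------------------------------------
# per-locus-set evaluation
# ---------------------------------------------------------------------------

def _infer_locus_tree(rows: dict[str, str], config: PipelineConfig
                      ) -> PhyloTree:
    if config.locus_tree_consensus:
        cons, _ = bootstrap_consensus(rows, B=config.bootstrap_B,
                                      threshold=config.consensus_threshold,
                                      seed=config.seed,
                                      method=("nj" if config.tree_method
                                              == "external"
                                              else config.tree_method))
        return cons
    if config.tree_method == "nj":
        return nj_tree(pairwise_distances(rows, model="JC69", cap=5.0))
    if config.tree_method == "ml":
        tree, _, _ = optimize_tree(rows)
        return tree
    if config.tree_method == "external":
        return _external_tree(rows, config.external_tree_cmd)
    raise ValueError(f"unknown tree method {config.tree_method!r}")


def _external_tree(rows: dict[str, str], cmd_template: str | None
                   ) -> PhyloTree:
    """External provider contract: a shell command template with ``{fasta}``
    and ``{out}`` placeholders producing a newick file."""
    if not cmd_template:
        raise PipelineError("external tree method requires external_tree_cmd")
    with tempfile.TemporaryDirectory() as td:
        fasta = os.path.join(td, "aln.fasta")
        out = os.path.join(td, "tree.nwk")
        with open(fasta, "w") as fh:
            for name, seq in rows.items():
                fh.write(f">{name}\n{seq}\n")
        subprocess.run(cmd_template.format(fasta=fasta, out=out), shell=True,
                       check=True, capture_output=True)
        with open(out) as fh:
            return PhyloTree.from_newick(fh.read())


def evaluate_locus_set(records: list[PlastomeRecord], loci,
                       reference_tree: PhyloTree,
                       config: PipelineConfig | None = None
                       ) -> MarkerEvaluation:
    """Extract, align and concatenate the loci, infer a tree, and measure its
    generalized-RF distance to the reference on the shared accessions.

    Accessions lacking any locus in the set are excluded (and reported).
    """
    config = config or PipelineConfig()
    loci = tuple(loci) if not isinstance(loci, str) else (loci,)
    matrices = [extract_locus(records, name, region="auto") for name in loci]
    common = set(records_accessions(records))
    for m in matrices:
        common &= set(m.rows)
    excluded = tuple(sorted(set(records_accessions(records)) - common))
    if len(common) < 4:
        raise PipelineError(
            f"insufficient taxa for {'+'.join(loci)}: {len(common)} usable")
    aligned_parts = []
    for m in matrices:
        rows = {a: m.rows[a] for a in sorted(common)}
        aligned_parts.append(align_rows(rows, how=config.alignment))
    rows = {a: "".join(p.rows[a] for p in aligned_parts)
            for a in sorted(common)}
    tree = _infer_locus_tree(rows, config)
    if config.collapse_min_subs > 0:
        ncols = len(next(iter(rows.values())))
        tree = tree.collapse_short_edges(config.collapse_min_subs / ncols)
    dist = tree_distance(tree, reference_tree, method=config.distance_method)
    if excluded:
        logger.info("loci %s: excluded accessions %s", "+".join(loci),
                    ", ".join(excluded))
    return MarkerEvaluation(loci=loci, accessions=tuple(sorted(common)),
                            excluded=excluded, tree=tree, distance=dist)


def records_accessions(records: list[PlastomeRecord]) -> list[str]:
    return [r.accession for r in records]


def search_combinations(records, top_loci: list[str],
                        reference_tree: PhyloTree,
                        config: PipelineConfig | None = None
                        ) -> list[MarkerEvaluation]:
    """Evaluate all non-empty subsets of the given loci; ascending distance,
    ties broken by fewer loci then alphabetically."""
    if not top_loci:
        raise ValueError("top_loci empty")
    config = config or PipelineConfig()
    m = len(top_loci)
    evals = []
    for mask in range(1, 2 ** m):
        subset = tuple(top_loci[i] for i in range(m) if mask >> i & 1)
        evals.append(evaluate_locus_set(records, subset, reference_tree,
                                        config))
    evals.sort(key=lambda e: e.key)
    for i, e in enumerate(evals, start=1):
        e.rank = i
    return evals


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _one_accession_per_species(records: list[PlastomeRecord]
                               ) -> list[PlastomeRecord]:
    seen, out = set(), []
    for r in sorted(records, key=lambda r: r.accession):
        if r.species not in seen:
            seen.add(r.species)
            out.append(r)
    return out


def run_pipeline(records: list[PlastomeRecord],
                 config: PipelineConfig | None = None,
                 out_dir: str | None = None) -> PipelineReport:
    """Whole procedure: reference tree, π hotspots, PI ranking, candidate
    union, per-candidate congruence, combination search.

    Deterministic given (records, config, config.seed).
    """
    config = config or PipelineConfig()
    if len(records) < 5 or len({r.species for r in records}) < 2:
        raise PipelineError("need >= 5 accessions spanning >= 2 species")
    stage = "reference_tree"
    try:
        genome_rows = {r.accession: r.sequence for r in records}
        aln = align_rows(genome_rows, how=config.alignment,
                         reference=records[0].accession)
        method = config.reference_tree_method or config.tree_method
        if method == "external":
            method = "nj"
        reference_tree, _ = bootstrap_consensus(
            aln.rows, B=config.bootstrap_B,
            threshold=config.consensus_threshold, seed=config.seed,
            method=method)

        stage = "diversity_hotspots"
        inter = _one_accession_per_species(records)
        inter_rows = {a: aln.rows[a] for a in records_accessions(inter)}
        inter_aln = MultipleAlignment(rows=inter_rows,
                                      reference=inter[0].accession)
        profile = divergence.sliding_window_pi(
            inter_aln, window=config.window, step=config.step,
            deletion=config.deletion)
        hotspots = divergence.top_k_regions(profile, inter[0], k=config.k_pi)

        stage = "informativeness"
        by_norm: dict[str, str] = {}
        for f in records[0].features:
            if f.kind == "CDS":
                by_norm.setdefault(normalize_locus_name(f.name), f.name)
        cds_names = [by_norm[k] for k in sorted(by_norm)]
        profiles = []
        for name in cds_names:
            try:
                matrix = extract_locus(records, name, region="feature")
            except PlastidKitError:
                continue
            rows = {a: s for a, s in matrix.rows.items()}
            lens = {len(s) for s in rows.values()}
            if len(lens) != 1:
                rows = align_rows(rows, how=config.alignment).rows
            guide = reference_tree.prune_to(set(rows)) \
                if set(rows) != reference_tree.taxa() else reference_tree
            rates = informativeness.estimate_site_rates(
                rows, guide, method=config.rate_method, locus=name)
            profiles.append(informativeness.pi_profile(rates))
        pi_ranking = informativeness.rank_loci_by_pi(profiles, k=config.k_PI)

        stage = "candidates"
        candidates = select_candidate_loci(hotspots, pi_ranking)

        stage = "evaluation"
        evaluations = []
        for cand in candidates:
            try:
                evaluations.append(evaluate_locus_set(
                    records, (cand["locus"],), reference_tree, config))
            except (PlastidKitError, ValueError) as exc:
                logger.warning("candidate %s skipped: %s", cand["locus"], exc)
        if not evaluations:
            raise PipelineError("no candidate locus could be evaluated")
        evaluations.sort(key=lambda e: e.key)
        for i, e in enumerate(evaluations, start=1):
            e.rank = i

        stage = "combinations"
        top = [e.loci[0] for e in evaluations[:config.top_m]]
        combos = search_combinations(records, top, reference_tree, config)
    except PipelineError:
        raise
    except Exception as exc:  # annotate which stage failed
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    best_single = evaluations[0]
    best_combo = combos[0]
    report = PipelineReport(candidates=candidates, evaluations=evaluations,
                            combination_evaluations=combos,
                            best_single=best_single,
                            best_combination=best_combo,
                            reference_tree=reference_tree,
                            hotspots=hotspots, pi_ranking=pi_ranking)
    if out_dir:
        _persist(report, profile, out_dir)
    return report


def _persist(report: PipelineReport, profile, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    report.summary_frame().to_csv(os.path.join(out_dir, "marker_ranking.tsv"),
                                  sep="\t", index=False)
    profile.to_frame().to_csv(os.path.join(out_dir, "pi_profile.tsv"),
                              sep="\t", index=False)
    with open(os.path.join(out_dir, "reference_tree.nwk"), "w") as fh:
        fh.write(report.reference_tree.to_newick() + "\n")
    summary = {
        "best_single": list(report.best_single.loci),
        "best_single_distance": report.best_single.distance.normalized,
        "best_combination": list(report.best_combination.loci),
        "best_combination_distance":
            report.best_combination.distance.normalized,
        "candidates": report.candidates,
        "hotspots": [{"name": h.name, "peak_pi": h.peak_pi}
                     for h in report.hotspots],
        "pi_ranking": [{"locus": p.locus, "net_pi_area": p.summary}
                       for p in report.pi_ranking],
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
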