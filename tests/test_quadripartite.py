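import numpy as np
import pytest

import plastidkit as pk
from plastidkit.genbank_io import PlastomeRecord, revcomp
from plastidkit.quadripartite import (NoInvertedRepeatError, _reflect_feature,
                                      _rotate_feature, canonicalize,
                                      compare_junctions,
                                      detect_and_canonicalize,
                                      detect_quadripartite, junction_report,
                                      partition_to_bed)


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_constructed_genome_recovered_exactly(rng):
    lsc, ir, ssc = (_random_seq(rng, n) for n in (8500, 2500, 1800))
    genome = lsc + ir + ssc + revcomp(ir)
    rec = PlastomeRecord("c1", "s", genome)
    part = detect_quadripartite(rec)
    assert part.lengths == {"LSC": 8500, "IRb": 2500, "SSC": 1800,
                            "IRa": 2500}
    assert part.lsc == (0, 8500)
    assert part.ir_identity == 1.0
    assert sum(part.lengths.values()) == len(genome)


def test_no_inverted_repeat_raises(rng):
    rec = PlastomeRecord("r1", "s", _random_seq(rng, 50000))
    with pytest.raises(NoInvertedRepeatError):
        detect_quadripartite(rec, min_ir_len=1000)


def test_short_genome_rejected(rng):
    rec = PlastomeRecord("r2", "s", _random_seq(rng, 1500))
    with pytest.raises(NoInvertedRepeatError):
        detect_quadripartite(rec, min_ir_len=1000)


def _rotated(rec, shift):
    L = len(rec)
    return PlastomeRecord(rec.accession, rec.species,
                          rec.sequence[shift:] + rec.sequence[:shift],
                          rec.circular,
                          [_rotate_feature(f, shift, L) for f in rec.features])


def _reflected(rec):
    L = len(rec)
    return PlastomeRecord(rec.accession, rec.species, revcomp(rec.sequence),
                          rec.circular,
                          [_reflect_feature(f, L) for f in rec.features])


def test_canonicalization_invariances(markers_dataset, rng):
    records, _ = markers_dataset
    for rec in records[:4]:
        c1, p1 = detect_and_canonicalize(rec)
        shift = int(rng.integers(1, len(rec)))
        c2, p2 = detect_and_canonicalize(_rotated(rec, shift))
        assert c1.sequence == c2.sequence and p1 == p2
        c3, p3 = detect_and_canonicalize(_reflected(rec))
        assert c1.sequence == c3.sequence and p1 == p3
        assert [f.key() for f in c1.features] == [f.key() for f in c3.features]
        # idempotence
        c4, p4 = canonicalize(c1, p1)
        assert c4.sequence == c1.sequence and p4 == p1


def test_redetection_on_canonical_genome_is_stable(markers_dataset):
    records, truth = markers_dataset
    rec = records[0]
    c1, p1 = detect_and_canonicalize(rec)
    p_again = detect_quadripartite(c1)
    assert p_again == p1


def test_junction_report_boundary_and_spanning(paperlike_dataset):
    records, truth = paperlike_dataset
    rec = records[0]
    part = truth.partitions[rec.accession]
    rep = junction_report(rec, part)
    assert set(rep.entries) == {"JLB", "JSB", "JSA", "JLA"}
    for e in rep.entries.values():
        assert e.left_dist is None or e.left_dist >= 0
        assert e.right_dist is None or e.right_dist >= 0
        if e.spanning_gene:
            assert e.spanning_gene[1] > 0 and e.spanning_gene[2] > 0


def test_planted_spanning_gene_detected():
    # a JSA expansion cutting inside ycf1 leaves it spanning the SSC/IRa
    # border with the planted extension
    params = pk.default_params("markers", seed=5,
                               junction_shifts=[("sp01", "JSA", 400)])
    records, truth = pk.simulate_dataset(params)
    rec = next(r for r in records if r.species == "sp01")
    part = pk.detect_quadripartite(rec)
    assert part == truth.partitions[rec.accession]
    rep = junction_report(rec, part)
    span = rep.entries["JSA"].spanning_gene
    assert span is not None and span[0] == "ycf1"
    assert span[2] == 400  # bp extending into IRa


def test_gene_ending_exactly_at_junction():
    params = pk.default_params("markers", seed=6)
    records, truth = pk.simulate_dataset(params)
    rec = records[0]
    part = truth.partitions[rec.accession]
    # plant a gene ending exactly at JSB (the IRb/SSC junction, which no
    # template feature abuts): it is the nearest left gene at distance 0,
    # never a spanning gene
    from plastidkit.genbank_io import Feature
    jsb = part.ssc[0]
    feats = rec.features + [Feature("edge", "gene", "+", [(jsb - 50, jsb)])]
    rec2 = PlastomeRecord(rec.accession, rec.species, rec.sequence,
                          rec.circular, feats)
    rep = junction_report(rec2, part)
    e = rep.entries["JSB"]
    assert e.spanning_gene is None or e.spanning_gene[0] != "edge"
    assert e.left_gene == "edge" and e.left_dist == 0


def test_compare_junctions_flags_planted_shift():
    base = pk.default_params("markers", seed=9)
    params = pk.default_params(
        "markers", seed=9, junction_shifts=[("sp03", "JLB", 550)])
    records, truth = pk.simulate_dataset(params)
    reports = []
    for rec in records:
        part = pk.detect_quadripartite(rec)
        assert part == truth.partitions[rec.accession]
        reports.append(junction_report(rec, part))
    df = compare_junctions(reports)
    deltas = df.drop_duplicates("accession").set_index("accession")[
        "ir_delta_vs_median"]
    shifted = [a for a, sp in truth.accession_species.items() if sp == "sp03"]
    assert all(deltas[a] == 550 for a in shifted)
    assert (deltas.drop(shifted) == 0).all()
    # identical genomes give all-zero deltas
    clean, _ = pk.simulate_dataset(base)
    reps0 = [junction_report(r, pk.detect_quadripartite(r)) for r in clean]
    assert (compare_junctions(reps0)["ir_delta_vs_median"] == 0).all()


def test_bed_export_lines(markers_dataset):
    records, truth = markers_dataset
    rec = records[0]
    bed = partition_to_bed(truth.partitions[rec.accession], rec.accession)
    lines = [ln.split("\t") for ln in bed.strip().splitlines()]
    assert {ln[3] for ln in lines} == {"LSC", "IRb", "SSC", "IRa"}
    total = sum(int(ln[2]) - int(ln[1]) for ln in lines)
    assert total == len(rec)
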