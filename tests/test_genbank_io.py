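import pytest

import plastidkit as pk
from plastidkit.genbank_io import (Feature, LocusNotFoundError, PlastomeRecord,
                                   extract_locus, feature_counts,
                                   normalize_locus_name, parse_locus_request,
                                   read_plastome, revcomp, write_record)

MINIMAL_GB = """\
LOCUS       TEST0001                  10 bp    DNA     circular PLN 01-JAN-2024
DEFINITION  Minimal test record.
ACCESSION   TEST0001
SOURCE      test organism
FEATURES             Location/Qualifiers
     gene            3..5
                     /gene="abc"
ORIGIN
        1 acgtacgtac
//
"""


def test_genbank_coordinates_are_converted_to_zero_based(tmp_path):
    p = tmp_path / "m.gb"
    p.write_text(MINIMAL_GB)
    rec = read_plastome(p, format="genbank")
    assert len(rec) == 10
    assert rec.circular
    (feat,) = rec.features
    assert feat.name == "abc"
    assert feat.intervals == [(2, 5)]


def test_genbank_round_trip_preserves_record(tmp_path, markers_dataset):
    rec = markers_dataset[0][0]
    path = tmp_path / "sim.gb"
    write_record(rec, path, format="genbank")
    back = read_plastome(path, format="genbank")
    assert back.sequence == rec.sequence
    assert back.accession == rec.accession
    assert [f.key() for f in back.features] == [f.key() for f in rec.features]
    # second write is byte-identical (idempotence)
    path2 = tmp_path / "sim2.gb"
    write_record(back, path2, format="genbank")
    write_record(read_plastome(path2), tmp_path / "sim3.gb")
    assert (tmp_path / "sim2.gb").read_text() == \
        (tmp_path / "sim3.gb").read_text()


def test_fasta_round_trip(tmp_path, markers_dataset):
    rec = markers_dataset[0][0]
    path = tmp_path / "sim.fasta"
    write_record(rec, path, format="fasta")
    back = read_plastome(path, format="fasta")
    assert back.sequence == rec.sequence
    assert back.features == []


def test_origin_spanning_join_round_trips(tmp_path):
    rec = PlastomeRecord(
        accession="ORI1", species="test", sequence="ACGTACGTACGTACGTACGT",
        features=[Feature("wrap", "gene", "+", [(15, 20), (0, 4)])])
    path = tmp_path / "ori.gb"
    write_record(rec, path)
    text = path.read_text()
    assert "join(" in text
    back = read_plastome(path)
    assert [f.key() for f in back.features] == [f.key() for f in rec.features]


def test_empty_or_malformed_input_errors(tmp_path):
    bad = tmp_path / "bad.gb"
    bad.write_text("not a genbank file\n")
    with pytest.raises(pk.PlastidKitError):
        read_plastome(bad)
    with pytest.raises(ValueError):
        PlastomeRecord(accession="x", species="s", sequence="")


def test_feature_counts_categories_and_additivity():
    rec = PlastomeRecord(accession="x", species="s", sequence="A" * 1000)
    assert feature_counts(rec) == {"genes": 0, "CDS": 0, "tRNA": 0,
                                   "rRNA": 0, "pseudogenes": 0}
    # four rRNAs present twice (one copy in each IR) -> count 8
    feats = []
    for copy in range(2):
        for i, name in enumerate(["rrn4.5", "rrn5", "rrn16", "rrn23"]):
            s = copy * 400 + i * 50
            feats.extend([Feature(name, "gene", "+", [(s, s + 40)]),
                          Feature(name, "rRNA", "+", [(s, s + 40)])])
    feats.append(Feature("rps16", "pseudogene", "+", [(900, 950)]))
    rec2 = PlastomeRecord(accession="y", species="s", sequence="A" * 1000,
                          features=feats)
    c = feature_counts(rec2)
    assert c["rRNA"] == 8
    assert c["genes"] == 9  # 8 rRNA gene features + 1 pseudogene
    assert c["pseudogenes"] == 1 and c["CDS"] == 1
    # additivity over disjoint feature lists
    half1 = PlastomeRecord("a", "s", "A" * 1000, features=feats[:8])
    half2 = PlastomeRecord("b", "s", "A" * 1000, features=feats[8:])
    whole = feature_counts(rec2)
    for k in whole:
        assert whole[k] == feature_counts(half1)[k] + feature_counts(half2)[k]


def test_locus_name_normalization():
    assert normalize_locus_name("trnH-GUG") == normalize_locus_name("trnH")
    assert normalize_locus_name("RpoB") == normalize_locus_name("rpob")
    assert normalize_locus_name("ycf1") != normalize_locus_name("ycf2")


def test_extract_locus_feature_mode(markers_dataset):
    records, _ = markers_dataset
    m = extract_locus(records, "rpoB")
    assert set(m.rows) == {r.accession for r in records}
    assert m.dropped == []
    # strand orientation: minus-strand loci come back reverse-complemented
    rec = records[0]
    feat = next(f for f in rec.features
                if f.name == "matK" and f.kind == "CDS")
    assert feat.strand == "-"
    seq = extract_locus([rec], "matK").rows[rec.accession]
    s, e = feat.intervals[0]
    assert revcomp(seq) == rec.sequence[s:e]


def test_extract_locus_missing_accession_reported(markers_dataset):
    records, _ = markers_dataset
    partial = [records[0]]
    stripped = PlastomeRecord(
        accession=records[1].accession, species=records[1].species,
        sequence=records[1].sequence,
        features=[f for f in records[1].features
                  if normalize_locus_name(f.name) != "rps19"])
    m = extract_locus(partial + [stripped], "rps19")
    assert m.dropped == [stripped.accession]
    assert set(m.rows) == {records[0].accession}
    with pytest.raises(LocusNotFoundError):
        extract_locus(partial, "nonexistent-gene")


def test_extract_locus_intergenic_mode(markers_dataset):
    records, _ = markers_dataset
    rec = records[0]
    m = extract_locus([rec], "trnK-trnQ", region="auto")
    seq = m.rows[rec.accession]
    trnk = next(f for f in rec.features if f.name == "trnK")
    trnq = next(f for f in rec.features if f.name == "trnQ")
    assert seq == rec.sequence[trnk.end:trnq.start]
    # multi-gene region label falls back to the outermost flanks
    mode, args = parse_locus_request("atpA-rpoB-rpoC1", [rec])
    assert mode == "intergenic" and args == ("atpA", "rpoC1")
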