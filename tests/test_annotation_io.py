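import io

import pytest

from rpclustermap import annotation_io as aio
from rpclustermap import build_from_template, map_cluster
from rpclustermap.exceptions import FormatError, InputError

FT_HEADER = (
    "# feature\tclass\tassembly\tgenomic_accession\tstart\tend\tstrand"
    "\tproduct_accession\tname\tsymbol\tGeneID\tlocus_tag"
    "\tfeature_interval_length\tproduct_length\tattributes\n"
)


def ft(rows):
    return FT_HEADER + "".join("\t".join(r) + "\n" for r in rows)


def test_read_feature_table_basic():
    text = ft(
        [
            ["CDS", "with_protein", "", "c1", "100", "399", "+", "",
             "50S ribosomal protein L22", "", "", "g1", "300", "99", ""],
            ["CDS", "with_protein", "", "c1", "500", "799", "-", "",
             "hypothetical protein", "", "", "g2", "300", "99", ""],
            ["tRNA", "tRNA", "", "c1", "900", "984", "+", "", "tRNA-Leu", "",
             "", "g3", "85", "", ""],
        ]
    )
    ann = aio.read_feature_table(io.StringIO(text), genome_id="g")
    recs = list(ann.all_genes())
    assert len(recs) == 3
    assert recs[0].product == "50S ribosomal protein L22"
    assert recs[1].strand == "-"
    assert recs[2].feature_type == "tRNA"


def test_feature_table_pseudo_attribute():
    text = ft(
        [
            ["gene", "protein_coding", "", "c1", "10", "309", "+", "",
             "50S ribosomal protein L18", "", "", "g1", "300", "", "pseudo"],
        ]
    )
    ann = aio.read_feature_table(io.StringIO(text))
    (rec,) = ann.all_genes()
    assert rec.pseudo and rec.feature_type == "CDS"


def test_feature_table_errors():
    with pytest.raises(FormatError, match="genomic_accession"):
        aio.read_feature_table(io.StringIO("# feature\tstart\tend\n"))
    bad = ft(
        [["CDS", "with_protein", "", "c1", "500", "100", "+", "", "x", "", "",
          "g1", "", "", ""]]
    )
    with pytest.raises(FormatError, match="start"):
        aio.read_feature_table(io.StringIO(bad))


GFF = """##gff-version 3
##sequence-region c1 1 2000
c1\tsrc\tCDS\t100\t399\t.\t+\t0\tID=g1;locus_tag=g1;product=50S ribosomal protein L22
"""


def test_read_gff3_minimal():
    ann = aio.read_gff3(io.StringIO(GFF), genome_id="g")
    (rec,) = ann.all_genes()
    assert (rec.start, rec.end, rec.strand) == (100, 399, "+")
    assert not rec.contig_edge
    assert ann.contig_length("c1") == 2000


def test_gff3_contig_edge_and_partial():
    text = (
        "##gff-version 3\n##sequence-region c1 1 600\n"
        "c1\ts\tCDS\t1\t300\t.\t+\t0\tID=a;locus_tag=a;product=x;partial=true\n"
        "c1\ts\tCDS\t400\t600\t.\t+\t0\tID=b;locus_tag=b;product=y\n"
    )
    ann = aio.read_gff3(io.StringIO(text))
    a, b = ann.all_genes()
    assert a.partial and a.contig_edge  # touches base 1
    assert b.contig_edge and not b.partial  # ends at contig length


def test_gff3_malformed_column_count():
    with pytest.raises(FormatError, match="line 2"):
        aio.read_gff3(io.StringIO("##gff-version 3\nc1\tonly\tthree\n"))


def test_genbank_qualifiers(make_annotation):
    ann, _ = build_from_template("thor_hsp20", 5)
    out = io.StringIO()
    aio.write_genbank(ann, out)
    back = aio.read_genbank(io.StringIO(out.getvalue()), genome_id=ann.genome_id)
    orig = {r.locus_tag: r for r in ann.all_genes()}
    for rec in back.all_genes():
        assert rec.pseudo == orig[rec.locus_tag].pseudo
        if not rec.pseudo and rec.feature_type == "CDS":
            assert rec.protein_seq == orig[rec.locus_tag].protein_seq


def test_genbank_fuzzy_location_is_partial_edge():
    gb = io.StringIO()
    ann, _ = build_from_template("asgard_core", 2)
    first = next(iter(ann.all_genes()))
    first.partial = True  # starts at base 1 -> fuzzy "<" on write
    aio.write_genbank(ann, gb)
    assert "<1" in gb.getvalue()
    back = aio.read_genbank(io.StringIO(gb.getvalue()))
    rec = next(iter(back.all_genes()))
    assert rec.partial and rec.contig_edge


def test_genbank_without_locus_line():
    with pytest.raises(FormatError, match="LOCUS"):
        aio.read_genbank(io.StringIO("not a genbank file\n"))


@pytest.mark.parametrize("template", ["thor_hsp20", "pr6_strand_mix", "ar10"])
def test_format_equivalence(template):
    """The same genome in all three formats parses to the same annotation."""
    ann, _ = build_from_template(template, 7)
    streams = {}
    for name, writer in (
        ("gff3", aio.write_gff3),
        ("feature_table", aio.write_feature_table),
        ("genbank", aio.write_genbank),
    ):
        buf = io.StringIO()
        writer(ann, buf)
        streams[name] = buf.getvalue()

    def essence(a):
        return [
            (r.contig_id, r.start, r.end, r.strand, r.locus_tag, r.product,
             r.pseudo, r.partial, r.contig_edge, r.feature_type)
            for r in a.all_genes()
        ]

    parsed = {
        "gff3": aio.read_gff3(io.StringIO(streams["gff3"]), genome_id=ann.genome_id),
        "feature_table": aio.read_feature_table(
            io.StringIO(streams["feature_table"]), genome_id=ann.genome_id
        ),
        "genbank": aio.read_genbank(
            io.StringIO(streams["genbank"]), genome_id=ann.genome_id
        ),
    }
    assert essence(parsed["gff3"]) == essence(ann)
    assert essence(parsed["feature_table"]) == essence(ann)
    assert essence(parsed["genbank"]) == essence(ann)


def test_annotation_json_round_trip():
    ann, _ = build_from_template("bin6_split", 11)
    buf = io.StringIO()
    aio.write_annotation_json(ann, buf)
    back = aio.read_annotation_json(io.StringIO(buf.getvalue()))
    assert aio.annotation_to_dict(back) == aio.annotation_to_dict(ann)


def test_duplicate_locus_tags_suffixed(caplog):
    text = ft(
        [
            ["CDS", "with_protein", "", "c1", "10", "309", "+", "", "x", "", "",
             "dup", "", "", ""],
            ["CDS", "with_protein", "", "c1", "400", "699", "+", "", "y", "", "",
             "dup", "", "", ""],
        ]
    )
    ann = aio.read_feature_table(io.StringIO(text))
    tags = [r.locus_tag for r in ann.all_genes()]
    assert tags == ["dup", "dup_2"]


def test_occurrence_report_tsv_and_json(registry):
    ann, _ = build_from_template("bin6_split", 1)
    occ = map_cluster(ann, registry.get_cluster_model("S10-spc-core", "archaeal"))
    tsv = io.StringIO()
    aio.write_occurrence_report([occ], tsv, "tsv")
    lines = tsv.getvalue().splitlines()
    assert lines[0].split("\t") == list(aio._REPORT_COLUMNS)
    row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
    assert row["status"] == "split" and row["n_segments"] == "3"

    # absent cluster -> empty segment list
    empty, _ = build_from_template("asgard_core", 1)
    occ_absent = map_cluster(
        empty, registry.get_cluster_model("L7ae", "archaeal")
    )
    tsv2 = io.StringIO()
    aio.write_occurrence_report([occ_absent], tsv2, "tsv")
    row2 = dict(
        zip(tsv2.getvalue().splitlines()[0].split("\t"),
            tsv2.getvalue().splitlines()[1].split("\t"))
    )
    assert row2["status"] == "absent" and row2["segment"] == ""

    js = io.StringIO()
    aio.write_occurrence_report([occ], js, "json")
    import json

    assert json.loads(js.getvalue())[0] == occ.to_dict()

    # identical input -> byte-identical output
    tsv3 = io.StringIO()
    aio.write_occurrence_report([occ], tsv3, "tsv")
    assert tsv3.getvalue() == tsv.getvalue()

    with pytest.raises(InputError, match="format"):
        aio.write_occurrence_report([occ], io.StringIO(), "xml")
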