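import io
import json
from importlib import resources

import numpy as np
import pytest

from rpclustermap import (
    SyntheticSpec,
    build_from_template,
    generate,
    generate_protein_seq,
    perturb,
    random_spec,
    template_names,
)
from rpclustermap.annotation_io import read_gff3, write_gff3, write_protein_fasta
from rpclustermap.exceptions import TemplateError
from rpclustermap.synthetic_genomes import (
    _filler_pool,
    template_token_count,
    typical_protein_length,
)
from rpclustermap.annotation_rescue import local_align


def test_unknown_template_lists_available():
    with pytest.raises(TemplateError, match="asgard_core"):
        build_from_template("no-such-template", 0)


def test_ar10_gene_count_matches_token_count_oracle():
    """The generated gene count equals an independent token count over the
    transcribed template document."""
    doc = json.loads(
        resources.files("rpclustermap.data").joinpath("templates.json").read_text()
    )
    expected = sum(
        item["fillers"] if "fillers" in item else len(item["block"])
        for contig in doc["ar10"]["contigs"]
        for item in contig
    )
    ann, _ = build_from_template("ar10", 123)
    assert ann.n_genes() == expected == template_token_count("ar10")


@pytest.mark.parametrize("template", sorted(template_names()))
def test_build_is_deterministic(template):
    a1, t1 = build_from_template(template, 1)
    a2, t2 = build_from_template(template, 1)
    buf1, buf2 = io.StringIO(), io.StringIO()
    write_gff3(a1, buf1)
    write_gff3(a2, buf2)
    assert buf1.getvalue() == buf2.getvalue()
    f1, f2 = io.StringIO(), io.StringIO()
    write_protein_fasta(a1, f1)
    write_protein_fasta(a2, f2)
    assert f1.getvalue() == f2.getvalue()
    assert t1.to_dict() == t2.to_dict()


def test_bin6_truth_plants_three_segments():
    _ann, truth = build_from_template("bin6_split", 7)
    expected = truth.models["S10-spc-core"]
    assert expected.n_segments == 3 and expected.status == "split"
    assert expected.segment_sizes == (10, 2, 6)


def test_protein_seq_determinism_and_distinctness():
    assert generate_protein_seq("uL22", 0, 0.0) == generate_protein_seq("uL22", 0, 0.0)
    assert generate_protein_seq("uL22", 0, 0.0) != generate_protein_seq("uS3", 0, 0.0)
    assert len(generate_protein_seq("uL22", 0)) == typical_protein_length("uL22")
    assert 60 <= typical_protein_length("uL22") <= 250


def test_mutation_rate_matches_hamming_oracle():
    base = generate_protein_seq("uL22", 0, 0.0)
    rates = []
    for seed in range(20):
        mutated = generate_protein_seq("uL22", seed, 0.1)
        assert len(mutated) == len(base)
        rates.append(sum(a != b for a, b in zip(base, mutated)) / len(base))
    mean = np.mean(rates)
    # binomial: sd of the mean over 20 x L trials is well under 0.01
    assert abs(mean - 0.1) < 0.03


def test_relabel_perturbation_recorded_in_truth():
    spec = SyntheticSpec(
        template="asgard_core",
        seed=4,
        perturbations=(
            {"op": "relabel_hp", "genes": ["uS3", "RNP1", "uL24", "uS14", "L32e", "uL15"]},
        ),
    )
    _ann, truth = generate(spec)
    assert sorted(truth.rescuable.values()) == sorted(
        ["L32e", "RNP1", "uL15", "uL24", "uS14", "uS3"]
    )
    assert truth.models["S10-spc-core"].status == "complete_contiguous"


def test_delete_moves_genes_to_missing():
    spec = SyntheticSpec(
        template="ar10",
        seed=4,
        perturbations=({"op": "delete", "genes": ["uL3", "uL4", "uL23"]},),
    )
    _ann, truth = generate(spec)
    assert truth.models["small-S10"].missing == {"uL3", "uL4", "uL23"}


def test_split_at_increases_segments():
    _base, truth0 = build_from_template("asgard_core", 2)
    spec = SyntheticSpec(
        template="asgard_core",
        seed=2,
        perturbations=({"op": "split_at", "position": 10, "distance": 5},),
    )
    _ann, truth = generate(spec)
    assert (
        truth.models["S10-spc-core"].n_segments
        == truth0.models["S10-spc-core"].n_segments + 1
    )
    assert truth.models["S10-spc-core"].status == "split"


def test_fragment_contigs_marks_edges():
    spec = SyntheticSpec(
        template="ar10", seed=3, perturbations=({"op": "fragment_contigs", "k": 12},)
    )
    ann, _truth = generate(spec)
    assert len(ann.contigs) == 12
    assert not ann.complete
    for cid, _len in ann.contigs:
        row = ann.genes[cid]
        assert row[0].contig_edge and row[-1].contig_edge


def test_invert_flips_block_strands():
    spec = SyntheticSpec(
        template="asgard_core",
        seed=2,
        perturbations=({"op": "invert", "start": 3, "end": 21},),
    )
    ann, truth = generate(spec)
    strands = {r.strand for r in list(ann.all_genes())[3:22]}
    assert strands == {"-"}
    assert truth.models["S10-spc-core"].status == "complete_contiguous"


def test_perturbation_referencing_absent_gene_fails():
    ann, truth = build_from_template("asgard_core", 1)
    spec = SyntheticSpec(
        template="asgard_core",
        seed=1,
        perturbations=({"op": "mark_pseudo", "gene": "rpoB"},),
    )
    with pytest.raises(TemplateError, match="rpoB"):
        perturb(ann, truth, spec)


def test_same_spec_same_bytes():
    spec = random_spec("thor_hsp20", 99)
    out = []
    for _ in range(2):
        ann, truth = generate(spec)
        buf = io.StringIO()
        write_gff3(ann, buf)
        out.append((buf.getvalue(), json.dumps(truth.to_dict(), sort_keys=True)))
    assert out[0] == out[1]


def test_emitted_gff_reread_without_loss():
    ann, _ = build_from_template("pr6_strand_mix", 6)
    buf = io.StringIO()
    write_gff3(ann, buf)
    back = read_gff3(io.StringIO(buf.getvalue()), genome_id=ann.genome_id)
    assert [r.locus_tag for r in back.all_genes()] == [
        r.locus_tag for r in ann.all_genes()
    ]
    assert [r.strand for r in back.all_genes()] == [r.strand for r in ann.all_genes()]


def test_filler_pool_stays_below_rescue_margin(panel):
    pool = _filler_pool()
    assert len(pool) == 64
    rng = np.random.default_rng(0)
    refs = [seq for g in panel.genes for seq, _ in panel.entries[g]]
    for cand in rng.choice(np.array(pool, dtype=object), size=5, replace=False):
        for ref in rng.choice(np.array(refs, dtype=object), size=10, replace=False):
            res = local_align(str(cand), str(ref))
            assert not (res.identity >= 0.30 and res.coverage >= 0.50)
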