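import pytest

from rpclustermap import build_reference_panel, load_registry
from rpclustermap.annotation_io import GeneRecord, GenomeAnnotation


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def panel():
    return build_reference_panel()


@pytest.fixture
def make_annotation(registry):
    """Factory: build a one-contig annotation from a list of gene names.

    ``None`` entries become hypothetical-protein filler records; strands
    default to '+'.
    """

    def _make(names, strands=None, genome_id="toy", contig_id="ctg1"):
        strands = strands or ["+"] * len(names)
        records = []
        pos = 1
        for i, (name, strand) in enumerate(zip(names, strands)):
            product = (
                "hypothetical protein" if name is None else registry.product_of(name)
            )
            records.append(
                GeneRecord(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    start=pos,
                    end=pos + 299,
                    strand=strand,
                    locus_tag=f"{genome_id}_{i + 1:04d}",
                    product=product,
                )
            )
            pos += 340
        length = records[-1].end if records else 1
        return GenomeAnnotation(
            genome_id=genome_id,
            contigs=((contig_id, length),),
            genes={contig_id: records},
            complete=True,
        )

    return _make
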