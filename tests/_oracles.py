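"""Independent oracles used by the test suite.

These deliberately re-derive expected results through routes that share no
code with the implementation under test: Biopython's PairwiseAligner for
local-alignment scores, exhaustive partition enumeration for segment
grouping, and a coordinate-flipping helper for reverse-complement symmetry.
"""

from __future__ import annotations

from itertools import combinations

from Bio import Align
from Bio.Align import substitution_matrices

from rpclustermap.annotation_io import GeneRecord, GenomeAnnotation


def biopython_local_score(query: str, reference: str) -> int:
    """Optimal local-alignment score under BLOSUM62, gap cost 11 + (k-1)*1."""
    aligner = Align.PairwiseAligner(
        mode="local", open_gap_score=-11, extend_gap_score=-1
    )
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return int(aligner.score(query, reference))


def enumerate_segments(
    names: list, members: set, accessory: set, gap_tolerance: int
) -> list[list[int]]:
    """Unique valid-and-maximal grouping of member hits, by full enumeration.

    Tries every way to split the ordered hit list into consecutive groups and
    returns the single partition in which every within-group neighbour pair is
    within the gap budget and no two adjacent groups could be merged.
    """
    hits = [i for i, n in enumerate(names) if n in members]
    if not hits:
        return []

    def gap(a: int, b: int) -> int:
        return sum(
            1 for n in names[a + 1 : b] if n not in members and n not in accessory
        )

    valid = []
    k = len(hits)
    for nsplit in range(k):
        for cuts in combinations(range(1, k), nsplit):
            bounds = [0, *cuts, k]
            groups = [hits[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
            if any(
                gap(g[i], g[i + 1]) > gap_tolerance
                for g in groups
                for i in range(len(g) - 1)
            ):
                continue
            if any(
                gap(groups[i][-1], groups[i + 1][0]) <= gap_tolerance
                for i in range(len(groups) - 1)
            ):
                continue
            valid.append(groups)
    assert len(valid) == 1, f"expected a unique maximal partition, got {len(valid)}"
    return valid[0]


def flip_genome(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Reverse-complement every contig: order reversed, strands flipped."""
    genes = {}
    for cid, length in ann.contigs:
        flipped = []
        for rec in reversed(ann.genes.get(cid, [])):
            flipped.append(
                GeneRecord(
                    genome_id=rec.genome_id,
                    contig_id=cid,
                    start=length - rec.end + 1,
                    end=length - rec.start + 1,
                    strand="-" if rec.strand == "+" else "+",
                    locus_tag=rec.locus_tag,
                    symbol=rec.symbol,
                    product=rec.product,
                    pseudo=rec.pseudo,
                    partial=rec.partial,
                    contig_edge=rec.contig_edge,
                    protein_seq=rec.protein_seq,
                    feature_type=rec.feature_type,
                )
            )
        genes[cid] = flipped
    return GenomeAnnotation(
        genome_id=ann.genome_id,
        contigs=ann.contigs,
        genes=genes,
        complete=ann.complete,
    )
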