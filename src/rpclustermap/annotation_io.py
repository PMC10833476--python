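"""Read genome annotations (NCBI feature table, GFF3, GenBank) and write reports.

All coordinates are 1-based inclusive in every format this module touches, so
records pass through unchanged.  Orientation lives exclusively in the strand
field; ``start <= end`` always holds.  A gene's position within its contig
("gene order index") is simply its index in the per-contig, start-sorted list.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Union

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    ExactPosition,
    FeatureLocation,
    SeqFeature,
)
from Bio.SeqRecord import SeqRecord

from .exceptions import FormatError, InputError

logger = logging.getLogger(__name__)

Stream = Union[str, IO[str]]

_FT_MANDATORY = ("feature", "genomic_accession", "start", "end", "strand", "locus_tag")


@dataclass
class GeneRecord:
    """One annotated feature (CDS, pseudogene row, or structural RNA)."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    symbol: str = ""
    product: str = ""
    pseudo: bool = False
    partial: bool = False
    contig_edge: bool = False
    protein_seq: Optional[str] = None
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"{self.locus_tag or '<feature>'}: invalid span "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.locus_tag}: invalid strand {self.strand!r}")

    @property
    def aa_length(self) -> Optional[int]:
        return len(self.protein_seq) if self.protein_seq else None


@dataclass
class GenomeAnnotation:
    """All features of one genome, per contig, sorted by start coordinate."""

    genome_id: str
    contigs: tuple[tuple[str, int], ...]  # (contig_id, length), input order
    genes: dict[str, list[GeneRecord]]
    complete: bool = False

    def __post_init__(self) -> None:
        for contig_id, records in self.genes.items():
            records.sort(key=lambda r: (r.start, r.end, r.locus_tag))
        if self.complete and len(self.contigs) != 1:
            raise InputError(
                f"{self.genome_id}: complete genome must be a single contig"
            )

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.contigs)

    def contig_length(self, contig_id: str) -> int:
        for cid, length in self.contigs:
            if cid == contig_id:
                return length
        raise InputError(f"unknown contig {contig_id!r}")

    def all_genes(self) -> Iterable[GeneRecord]:
        for cid, _ in self.contigs:
            yield from self.genes.get(cid, [])

    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def record_by_locus(self, locus_tag: str) -> GeneRecord:
        for rec in self.all_genes():
            if rec.locus_tag == locus_tag:
                return rec
        raise InputError(f"unknown locus_tag {locus_tag!r}")


# ---------------------------------------------------------------------------
# shared assembly helpers
# ---------------------------------------------------------------------------


def _as_text(stream: Stream) -> str:
    if isinstance(stream, str):
        with open(stream, encoding="utf-8") as fh:
            return fh.read()
    return stream.read()


def _dedupe_locus_tags(records: list[GeneRecord]) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        n = seen.get(rec.locus_tag, 0) + 1
        seen[rec.locus_tag] = n
        if n > 1:
            new = f"{rec.locus_tag}_{n}"
            logger.warning("duplicate locus_tag %s renamed to %s", rec.locus_tag, new)
            rec.locus_tag = new


def _assemble(
    genome_id: str,
    records: list[GeneRecord],
    contig_lengths: dict[str, int],
    contig_order: list[str],
    complete: Optional[bool] = None,
) -> GenomeAnnotation:
    _dedupe_locus_tags(records)
    genes: dict[str, list[GeneRecord]] = {cid: [] for cid in contig_order}
    for rec in records:
        genes.setdefault(rec.contig_id, []).append(rec)
        if rec.contig_id not in contig_order:
            contig_order.append(rec.contig_id)
    contigs = tuple(
        (cid, contig_lengths.get(cid) or max((r.end for r in genes[cid]), default=1))
        for cid in contig_order
    )
    ann = GenomeAnnotation(
        genome_id=genome_id,
        contigs=contigs,
        genes=genes,
        complete=len(contigs) == 1 if complete is None else complete,
    )
    _apply_edge_flags(ann)
    return ann


def _apply_edge_flags(ann: GenomeAnnotation) -> None:
    # a feature is at a contig edge if its span touches base 1 or the final
    # base of its contig (fuzzy-boundary flags are set by the readers).
    for cid, length in ann.contigs:
        for rec in ann.genes.get(cid, []):
            if rec.start == 1 or rec.end >= length:
                rec.contig_edge = True


# ---------------------------------------------------------------------------
# NCBI assembly feature table
# ---------------------------------------------------------------------------


def read_feature_table(
    stream: Stream, genome_id: Optional[str] = None, include_non_cds: bool = True
) -> GenomeAnnotation:
    """Parse the tab-delimited NCBI assembly feature-table dialect.

    Columns are located by name from the ``# feature`` header row, never by
    position.  One :class:`GeneRecord` is produced per CDS row (and per
    pseudogene row that has no CDS); plain gene rows are merged into their CDS
    by locus_tag.
    """
    text = _as_text(stream)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].lstrip("#").strip().startswith("feature"):
        raise FormatError("feature table must start with a '# feature' header row")
    header = [c.strip() for c in lines[0].lstrip("# ").split("\t")]
    colidx = {name: i for i, name in enumerate(header)}
    for col in _FT_MANDATORY:
        if col not in colidx:
            raise FormatError(f"feature table is missing mandatory column {col!r}")

    def get(row: list[str], col: str) -> str:
        i = colidx.get(col)
        return row[i].strip() if i is not None and i < len(row) else ""

    cds_rows: list[GeneRecord] = []
    gene_rows: dict[str, dict] = {}
    gid = genome_id or "genome"
    contig_order: list[str] = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            continue
        row = ln.split("\t")
        feature = get(row, "feature")
        contig = get(row, "genomic_accession")
        if contig and contig not in contig_order:
            contig_order.append(contig)
        try:
            start, end = int(get(row, "start")), int(get(row, "end"))
        except ValueError as exc:
            raise FormatError(f"non-numeric coordinates in row: {ln!r}") from exc
        attributes = get(row, "attributes")
        common = dict(
            genome_id=gid,
            contig_id=contig,
            start=start,
            end=end,
            strand=get(row, "strand"),
            locus_tag=get(row, "locus_tag"),
            symbol=get(row, "symbol"),
            product=get(row, "name"),
            pseudo="pseudo" in attributes,
            partial="partial" in attributes,
        )
        if feature == "CDS":
            cds_rows.append(GeneRecord(**common, feature_type="CDS"))
        elif feature == "gene":
            gene_rows[common["locus_tag"]] = common
        elif include_non_cds and feature in ("tRNA", "rRNA", "ncRNA", "tmRNA"):
            cds_rows.append(GeneRecord(**common, feature_type=feature))

    covered = {r.locus_tag for r in cds_rows}
    for locus, common in gene_rows.items():
        if locus in covered:
            for rec in cds_rows:
                if rec.locus_tag == locus:
                    rec.pseudo = rec.pseudo or common["pseudo"]
                    rec.partial = rec.partial or common["partial"]
                    rec.symbol = rec.symbol or common["symbol"]
        else:
            # pseudogene rows are deposited as bare gene rows; keep them as
            # coding features so cluster occupancy still counts them.
            cds_rows.append(GeneRecord(**common, feature_type="CDS"))

    return _assemble(gid, cds_rows, {}, contig_order)


def write_feature_table(ann: GenomeAnnotation, stream: IO[str]) -> None:
    cols = [
        "feature", "class", "assembly", "genomic_accession", "start", "end",
        "strand", "product_accession", "name", "symbol", "GeneID", "locus_tag",
        "feature_interval_length", "product_length", "attributes",
    ]
    stream.write("# " + "\t".join(cols) + "\n")
    for rec in ann.all_genes():
        attrs = []
        if rec.pseudo:
            attrs.append("pseudo")
        if rec.partial:
            attrs.append("partial")
        if rec.pseudo and rec.feature_type == "CDS":
            feature, klass = "gene", "protein_coding"
        elif rec.feature_type == "CDS":
            feature, klass = "CDS", "with_protein"
        else:
            feature, klass = rec.feature_type, rec.feature_type
        aa = rec.aa_length
        row = [
            feature, klass, "", rec.contig_id, str(rec.start), str(rec.end),
            rec.strand, "", rec.product, rec.symbol, "", rec.locus_tag,
            str(rec.end - rec.start + 1), str(aa) if aa else "",
            ";".join(attrs),
        ]
        stream.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(
    stream: Stream, genome_id: Optional[str] = None, include_non_cds: bool = True
) -> GenomeAnnotation:
    text = _as_text(stream)
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln or ln.startswith("#"):
            continue
        if len(ln.split("\t")) != 9:
            raise FormatError(f"GFF3 line {lineno}: expected 9 tab-separated columns")

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    contig_lengths: dict[str, int] = {}
    contig_order: list[str] = []
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            contig_lengths[parts[1]] = int(parts[3])
            contig_order.append(parts[1])

    gid = genome_id or "genome"
    wanted = {"CDS"} | ({"tRNA", "rRNA", "ncRNA", "tmRNA"} if include_non_cds else set())
    records: list[GeneRecord] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in wanted:
            continue
        attr = {k: v[0] for k, v in feat.attributes.items() if v}
        records.append(
            GeneRecord(
                genome_id=gid,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                locus_tag=attr.get("locus_tag", attr.get("ID", "")),
                symbol=attr.get("gene", ""),
                product=attr.get("product", ""),
                pseudo=attr.get("pseudo", "").lower() == "true",
                partial=attr.get("partial", "").lower() == "true",
                feature_type=feat.featuretype,
            )
        )
    return _assemble(gid, records, contig_lengths, contig_order)


def write_gff3(ann: GenomeAnnotation, stream: IO[str]) -> None:
    stream.write("##gff-version 3\n")
    for cid, length in ann.contigs:
        stream.write(f"##sequence-region {cid} 1 {length}\n")
    for rec in ann.all_genes():
        attrs = [f"ID={rec.locus_tag}", f"locus_tag={rec.locus_tag}"]
        if rec.symbol:
            attrs.append(f"gene={rec.symbol}")
        if rec.product:
            attrs.append(f"product={rec.product}")
        if rec.pseudo:
            attrs.append("pseudo=true")
        if rec.partial:
            attrs.append("partial=true")
        stream.write(
            "\t".join(
                [
                    rec.contig_id, "rpclustermap", rec.feature_type,
                    str(rec.start), str(rec.end), ".", rec.strand, "0",
                    ";".join(attrs),
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------


def read_genbank(stream: Stream, genome_id: Optional[str] = None) -> GenomeAnnotation:
    text = _as_text(stream)
    if "LOCUS" not in text.split("\n", 1)[0] and not text.lstrip().startswith("LOCUS"):
        raise FormatError("GenBank input has no LOCUS line")
    handle = io.StringIO(text)
    records: list[GeneRecord] = []
    contig_lengths: dict[str, int] = {}
    contig_order: list[str] = []
    gid = genome_id
    for seqrec in SeqIO.parse(handle, "genbank"):
        if gid is None:
            gid = seqrec.id
        contig_lengths[seqrec.id] = len(seqrec.seq)
        contig_order.append(seqrec.id)
        for feat in seqrec.features:
            if feat.type not in ("CDS", "tRNA", "rRNA", "ncRNA", "tmRNA"):
                continue
            quals = feat.qualifiers
            loc = feat.location
            fuzzy = isinstance(loc.start, BeforePosition) or isinstance(
                loc.end, AfterPosition
            )
            note = ";".join(quals.get("note", []))
            rec = GeneRecord(
                genome_id=gid,
                contig_id=seqrec.id,
                start=int(loc.start) + 1,
                end=int(loc.end),
                strand="-" if loc.strand == -1 else "+",
                locus_tag=quals.get("locus_tag", [""])[0],
                symbol=quals.get("gene", [""])[0],
                product=quals.get("product", [""])[0],
                pseudo="pseudo" in quals or "pseudogene" in quals,
                partial=fuzzy or "partial" in note,
                contig_edge=fuzzy,
                protein_seq=quals.get("translation", [None])[0],
                feature_type=feat.type,
            )
            records.append(rec)
    if gid is None:
        raise FormatError("GenBank input contains no records")
    return _assemble(gid, records, contig_lengths, contig_order)


def write_genbank(ann: GenomeAnnotation, stream: IO[str]) -> None:
    seqrecs = []
    for cid, length in ann.contigs:
        seqrec = SeqRecord(
            Seq("N" * length),
            id=cid,
            name=cid[:16].replace("|", "_"),
            description=f"{ann.genome_id} synthetic annotation",
            annotations={"molecule_type": "DNA"},
        )
        for rec in ann.genes.get(cid, []):
            start = ExactPosition(rec.start - 1)
            end = ExactPosition(rec.end)
            note = []
            if rec.partial:
                # fuzzy boundaries imply a contig edge on re-read, so use them
                # only when the gene really touches one; otherwise annotate.
                if rec.start == 1:
                    start = BeforePosition(rec.start - 1)
                elif rec.end >= length:
                    end = AfterPosition(rec.end)
                else:
                    note.append("partial")
            quals: dict[str, list[str]] = {"locus_tag": [rec.locus_tag]}
            if rec.symbol:
                quals["gene"] = [rec.symbol]
            if rec.product:
                quals["product"] = [rec.product]
            if rec.pseudo:
                quals["pseudo"] = [""]
            elif rec.protein_seq and rec.feature_type == "CDS":
                quals["translation"] = [rec.protein_seq]
            if note:
                quals["note"] = note
            seqrec.features.append(
                SeqFeature(
                    FeatureLocation(start, end, strand=-1 if rec.strand == "-" else 1),
                    type=rec.feature_type,
                    qualifiers=quals,
                )
            )
        seqrecs.append(seqrec)
    SeqIO.write(seqrecs, stream, "genbank")


# ---------------------------------------------------------------------------
# protein FASTA attachment
# ---------------------------------------------------------------------------


def write_protein_fasta(ann: GenomeAnnotation, stream: IO[str]) -> None:
    for rec in ann.all_genes():
        if rec.protein_seq:
            stream.write(f">{rec.locus_tag} {rec.product}\n{rec.protein_seq}\n")


def attach_proteins(ann: GenomeAnnotation, stream: Stream) -> GenomeAnnotation:
    """Attach sequences from a protein FASTA (headers = locus_tag) in place."""
    text = _as_text(stream)
    seqs: dict[str, str] = {}
    for seqrec in SeqIO.parse(io.StringIO(text), "fasta"):
        seqs[seqrec.id] = str(seqrec.seq)
    for rec in ann.all_genes():
        if rec.locus_tag in seqs:
            rec.protein_seq = seqs[rec.locus_tag]
    return ann


# ---------------------------------------------------------------------------
# internal JSON genome dump (lossless round trip)
# ---------------------------------------------------------------------------


def annotation_to_dict(ann: GenomeAnnotation) -> dict:
    return {
        "genome_id": ann.genome_id,
        "complete": ann.complete,
        "contigs": [list(c) for c in ann.contigs],
        "genes": {
            cid: [
                {
                    "contig_id": r.contig_id,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                    "locus_tag": r.locus_tag,
                    "symbol": r.symbol,
                    "product": r.product,
                    "pseudo": r.pseudo,
                    "partial": r.partial,
                    "contig_edge": r.contig_edge,
                    "protein_seq": r.protein_seq,
                    "feature_type": r.feature_type,
                }
                for r in ann.genes.get(cid, [])
            ]
            for cid, _ in ann.contigs
        },
    }


def annotation_from_dict(doc: dict) -> GenomeAnnotation:
    genes = {
        cid: [GeneRecord(genome_id=doc["genome_id"], **rec) for rec in recs]
        for cid, recs in doc["genes"].items()
    }
    return GenomeAnnotation(
        genome_id=doc["genome_id"],
        contigs=tuple((c[0], c[1]) for c in doc["contigs"]),
        genes=genes,
        complete=doc["complete"],
    )


def write_annotation_json(ann: GenomeAnnotation, stream: IO[str]) -> None:
    json.dump(annotation_to_dict(ann), stream, indent=1, sort_keys=True)
    stream.write("\n")


def read_annotation_json(stream: Stream) -> GenomeAnnotation:
    return annotation_from_dict(json.loads(_as_text(stream)))


# ---------------------------------------------------------------------------
# occurrence reports
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = (
    "genome", "family", "model", "status", "n_segments", "segment",
    "members_found", "members_missing", "insertions", "pseudo_members",
    "partial_members",
)


def write_occurrence_report(occurrences, stream: IO[str], format: str = "tsv") -> None:
    """Serialize ClusterOccurrence objects as TSV or JSON (deterministic)."""
    if format == "json":
        json.dump(
            [occ.to_dict() for occ in occurrences], stream, indent=1, sort_keys=True
        )
        stream.write("\n")
        return
    if format != "tsv":
        raise InputError(f"unknown report format {format!r} (expected tsv or json)")
    stream.write("\t".join(_REPORT_COLUMNS) + "\n")
    for occ in occurrences:
        segments = ";".join(
            f"{s.contig_id}:{s.first_index}-{s.last_index}:{s.orientation}"
            for s in occ.segments
        )
        row = [
            occ.genome_id,
            occ.model.family,
            occ.model.name,
            occ.status,
            str(len(occ.segments)),
            segments,
            ",".join(occ.found_members()),
            ",".join(sorted(occ.missing)),
            ",".join(name for name, _ in occ.insertions),
            ",".join(sorted(occ.pseudo_members)),
            ",".join(sorted(occ.partial_members)),
        ]
        stream.write("\t".join(row) + "\n")
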