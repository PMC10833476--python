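"""Locate cluster models in a genome and classify their organization.

A cluster model is mapped onto a genome by collecting *member hits* (genes
whose canonical name -- after overlaying accepted rescue calls -- belongs to
the model) and grouping them, left to right within each contig, into maximal
runs in which consecutive hits are separated by at most ``gap_tolerance``
foreign genes.  Accessory genes (e.g. IF(Sui) or secY inside the archaeal
S10-spc block) neither break a run nor count as insertions; unannotated
hypothetical proteins count toward the gap budget but are not reported as
insertions; *named* foreign genes inside a segment (the Hsp20 case) are the
insertions.  Segments never span contigs -- ``at_contig_edge`` flags mark
potential continuity across assembly breaks instead.

Status classification follows the occupancy rules: ``complete_contiguous``
(all members, one segment), ``split`` (two or more segments with at most
``allowed_missing`` members absent), ``partial`` (anything else with at least
one member), ``absent``.  Pseudogene members count as present but are listed
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .annotation_io import GeneRecord, GenomeAnnotation
from .cluster_models import ClusterModel, Registry, load_registry

DEFAULT_GAP_TOLERANCE = 2
DEFAULT_ALLOWED_MISSING = 1
DEFAULT_ADJACENCY_WINDOW = 12

STATUSES = ("complete_contiguous", "split", "partial", "absent")


@dataclass(frozen=True)
class MemberHit:
    gene: str
    record: GeneRecord
    index: int  # gene-order index on the contig
    via_rescue: bool = False

    @property
    def pseudo(self) -> bool:
        return self.record.pseudo

    @property
    def partial(self) -> bool:
        return self.record.partial


@dataclass(frozen=True)
class Segment:
    contig_id: str
    hits: tuple[MemberHit, ...]  # presented in model order when reverse
    orientation: str  # forward | reverse
    first_index: int
    last_index: int
    at_contig_edge: bool

    def __len__(self) -> int:
        return len(self.hits)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(h.gene for h in self.hits)


@dataclass
class ClusterOccurrence:
    model: ClusterModel
    genome_id: str
    segments: tuple[Segment, ...]
    status: str
    missing: frozenset[str]
    insertions: tuple[tuple[str, str], ...]  # (gene-or-product, position)
    pseudo_members: frozenset[str]
    partial_members: frozenset[str]
    extra_copies: tuple[str, ...] = ()
    genome_complete: bool = False
    annotation: Optional[GenomeAnnotation] = field(default=None, repr=False)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def found_members(self) -> tuple[str, ...]:
        """Found member genes, in model order."""
        found = {h.gene for s in self.segments for h in s.hits}
        return tuple(g for g in self.model.members if g in found)

    def segment_sizes(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.segments)

    def to_dict(self) -> dict:
        return {
            "genome": self.genome_id,
            "genome_complete": self.genome_complete,
            "family": self.model.family,
            "model": self.model.name,
            "variant": self.model.variant,
            "status": self.status,
            "n_segments": self.n_segments,
            "segments": [
                {
                    "contig": s.contig_id,
                    "first_index": s.first_index,
                    "last_index": s.last_index,
                    "orientation": s.orientation,
                    "at_contig_edge": s.at_contig_edge,
                    "hits": [
                        {
                            "gene": h.gene,
                            "locus_tag": h.record.locus_tag,
                            "via_rescue": h.via_rescue,
                            "pseudo": h.pseudo,
                            "partial": h.partial,
                        }
                        for h in s.hits
                    ],
                }
                for s in self.segments
            ],
            "missing": sorted(self.missing),
            "insertions": [list(i) for i in self.insertions],
            "pseudo_members": sorted(self.pseudo_members),
            "partial_members": sorted(self.partial_members),
            "extra_copies": list(self.extra_copies),
        }


def effective_names(
    annotation: GenomeAnnotation,
    registry: Registry,
    rescue_overlay: Mapping[str, str] = (),
) -> dict[str, list[tuple[GeneRecord, Optional[str], bool]]]:
    """Per contig: (record, canonical-name-or-None, via_rescue) in gene order."""
    overlay = dict(rescue_overlay)
    out: dict[str, list[tuple[GeneRecord, Optional[str], bool]]] = {}
    for cid, _ in annotation.contigs:
        row = []
        for rec in annotation.genes.get(cid, []):
            name = registry.canonicalize_gene_name(rec.symbol, rec.product)
            via_rescue = False
            if name is None and rec.locus_tag in overlay:
                name = overlay[rec.locus_tag]
                via_rescue = True
            row.append((rec, name, via_rescue))
        out[cid] = row
    return out


def _classify_status(
    n_found: int, n_members: int, n_segments: int, allowed_missing: int
) -> str:
    if n_found == 0:
        return "absent"
    missing = n_members - n_found
    if missing == 0 and n_segments == 1:
        return "complete_contiguous"
    if n_segments >= 2 and missing <= allowed_missing:
        return "split"
    return "partial"


def _segment_orientation(hits: list[MemberHit], model: ClusterModel) -> str:
    """Reverse iff the hits read against the model's canonical order.

    Direction is decided by the trend of member indices along the genome;
    single-gene segments are forward by convention, exact ties fall back to
    the majority strand of the hits.
    """
    idx = [model.member_index(h.gene) for h in hits]
    trend = sum(
        (1 if b > a else -1 if b < a else 0) for a, b in zip(idx, idx[1:])
    )
    if trend > 0:
        return "forward"
    if trend < 0:
        return "reverse"
    if len(hits) == 1:
        return "forward"
    minus = sum(1 for h in hits if h.record.strand == "-")
    return "reverse" if minus * 2 > len(hits) else "forward"


def map_cluster(
    annotation: GenomeAnnotation,
    model: ClusterModel,
    rescue_overlay: Mapping[str, str] = (),
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    allowed_missing: int = DEFAULT_ALLOWED_MISSING,
    registry: Optional[Registry] = None,
    named_rows: Optional[dict] = None,
) -> ClusterOccurrence:
    """Map one cluster model onto one genome."""
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    registry = registry or load_registry()
    rows = (
        named_rows
        if named_rows is not None
        else effective_names(annotation, registry, rescue_overlay)
    )
    members = set(model.members)
    accessory = set(model.accessory)

    raw_segments: list[tuple[str, list[MemberHit]]] = []
    for cid, _ in annotation.contigs:
        row = rows[cid]
        run: list[MemberHit] = []
        for pos, (rec, name, via_rescue) in enumerate(row):
            if name not in members:
                continue
            if run:
                foreign = sum(
                    1
                    for _r, n, _v in row[run[-1].index + 1 : pos]
                    if n not in members and n not in accessory
                )
                if foreign > gap_tolerance:
                    raw_segments.append((cid, run))
                    run = []
            run.append(MemberHit(gene=name, record=rec, index=pos, via_rescue=via_rescue))
        if run:
            raw_segments.append((cid, run))

    # paralog handling: a member name is claimed by the segment with the most
    # distinct members (then the leftmost); surplus hits become extra copies.
    order = sorted(
        range(len(raw_segments)),
        key=lambda i: (-len({h.gene for h in raw_segments[i][1]}), i),
    )
    claimed: set[str] = set()
    keep_hits: dict[int, list[MemberHit]] = {}
    extra: list[str] = []
    for i in order:
        _cid, run = raw_segments[i]
        kept = []
        for h in run:
            if h.gene in claimed:
                extra.append(h.gene)
            else:
                claimed.add(h.gene)
                kept.append(h)
        keep_hits[i] = kept

    segments: list[Segment] = []
    insertions: list[tuple[str, str]] = []
    for i, (cid, _run) in enumerate(raw_segments):
        hits = keep_hits[i]
        if not hits:
            continue
        row = rows[cid]
        first, last = hits[0].index, hits[-1].index
        # named foreign genes physically inside the segment's span
        for pos in range(first, last + 1):
            _rec, name, _v = row[pos]
            if name is not None and name not in members and name not in accessory:
                lefts = [h.gene for h in hits if h.index < pos]
                rights = [h.gene for h in hits if h.index > pos]
                position = f"{lefts[-1] if lefts else '^'}|{rights[0] if rights else '$'}"
                insertions.append((name, position))
        orientation = _segment_orientation(hits, model)
        shown = tuple(hits if orientation == "forward" else list(reversed(hits)))
        at_edge = (
            first == 0
            or last == len(row) - 1
            or any(h.record.contig_edge for h in hits)
        )
        segments.append(
            Segment(
                contig_id=cid,
                hits=shown,
                orientation=orientation,
                first_index=first,
                last_index=last,
                at_contig_edge=at_edge,
            )
        )

    found = {h.gene for s in segments for h in s.hits}
    missing = frozenset(members - found)
    status = _classify_status(
        len(found), len(members), len(segments), allowed_missing
    )
    pseudo_members = frozenset(
        h.gene for s in segments for h in s.hits if h.pseudo
    )
    partial_members = frozenset(
        h.gene for s in segments for h in s.hits if h.partial
    )
    return ClusterOccurrence(
        model=model,
        genome_id=annotation.genome_id,
        segments=tuple(segments),
        status=status,
        missing=missing,
        insertions=tuple(insertions),
        pseudo_members=pseudo_members,
        partial_members=partial_members,
        extra_copies=tuple(extra),
        genome_complete=annotation.complete,
        annotation=annotation,
    )


def detect_insertions(occurrence: ClusterOccurrence) -> tuple[tuple[str, str], ...]:
    """Named foreign genes inside the occurrence's segments (already computed)."""
    return occurrence.insertions


def normalize_orientation(occurrence: ClusterOccurrence) -> ClusterOccurrence:
    """Present every reverse segment's hits in model order (idempotent)."""
    segments = []
    for seg in occurrence.segments:
        hits = seg.hits
        genome_order = tuple(sorted(hits, key=lambda h: h.index))
        if seg.orientation == "reverse":
            shown = tuple(reversed(genome_order))
        else:
            shown = genome_order
        segments.append(replace(seg, hits=shown))
    return replace(occurrence, segments=tuple(segments))


def map_genome(
    annotation: GenomeAnnotation,
    variant: str,
    rescue_overlay: Mapping[str, str] = (),
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    allowed_missing: int = DEFAULT_ALLOWED_MISSING,
    registry: Optional[Registry] = None,
) -> list[ClusterOccurrence]:
    """Map every registered model of the given variant onto the genome."""
    registry = registry or load_registry()
    rows = effective_names(annotation, registry, rescue_overlay)
    return [
        map_cluster(
            annotation,
            model,
            rescue_overlay,
            gap_tolerance,
            allowed_missing,
            registry,
            named_rows=rows,
        )
        for model in registry.models_for_variant(variant)
    ]


@dataclass(frozen=True)
class CooccurrenceGroup:
    families: tuple[str, ...]  # sorted
    intervals: tuple[tuple[str, int, int], ...]  # (contig, first, last) per contig

    def __len__(self) -> int:
        return len(self.families)


def detect_cooccurrence(
    occurrences: Iterable[ClusterOccurrence],
    adjacency_window: int = DEFAULT_ADJACENCY_WINDOW,
) -> list[CooccurrenceGroup]:
    """Group cluster families whose segments lie near each other.

    Two families co-occur when some segment of one lies within
    ``adjacency_window`` gene positions of a segment of the other on the same
    contig; groups are transitive closures over that relation.
    """
    occurrences = list(occurrences)
    genomes = {o.genome_id for o in occurrences}
    if len(genomes) > 1:
        raise ValueError(f"occurrences from multiple genomes: {sorted(genomes)}")
    segs: list[tuple[str, str, int, int]] = []
    for occ in occurrences:
        for seg in occ.segments:
            segs.append((occ.model.family, seg.contig_id, seg.first_index, seg.last_index))
    families = sorted({s[0] for s in segs})
    parent = {f: f for f in families}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for fa, ca, first_a, last_a in segs:
        for fb, cb, first_b, last_b in segs:
            if fa >= fb or ca != cb:
                continue
            if first_b > last_a:
                gap = first_b - last_a - 1
            elif first_a > last_b:
                gap = first_a - last_b - 1
            else:
                gap = 0
            if gap <= adjacency_window:
                parent[find(fa)] = find(fb)

    members: dict[str, list[str]] = {}
    for f in families:
        members.setdefault(find(f), []).append(f)
    groups = []
    for group_families in members.values():
        fams = tuple(sorted(group_families))
        spans: dict[str, tuple[int, int]] = {}
        for fam, cid, first, last in segs:
            if fam not in fams:
                continue
            lo, hi = spans.get(cid, (first, last))
            spans[cid] = (min(lo, first), max(hi, last))
        intervals = tuple((cid, lo, hi) for cid, (lo, hi) in sorted(spans.items()))
        groups.append(CooccurrenceGroup(families=fams, intervals=intervals))
    groups.sort(key=lambda g: (-len(g.families), g.families))
    return groups
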