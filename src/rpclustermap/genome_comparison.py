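"""Cross-genome aggregation: status matrix, dispersion, assembly concerns, maps.

The dispersion and completeness summaries quantify what cluster maps show
qualitatively -- how scattered the r-protein clusters of a genome are.  Both
formulas are this package's own summaries (documented in docs/methods.md),
not literature-standard statistics:

* ``dispersion(g)``   = mean number of segments over the families present,
* ``completeness(g)`` = fraction of present families that are
  ``complete_contiguous``.

Assembly-concern flags encode the heuristics that make a metagenome-assembled
genome suspect: a universal gene annotated as a pseudogene, universal genes
(uL3-uL4-uL23) missing genome-wide, the S10-spc core split inside a complete
genome, or a high fraction of partial cluster genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Iterable, Optional

import pandas as pd

from .cluster_mapping import ClusterOccurrence
from .cluster_models import FAMILIES, Registry, load_registry
from .exceptions import InputError

UNIVERSAL_TRIAD = frozenset({"uL3", "uL4", "uL23"})

CONCERN_REASONS = (
    "universal_gene_pseudo",
    "universal_genes_missing",
    "core_split",
    "high_partial_fraction",
)


@dataclass(frozen=True)
class CellStats:
    status: str
    n_segments: int
    fraction_members_found: float
    partial_fraction: float


ABSENT_CELL = CellStats("absent", 0, 0.0, 0.0)


@dataclass
class StatusMatrix:
    """Genomes x cluster families table of occurrence statuses."""

    rows: tuple[str, ...]  # genome ids
    columns: tuple[str, ...]  # families
    cells: dict[tuple[str, str], CellStats]

    def cell(self, genome_id: str, family: str) -> CellStats:
        return self.cells[(genome_id, family)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                fam: [self.cells[(g, fam)].status for g in self.rows]
                for fam in self.columns
            },
            index=list(self.rows),
        )

    def to_tsv(self, stream: IO[str]) -> None:
        self.to_frame().to_csv(stream, sep="\t", index_label="genome")

    def to_json(self, stream: IO[str]) -> None:
        doc = {
            g: {
                fam: {
                    "status": c.status,
                    "n_segments": c.n_segments,
                    "fraction_members_found": round(c.fraction_members_found, 4),
                    "partial_fraction": round(c.partial_fraction, 4),
                }
                for fam in self.columns
                for c in [self.cells[(g, fam)]]
            }
            for g in self.rows
        }
        json.dump(doc, stream, indent=1, sort_keys=True)
        stream.write("\n")


def build_status_matrix(
    occurrences: Iterable[ClusterOccurrence],
    registry: Optional[Registry] = None,
) -> StatusMatrix:
    """Aggregate occurrences into a genomes x families matrix.

    Each family's cell reflects the family's *primary* model for the
    occurrence's variant (e.g. the archaeal S10-spc core, not the small S10
    sub-cluster).  Families with no mapped primary model yield absent cells.
    """
    registry = registry or load_registry()
    by_genome: dict[str, dict[str, ClusterOccurrence]] = {}
    for occ in occurrences:
        per = by_genome.setdefault(occ.genome_id, {})
        key = occ.model.name
        if key in per:
            raise InputError(
                f"duplicate occurrence of model {key!r} for genome "
                f"{occ.genome_id!r}"
            )
        per[key] = occ
    rows = tuple(sorted(by_genome))
    cells: dict[tuple[str, str], CellStats] = {}
    for genome_id in rows:
        per = by_genome[genome_id]
        variants = {o.model.variant for o in per.values()}
        for family in FAMILIES:
            occ = None
            for variant in sorted(variants):
                primary = registry.primary_model(family, variant)
                if primary and primary.name in per:
                    occ = per[primary.name]
                    break
            if occ is None or occ.status == "absent":
                cells[(genome_id, family)] = ABSENT_CELL
                continue
            found = occ.found_members()
            n_partial = len(occ.partial_members)
            cells[(genome_id, family)] = CellStats(
                status=occ.status,
                n_segments=occ.n_segments,
                fraction_members_found=len(found) / len(occ.model.members),
                partial_fraction=n_partial / len(found) if found else 0.0,
            )
    return StatusMatrix(rows=rows, columns=FAMILIES, cells=cells)


def dispersion_metrics(matrix: StatusMatrix) -> pd.DataFrame:
    """Per-genome dispersion and completeness summaries.

    dispersion = mean segments per present family (>= 1 when anything is
    present); completeness = fraction of present families that are
    complete_contiguous.  Genomes with no present family get NaN dispersion
    and completeness 0.
    """
    if not matrix.rows:
        raise InputError("empty status matrix")
    out = []
    for genome_id in matrix.rows:
        present = [
            matrix.cells[(genome_id, fam)]
            for fam in matrix.columns
            if matrix.cells[(genome_id, fam)].status != "absent"
        ]
        n = len(present)
        out.append(
            {
                "genome": genome_id,
                "n_present_families": n,
                "dispersion": (
                    sum(c.n_segments for c in present) / n if n else float("nan")
                ),
                "completeness": (
                    sum(1 for c in present if c.status == "complete_contiguous") / n
                    if n
                    else 0.0
                ),
            }
        )
    return pd.DataFrame(out).set_index("genome")


@dataclass(frozen=True)
class AssemblyConcern:
    genome_id: str
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.reasons:
            raise InputError("AssemblyConcern requires at least one reason")


def flag_assembly_concerns(
    occurrences: Iterable[ClusterOccurrence],
    partial_threshold: float = 0.10,
    registry: Optional[Registry] = None,
) -> list[AssemblyConcern]:
    """Flag genomes whose cluster occupancy suggests mis-assembly/mis-binning."""
    registry = registry or load_registry()
    by_genome: dict[str, list[ClusterOccurrence]] = {}
    for occ in occurrences:
        by_genome.setdefault(occ.genome_id, []).append(occ)
    concerns = []
    for genome_id in sorted(by_genome):
        occs = by_genome[genome_id]
        reasons: list[str] = []
        member_union: set[str] = set()
        found_union: set[str] = set()
        pseudo_union: set[str] = set()
        partial_union: set[str] = set()
        for occ in occs:
            member_union.update(occ.model.members)
            found_union.update(occ.found_members())
            pseudo_union.update(occ.pseudo_members)
            partial_union.update(occ.partial_members)

        core_members: set[str] = set()
        for occ in occs:
            if occ.model.family == "S10-spc" and occ.model.primary:
                core_members.update(occ.model.core)
                if (
                    occ.genome_complete
                    and sum(
                        1
                        for seg in occ.segments
                        if any(h.gene in occ.model.core for h in seg.hits)
                    )
                    >= 2
                ):
                    reasons.append("core_split")
        if pseudo_union & core_members:
            reasons.append("universal_gene_pseudo")
        if (UNIVERSAL_TRIAD & member_union) - found_union:
            reasons.append("universal_genes_missing")
        if found_union:
            fraction = len(partial_union & found_union) / len(found_union)
            if fraction >= partial_threshold:
                reasons.append("high_partial_fraction")
        if reasons:
            concerns.append(
                AssemblyConcern(
                    genome_id=genome_id,
                    reasons=tuple(sorted(set(reasons))),
                )
            )
    return concerns


def render_cluster_map(occurrence: ClusterOccurrence) -> str:
    """Deterministic one-line-per-segment text diagram of an occurrence.

    Markers: ``name^`` pseudogene, ``name~`` partial gene, ``{name}`` foreign
    insertion, a leading ``*`` for segments at a contig edge, and trailing
    ``∅name`` entries for missing members.
    """
    lines = [
        f"# {occurrence.genome_id} | {occurrence.model.family}/"
        f"{occurrence.model.name} | {occurrence.status}"
    ]
    insertion_names = [name for name, _pos in occurrence.insertions]
    for seg in occurrence.segments:
        parts = []
        for h in seg.hits:
            marker = h.gene + ("^" if h.pseudo else "") + ("~" if h.partial else "")
            parts.append(f"[{marker}]")
        prefix = "*" if seg.at_contig_edge else " "
        suffix = f" ({seg.orientation})" if seg.orientation == "reverse" else ""
        lines.append(f"{prefix}{seg.contig_id}: " + " ".join(parts) + suffix)
    if insertion_names:
        lines.append("  insertions: " + " ".join(f"{{{n}}}" for n in insertion_names))
    if occurrence.missing:
        lines.append("  missing: " + " ".join(f"∅{g}" for g in sorted(occurrence.missing)))
    return "\n".join(lines) + "\n"
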