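"""Rescue cluster members hidden behind "hypothetical protein" labels.

Metagenome-assembled genomes routinely deposit genuine r-protein genes as
unannotated hypothetical proteins.  This module replaces the manual
BLAST-based reannotation step with an internal Smith-Waterman local aligner
(BLOSUM62, affine gaps: a gap of length k costs ``open + (k-1) * extend``,
defaults 11/1) run against a reference panel of per-gene protein sequences.
A hypothetical record is reassigned to the best-scoring panel gene when the
alignment reaches the identity and coverage thresholds; the annotation itself
is never mutated -- accepted calls are overlaid during cluster mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import IO, Iterable, Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from numba import njit

from .annotation_io import GenomeAnnotation, _as_text
from .cluster_models import Registry, load_registry
from .exceptions import InputError, RegistryError

logger = logging.getLogger(__name__)

ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"
_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


def _blosum62_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = int(blosum[a, b])
    return mat


_BLOSUM62 = _blosum62_matrix()


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 11  # cost of the first residue of a gap
    gap_extend: int = 1  # cost of each further residue


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    identity: float  # matches / alignment columns
    coverage: float  # reference residues aligned / reference length
    query_span: tuple[int, int]  # 0-based half-open on the query
    ref_span: tuple[int, int]  # 0-based half-open on the reference
    n_columns: int
    n_matches: int


def _encode(seq: str, which: str) -> np.ndarray:
    if not seq:
        raise InputError(f"{which} sequence is empty")
    out = np.empty(len(seq), dtype=np.int8)
    for i, aa in enumerate(seq.upper()):
        code = _CODE.get(aa)
        if code is None:
            raise InputError(
                f"invalid residue {aa!r} at position {i + 1} of {which} sequence"
            )
        out[i] = code
    return out


@njit(cache=True)
def _gotoh_fill(q, r, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = q.shape[0], r.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**8, dtype=np.int32)  # gap in query (along ref)
    F = np.full((n + 1, m + 1), -10**8, dtype=np.int32)  # gap in ref (along query)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open
            e2 = E[i, j - 1] - gap_extend
            E[i, j] = e if e >= e2 else e2
            f = H[i - 1, j] - gap_open
            f2 = F[i - 1, j] - gap_extend
            F[i, j] = f if f >= f2 else f2
            h = H[i - 1, j - 1] + sub[q[i - 1], r[j - 1]]
            v = h
            if E[i, j] > v:
                v = E[i, j]
            if F[i, j] > v:
                v = F[i, j]
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best, bi, bj = v, i, j
    return H, E, F, best, bi, bj


def local_align(
    query: str, reference: str, params: AlignParams = DEFAULT_PARAMS
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns the optimal score plus identity (matches over alignment columns),
    coverage (fraction of the reference length aligned) and the aligned spans.
    """
    if params.matrix != "BLOSUM62":
        raise InputError(f"unsupported scoring matrix {params.matrix!r}")
    q = _encode(query, "query")
    r = _encode(reference, "reference")
    H, E, F, best, bi, bj = _gotoh_fill(
        q, r, _BLOSUM62, np.int32(params.gap_open), np.int32(params.gap_extend)
    )
    if best <= 0:
        return AlignmentResult(0, 0.0, 0.0, (0, 0), (0, 0), 0, 0)

    # traceback with explicit state (H / E / F) to respect affine gaps
    i, j, state = bi, bj, "H"
    n_cols = n_matches = 0
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == E[i, j]:
                state = "E"
                continue
            if H[i, j] == F[i, j]:
                state = "F"
                continue
            n_cols += 1
            if q[i - 1] == r[j - 1]:
                n_matches += 1
            i, j = i - 1, j - 1
        elif state == "E":  # gap in the query: consume a reference residue
            n_cols += 1
            came_from_h = E[i, j] == H[i, j - 1] - params.gap_open
            j -= 1
            if came_from_h:
                state = "H"
        else:  # "F": gap in the reference: consume a query residue
            n_cols += 1
            came_from_h = F[i, j] == H[i - 1, j] - params.gap_open
            i -= 1
            if came_from_h:
                state = "H"
    qs, rs = i, j
    ref_aligned = bj - rs
    return AlignmentResult(
        score=int(best),
        identity=n_matches / n_cols if n_cols else 0.0,
        coverage=ref_aligned / len(reference),
        query_span=(qs, bi),
        ref_span=(rs, bj),
        n_columns=n_cols,
        n_matches=n_matches,
    )


@lru_cache(maxsize=262144)
def _align_default(query: str, reference: str) -> AlignmentResult:
    # panel references and pooled filler sequences repeat heavily across
    # genomes, so memoizing default-parameter alignments pays off
    return local_align(query, reference)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------


@dataclass
class ReferencePanel:
    """Per-gene reference amino-acid sequences used for rescue and length checks."""

    entries: dict[str, tuple[tuple[str, str], ...]]  # gene -> ((seq, source), ...)
    typical_length: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        registry = load_registry()
        for gene, seqs in self.entries.items():
            if gene not in registry.genes:
                raise RegistryError(f"panel gene {gene!r} is not registered")
            for seq, _src in seqs:
                bad = set(seq.upper()) - set(ALPHABET)
                if bad:
                    raise InputError(
                        f"panel entry for {gene!r} has invalid residues {sorted(bad)}"
                    )
        for gene, seqs in self.entries.items():
            self.typical_length.setdefault(
                gene, int(round(np.mean([len(s) for s, _ in seqs])))
            )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    @classmethod
    def from_fasta(cls, stream: Union[str, IO[str]]) -> "ReferencePanel":
        """Load a panel from FASTA with headers ``>canonicalName source=...``."""
        import io as _io

        entries: dict[str, list[tuple[str, str]]] = {}
        for rec in SeqIO.parse(_io.StringIO(_as_text(stream)), "fasta"):
            source = ""
            for tok in rec.description.split():
                if tok.startswith("source="):
                    source = tok[len("source="):]
            entries.setdefault(rec.id, []).append((str(rec.seq).upper(), source))
        return cls({g: tuple(v) for g, v in entries.items()})

    def to_fasta(self, stream: IO[str]) -> None:
        for gene in self.genes:
            for seq, source in self.entries[gene]:
                stream.write(f">{gene} source={source or 'synthetic'}\n{seq}\n")


# ---------------------------------------------------------------------------
# rescue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RescueThresholds:
    min_identity: float = 0.30
    min_coverage: float = 0.50


DEFAULT_THRESHOLDS = RescueThresholds()


@dataclass(frozen=True)
class RescueCall:
    locus_tag: str
    assigned: str
    identity: float
    coverage: float
    score: int
    accepted: bool


def rescue_hypotheticals(
    annotation: GenomeAnnotation,
    panel: ReferencePanel,
    thresholds: RescueThresholds = DEFAULT_THRESHOLDS,
    registry: Optional[Registry] = None,
) -> list[RescueCall]:
    """Align every unassigned (hypothetical) protein against the panel.

    Every gene whose symbol/product resolves to no registered name is aligned
    against all panel entries; the best-scoring entry (ties broken by the
    lexicographically smallest gene name) yields one call per locus, flagged
    accepted when both thresholds are met.  The annotation is not mutated.
    """
    registry = registry or load_registry()
    calls: list[RescueCall] = []
    if not panel.entries:
        return calls
    for rec in annotation.all_genes():
        if rec.feature_type != "CDS":
            continue
        if registry.canonicalize_gene_name(rec.symbol, rec.product) is not None:
            continue
        if not rec.protein_seq:
            logger.warning(
                "%s: hypothetical record has no protein sequence; skipped",
                rec.locus_tag,
            )
            continue
        best: Optional[tuple[int, str, AlignmentResult]] = None
        for gene in panel.genes:  # sorted: deterministic tie-breaking
            for seq, _source in panel.entries[gene]:
                res = _align_default(rec.protein_seq, seq)
                if best is None or res.score > best[0]:
                    best = (res.score, gene, res)
        assert best is not None
        score, gene, res = best
        calls.append(
            RescueCall(
                locus_tag=rec.locus_tag,
                assigned=gene,
                identity=round(res.identity, 4),
                coverage=round(res.coverage, 4),
                score=score,
                accepted=(
                    res.identity >= thresholds.min_identity
                    and res.coverage >= thresholds.min_coverage
                ),
            )
        )
    return calls


def accepted_overlay(calls: Iterable[RescueCall]) -> dict[str, str]:
    """locus_tag -> gene mapping of accepted calls, for the mapping stage."""
    return {c.locus_tag: c.assigned for c in calls if c.accepted}


def flag_partials(
    annotation: GenomeAnnotation,
    panel: ReferencePanel,
    min_length_fraction: float = 0.7,
    registry: Optional[Registry] = None,
    rescue_calls: Iterable[RescueCall] = (),
) -> tuple[GenomeAnnotation, float]:
    """Flag genes much shorter than their family's typical length.

    Returns a modified copy of the annotation plus the genome's partial
    fraction (percentage of cluster-assigned genes flagged partial).  A gene is
    partial when its coding length is below ``min_length_fraction`` times the
    reference length of its assigned family, or when it sits at a contig edge
    and is truncated relative to that length.
    """
    registry = registry or load_registry()
    overlay = accepted_overlay(rescue_calls)
    new_genes = {
        cid: [replace(r) for r in annotation.genes.get(cid, [])]
        for cid, _ in annotation.contigs
    }
    n_cluster = n_partial = 0
    for records in new_genes.values():
        for rec in records:
            name = registry.canonicalize_gene_name(
                rec.symbol, rec.product
            ) or overlay.get(rec.locus_tag)
            typical = panel.typical_length.get(name) if name else None
            if typical is None:
                continue
            n_cluster += 1
            aa = rec.aa_length
            if aa is not None:
                if aa < min_length_fraction * typical:
                    rec.partial = True
                elif rec.contig_edge and aa < typical:
                    rec.partial = True
            if rec.partial:
                n_partial += 1
    copy = GenomeAnnotation(
        genome_id=annotation.genome_id,
        contigs=annotation.contigs,
        genes=new_genes,
        complete=annotation.complete,
    )
    fraction = 100.0 * n_partial / n_cluster if n_cluster else 0.0
    return copy, fraction
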