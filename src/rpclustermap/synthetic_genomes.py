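"""Synthetic annotated genomes with planted, machine-readable truth.

Each template transcribes one of the characteristic r-protein cluster
arrangements (the canonical Asgard S10-spc core, the bacterial 21-gene
S10+spc block, the B. subtilis-like str cluster, the bin6 three-way split,
the B-35 hypothetical-protein mislabels, the Hsp20 insertion, the missing
uL3-uL4-uL23 pathology, the AR10 four-cluster superstring, and the PR6
mixed-strand rearrangement).  Generated genomes are ordinary
:class:`~rpclustermap.annotation_io.GenomeAnnotation` objects with
deterministic pseudo-protein sequences, exportable as GFF3 + protein FASTA
(and feature table / GenBank), and every genome ships with a
:class:`PlantedTruth` record derived by an independent mini-scanner that
walks ground-truth gene names directly -- no parsing, alignment, or
orientation logic is shared with the mapping pipeline it validates.

Background ("filler") genes are labelled ``hypothetical protein`` and drawn
from a fixed pool of random sequences rejection-sampled to stay safely below
the rescue acceptance thresholds against every panel entry.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation_io import (
    GeneRecord,
    GenomeAnnotation,
    write_annotation_json,
    write_feature_table,
    write_genbank,
    write_gff3,
    write_protein_fasta,
)
from .annotation_rescue import ReferencePanel, _align_default
from .cluster_models import Registry, load_registry
from .exceptions import TemplateError

# mapping parameters used when deriving planted truth; must mirror the
# documented defaults of the mapping stage
DEFAULT_GAP_TOLERANCE = 2
DEFAULT_ALLOWED_MISSING = 1
DEFAULT_ADJACENCY_WINDOW = 12

_AA20 = np.array(list("ARNDCQEGHILKMFPSTWYV"))
_HP_PRODUCT = "hypothetical protein"
_FILLER_POOL_SIZE = 64
_INTERGENIC = 40  # bp between consecutive genes


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


# ---------------------------------------------------------------------------
# deterministic pseudo-protein sequences
# ---------------------------------------------------------------------------


def typical_protein_length(gene: str) -> int:
    """Fixed per-gene reference length, 60-250 aa, derived from the name."""
    return 60 + _crc(gene + "/len") % 191


@lru_cache(maxsize=1024)
def _base_seq(gene: str) -> str:
    rng = np.random.default_rng([_crc(gene), 0xBA5E])
    return "".join(rng.choice(_AA20, size=typical_protein_length(gene)))


def generate_protein_seq(gene: str, seed: int, mutation_rate: float = 0.0) -> str:
    """Deterministic pseudo-protein for a gene, point-mutated at ``mutation_rate``."""
    if not 0 <= mutation_rate < 1:
        raise TemplateError(f"mutation_rate must be in [0, 1); got {mutation_rate}")
    base = _base_seq(gene)
    if mutation_rate == 0:
        return base
    rng = np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, _crc(gene), int(mutation_rate * 1_000_000)]
    )
    residues = np.array(list(base))
    hit = rng.random(len(base)) < mutation_rate
    for i in np.nonzero(hit)[0]:
        choices = _AA20[_AA20 != residues[i]]
        residues[i] = rng.choice(choices)
    return "".join(residues)


@lru_cache(maxsize=1)
def build_reference_panel() -> ReferencePanel:
    """Panel of unmutated base sequences for every registered protein gene."""
    registry = load_registry()
    entries = {}
    for gene in registry.genes:
        if gene == "tRNA(leu)":  # structural RNA, no protein
            continue
        entries[gene] = ((_base_seq(gene), "synthetic"),)
    return ReferencePanel(entries)


@lru_cache(maxsize=1)
def _filler_pool() -> tuple[str, ...]:
    """Fixed pool of background sequences that can never be rescued.

    Rejection sampling guarantees no panel entry aligns with identity >= 0.27
    at coverage >= 0.40 (the rescue acceptance margin is 0.30/0.50).
    """
    panel = build_reference_panel()
    refs = [seq for gene in panel.genes for seq, _ in panel.entries[gene]]
    rng = np.random.default_rng([0xF111E5])
    pool: list[str] = []
    while len(pool) < _FILLER_POOL_SIZE:
        length = int(rng.integers(80, 181))
        cand = "".join(rng.choice(_AA20, size=length))
        ok = True
        for ref in refs:
            res = _align_default(cand, ref)
            if res.identity >= 0.27 and res.coverage >= 0.40:
                ok = False
                break
        if ok:
            pool.append(cand)
    return tuple(pool)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def load_templates() -> dict:
    text = resources.files("rpclustermap.data").joinpath("templates.json").read_text()
    return json.loads(text)


def template_names() -> tuple[str, ...]:
    return tuple(sorted(load_templates()))


def template_token_count(name: str) -> int:
    """Number of gene tokens (members, HPs, fillers) in a template."""
    tpl = _get_template(name)
    n = 0
    for contig in tpl["contigs"]:
        for item in contig:
            n += item["fillers"] if "fillers" in item else len(item["block"])
    return n


def _get_template(name: str) -> dict:
    templates = load_templates()
    if name not in templates:
        raise TemplateError(
            f"unknown template {name!r}; available: {', '.join(sorted(templates))}"
        )
    return templates[name]


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpectedOccurrence:
    status: str
    n_segments: int
    segment_sizes: tuple[int, ...]
    missing: frozenset[str]
    pseudo: frozenset[str]
    partial: frozenset[str]
    insertions: tuple[str, ...]


@dataclass
class PlantedTruth:
    genome_id: str
    variant: str
    models: dict[str, ExpectedOccurrence]
    rescuable: dict[str, str]  # locus_tag -> true gene name
    cooccur_groups: tuple[tuple[str, ...], ...]  # sorted family tuples

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "variant": self.variant,
            "models": {
                name: {
                    "status": e.status,
                    "n_segments": e.n_segments,
                    "segment_sizes": list(e.segment_sizes),
                    "missing": sorted(e.missing),
                    "pseudo": sorted(e.pseudo),
                    "partial": sorted(e.partial),
                    "insertions": list(e.insertions),
                }
                for name, e in sorted(self.models.items())
            },
            "rescuable": dict(sorted(self.rescuable.items())),
            "cooccur_groups": [list(g) for g in self.cooccur_groups],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PlantedTruth":
        return cls(
            genome_id=doc["genome_id"],
            variant=doc["variant"],
            models={
                name: ExpectedOccurrence(
                    status=e["status"],
                    n_segments=e["n_segments"],
                    segment_sizes=tuple(e["segment_sizes"]),
                    missing=frozenset(e["missing"]),
                    pseudo=frozenset(e["pseudo"]),
                    partial=frozenset(e["partial"]),
                    insertions=tuple(e["insertions"]),
                )
                for name, e in doc["models"].items()
            },
            rescuable=dict(doc["rescuable"]),
            cooccur_groups=tuple(tuple(g) for g in doc["cooccur_groups"]),
        )


def derive_truth(
    annotation: GenomeAnnotation,
    rescuable: dict[str, str],
    variant: str,
    registry: Optional[Registry] = None,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    allowed_missing: int = DEFAULT_ALLOWED_MISSING,
    adjacency_window: int = DEFAULT_ADJACENCY_WINDOW,
) -> PlantedTruth:
    """Derive the expected mapping outcome by scanning ground-truth names.

    Works directly on canonical names (with the rescuable overlay applied),
    so it is independent of the alignment, orientation, paralog, and I/O
    machinery of the mapping pipeline it is used to validate.
    """
    registry = registry or load_registry()
    named: dict[str, list] = {}
    for cid, _ in annotation.contigs:
        row = []
        for rec in annotation.genes.get(cid, []):
            name = registry.canonicalize_gene_name(rec.symbol, rec.product)
            if name is None:
                name = rescuable.get(rec.locus_tag)
            row.append((rec, name))
        named[cid] = row

    models: dict[str, ExpectedOccurrence] = {}
    seg_index: list[tuple[str, str, int, int]] = []  # family, contig, first, last
    for model in registry.models_for_variant(variant):
        members = set(model.members)
        accessory = set(model.accessory)
        segments: list[tuple[str, list[int]]] = []
        found: set[str] = set()
        pseudo: set[str] = set()
        partial: set[str] = set()
        insertions: list[str] = []
        for cid, row in named.items():
            run: list[int] = []
            for pos, (rec, name) in enumerate(row):
                if name not in members:
                    continue
                if run:
                    foreign = sum(
                        1
                        for _r, n in row[run[-1] + 1 : pos]
                        if n not in members and n not in accessory
                    )
                    if foreign > gap_tolerance:
                        segments.append((cid, run))
                        run = []
                run.append(pos)
                found.add(name)
                if rec.pseudo:
                    pseudo.add(name)
                if rec.partial:
                    partial.add(name)
            if run:
                segments.append((cid, run))
        for cid, run in segments:
            row = named[cid]
            for pos in range(run[0], run[-1] + 1):
                name = row[pos][1]
                if name is not None and name not in members and name not in accessory:
                    insertions.append(name)
            seg_index.append((model.family, cid, run[0], run[-1]))
        missing = members - found
        n_seg = len(segments)
        if not found:
            status = "absent"
        elif not missing and n_seg == 1:
            status = "complete_contiguous"
        elif n_seg >= 2 and len(missing) <= allowed_missing:
            status = "split"
        else:
            status = "partial"
        models[model.name] = ExpectedOccurrence(
            status=status,
            n_segments=n_seg,
            segment_sizes=tuple(len(run) for _cid, run in segments),
            missing=frozenset(missing),
            pseudo=frozenset(pseudo),
            partial=frozenset(partial),
            insertions=tuple(insertions),
        )

    groups = _family_groups(seg_index, adjacency_window)
    return PlantedTruth(
        genome_id=annotation.genome_id,
        variant=variant,
        models=models,
        rescuable=dict(rescuable),
        cooccur_groups=groups,
    )


def _family_groups(
    seg_index: list[tuple[str, str, int, int]], window: int
) -> tuple[tuple[str, ...], ...]:
    families = sorted({fam for fam, *_ in seg_index})
    parent = {f: f for f in families}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for fam_a, cid_a, first_a, last_a in seg_index:
        for fam_b, cid_b, first_b, last_b in seg_index:
            if fam_a >= fam_b or cid_a != cid_b:
                continue
            if first_b > last_a:
                gap = first_b - last_a - 1
            elif first_a > last_b:
                gap = first_a - last_b - 1
            else:
                gap = 0
            if gap <= window:
                parent[find(fam_a)] = find(fam_b)
    groups: dict[str, list[str]] = {}
    for f in families:
        groups.setdefault(find(f), []).append(f)
    return tuple(sorted(tuple(sorted(g)) for g in groups.values()))


# ---------------------------------------------------------------------------
# building genomes
# ---------------------------------------------------------------------------


@dataclass
class _Token:
    name: Optional[str]  # canonical gene name; None for filler
    strand: str = "+"
    relabel: bool = False
    pseudo: bool = False
    partial_fraction: Optional[float] = None
    filler_idx: int = 0


def _tokens_from_template(tpl: dict, seed: int) -> list[list[_Token]]:
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xF1])
    contigs: list[list[_Token]] = []
    for contig in tpl["contigs"]:
        row: list[_Token] = []
        for item in contig:
            if "fillers" in item:
                for _ in range(item["fillers"]):
                    row.append(
                        _Token(None, filler_idx=int(rng.integers(_FILLER_POOL_SIZE)))
                    )
            else:
                strand = item.get("strand", "+")
                for gene in item["block"]:
                    if gene == "HP":
                        row.append(
                            _Token(
                                None,
                                strand=strand,
                                filler_idx=int(rng.integers(_FILLER_POOL_SIZE)),
                            )
                        )
                    else:
                        row.append(_Token(gene, strand=strand))
        contigs.append(row)
    return contigs


def _realize(
    genome_id: str,
    token_contigs: list[list[_Token]],
    seed: int,
    mutation_rate: float,
    registry: Registry,
) -> tuple[GenomeAnnotation, dict[str, str]]:
    pool = _filler_pool()
    rescuable: dict[str, str] = {}
    genes: dict[str, list[GeneRecord]] = {}
    contigs: list[tuple[str, int]] = []
    counter = 0
    for ci, row in enumerate(token_contigs):
        cid = f"ctg{ci + 1}"
        records: list[GeneRecord] = []
        pos = 1
        for tok in row:
            counter += 1
            locus = f"{genome_id}_{counter:05d}"
            if tok.name is None:
                seq: Optional[str] = pool[tok.filler_idx]
                product = _HP_PRODUCT
                ftype = "CDS"
            elif tok.name == "tRNA(leu)":
                seq = None
                product = registry.product_of(tok.name)
                ftype = "tRNA"
            else:
                seq = generate_protein_seq(tok.name, seed, mutation_rate)
                product = (
                    _HP_PRODUCT if tok.relabel else registry.product_of(tok.name)
                )
                ftype = "CDS"
            partial = False
            if tok.partial_fraction is not None and seq is not None:
                seq = seq[: max(1, int(len(seq) * tok.partial_fraction))]
                partial = True
            span = 3 * len(seq) + 3 if seq is not None else 85
            rec = GeneRecord(
                genome_id=genome_id,
                contig_id=cid,
                start=pos,
                end=pos + span - 1,
                strand=tok.strand,
                locus_tag=locus,
                product=product,
                pseudo=tok.pseudo,
                partial=partial,
                protein_seq=seq,
                feature_type=ftype,
            )
            records.append(rec)
            if tok.relabel and tok.name is not None:
                rescuable[locus] = tok.name
            pos = rec.end + 1 + _INTERGENIC
        contigs.append((cid, records[-1].end if records else 1))
        genes[cid] = records
    ann = GenomeAnnotation(
        genome_id=genome_id,
        contigs=tuple(contigs),
        genes=genes,
        complete=len(contigs) == 1,
    )
    _set_edges(ann)
    return ann, rescuable


def _set_edges(ann: GenomeAnnotation) -> None:
    for cid, length in ann.contigs:
        for rec in ann.genes.get(cid, []):
            rec.contig_edge = rec.start == 1 or rec.end >= length


def build_from_template(
    name: str,
    seed: int,
    mutation_rate: Optional[float] = None,
    registry: Optional[Registry] = None,
) -> tuple[GenomeAnnotation, PlantedTruth]:
    """Generate a genome (with protein sequences) plus its planted truth."""
    registry = registry or load_registry()
    tpl = _get_template(name)
    rate = tpl.get("mutation_rate", 0.05) if mutation_rate is None else mutation_rate
    token_contigs = _tokens_from_template(tpl, seed)
    flat = [tok for row in token_contigs for tok in row]
    for gene in tpl.get("relabel", ()):
        _first_token(flat, gene).relabel = True
    for gene in tpl.get("pseudo", ()):
        _first_token(flat, gene).pseudo = True
    for gene, frac in tpl.get("partial", {}).items():
        _first_token(flat, gene).partial_fraction = float(frac)
    genome_id = f"{name}_{seed}"
    ann, rescuable = _realize(genome_id, token_contigs, seed, rate, registry)
    truth = derive_truth(ann, rescuable, tpl["variant"], registry)
    return ann, truth


def _first_token(tokens: list[_Token], gene: str) -> _Token:
    for tok in tokens:
        if tok.name == gene:
            return tok
    raise TemplateError(f"gene {gene!r} not present in template")


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Template + seed + ordered perturbation list; fully deterministic."""

    template: str
    seed: int
    mutation_rate: Optional[float] = None
    perturbations: tuple[dict, ...] = ()

    def to_dict(self) -> dict:
        return {
            "template": self.template,
            "seed": self.seed,
            "mutation_rate": self.mutation_rate,
            "perturbations": [dict(p) for p in self.perturbations],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticSpec":
        return cls(
            template=doc["template"],
            seed=int(doc["seed"]),
            mutation_rate=doc.get("mutation_rate"),
            perturbations=tuple(doc.get("perturbations", ())),
        )

    @classmethod
    def from_file(cls, path) -> "SyntheticSpec":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def _find_record(
    ann: GenomeAnnotation, gene: str, registry: Registry, rescuable: dict[str, str]
) -> GeneRecord:
    for rec in ann.all_genes():
        name = registry.canonicalize_gene_name(rec.symbol, rec.product)
        if name is None:
            name = rescuable.get(rec.locus_tag)
        if name == gene:
            return rec
    raise TemplateError(f"perturbation references absent gene {gene!r}")


def _relayout(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Recompute coordinates and contig lengths after structural edits."""
    contigs = []
    for cid, _ in ann.contigs:
        pos = 1
        for rec in ann.genes.get(cid, []):
            span = 3 * len(rec.protein_seq) + 3 if rec.protein_seq else 85
            rec.start, rec.end = pos, pos + span - 1
            pos = rec.end + 1 + _INTERGENIC
        last = ann.genes[cid][-1].end if ann.genes.get(cid) else 1
        contigs.append((cid, last))
    out = GenomeAnnotation(
        genome_id=ann.genome_id,
        contigs=tuple(contigs),
        genes=ann.genes,
        complete=len(contigs) == 1,
    )
    _set_edges(out)
    return out


def perturb(
    annotation: GenomeAnnotation,
    truth: PlantedTruth,
    spec: SyntheticSpec,
    registry: Optional[Registry] = None,
) -> tuple[GenomeAnnotation, PlantedTruth]:
    """Apply the spec's perturbations in order and re-derive the truth."""
    registry = registry or load_registry()
    tpl = _get_template(spec.template)
    rate = (
        tpl.get("mutation_rate", 0.05)
        if spec.mutation_rate is None
        else spec.mutation_rate
    )
    ann = annotation
    rescuable = dict(truth.rescuable)
    pool = _filler_pool()
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 0xC0])
    counter = ann.n_genes()
    for op in spec.perturbations:
        kind = op["op"]
        if kind == "relabel_hp":
            for gene in op["genes"]:
                rec = _find_record(ann, gene, registry, rescuable)
                rec.product = _HP_PRODUCT
                rec.symbol = ""
                rescuable[rec.locus_tag] = gene
        elif kind == "mark_pseudo":
            _find_record(ann, op["gene"], registry, rescuable).pseudo = True
        elif kind == "truncate_partial":
            rec = _find_record(ann, op["gene"], registry, rescuable)
            frac = float(op["fraction"])
            if rec.protein_seq:
                rec.protein_seq = rec.protein_seq[
                    : max(1, int(len(rec.protein_seq) * frac))
                ]
            rec.partial = True
        elif kind == "delete":
            loci = set()
            for gene in op["genes"]:
                loci.add(_find_record(ann, gene, registry, rescuable).locus_tag)
            for cid in list(ann.genes):
                ann.genes[cid] = [
                    r for r in ann.genes[cid] if r.locus_tag not in loci
                ]
        elif kind == "split_at":
            cid = op.get("contig") or ann.contigs[0][0]
            position = int(op["position"])
            row = ann.genes[cid]
            if not 0 <= position <= len(row):
                raise TemplateError(
                    f"split_at position {position} outside contig {cid!r}"
                )
            spacers = []
            for _ in range(int(op["distance"])):
                counter += 1
                idx = int(rng.integers(_FILLER_POOL_SIZE))
                spacers.append(
                    GeneRecord(
                        genome_id=ann.genome_id,
                        contig_id=cid,
                        start=1,
                        end=2,
                        strand="+",
                        locus_tag=f"{ann.genome_id}_x{counter:05d}",
                        product=_HP_PRODUCT,
                        protein_seq=pool[idx],
                    )
                )
            ann.genes[cid] = row[:position] + spacers + row[position:]
        elif kind == "insert":
            cid = op.get("contig") or ann.contigs[0][0]
            position = int(op["position"])
            counter += 1
            gene = op["gene"]
            if gene not in registry.genes:
                raise TemplateError(f"insert references unregistered gene {gene!r}")
            rec = GeneRecord(
                genome_id=ann.genome_id,
                contig_id=cid,
                start=1,
                end=2,
                strand="+",
                locus_tag=f"{ann.genome_id}_x{counter:05d}",
                product=registry.product_of(gene),
                protein_seq=generate_protein_seq(gene, spec.seed, rate),
            )
            row = ann.genes[cid]
            position = min(max(position, 0), len(row))
            ann.genes[cid] = row[:position] + [rec] + row[position:]
        elif kind == "invert":
            cid = op.get("contig") or ann.contigs[0][0]
            lo, hi = int(op["start"]), int(op["end"])
            row = ann.genes[cid]
            if not (0 <= lo <= hi < len(row)):
                raise TemplateError(f"invert range {lo}..{hi} invalid for {cid!r}")
            chunk = row[lo : hi + 1][::-1]
            for r in chunk:
                r.strand = "-" if r.strand == "+" else "+"
            ann.genes[cid] = row[:lo] + chunk + row[hi + 1 :]
        elif kind == "fragment_contigs":
            k = int(op["k"])
            ann = _fragment(ann, k, rng)
        else:
            raise TemplateError(f"unknown perturbation op {kind!r}")
        # re-layout after each structural edit so positions stay consistent
        ann = _relayout(ann)
    new_truth = derive_truth(ann, rescuable, truth.variant, registry)
    return ann, new_truth


def _fragment(ann: GenomeAnnotation, k: int, rng) -> GenomeAnnotation:
    if k <= len(ann.contigs):
        raise TemplateError(
            f"fragment_contigs: k={k} must exceed current contig count "
            f"{len(ann.contigs)}"
        )
    rows = [(cid, list(ann.genes.get(cid, []))) for cid, _ in ann.contigs]
    while len(rows) < k:
        eligible = [i for i, (_c, row) in enumerate(rows) if len(row) >= 2]
        if not eligible:
            break
        i = int(rng.choice(eligible))
        cid, row = rows[i]
        cut = int(rng.integers(1, len(row)))
        rows[i : i + 1] = [(f"{cid}a", row[:cut]), (f"{cid}b", row[cut:])]
    genes = {}
    contigs = []
    for idx, (_old, row) in enumerate(rows):
        cid = f"ctg{idx + 1}"
        for rec in row:
            rec.contig_id = cid
        genes[cid] = row
        contigs.append((cid, 1))
    return GenomeAnnotation(
        genome_id=ann.genome_id,
        contigs=tuple(contigs),
        genes=genes,
        complete=False,
    )


def generate(
    spec: SyntheticSpec, registry: Optional[Registry] = None
) -> tuple[GenomeAnnotation, PlantedTruth]:
    """Build the template genome and apply the spec's perturbations."""
    ann, truth = build_from_template(
        spec.template, spec.seed, spec.mutation_rate, registry
    )
    if spec.perturbations:
        ann, truth = perturb(ann, truth, spec, registry)
    return ann, truth


def random_spec(template: str, seed: int) -> SyntheticSpec:
    """A seeded, always-valid random perturbation spec for property testing."""
    registry = load_registry()
    tpl = _get_template(template)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xA11])
    member_names = {g for m in registry.models_for_variant(tpl["variant"]) for g in m.members}
    present: list[str] = []
    n_tokens = 0
    for contig in tpl["contigs"]:
        for item in contig:
            if "fillers" in item:
                n_tokens += item["fillers"]
            else:
                for gene in item["block"]:
                    n_tokens += 1
                    if gene in member_names and gene != "HP":
                        present.append(gene)
    relabelled = set(tpl.get("relabel", ()))
    used: set[str] = set(relabelled)
    ops: list[dict] = []

    def pick(k: int) -> list[str]:
        avail = [g for g in present if g not in used]
        if not avail:
            return []
        chosen = list(rng.choice(avail, size=min(k, len(avail)), replace=False))
        used.update(chosen)
        return chosen

    # at most one structural edit (applied first: positions refer to the
    # unperturbed gene order), then content edits
    structural = rng.integers(0, 4)
    if structural == 1:
        ops.append(
            {
                "op": "split_at",
                "position": int(rng.integers(1, n_tokens)),
                "distance": int(DEFAULT_GAP_TOLERANCE + 1 + rng.integers(0, 3)),
            }
        )
    elif structural == 2:
        ops.append(
            {
                "op": "insert",
                "gene": str(rng.choice(["Hsp20", "dut", "secY", "gltX"])),
                "position": int(rng.integers(0, n_tokens + 1)),
            }
        )
    elif structural == 3:
        ops.append({"op": "fragment_contigs", "k": int(rng.integers(2, 4))})

    if rng.random() < 0.5:
        genes = pick(int(rng.integers(1, 4)))
        if genes:
            ops.append({"op": "relabel_hp", "genes": genes})
    if rng.random() < 0.4:
        genes = pick(1)
        if genes:
            ops.append({"op": "mark_pseudo", "gene": genes[0]})
    if rng.random() < 0.4:
        genes = pick(1)
        if genes:
            ops.append(
                {
                    "op": "truncate_partial",
                    "gene": genes[0],
                    "fraction": float(np.round(0.25 + 0.2 * rng.random(), 3)),
                }
            )
    if rng.random() < 0.4:
        genes = pick(int(rng.integers(1, 3)))
        if genes:
            ops.append({"op": "delete", "genes": genes})
    return SyntheticSpec(template=template, seed=seed, perturbations=tuple(ops))


# ---------------------------------------------------------------------------
# bundle export
# ---------------------------------------------------------------------------


def write_bundle(
    ann: GenomeAnnotation, truth: PlantedTruth, outdir, formats: tuple[str, ...] = ()
) -> None:
    """Write genome.gff3 + proteins.faa + truth.json (optionally more formats)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.gff3", "w") as fh:
        write_gff3(ann, fh)
    with open(out / "proteins.faa", "w") as fh:
        write_protein_fasta(ann, fh)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    if "feature_table" in formats:
        with open(out / "genome_feature_table.txt", "w") as fh:
            write_feature_table(ann, fh)
    if "genbank" in formats:
        with open(out / "genome.gbk", "w") as fh:
            write_genbank(ann, fh)
    if "json" in formats:
        with open(out / "genome.json", "w") as fh:
            write_annotation_json(ann, fh)
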