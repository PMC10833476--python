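"""Registry of ribosomal-protein gene names, aliases, and canonical cluster models.

The registry is the package's single source of nomenclature.  Gene names follow
the universal r-protein naming scheme (``uS``/``uL`` prefixes for universal
families, ``e``-suffixed names such as ``L32e`` for Archaea/Eukarya-specific
families) plus the non-ribosomal genes that are constitutive members of the
clusters (RNA-polymerase subunits, translation factors, and so on).

Cluster models are grouped into five top-level families:

* ``S10-spc``   -- the large universal block (archaeal core with four
  Archaea-Eukarya-specific additions; bacterial 21-gene S10+spc block;
  archaeal small S10 cluster ``uL3-uL4-uL23-uL2``),
* ``str-L30e``  -- the str cluster and its archaeal L30e-carrying equivalent,
* ``alpha-L18e`` -- the alpha operon and its archaeal L18e-carrying equivalent,
* ``L7ae-S24e`` -- the archaeal L7ae and S24e-S27ae clusters,
* ``L31e-L11``  -- the L31e segment and the L11-L1-L10-L12 cluster.

The registry content ships as an editable JSON document
(``data/registry.json``); this module only validates and serves it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

from .exceptions import RegistryError

CATEGORIES = frozenset(
    {
        "universal-rprotein",
        "archaea-eukarya-rprotein",
        "non-rprotein-cluster-gene",
        "accessory",
    }
)

FAMILIES = (
    "S10-spc",
    "str-L30e",
    "alpha-L18e",
    "L7ae-S24e",
    "L31e-L11",
)

VARIANTS = ("archaeal", "bacterial")


def _norm(text: str) -> str:
    """Whitespace-normalized, case-folded key used for alias matching."""
    return " ".join(text.split()).casefold()


@dataclass(frozen=True)
class GeneName:
    canonical: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RegistryError(
                f"unknown gene category {self.category!r} for {self.canonical!r}"
            )


@dataclass(frozen=True)
class ClusterModel:
    """A named canonical cluster: ordered members, core subset, accessory set."""

    name: str
    family: str
    variant: str
    members: tuple[str, ...]
    core: tuple[str, ...]
    accessory: frozenset[str] = field(default_factory=frozenset)
    primary: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise RegistryError(f"model {self.name!r} has no members")
        if self.family not in FAMILIES:
            raise RegistryError(f"model {self.name!r}: unknown family {self.family!r}")
        if self.variant not in VARIANTS:
            raise RegistryError(f"model {self.name!r}: unknown variant {self.variant!r}")
        if not set(self.core) <= set(self.members):
            raise RegistryError(f"model {self.name!r}: core is not a subset of members")

    def member_index(self, gene: str) -> int:
        return self.members.index(gene)


def model_diff(a: ClusterModel, b: ClusterModel) -> tuple[set[str], set[str]]:
    """Order-insensitive symmetric difference of two models' member sets."""
    sa, sb = set(a.members), set(b.members)
    return sa - sb, sb - sa


class Registry:
    """Gene-name registry, alias table, and cluster-model collection."""

    def __init__(
        self,
        genes: dict[str, str],
        products: dict[str, str],
        aliases: dict[str, str],
        reserved: Iterable[str],
        models: Iterable[ClusterModel],
    ) -> None:
        self.genes: dict[str, GeneName] = {
            name: GeneName(name, cat) for name, cat in genes.items()
        }
        self._products = dict(products)
        self._reserved = frozenset(_norm(r) for r in reserved)
        self.models: tuple[ClusterModel, ...] = tuple(models)

        # alias lookup: canonical names resolve to themselves, then products,
        # then explicit aliases; the mapping must stay many-to-one.
        lookup: dict[str, str] = {}
        for name in self.genes:
            lookup[_norm(name)] = name
        inverted_products = {prod: gene for gene, prod in products.items()}
        for source in (inverted_products, aliases):
            for raw, canonical in source.items():
                if canonical not in self.genes:
                    raise RegistryError(
                        f"alias {raw!r} points at unregistered gene {canonical!r}"
                    )
                key = _norm(raw)
                if key in self._reserved:
                    raise RegistryError(f"alias {raw!r} collides with a reserved label")
                if key in lookup and lookup[key] != canonical:
                    raise RegistryError(
                        f"alias {raw!r} maps to both {lookup[key]!r} and {canonical!r}"
                    )
                lookup[key] = canonical
        self._alias_lookup = lookup

        self._by_key: dict[tuple[str, str], ClusterModel] = {}
        for model in self.models:
            for gene in (*model.members, *model.accessory):
                if gene not in self.genes:
                    raise RegistryError(
                        f"model {model.name!r} references unregistered gene {gene!r}"
                    )
            key = (model.name, model.variant)
            if key in self._by_key:
                raise RegistryError(f"duplicate model {key!r}")
            self._by_key[key] = model

    # -- lookups -----------------------------------------------------------

    def canonicalize_gene_name(
        self, raw_symbol: str, raw_product: str
    ) -> Optional[str]:
        """Resolve a (symbol, product) pair to a canonical gene name.

        Symbol match takes precedence over product match.  Hypothetical-protein
        labels and unknown strings resolve to ``None`` (never an exception);
        the hypothetical-protein label is reserved for the rescue stage.
        """
        for raw in (raw_symbol, raw_product):
            if not raw:
                continue
            key = _norm(raw)
            if key in self._reserved:
                return None
            hit = self._alias_lookup.get(key)
            if hit is not None:
                return hit
        return None

    def is_reserved_label(self, product: str) -> bool:
        return _norm(product) in self._reserved

    def product_of(self, gene: str) -> str:
        """Representative product string for a canonical gene (for writers)."""
        try:
            return self._products[gene]
        except KeyError:
            raise RegistryError(f"no product string registered for {gene!r}") from None

    def get_cluster_model(self, name: str, variant: str) -> ClusterModel:
        try:
            return self._by_key[(name, variant)]
        except KeyError:
            options = ", ".join(sorted(f"{n}/{v}" for n, v in self._by_key))
            raise RegistryError(
                f"unknown cluster model {name!r} (variant {variant!r}); "
                f"registered models: {options}"
            ) from None

    def models_for_variant(self, variant: str) -> tuple[ClusterModel, ...]:
        if variant not in VARIANTS:
            raise RegistryError(
                f"unknown variant {variant!r}; expected one of {VARIANTS}"
            )
        return tuple(m for m in self.models if m.variant == variant)

    def primary_model(self, family: str, variant: str) -> Optional[ClusterModel]:
        for m in self.models:
            if m.family == family and m.variant == variant and m.primary:
                return m
        return None

    @property
    def families(self) -> tuple[str, ...]:
        return FAMILIES

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "Registry":
        models = [
            ClusterModel(
                name=m["name"],
                family=m["family"],
                variant=m["variant"],
                members=tuple(m["members"]),
                core=tuple(m["core"]),
                accessory=frozenset(m.get("accessory", ())),
                primary=bool(m.get("primary", False)),
            )
            for m in doc["models"]
        ]
        return cls(
            genes=doc["genes"],
            products=doc.get("products", {}),
            aliases=doc.get("aliases", {}),
            reserved=doc.get("reserved", ()),
            models=models,
        )

    @classmethod
    def from_json(cls, path) -> "Registry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@lru_cache(maxsize=1)
def load_registry() -> Registry:
    """The packaged default registry (cached)."""
    text = resources.files("rpclustermap.data").joinpath("registry.json").read_text()
    return Registry.from_dict(json.loads(text))
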