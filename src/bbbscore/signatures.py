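"""Gene-set management: GMT IO, signature selection, measurement filtering.

Cell-type signatures (endothelial cells, astrocytes, pericytes, microglia,
neurons, oligodendrocytes) drive the infiltration scores; stromal/immune
sets feed the purity estimate; an extracellular-matrix list and
immune-checkpoint gene pairs feed the downstream ranking and checkpoint
scores.  When a resource ships several signature variants for one cell type
(as xCell does), the variant with the most genes is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator

VALID_CATEGORIES = ("cell_type", "stromal", "immune", "ecm", "checkpoint", "other")


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty collection of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]
    category: str = "other"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            # dedup preserving first occurrence
            seen: dict[str, None] = dict.fromkeys(self.genes)
            object.__setattr__(self, "genes", tuple(seen))
        if self.category not in VALID_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class SignatureCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet]
    source: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set names: {dupes[:5]!r}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass(frozen=True)
class GenePairList:
    """Ordered (gene_A, gene_B) pairs for quotient-based checkpoint scoring."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"pair with identical genes: {a!r}")

    def __len__(self) -> int:
        return len(self.pairs)


def read_gmt(path) -> SignatureCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are deduplicated; a line with no genes or a
    repeated set name is an error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, description, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=tuple(genes), description=description))
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return SignatureCollection(sets, source=str(path))


def write_gmt(collection: SignatureCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def _normalize(name: str) -> str:
    return name.strip().lower().replace("_", " ")


def select_largest_signature(
    collection: SignatureCollection, cell_type: str
) -> GeneSet:
    """Return the largest signature whose name matches a cell type.

    Matching is a case-insensitive prefix match on the cell-type token
    (resources name signature variants like ``Astrocytes_SOURCE_1``).  Among
    matches the set with the most genes wins; ties break lexicographically by
    set name so the choice is independent of collection order.
    """
    token = _normalize(cell_type)
    matches = [s for s in collection if _normalize(s.name).startswith(token)]
    if not matches:
        raise KeyError(f"no signature matching cell type {cell_type!r}")
    return min(matches, key=lambda s: (-len(s), s.name))


def restrict_to_measured(
    gene_set: GeneSet, matrix, min_genes: int = 1
) -> GeneSet:
    """Intersect a gene set with the genes measured in an expression matrix.

    Order of the original set is preserved.  Raises when fewer than
    ``min_genes`` members are measured, since an under-covered signature
    yields meaningless enrichment.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    measured = set(matrix.gene_ids)
    kept = tuple(g for g in gene_set.genes if g in measured)
    if len(kept) < min_genes:
        raise ValueError(
            f"set {gene_set.name!r}: only {len(kept)}/{len(gene_set)} genes "
            f"measured (min_genes={min_genes})"
        )
    return GeneSet(gene_set.name, kept, gene_set.category, gene_set.description)


def read_gene_pairs(path, expected_pairs: int | None = None) -> GenePairList:
    """Read a two-column TSV of (gene_A, gene_B) pairs, header included."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"empty pair file: {path}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((parts[0], parts[1]))
    if expected_pairs is not None and len(pairs) != expected_pairs:
        raise ValueError(
            f"{path}: expected {expected_pairs} pairs, found {len(pairs)}"
        )
    return GenePairList(tuple(pairs))


def load_bundled(name: str):
    """Return the path of a bundled fixture file (editable defaults).

    Available fixtures: ``cell_type_signatures.gmt``,
    ``stromal_immune_signatures.gmt``, ``ecm_genes_synthetic.gmt``,
    ``checkpoint_genes.gmt``, ``impres_pairs_synthetic.tsv``.
    """
    ref = resources.files("bbbscore.data").joinpath(name)
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled fixture named {name!r}")
    return ref
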