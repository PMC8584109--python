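"""Gene-set collections in GMT format.

GMT is the tab-separated format MSigDB uses to distribute gene-set
collections: one set per line as ``name<TAB>description<TAB>gene1<TAB>...``.
A :class:`GeneSetCollection` keeps pathways in file order and member genes as
ordered, duplicate-free lists of symbols.  Symbols are matched case-sensitively
as exact strings; no alias resolution is attempted, so the same symbol
convention must be used in the expression matrix and the GMT file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "intersect_with_universe",
]


@dataclass
class GeneSetCollection:
    """Named, ordered collection of gene sets (pathways).

    Parameters
    ----------
    name
        Collection label (e.g. ``"c2.reactome"``); carried through reports.
    sets
        Ordered mapping from pathway name to its member gene symbols.
        Within-set duplicates are removed keeping first occurrence.
    """

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for pw, genes in self.sets.items():
            seen: set[str] = set()
            members = [g for g in genes if not (g in seen or seen.add(g))]
            if not members:
                raise ValueError(f"pathway {pw!r} has no member genes")
            clean[pw] = members
        self.sets = clean

    @property
    def pathway_names(self) -> list[str]:
        return list(self.sets)

    @property
    def n_pathways(self) -> int:
        return len(self.sets)

    @property
    def n_edges(self) -> int:
        """Total number of (gene, pathway) membership pairs."""
        return sum(len(m) for m in self.sets.values())

    def gene_universe(self) -> list[str]:
        """Sorted union of all member symbols."""
        return sorted({g for m in self.sets.values() for g in m})

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, pathway: str) -> list[str]:
        return self.sets[pathway]

    def __contains__(self, pathway: str) -> bool:
        return pathway in self.sets


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each non-blank line needs at least three tab-separated fields
    (name, description, one or more genes); the description is discarded.
    Raises ``ValueError`` naming the offending line on malformed input or a
    duplicate pathway name.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed GMT line "
                    f"({len(fields)} fields, need >= 3)"
                )
            pw = fields[0]
            if pw in sets:
                raise ValueError(f"{path.name}:{lineno}: duplicate pathway name {pw!r}")
            genes = [g for g in fields[2:] if g]
            seen: set[str] = set()
            sets[pw] = [g for g in genes if not (g in seen or seen.add(g))]
            if not sets[pw]:
                raise ValueError(f"{path.name}:{lineno}: pathway {pw!r} has no genes")
    return GeneSetCollection(name=name or path.stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    """Write a collection in GMT format (UTF-8, tab-separated, no quoting)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for pw, genes in collection.sets.items():
            fh.write("\t".join([pw, description, *genes]) + "\n")


def intersect_with_universe(
    collection: GeneSetCollection, universe: Sequence[str] | Iterable[str]
) -> tuple[GeneSetCollection, list[str]]:
    """Restrict a collection to the genes measured in an expression matrix.

    Each pathway's member list is intersected with ``universe`` (preserving
    member order); pathways left empty are dropped.  Returns the reduced
    collection and the sorted union of surviving members — the gene list that
    becomes the model input for this collection.

    Raises ``ValueError`` if the universe is empty or no pathway survives.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("gene universe is empty")
    sets: dict[str, list[str]] = {}
    for pw, genes in collection.sets.items():
        kept = [g for g in genes if g in uni]
        if kept:
            sets[pw] = kept
    if not sets:
        raise ValueError(
            f"collection {collection.name!r} has no overlap with the gene universe"
        )
    reduced = GeneSetCollection(name=collection.name, sets=sets)
    return reduced, reduced.gene_universe()
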