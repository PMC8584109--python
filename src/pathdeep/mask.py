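"""Gene-to-pathway membership masks and their random-linked null counterpart."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gmt import GeneSetCollection

__all__ = ["MembershipMask", "build_mask", "randomize_mask", "full_mask"]


@dataclass
class MembershipMask:
    """Binary genes x pathways matrix fixing which first-layer weights may be nonzero.

    Entry (j, i) is 1 iff gene j may connect to pathway node i.  Biological
    masks transcribe gene-set membership and have no empty rows or columns;
    random-linked masks conserve only the total edge count, so zero-degree
    rows/columns are permitted there.
    """

    matrix: np.ndarray
    gene_order: list[str]
    pathway_order: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("mask matrix must be 2-D (genes x pathways)")
        if self.matrix.shape != (len(self.gene_order), len(self.pathway_order)):
            raise ValueError("mask shape does not match gene/pathway orders")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pathways(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.gene_order,
                     columns=self.pathway_order).to_csv(path, sep="\t")


def build_mask(collection: GeneSetCollection, gene_order: list[str]) -> MembershipMask:
    """Transcribe gene-set membership into a binary mask.

    Rows follow ``gene_order``, columns follow the collection's pathway order.
    Every collection member must appear in ``gene_order`` (intersect the
    collection with the dataset's gene universe first).
    """
    pos = {g: j for j, g in enumerate(gene_order)}
    m = np.zeros((len(gene_order), collection.n_pathways), dtype=np.int8)
    for i, (pw, genes) in enumerate(collection.sets.items()):
        for g in genes:
            if g not in pos:
                raise KeyError(
                    f"gene {g!r} of pathway {pw!r} absent from gene_order"
                )
            m[pos[g], i] = 1
    return MembershipMask(matrix=m, gene_order=list(gene_order),
                          pathway_order=collection.pathway_names)


def randomize_mask(mask: MembershipMask, seed: int) -> MembershipMask:
    """Degree-total-conserving random-linked null mask.

    Places exactly ``mask.n_edges`` ones uniformly at random without
    replacement over all (gene, pathway) cells; only the total link count is
    conserved, not per-gene or per-pathway degrees.
    """
    n_cells = mask.n_genes * mask.n_pathways
    e = mask.n_edges
    if e > n_cells:
        raise ValueError(f"edge count {e} exceeds cell count {n_cells}")
    rng = np.random.default_rng(seed)
    flat = np.zeros(n_cells, dtype=np.int8)
    flat[rng.choice(n_cells, size=e, replace=False)] = 1
    return MembershipMask(matrix=flat.reshape(mask.matrix.shape),
                          gene_order=list(mask.gene_order),
                          pathway_order=list(mask.pathway_order))


def full_mask(n_inputs: int, width: int,
              gene_order: list[str] | None = None) -> MembershipMask:
    """All-ones mask: the masked layer degenerates to a dense layer."""
    genes = gene_order if gene_order is not None else [f"x{j}" for j in range(n_inputs)]
    units = [f"unit_{i}" for i in range(width)]
    return MembershipMask(matrix=np.ones((n_inputs, width), dtype=np.int8),
                          gene_order=list(genes), pathway_order=units)
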