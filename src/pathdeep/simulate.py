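"""Synthetic expression fixtures with a plantable pathway-level class signal.

The generator emulates the stage of the pipeline the classifier actually
consumes: continuous expression on the standardized scale, a binary phenotype,
and four pseudo-project strata.  Baseline values are i.i.d. Gaussian per gene;
for case samples, every gene belonging to a designated *signal pathway*
receives an additive mean shift of ``effect_size * noise_sd``.  A convenience
wrapper emits strictly monotone-transformed positive-scale values shaped like
log2(FPKM + 0.001) for I/O round-trip tests.

What it does not emulate: count noise, gene-gene correlation beyond the shared
class shift, library-size or batch effects, tissue-specific structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset
from .gmt import GeneSetCollection

__all__ = ["FixtureSpec", "generate_collection", "generate_expression",
           "generate_fpkm_like"]

PSEUDO_PROJECTS = ("proj_A", "proj_B", "proj_C", "proj_D")


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    ``genes_per_pathway`` is an inclusive (low, high) size range; members are
    sampled without replacement per pathway, overlap across pathways allowed.
    ``signal_pathways`` lists generated pathway names (``PW_0001`` ...) whose
    member genes carry the class shift of ``effect_size * noise_sd``.
    ``class_balance`` is the fraction of case (label 1) samples.
    """

    n_samples: int = 500
    n_genes: int = 200
    n_pathways: int = 20
    genes_per_pathway: tuple[int, int] = (5, 20)
    signal_pathways: tuple[str, ...] = ("PW_0001",)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_pathways) < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.genes_per_pathway
        if not 1 <= lo <= hi:
            raise ValueError("genes_per_pathway range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("genes_per_pathway max exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        self.signal_pathways = tuple(self.signal_pathways)
        unknown = set(self.signal_pathways) - set(self.pathway_names())
        if unknown:
            raise ValueError(f"signal_pathways not among generated names: {sorted(unknown)}")

    def gene_names(self) -> list[str]:
        return [f"GENE_{j + 1:05d}" for j in range(self.n_genes)]

    def pathway_names(self) -> list[str]:
        return [f"PW_{i + 1:04d}" for i in range(self.n_pathways)]


def _rngs(spec: FixtureSpec) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(2)
    return np.random.default_rng(child[0]), np.random.default_rng(child[1])


def generate_collection(spec: FixtureSpec) -> GeneSetCollection:
    """Random gene-set collection: sizes uniform in the requested range,
    members sampled without replacement per set; deterministic from seed."""
    rng, _ = _rngs(spec)
    genes = spec.gene_names()
    lo, hi = spec.genes_per_pathway
    sets: dict[str, list[str]] = {}
    for pw in spec.pathway_names():
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(spec.n_genes, size=size, replace=False)
        sets[pw] = [genes[j] for j in sorted(members)]
    return GeneSetCollection(name="synthetic", sets=sets)


def _labels_groups(spec: FixtureSpec, rng: np.random.Generator
                   ) -> tuple[np.ndarray, list[str]]:
    n1 = int(round(spec.class_balance * spec.n_samples))
    n1 = min(max(n1, 1), spec.n_samples - 1)  # keep both classes
    labels = np.zeros(spec.n_samples, dtype=int)
    labels[rng.choice(spec.n_samples, size=n1, replace=False)] = 1
    groups = [PSEUDO_PROJECTS[i % len(PSEUDO_PROJECTS)]
              for i in range(spec.n_samples)]
    return labels, groups


def generate_expression(spec: FixtureSpec,
                        collection: GeneSetCollection) -> ExpressionDataset:
    """Gaussian expression with an additive class shift on signal-pathway genes."""
    missing = [pw for pw in spec.signal_pathways if pw not in collection]
    if missing:
        raise ValueError(f"signal pathways not in collection: {missing}")
    _, rng = _rngs(spec)
    labels, groups = _labels_groups(spec, rng)
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))

    genes = spec.gene_names()
    pos = {g: j for j, g in enumerate(genes)}
    signal_cols = sorted({pos[g] for pw in spec.signal_pathways
                          for g in collection[pw]})
    if signal_cols and spec.effect_size > 0:
        shift = spec.effect_size * spec.noise_sd
        values[np.ix_(labels == 1, signal_cols)] += shift

    sample_ids = [f"S{i + 1:05d}" for i in range(spec.n_samples)]
    return ExpressionDataset(values=values, gene_symbols=genes,
                             sample_ids=sample_ids, labels=labels,
                             groups=groups)


def generate_fpkm_like(spec: FixtureSpec,
                       collection: GeneSetCollection) -> ExpressionDataset:
    """Positive-scale variant shaped like log2(FPKM + 0.001).

    Applies log2(2^(a + b*z) + 0.001) to the standardized-scale values z, a
    strictly monotone per-gene transform giving a realistic dynamic range for
    I/O and standardization tests; the class signal is preserved.
    """
    base = generate_expression(spec, collection)
    values = np.log2(np.exp2(3.0 + 1.5 * base.values) + 0.001)
    return ExpressionDataset(values=values, gene_symbols=base.gene_symbols,
                             sample_ids=base.sample_ids, labels=base.labels,
                             groups=base.groups)
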