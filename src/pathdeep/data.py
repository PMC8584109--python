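"""Labeled expression matrices, sample-wise standardization, stratified splits.

The expected input is a samples x genes matrix of continuous expression values
(e.g. log2(FPKM + 0.001)) with gene-symbol column names, a binary phenotype
label per sample (1 = cancer, 0 = normal) and an optional per-sample group tag
(project / tissue) used as an extra stratification factor.

Standardization is sample-wise: each sample row is centred and scaled by its
own mean and standard deviation over ALL measured genes, before any pathway
subsetting.  Splits are repeated stratified half-splits: within every
(label x group) cell half the samples go to train (floor) and the remainder to
test, so e.g. 19,131 samples yield a 9,565 / 9,566 partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SplitPlan",
    "standardize_samplewise",
    "make_split_plan",
    "subset_genes",
    "read_expression_tsv",
    "read_labels_tsv",
]


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with labels and optional strata.

    Attributes
    ----------
    values : (n_samples, n_genes) float array
    gene_symbols : column names, one per gene
    sample_ids : row names, one per sample
    labels : int array in {0, 1}; 1 = case (cancer), 0 = control (normal)
    groups : optional per-sample stratum tag (project / tissue)
    """

    values: np.ndarray
    gene_symbols: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_symbols = list(self.gene_symbols)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n, g = self.values.shape
        if len(self.gene_symbols) != g:
            raise ValueError(
                f"{len(self.gene_symbols)} gene symbols for {g} matrix columns"
            )
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids and labels must match the row count")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        if self.groups is not None:
            self.groups = list(self.groups)
            if len(self.groups) != n:
                raise ValueError("groups must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        labels: Sequence[int] | pd.Series,
        groups: Sequence[str] | None = None,
        name_order_check: bool = True,
    ) -> "ExpressionDataset":
        """Build from a samples x genes DataFrame (index = sample IDs)."""
        if isinstance(labels, pd.Series) and name_order_check:
            labels = labels.reindex(frame.index)
            if labels.isna().any():
                missing = labels.index[labels.isna()].tolist()
                raise ValueError(f"labels missing for samples: {missing[:5]}")
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_symbols=[str(c) for c in frame.columns],
            sample_ids=[str(i) for i in frame.index],
            labels=np.asarray(labels, dtype=int),
            groups=list(groups) if groups is not None else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.gene_symbols)

    def with_labels(self, labels: np.ndarray) -> "ExpressionDataset":
        """Shallow copy with a replaced label vector (used by permutations)."""
        return replace(self, labels=np.asarray(labels, dtype=int))


@dataclass
class SplitPlan:
    """Repeated stratified half-splits, reproducible from ``seed``."""

    repeats: list[tuple[list[int], list[int]]]
    seed: int
    n_samples: int = 0

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_samples": self.n_samples,
            "repeats": [
                {"train": list(map(int, tr)), "test": list(map(int, te))}
                for tr, te in self.repeats
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        repeats = [(r["train"], r["test"]) for r in payload["repeats"]]
        return cls(repeats=repeats, seed=payload["seed"],
                   n_samples=payload.get("n_samples", 0))


def standardize_samplewise(data: ExpressionDataset) -> ExpressionDataset:
    """Z-score each sample over all genes (row mean 0, row sd 1, ddof=1).

    This is performed on the full measured gene set *before* any pathway
    subsetting, so downstream gene selection does not change the values.
    Raises ``ValueError`` naming the sample for any constant row.
    """
    mu = data.values.mean(axis=1, keepdims=True)
    sd = data.values.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        names = [data.sample_ids[i] for i in bad[:5]]
        raise ValueError(f"constant expression row(s), cannot standardize: {names}")
    return replace(data, values=(data.values - mu) / sd)


def _split_cell(indices: np.ndarray, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    # half to train (floor), remainder to test: 19131 -> 9565 / 9566
    perm = rng.permutation(indices)
    n_train = len(indices) // 2
    return perm[:n_train], perm[n_train:]


def make_split_plan(data: ExpressionDataset, n_repeats: int = 20,
                    seed: int = 0) -> SplitPlan:
    """Repeated stratified half-splits of the samples.

    Stratification cells are (label x group) when group tags are present,
    otherwise label alone.  Within each cell, ``floor(n/2)`` samples are
    assigned to train and the remainder to test, independently per repeat.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    labels = data.labels
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both label classes must be present to split")
    if data.groups is not None:
        keys = [f"{l}\x00{g}" for l, g in zip(labels, data.groups)]
    else:
        keys = [str(l) for l in labels]
    cells: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        cells.setdefault(k, []).append(i)

    rng = np.random.default_rng(seed)
    repeats: list[tuple[list[int], list[int]]] = []
    for _ in range(n_repeats):
        train: list[int] = []
        test: list[int] = []
        for k in sorted(cells):
            tr, te = _split_cell(np.asarray(cells[k]), rng)
            train.extend(tr.tolist())
            test.extend(te.tolist())
        repeats.append((sorted(train), sorted(test)))
    return SplitPlan(repeats=repeats, seed=seed, n_samples=data.n_samples)


def subset_genes(data: ExpressionDataset, genes: Sequence[str]) -> ExpressionDataset:
    """Restrict and reorder columns to ``genes``; values are not re-standardized."""
    pos = {g: j for j, g in enumerate(data.gene_symbols)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise KeyError(f"genes absent from dataset: {missing[:10]}"
                       + (" ..." if len(missing) > 10 else ""))
    cols = [pos[g] for g in genes]
    return replace(data, values=data.values[:, cols], gene_symbols=list(genes))


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix: header = gene symbols, first column = sample ID."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    """Read a two/three-column TSV: sample ID, label, optional group."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in frame.columns:
        raise ValueError("labels file must have a 'label' column")
    return frame
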