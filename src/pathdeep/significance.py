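"""Label-permutation significance test for phenotype-associated pathways.

For each pathway the observed statistic is the difference of class-mean
pathway indices (mean over case samples minus mean over control samples).
Its null distribution comes from label permutation: the training-fold labels
are shuffled, the masked network is retrained on the shuffled labels, pathway
indices are recomputed, and the class difference is re-measured — repeated
``n_perm`` times.  The observed difference is then z-tested against the
per-pathway permutation mean and sd, and Benjamini-Hochberg FDR q-values are
computed across pathways.

Retraining per permutation is the reference procedure.  A fast mode that
trains once and only re-labels the index matrix is provided for exploration;
it is NOT the reference procedure and underestimates the null spread
contributed by refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset
from .gmt import GeneSetCollection
from .interpret import pathway_index
from .model import PathDeep, TrainConfig

__all__ = [
    "PathwaySignificanceTable",
    "observed_group_difference",
    "permutation_null",
    "significance_test",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwaySignificanceTable:
    """Per-pathway permutation z-test results.

    ``table`` columns: pathway, observed_diff, null_mean, null_sd, z, p, q,
    significant — sorted by q then p ascending.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> list[str]:
        return self.table.loc[self.table["significant"], "pathway"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def observed_group_difference(indices: pd.DataFrame,
                              labels: Sequence[int]) -> pd.Series:
    """Per-pathway mean index in class 1 minus mean index in class 0."""
    labels = np.asarray(list(labels), dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes must be present")
    return indices[labels == 1].mean(axis=0) - indices[labels == 0].mean(axis=0)


def permutation_null(
    data: ExpressionDataset,
    collection: GeneSetCollection,
    train_idx: Sequence[int],
    n_perm: int = 1000,
    config: TrainConfig | None = None,
    seed: int = 0,
    retrain: bool = True,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 50,
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Per-pathway permutation-null mean and sd of the class-mean difference.

    Each permutation shuffles the labels of the training fold (class counts
    preserved), retrains a fresh-seeded model on the shuffled labels
    (``retrain=True``, the reference procedure), recomputes pathway indices on
    the training fold and records the class difference under the shuffled
    labels.  Returns (null_mean, null_sd, all null differences), the sd using
    ddof=1.  Fully reproducible from ``seed``.

    With ``checkpoint_path`` set, accumulated null differences are written to
    TSV every ``checkpoint_every`` permutations so long runs can be inspected
    or resumed externally.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    config = config or TrainConfig()
    train_idx = np.asarray(list(train_idx), dtype=int)
    base_labels = data.labels[train_idx]
    if len(np.unique(base_labels)) < 2:
        raise ValueError("training fold must contain both classes")

    rng = np.random.default_rng(seed)
    model_seeds = np.random.SeedSequence(seed).generate_state(n_perm) % (2 ** 31)

    if not retrain:
        fixed = PathDeep.from_collection(
            data, collection, head_spec=config.head_spec,
            seed=int(model_seeds[0])).fit(train_idx, config)
        fixed_idx = pathway_index(fixed).loc[
            [data.sample_ids[i] for i in train_idx]]

    diffs: list[pd.Series] = []
    for k in range(n_perm):
        shuffled = rng.permutation(base_labels)
        if retrain:
            perm_labels = data.labels.copy()
            perm_labels[train_idx] = shuffled
            perm_data = data.with_labels(perm_labels)
            res = PathDeep.from_collection(
                perm_data, collection, head_spec=config.head_spec,
                seed=int(model_seeds[k])).fit(train_idx, config)
            idx = pathway_index(res).loc[
                [data.sample_ids[i] for i in train_idx]]
        else:
            idx = fixed_idx
        diffs.append(observed_group_difference(idx, shuffled))
        logger.debug("permutation %d/%d done", k + 1, n_perm)
        if checkpoint_path is not None and (k + 1) % checkpoint_every == 0:
            pd.DataFrame(diffs).to_csv(checkpoint_path, sep="\t", index=False)

    null = pd.DataFrame(diffs).reset_index(drop=True)
    if checkpoint_path is not None:
        null.to_csv(checkpoint_path, sep="\t", index=False)
    return null.mean(axis=0), null.std(axis=0, ddof=1), null


def significance_test(
    observed: pd.Series | Sequence[float],
    null_mean: pd.Series | Sequence[float],
    null_sd: pd.Series | Sequence[float],
    alpha: float = 0.05,
    alternative: str = "two-sided",
    pathway_order: Sequence[str] | None = None,
) -> PathwaySignificanceTable:
    """Z-test each pathway's observed difference against its permutation null.

    p-values are two-sided normal tails by default (``"greater"`` gives the
    one-sided upper tail); q-values are Benjamini-Hochberg across all
    pathways.  A pathway with zero null sd gets p = 1 and a warning, since no
    spread was observed under permutation.  The returned table is sorted by
    q then p ascending and flags pathways with q < alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if isinstance(observed, pd.Series) and pathway_order is None:
        pathway_order = list(observed.index)
    observed = np.asarray(observed, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    null_sd = np.asarray(null_sd, dtype=float)
    if not (observed.shape == null_mean.shape == null_sd.shape):
        raise ValueError("observed, null_mean and null_sd must be conformable")
    if pathway_order is None:
        pathway_order = [f"pathway_{i}" for i in range(observed.size)]

    z = np.full(observed.shape, np.nan)
    ok = null_sd > 0
    z[ok] = (observed[ok] - null_mean[ok]) / null_sd[ok]
    if (~ok).any():
        bad = [pathway_order[i] for i in np.flatnonzero(~ok)[:5]]
        warnings.warn(f"zero permutation-null sd, p set to 1 for: {bad}",
                      stacklevel=2)
        logger.warning("zero null sd for %d pathway(s)", int((~ok).sum()))
    if alternative == "two-sided":
        p = np.where(ok, 2 * stats.norm.sf(np.abs(z)), 1.0)
    elif alternative == "greater":
        p = np.where(ok, stats.norm.sf(z), 1.0)
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    p = np.clip(p, 0.0, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")

    table = pd.DataFrame({
        "pathway": list(pathway_order),
        "observed_diff": observed,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "z": z,
        "p": p,
        "q": q,
        "significant": q < alpha,
    }).sort_values(["q", "p"], ascending=True, kind="mergesort").reset_index(drop=True)
    return PathwaySignificanceTable(table=table, alpha=alpha)
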