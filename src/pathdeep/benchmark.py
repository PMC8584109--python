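"""Training benchmarks: repeated-split accuracy and the random-linked null screen.

The architecture screen asks whether a gene-set collection's membership
structure carries information beyond its connection density: the biological
mask is trained once per collection and compared, by a one-sample z-test, to
the accuracy distribution of ``n_null`` *random-linked* models whose masks
conserve the total edge count but scatter the edges uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset, standardize_samplewise, subset_genes
from .gmt import GeneSetCollection, intersect_with_universe
from .mask import build_mask, randomize_mask
from .model import PathDeep, PathDeepResults, TrainConfig

__all__ = [
    "AccuracyReport",
    "train",
    "evaluate_accuracy",
    "null_accuracy_ztest",
    "run_collection_screen",
    "compare_accuracy_lists",
    "sample_train_configs",
]

logger = logging.getLogger(__name__)


@dataclass
class AccuracyReport:
    """Per-repeat test accuracies with their mean and sd (ddof=1)."""

    accuracies: list[float]
    mean: float
    sd: float

    @classmethod
    def from_accuracies(cls, accuracies: Sequence[float]) -> "AccuracyReport":
        acc = [float(a) for a in accuracies]
        mean = float(np.mean(acc))
        sd = float(np.std(acc, ddof=1)) if len(acc) > 1 else float("nan")
        return cls(accuracies=acc, mean=mean, sd=sd)


def train(model: PathDeep, train_idx: Sequence[int],
          config: TrainConfig | None = None) -> PathDeepResults:
    """Functional alias for :meth:`PathDeep.fit`."""
    return model.fit(train_idx, config)


def evaluate_accuracy(results: PathDeepResults, test_idx: Sequence[int],
                      data: ExpressionDataset | None = None,
                      threshold: float = 0.5) -> float:
    """Functional alias for :meth:`PathDeepResults.accuracy`."""
    return results.accuracy(test_idx, data=data, threshold=threshold)


def null_accuracy_ztest(observed_accuracy: float,
                        null_accuracies: Sequence[float],
                        alternative: str = "greater") -> tuple[float, float]:
    """One-sample z-test of an observed accuracy against a null sample.

    ``z = (observed - mean(null)) / sd(null)`` with the n-1 sd convention.
    The default alternative is one-sided upper tail (the masked architecture
    is hypothesised to beat its random-linked null); ``"two-sided"`` is
    available.
    """
    null = np.asarray(list(null_accuracies), dtype=float)
    if null.size < 2:
        raise ValueError("need at least 2 null accuracies")
    sd = null.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(null.mean())):
        raise ValueError("null accuracies have zero standard deviation")
    z = float((observed_accuracy - null.mean()) / sd)
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return z, p


def run_collection_screen(
    data: ExpressionDataset,
    collections: Sequence[GeneSetCollection],
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    n_null: int = 100,
    config: TrainConfig | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> pd.DataFrame:
    """Screen gene-set collections by biological-vs-random-linked accuracy.

    For every collection: standardize the full matrix sample-wise (once,
    before any subsetting), restrict genes to the collection's surviving
    members, train one biological-mask model and ``n_null`` random-linked
    models (fresh mask seed each), and z-test the biological accuracy against
    the null accuracies.  Returns a table sorted by ascending p.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    config = config or TrainConfig()
    base = standardize_samplewise(data) if standardize else data
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_null + 1) % (2 ** 31)
    rows = []
    for c, coll in enumerate(collections):
        reduced, retained = intersect_with_universe(coll, base.gene_symbols)
        sub = subset_genes(base, retained)
        bio_mask = build_mask(reduced, retained)
        bio = PathDeep(sub, bio_mask, head_spec=config.head_spec,
                       seed=int(seeds[0]) + c).fit(train_idx, config)
        acc = bio.accuracy(test_idx)
        null_accs = []
        for k in range(n_null):
            rl_mask = randomize_mask(bio_mask, seed=int(seeds[1 + k]) + c)
            rl = PathDeep(sub, rl_mask, head_spec=config.head_spec,
                          seed=int(seeds[1 + n_null + k]) + c).fit(train_idx, config)
            null_accs.append(rl.accuracy(test_idx))
            logger.debug("collection=%s null=%d acc=%.4f", coll.name, k, null_accs[-1])
        z, p = null_accuracy_ztest(acc, null_accs)
        rows.append({
            "collection": coll.name,
            "n_pathways": reduced.n_pathways,
            "n_genes": len(retained),
            "accuracy": acc,
            "null_mean": float(np.mean(null_accs)),
            "null_sd": float(np.std(null_accs, ddof=1)),
            "z": z,
            "p": p,
        })
    return (pd.DataFrame(rows)
            .sort_values("p", ascending=True, kind="mergesort")
            .reset_index(drop=True))


def compare_accuracy_lists(a: Sequence[float], b: Sequence[float]
                           ) -> tuple[float, float]:
    """Welch's t-test between two repeated-run accuracy lists; returns (t, p)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=False)
    return float(t), float(p)


def sample_train_configs(n: int, seed: int = 0,
                         max_epochs: int = 200) -> list[TrainConfig]:
    """Seeded random hyperparameter draws (head widths, learning rate, batch)."""
    rng = np.random.default_rng(seed)
    widths1 = [64, 128, 256]
    widths2 = [16, 32, 64]
    batches = [16, 32, 64]
    configs = []
    for k in range(n):
        lr = float(10 ** rng.uniform(-4, -2))
        configs.append(TrainConfig(
            learning_rate=lr,
            batch_size=int(rng.choice(batches)),
            max_epochs=max_epochs,
            head_spec=(int(rng.choice(widths1)), int(rng.choice(widths2)), 1),
            seed=int(rng.integers(0, 2 ** 31)),
        ))
    return configs
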