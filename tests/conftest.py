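import numpy as np
import pytest

from pathdeep import (ExpressionDataset, FixtureSpec, GeneSetCollection,
                      generate_collection, generate_expression,
                      standardize_samplewise)


@pytest.fixture
def tiny_collection() -> GeneSetCollection:
    return GeneSetCollection(name="tiny", sets={"PW1": ["G1", "G2"],
                                                "PW2": ["G2", "G3"]})


def random_dataset(n_samples: int, n_genes: int, seed: int = 0,
                   groups: bool = False) -> ExpressionDataset:
    """Unstructured Gaussian dataset with balanced random labels."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_samples, dtype=int)
    labels[rng.choice(n_samples, size=n_samples // 2, replace=False)] = 1
    return ExpressionDataset(
        values=rng.normal(size=(n_samples, n_genes)),
        gene_symbols=[f"G{j + 1}" for j in range(n_genes)],
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        labels=labels,
        groups=[f"grp{i % 4}" for i in range(n_samples)] if groups else None,
    )


def planted_fixture(seed: int = 0, n_samples: int = 500, n_genes: int = 200,
                    n_pathways: int = 20, effect_size: float = 1.0,
                    signal=("PW_0001",), standardize: bool = True):
    """Standardized planted-signal dataset + its collection and spec."""
    spec = FixtureSpec(n_samples=n_samples, n_genes=n_genes,
                       n_pathways=n_pathways, genes_per_pathway=(5, 20),
                       signal_pathways=tuple(signal),
                       effect_size=effect_size, seed=seed)
    coll = generate_collection(spec)
    data = generate_expression(spec, coll)
    if standardize:
        data = standardize_samplewise(data)
    return spec, coll, data
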