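import numpy as np
import pytest

from pathdeep import (ExpressionDataset, GeneSetCollection, PathDeep,
                      TrainConfig, build_mask, contribution_index, full_mask,
                      make_split_plan, pathway_index, select_top_fraction,
                      subset_retrain_experiment)

from conftest import planted_fixture, random_dataset


def results_with_weights(values, gene_symbols, w1, bias, mask_matrix,
                         labels=None):
    """Fitted-results stand-in with prescribed first-layer weights."""
    n = np.asarray(values).shape[0]
    data = ExpressionDataset(
        values=values, gene_symbols=gene_symbols,
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels if labels is not None else [i % 2 for i in range(n)])
    from pathdeep import MembershipMask
    mask = MembershipMask(matrix=mask_matrix, gene_order=gene_symbols,
                          pathway_order=[f"P{i}" for i in
                                         range(np.asarray(mask_matrix).shape[1])])
    from pathdeep.model import PathDeepResults
    model = PathDeep(data, mask, head_spec=(2, 1), seed=0)
    params = model.initial_params
    params["w1"] = np.asarray(w1, dtype=float) * mask.matrix
    params["b1"] = np.asarray(bias, dtype=float)
    cfg = TrainConfig(max_epochs=0, early_stop_patience=0, head_spec=(2, 1))
    return PathDeepResults(model=model, params=params, config=cfg,
                           train_idx=np.arange(n),
                           training_meta={"epochs_run": 0,
                                          "final_train_loss": float("nan"),
                                          "init_seed": 0,
                                          "config": {}})


class TestPathwayIndex:
    def test_unit_weights_sum_expression(self):
        res = results_with_weights([[1.0, 2.0, 3.0]], list("abc"),
                                   w1=[[1.0], [1.0], [1.0]], bias=[0.0],
                                   mask_matrix=[[1], [1], [1]])
        np.testing.assert_allclose(pathway_index(res).values, [[6.0]])

    def test_zero_expression_returns_bias(self):
        res = results_with_weights(np.zeros((2, 3)), list("abc"),
                                   w1=np.ones((3, 2)), bias=[0.5, -1.5],
                                   mask_matrix=np.ones((3, 2)))
        np.testing.assert_allclose(pathway_index(res).values,
                                   [[0.5, -1.5], [0.5, -1.5]])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, g, p = 30, 50, 7
        mask = (rng.random((g, p)) < 0.3).astype(int)
        res = results_with_weights(rng.normal(size=(n, g)),
                                   [f"G{j}" for j in range(g)],
                                   w1=rng.normal(size=(g, p)),
                                   bias=rng.normal(size=p),
                                   mask_matrix=mask)
        got = pathway_index(res).values
        x = res.model.data.values
        w = res.params["w1"] * mask
        b = res.params["b1"]
        expected = np.zeros((n, p))
        for s in range(n):
            for i in range(p):
                acc = b[i]
                for j in range(g):
                    acc += x[s, j] * w[j, i]
                expected[s, i] = acc
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestContributionIndex:
    def test_constant_expression_sums_pathway_weights(self):
        res = results_with_weights(np.ones((3, 1)), ["g"],
                                   w1=[[0.5, -0.2]], bias=[0.0, 0.0],
                                   mask_matrix=[[1, 1]])
        table = contribution_index(res)
        assert table.loc["g", "index"] == pytest.approx(0.3)

    def test_signed_cancellation_across_samples(self):
        # +1 then -1 expression with weight 1: abs applies AFTER the mean
        res = results_with_weights([[1.0], [-1.0]], ["g"],
                                   w1=[[1.0]], bias=[0.0], mask_matrix=[[1]])
        assert contribution_index(res).loc["g", "index"] == pytest.approx(0.0)

    def test_gene_in_no_pathway_has_zero_index(self):
        res = results_with_weights([[2.0, 3.0]], ["g1", "g2"],
                                   w1=[[1.0], [5.0]], bias=[0.0],
                                   mask_matrix=[[1], [0]])
        table = contribution_index(res)
        assert table.loc["g2", "index"] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, g, p = 30, 50, 6
        mask = (rng.random((g, p)) < 0.3).astype(int)
        res = results_with_weights(rng.normal(size=(n, g)),
                                   [f"G{j}" for j in range(g)],
                                   w1=rng.normal(size=(g, p)),
                                   bias=rng.normal(size=p), mask_matrix=mask)
        got = contribution_index(res)["index"].to_numpy()
        x = res.model.data.values
        w = res.params["w1"] * mask
        expected = np.zeros(g)
        for j in range(g):
            total = 0.0
            for s in range(n):
                for i in range(p):
                    total += x[s, j] * w[j, i]
            expected[j] = abs(total / n)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_scaling_expression_scales_indices_linearly(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 5))
        mask = np.ones((5, 2))
        w = rng.normal(size=(5, 2))
        res1 = results_with_weights(x, [f"G{j}" for j in range(5)], w,
                                    bias=[0.3, -0.7], mask_matrix=mask)
        res3 = results_with_weights(3.0 * x, [f"G{j}" for j in range(5)], w,
                                    bias=[0.3, -0.7], mask_matrix=mask)
        p1 = pathway_index(res1).values - res1.params["b1"]
        p3 = pathway_index(res3).values - res3.params["b1"]
        np.testing.assert_allclose(p3, 3.0 * p1, atol=1e-10)
        np.testing.assert_allclose(contribution_index(res3)["index"],
                                   3.0 * contribution_index(res1)["index"],
                                   atol=1e-10)


class TestTopFraction:
    @staticmethod
    def _table(n, seed=0):
        import pandas as pd
        rng = np.random.default_rng(seed)
        idx = rng.random(n)
        t = pd.DataFrame({"index": idx},
                         index=[f"GENE_{j:05d}" for j in range(n)])
        t.index.name = "gene"
        t["rank"] = t["index"].rank(method="dense", ascending=False).astype(int)
        return t

    @pytest.mark.parametrize("fraction,expected", [(0.01, 57), (0.5, 2898)])
    def test_counts_on_5796_ranked_genes(self, fraction, expected):
        table = self._table(5796)
        assert len(select_top_fraction(table, fraction)) == expected

    def test_full_fraction_returns_rank_order(self):
        table = self._table(10, seed=1)
        top = select_top_fraction(table, 1.0)
        assert len(top) == 10
        vals = table.loc[top, "index"].to_numpy()
        assert (np.diff(vals) <= 0).all()

    def test_ties_break_lexicographically(self):
        import pandas as pd
        t = pd.DataFrame({"index": [1.0, 1.0, 0.5]}, index=["B", "A", "C"])
        t.index.name = "gene"
        assert select_top_fraction(t, 0.67) == ["A", "B"]

    def test_zero_selection_is_error(self):
        with pytest.raises(ValueError):
            select_top_fraction(self._table(10), 0.05)


class TestSubsetRetrain:
    def test_planted_signal_genes_beat_random_subset(self):
        spec, coll, data = planted_fixture(seed=33, n_samples=300, n_genes=120,
                                           n_pathways=10)
        plan = make_split_plan(data, n_repeats=2, seed=33)
        cfg = TrainConfig(max_epochs=25, early_stop_patience=0,
                          head_spec=(8, 1), seed=0)
        signal_genes = list(coll[spec.signal_pathways[0]])
        rng = np.random.default_rng(5)
        non_signal = [g for g in coll.gene_universe() if g not in signal_genes]
        rand_genes = list(rng.choice(non_signal, size=len(signal_genes),
                                     replace=False))
        top = subset_retrain_experiment(data, coll, signal_genes, plan, cfg)
        rand = subset_retrain_experiment(data, coll, rand_genes, plan, cfg)
        assert top.mean > rand.mean

    def test_empty_reintersection_is_error(self, tiny_collection):
        data = random_dataset(30, 6, seed=3)
        plan = make_split_plan(data, n_repeats=1, seed=0)
        with pytest.raises(ValueError, match="no overlap"):
            subset_retrain_experiment(data, tiny_collection, ["G5", "G6"], plan)
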