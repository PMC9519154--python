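"""Global network, RWR/GDS, ranking and running-sum scoring."""

import numpy as np
import pandas as pd
import pytest

from pagicross.io import DataError, Pathway, PathwayCollection
from pagicross import pagi, preprocess as pp, synthio
from pagicross.config import SimConfig

from conftest import brute_running_sum, random_connected_graph


def collection(*pathways):
    return PathwayCollection([Pathway(f"p{i}", f"p{i}", set(g), e)
                              for i, (g, e) in enumerate(pathways)])


class TestGlobalNetwork:
    def test_union_of_shared_members(self):
        g1 = [f"a{i}" for i in range(9)] + ["shared"]
        g2 = [f"b{i}" for i in range(9)] + ["shared"]
        pc = collection((g1, []), (g2, []))
        net = pagi.build_global_network(pc)
        assert len(net.nodes) == 19

    def test_duplicate_edges_collapse(self):
        pc = collection((["x", "y"], [("x", "y")]),
                        (["x", "y"], [("y", "x")]))
        net = pagi.build_global_network(pc)
        assert net.adjacency.sum() == 2  # one undirected edge

    def test_column_stochastic_with_isolated_component(self):
        pc = collection((["a", "b", "c"], [("a", "b"), ("b", "c")]),
                        (["d", "e"], [("d", "e")]))
        net = pagi.build_global_network(pc)
        col = net.M.sum(axis=0)
        deg = net.adjacency.sum(axis=0)
        np.testing.assert_allclose(col[deg > 0], 1.0)
        assert (col[deg == 0] == 0).all()

    def test_empty_collection_raises(self):
        with pytest.raises(DataError):
            pagi.build_global_network(PathwayCollection([]))


class TestTScores:
    def test_identical_groups_give_zero(self):
        x = np.tile(np.arange(6, dtype=float), (4, 1))
        expr = pd.DataFrame(x, index=list("abcd"),
                            columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["AD"] * 3 + ["control"] * 3, index=expr.columns)
        t = pagi.t_scores(expr, groups)
        # groups see the same values only for constant rows; build one
        expr.loc["a"] = 1.0
        t = pagi.t_scores(expr, groups)
        assert t["a"] == 0.0

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(10, 8)),
                            columns=[f"s{i}" for i in range(8)])
        g1 = pd.Series(["AD"] * 4 + ["control"] * 4, index=expr.columns)
        g2 = pd.Series(["control"] * 4 + ["AD"] * 4, index=expr.columns)
        t1, t2 = pagi.t_scores(expr, g1), pagi.t_scores(expr, g2)
        np.testing.assert_allclose(t1.to_numpy(), -t2.to_numpy())

    def test_affected_genes_have_larger_t(self, small_dataset):
        _, mrna, _, truth = small_dataset
        expr = pd.DataFrame(np.log2(mrna.counts.to_numpy() + 1.0),
                            index=mrna.counts.index,
                            columns=mrna.counts.columns)
        t = pagi.t_scores(expr, mrna.pheno["group"]).abs()
        aff = t.loc[truth.affected_genes].mean()
        rest = t.drop(index=truth.affected_genes).mean()
        assert aff > rest + 1.0


class TestRwrGds:
    def two_node_net(self):
        return pagi.build_global_network(
            collection((["A", "B"], [("A", "B")])))

    def test_two_node_closed_form(self):
        net = self.two_node_net()
        p = pagi.rwr_stationary(net, np.array([1.0, 0.0]), r=0.5)
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-9)

    def test_gds_minmax_formula(self):
        p_inf = np.array([0.2, 0.5, 0.3])
        gds = (p_inf - p_inf.min()) / (p_inf.max() - p_inf.min())
        np.testing.assert_allclose(gds, [0.0, 1.0, 1 / 3])
        # through the public surface: stationary vector is preserved and
        # min-max applied
        net = pagi.build_global_network(
            collection((["a", "b", "c"], [("a", "b"), ("b", "c")])))
        infl = pagi.rwr_gds(net, pd.Series({"a": 1.0, "b": 2.0, "c": 1.5}),
                            r=0.7)
        assert infl["GDS"].min() == 0.0
        assert infl["GDS"].max() == 1.0
        np.testing.assert_allclose(infl["p_inf"].sum(), 1.0, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_iterative_matches_linear_solve(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        nodes, edges = random_connected_graph(n, rng)
        net = pagi.build_global_network(collection((nodes, edges)))
        t = pd.Series(rng.exponential(1.0, size=n), index=net.nodes)
        infl = pagi.rwr_gds(net, t, r=0.7, tol=1e-14)
        direct = pagi.rwr_linear_solve(net, infl["p0"].to_numpy(), r=0.7)
        assert np.abs(infl["p_inf"].to_numpy() - direct).max() < 1e-8

    def test_all_zero_signal_raises(self):
        net = self.two_node_net()
        with pytest.raises(DataError, match="no signal"):
            pagi.rwr_gds(net, pd.Series({"A": 0.0, "B": 0.0}))


class TestRankGenes:
    def test_descending_order(self):
        w = pd.Series({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})
        ranked = pagi.rank_genes(w)
        assert list(ranked.index) == ["g1", "g2", "g3", "g4"]

    def test_ties_lexicographic_and_stable(self):
        w = pd.Series({"zz": 2.0, "aa": 2.0, "mm": 5.0})
        r1 = pagi.rank_genes(w)
        r2 = pagi.rank_genes(w.sample(frac=1, random_state=1))
        assert list(r1.index) == ["mm", "aa", "zz"]
        assert list(r1.index) == list(r2.index)

    def test_zero_weight_ranked_last(self):
        w = pd.Series({"a": 1.0, "b": 0.0, "c": 2.0})
        assert list(pagi.rank_genes(w).index) == ["c", "a", "b"]


class TestPathwayScore:
    def worked_ranked(self):
        return pd.DataFrame({"weight": [4.0, 3.0, 2.0, 1.0]},
                            index=pd.Index(["g1", "g2", "g3", "g4"],
                                           name="gene"))

    def test_worked_example(self):
        rec = pagi.pathway_score(self.worked_ranked(), {"g1", "g2"}, "p")
        assert rec.score == pytest.approx(1.0)
        assert rec.peak_index == 2
        assert rec.gene_pct == pytest.approx(0.5)
        assert rec.tag_pct == pytest.approx(1.0)
        assert rec.signal == pytest.approx(1.0)

    def test_bottom_set_scores_negative(self):
        rec = pagi.pathway_score(self.worked_ranked(), {"g3", "g4"}, "p")
        assert rec.score < 0

    def test_degenerate_cases_skipped(self):
        ranked = self.worked_ranked()
        assert pagi.pathway_score(ranked, {"nope"}, "p") is None
        assert pagi.pathway_score(ranked, {"g1", "g2", "g3", "g4"}, "p") is None
        ranked.loc[["g1", "g2"], "weight"] = 0.0
        assert pagi.pathway_score(ranked, {"g1", "g2"}, "p") is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        genes = [f"g{i:03d}" for i in range(n)]
        w = pd.Series(rng.exponential(1.0, size=n), index=genes)
        ranked = pagi.rank_genes(w)
        members = set(rng.choice(genes, size=30, replace=False))
        rec = pagi.pathway_score(ranked, members, "p")
        score, peak = brute_running_sum(list(ranked.index),
                                        ranked["weight"].to_numpy(), members)
        assert rec.score == score
        assert rec.peak_index == peak
        assert -1.0 <= rec.score <= 1.0


class TestPermutationFdr:
    @pytest.fixture(scope="class")
    def scored(self, small_dataset):
        pathways, mrna, _, truth = small_dataset
        expr = pd.DataFrame(np.log2(mrna.counts.to_numpy() + 1.0),
                            index=mrna.counts.index,
                            columns=mrna.counts.columns)
        net = pagi.build_global_network(pathways)
        table, infl = pagi.permutation_fdr(
            expr, mrna.pheno["group"], net, pathways,
            n_permutations=99, seed=5)
        return table, infl, truth

    def test_planted_pathways_rank_top(self, scored):
        table, _, truth = scored
        top = table["score"].abs().sort_values(ascending=False)
        assert set(truth.dysregulated_pathway_ids) <= set(top.index[:4])

    def test_perm_p_bounds_and_bh_order(self, scored):
        table, _, _ = scored
        assert ((table["perm_p"] > 0) & (table["perm_p"] <= 1)).all()
        # BH-adjusted values preserve the p-value ordering
        srt = table.sort_values("perm_p")
        assert (srt["fdr"].diff().dropna() >= -1e-12).all()
        assert (table["fdr"] >= table["perm_p"] - 1e-12).all()

    def test_too_few_permutations_rejected(self, small_dataset):
        pathways, mrna, _, _ = small_dataset
        expr = pd.DataFrame(np.log2(mrna.counts.to_numpy() + 1.0),
                            index=mrna.counts.index,
                            columns=mrna.counts.columns)
        net = pagi.build_global_network(pathways)
        with pytest.raises(DataError):
            pagi.permutation_fdr(expr, mrna.pheno["group"], net, pathways,
                                 n_permutations=5)

    def test_monotone_in_effect_size(self):
        """Stronger planted shifts never lower planted-pathway scores."""
        means = []
        for delta in (0.5, 1.0, 2.0):
            cfg = SimConfig(n_genes=300, n_lnc=20, n_pathways=6,
                            n_dysregulated=2, pathway_size_range=(25, 40),
                            n_case=25, n_control=25, n_modules=0,
                            effect_delta=delta, seed=21)
            pc = synthio.simulate_pathways(cfg)
            mrna, _, truth = synthio.simulate_counts(cfg, pc)
            expr = pd.DataFrame(np.log2(mrna.counts.to_numpy() + 1.0),
                                index=mrna.counts.index,
                                columns=mrna.counts.columns)
            net = pagi.build_global_network(pc)
            t = pagi.t_scores(expr, mrna.pheno["group"])
            infl = pagi.rwr_gds(net, t)
            ranked = pagi.rank_genes(pagi.gene_weights(t, infl))
            scores = [pagi.pathway_score(ranked, pc[pid].genes, pid).score
                      for pid in truth.dysregulated_pathway_ids]
            means.append(np.mean(scores))
        assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9
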