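import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fermtx as fx
from fermtx.errors import ValidationError


class TestSpearman:
    def test_hand_computed_three_point_fixture(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (2, 1, 1) gives -0.5
        result = fx.spearman([1, 2, 3], [3, 1, 2])
        assert result.rho == pytest.approx(-0.5)

    def test_monotone_transform_gives_unit_rho_and_zero_p(self):
        x = np.array([0.5, 1.2, 3.3, 4.0, 9.1])
        result = fx.spearman(x, np.exp(x))
        assert result.rho == pytest.approx(1.0)
        assert result.pvalue == 0.0

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(size=15)
        base = fx.spearman(x, y).rho
        assert fx.spearman(np.exp(x), y).rho == pytest.approx(base)
        assert fx.spearman(x, stats.rankdata(y)).rho == pytest.approx(base)

    def test_pairwise_complete_handling(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        result = fx.spearman(x, y)
        assert result.n == 3
        assert result.rho == pytest.approx(1.0)

    def test_constant_vector_reported_missing(self):
        result = fx.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(result.rho)

    @pytest.mark.parametrize("n", [8, 9])
    def test_p_within_two_fold_of_exhaustive_permutation(self, n):
        rng = np.random.default_rng(100 + n)
        x, y = rng.normal(size=n), rng.normal(size=n)
        result = fx.spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (rx[perms] @ ry / n - rx.mean() * ry.mean()) / (rx.std() * ry.std())
        p_exact = float((np.abs(rhos) >= abs(result.rho) - 1e-12).mean())
        assert p_exact / 2 <= result.pvalue <= p_exact * 2


class TestFocalCorrelations:
    def test_focal_duplicated_as_target(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(4, 10))
        values[1] = values[0]
        expr = pd.DataFrame(values, index=["f", "dup", "a", "b"], columns=range(10))
        table = fx.focal_gene_correlations(expr, ["f"], ["dup"])
        assert table.iloc[0]["rho"] == pytest.approx(1.0)
        assert table.iloc[0]["pvalue"] == 0.0

    def test_planted_coregulated_pair_detected(self, small_dataset):
        hits = 0
        runs = 10
        for seed in range(runs):
            ds = fx.simulate_dataset(fx.GeneratorConfig(n_genes=600), seed=seed)
            expr = fx.normalize(ds.counts, "mor_log2").values
            focal = list(ds.truth.focal_genes)
            partner = [
                g for g in ds.truth.qtt_genes.gene_id if g not in set(focal)
            ][:1]
            table = fx.focal_gene_correlations(expr, focal[:1], partner)
            hits += table.iloc[0]["rho"] >= 0.8
        assert hits / runs >= 0.9

    def test_empty_target_list(self, small_dataset):
        expr = fx.normalize(small_dataset.counts, "cpm_log2").values
        table = fx.focal_gene_correlations(expr, [expr.index[0]], [])
        assert table.empty

    def test_unknown_focal_id_listed(self):
        expr = pd.DataFrame(np.zeros((2, 5)), index=["a", "b"])
        with pytest.raises(ValidationError, match="missing"):
            fx.focal_gene_correlations(expr, ["missing"])


class TestNetwork:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["focal", "target", "rho", "pvalue"])

    def test_no_significant_pairs_gives_empty_network(self):
        t = self.table([("a", "b", 0.5, 0.9), ("a", "c", 0.2, 0.06)])
        assert fx.build_network(t).number_of_edges() == 0

    def test_three_pairwise_significant_genes_form_triangle(self):
        t = self.table(
            [("a", "b", 0.9, 0.01), ("a", "c", 0.8, 0.02), ("b", "c", 0.85, 0.001)]
        )
        graph = fx.build_network(t)
        assert graph.number_of_edges() == 3
        assert nx.is_connected(graph)

    def test_edges_exactly_match_p_filter(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"f{i % 3}", f"t{i}", rng.uniform(-1, 1), rng.uniform(0, 1))
            for i in range(200)
        ]
        t = self.table(rows)
        graph = fx.build_network(t, p_threshold=0.05)
        expected = int(((t["pvalue"] < 0.05) & (t["focal"] != t["target"])).sum())
        assert graph.number_of_edges() == expected
        assert fx.network_edge_table(graph).shape[0] == expected


class TestEnrichment:
    def test_printed_toy_matches_closed_form(self):
        sets = fx.GeneSetCollection({"s": tuple("abcd")})
        universe = set("abcdefghij")
        result = fx.enrich(set("abcde"), universe, sets)
        # C(4,4)*C(6,1)/C(10,5) = 6/252
        assert result["pvalue"].iloc[0] == pytest.approx(6 / 252)

    def test_zero_overlap_gives_p_one(self):
        sets = fx.GeneSetCollection({"s": ("x", "y")})
        result = fx.enrich({"a"}, {"a", "b", "x", "y"}, sets)
        assert result["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_query_equals_universe_saturates(self):
        universe = {f"g{i}" for i in range(8)}
        sets = fx.GeneSetCollection({"s": tuple(list(universe)[:3])})
        result = fx.enrich(universe, universe, sets)
        assert result["k"].iloc[0] == result["K"].iloc[0]
        assert result["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universe(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(11)]
        members = tuple(rng.choice(universe, size=4, replace=False))
        query = set(rng.choice(universe, size=5, replace=False))
        sets = fx.GeneSetCollection({"s": members})
        p_impl = fx.enrich(query, set(universe), sets)["pvalue"].iloc[0]
        k_obs = len(query & set(members))
        n_draw = len(query)
        hits = total = 0
        for draw in itertools.combinations(universe, n_draw):
            total += 1
            if len(set(draw) & set(members)) >= k_obs:
                hits += 1
        assert p_impl == pytest.approx(hits / total, rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            fx.enrich(set(), set(), fx.GeneSetCollection({"s": ("a",)}))


class TestAccumulatedFC:
    def table(self):
        return pd.DataFrame(
            {
                "log2FC": [-2.5, -1.5, 0.4, 3.0],
                "direction": ["down", "down", "ns", "up"],
            },
            index=["g1", "g2", "g3", "g4"],
        )

    def test_hand_sum_over_degs_only(self):
        total, count = fx.accumulated_fc(self.table(), ["g1", "g2", "g3"])
        assert total == pytest.approx(-4.0)
        assert count == 2

    def test_deg_free_set_is_zero(self):
        total, count = fx.accumulated_fc(self.table(), ["g3", "absent"])
        assert (total, count) == (0.0, 0)

    def test_additive_over_disjoint_sets(self):
        whole, _ = fx.accumulated_fc(self.table(), ["g1", "g2", "g4"])
        part1, _ = fx.accumulated_fc(self.table(), ["g1", "g4"])
        part2, _ = fx.accumulated_fc(self.table(), ["g2"])
        assert whole == pytest.approx(part1 + part2)


class TestMetaboliteCorrelations:
    def test_duplicated_metabolite_has_unit_rho(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=10)
        table = pd.DataFrame({"m1": values, "m1_copy": values, "m2": rng.normal(size=10)})
        rho, pval, nobs = fx.metabolite_correlations(table)
        assert rho.loc["m1", "m1_copy"] == pytest.approx(1.0)

    def test_pairwise_complete_counts(self):
        table = pd.DataFrame(
            {
                "m1": [1.0, 2.0, np.nan, 4.0, 5.0],
                "m2": [2.0, np.nan, 3.0, 5.0, 6.0],
            }
        )
        rho, pval, nobs = fx.metabolite_correlations(table)
        assert nobs.loc["m1", "m2"] == 3

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
        rho, pval, nobs = fx.metabolite_correlations(table)
        np.testing.assert_allclose(rho.to_numpy(), rho.to_numpy().T)
        np.testing.assert_allclose(pval.to_numpy(), pval.to_numpy().T)
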