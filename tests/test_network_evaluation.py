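"""Topology metrics, expression preprocessing, sweep, stress and climate tests."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mircrosstalk.network_evaluation import (
    climate_sd_test,
    dynamic_ecotype_groups,
    pair_correlations,
    preprocess_expression,
    stress_share_test,
    threshold_sweep,
    topology,
)
from conftest import profile


def brute_force_betweenness(graph):
    """All-pairs shortest-path enumeration with fractional counting."""
    node_bt = {n: 0.0 for n in graph.nodes}
    edge_bt = {frozenset(e): 0.0 for e in graph.edges}
    nodes = sorted(graph.nodes)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        w = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                node_bt[v] += w
            for a, b in zip(path, path[1:]):
                edge_bt[frozenset((a, b))] += w
    return node_bt, edge_bt


class TestTopology:
    def test_path_center(self):
        g = nx.path_graph(["a", "b", "c"])
        report = topology(g)
        assert report.node_betweenness["b"] == 1.0

    def test_star_center_counts_leaf_pairs(self):
        g = nx.star_graph(3)  # center 0, three leaves
        assert topology(g).node_betweenness[0] == 3.0

    def test_top_fraction_rule(self):
        g = nx.Graph()
        for i in range(1, 10):
            g.add_edge(0, i)  # node 0 degree 9, leaves degree 1
        report = topology(g, percentile=0.15)
        # ceil(0.15 * 10) = 2 hubs before tie extension; the 9 tied leaves
        # extend the cut, so either exactly the high-degree node plus the
        # tied block is included
        assert 0 in report.hubs
        assert len(report.hubs) in (2, 10)

    def test_node_classes_partition(self):
        g = nx.barbell_graph(4, 2)
        report = topology(g)
        assert set(report.node_class) == set(g.nodes)
        assert set(report.node_class.values()) <= {
            "hub-bottleneck",
            "hub-nonbottleneck",
            "nonhub-bottleneck",
            "nonhub-nonbottleneck",
        }

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            topology(nx.Graph())

    def test_betweenness_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            report = topology(g)
            node_bt, edge_bt = brute_force_betweenness(g)
            for v in g.nodes:
                assert report.node_betweenness[v] == pytest.approx(node_bt[v])
            for e in g.edges:
                assert report.edge_betweenness[frozenset(e)] == pytest.approx(
                    edge_bt[frozenset(e)]
                )


class TestExpression:
    def test_replicate_average_then_log2(self):
        raw = pd.DataFrame(
            {
                "mirna": ["m1"] * 12,
                "sample": [f"s{i}" for i in range(6)] * 2,
                "value": [4.0] * 6 + [8.0] * 6,
            }
        )
        matrix = preprocess_expression(raw)
        assert matrix.loc["m1"].tolist() == pytest.approx([math.log2(6)] * 6)

    def test_sparse_mirnas_dropped_at_boundary(self):
        rows = []
        for m, n_samples in (("keep", 6), ("drop", 5)):
            for i in range(n_samples):
                rows.append({"mirna": m, "sample": f"s{i}", "value": 2.0})
        matrix = preprocess_expression(pd.DataFrame(rows))
        assert list(matrix.index) == ["keep"]

    def test_zeros_are_missing(self):
        rows = [
            {"mirna": "m", "sample": f"s{i}", "value": 0.0 if i < 3 else 2.0}
            for i in range(9)
        ]
        matrix = preprocess_expression(pd.DataFrame(rows))
        assert matrix.loc["m"].notna().sum() == 6

    def test_negative_rejected(self):
        raw = pd.DataFrame({"mirna": ["m"], "sample": ["s"], "value": [-1.0]})
        with pytest.raises(ValueError):
            preprocess_expression(raw)


class TestPairCorrelations:
    def _matrix(self):
        x = np.arange(10, dtype=float)
        return pd.DataFrame(
            {"a": x, "b": x, "c": -x, "d": [0] * 10},
            index=[f"s{i}" for i in range(10)],
        ).T

    def test_identical_and_negated_profiles(self):
        table = pair_correlations(self._matrix(), [("a", "b"), ("a", "c")])
        r = dict(zip(zip(table.mirna_i, table.mirna_j), table.r))
        assert r[("a", "b")] == pytest.approx(1.0)
        assert r[("a", "c")] == pytest.approx(-1.0)

    def test_insufficient_overlap_skipped(self):
        m = self._matrix()
        m.loc["a", m.columns[2:]] = np.nan
        table = pair_correlations(m, [("a", "b")])
        assert len(table) == 0

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(12)
        rows = {}
        r_values = []
        for k in range(200):
            x = rng.normal(size=30)
            y = 0.6 * x + math.sqrt(1 - 0.36) * rng.normal(size=30)
            rows = pd.DataFrame([x, y], index=["p", "q"])
            r_values.append(
                pair_correlations(rows, [("p", "q")]).r.iloc[0]
            )
        assert np.mean(r_values) == pytest.approx(0.6, abs=0.1)


class TestThresholdSweep:
    def test_final_pairs_monotone_and_ordering(self, default_run, default_truth):
        from mircrosstalk.synthetic_fixtures import generate_expression

        expr = preprocess_expression(generate_expression(default_truth))
        sweep = threshold_sweep(
            default_run["profiles"], expr, [0.0, 0.5, 0.85, 1.0]
        )
        assert (sweep.n_final_pairs.diff().dropna() <= 0).all()
        row = sweep[sweep.threshold == 0.85].iloc[0]
        # planted cooperative pairs are strongly co-expressed; discordant
        # (deleted) pairs are not
        assert row.mean_r_final > row.mean_r_deleted + 0.3

    def test_vacuous_threshold_has_no_deleted_pairs(self, default_run, default_truth):
        from mircrosstalk.synthetic_fixtures import generate_expression

        expr = preprocess_expression(generate_expression(default_truth))
        sweep = threshold_sweep(default_run["profiles"], expr, [0.0])
        assert sweep.n_deleted_pairs.iloc[0] == 0
        assert math.isnan(sweep.mean_r_deleted.iloc[0])


class TestStressShare:
    def test_all_edges_share(self):
        stress = {"a": {"cold"}, "b": {"cold"}, "c": {"cold", "salt"}}
        frac, p = stress_share_test(
            [("a", "b"), ("b", "c")], stress,
            rng=np.random.default_rng(0), n_perm=50,
        )
        assert frac == 1.0

    def test_no_annotations(self):
        frac, p = stress_share_test(
            [("a", "b")], {}, rng=np.random.default_rng(0), n_perm=50
        )
        assert frac == 0.0 and p == 1.0

    def test_enriched_network_is_significant(self):
        rng = np.random.default_rng(42)
        # 20 miRNAs; only the first 6 share a stress; network heavily favors them
        stress = {f"m{i}": {"drought"} for i in range(6)}
        universe = [f"m{i}" for i in range(20)]
        edges = [(f"m{i}", f"m{j}") for i in range(6) for j in range(i + 1, 6)]
        frac, p = stress_share_test(
            edges, stress, universe=universe, n_perm=500, rng=rng
        )
        assert frac == 1.0 and p <= 0.05


class TestClimate:
    def _table(self, rng, n=100):
        return pd.DataFrame(
            {"temperature_seasonality": rng.normal(20, 10, size=n)},
            index=[f"e{i}" for i in range(n)],
        )

    def test_tight_cluster_has_small_p(self):
        rng = np.random.default_rng(1)
        table = self._table(rng)
        group = [f"e{i}" for i in range(10)]
        table.loc[group, "temperature_seasonality"] = rng.normal(50, 0.1, size=10)
        result = climate_sd_test(
            group, table, "temperature_seasonality",
            n_perm=500, rng=np.random.default_rng(2),
        )
        assert result.p_empirical == 0.0

    def test_fraction_arithmetic(self):
        # p is the fraction of permutations with a strictly smaller SD
        rng = np.random.default_rng(3)
        table = self._table(rng)
        group = list(table.index[:10])
        result = climate_sd_test(
            group, table, "temperature_seasonality",
            n_perm=1000, rng=np.random.default_rng(4),
        )
        assert 0.0 <= result.p_empirical <= 1.0
        assert result.sd_observed == pytest.approx(
            table.loc[group, "temperature_seasonality"].std(ddof=1)
        )

    def test_small_group_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            climate_sd_test(["e1"], self._table(rng), "temperature_seasonality")

    def test_unknown_variable_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            climate_sd_test(["e1", "e2"], self._table(rng), "altitude")


class TestDynamicGroups:
    def test_disjoint_loss_groups_have_zero_overlap(self):
        profiles = {
            ("m1", "t"): profile("m1", "t", {"e1": "l", "e2": "k", "e3": "k", "e4": "k"}),
            ("m2", "t"): profile("m2", "t", {"e1": "k", "e2": "k", "e3": "l", "e4": "k"}),
        }
        groups = dynamic_ecotype_groups(profiles, "t")
        assert groups[("m1", "t")] == {"e1"}
        assert groups[("m2", "t")] == {"e3"}
        assert not (groups[("m1", "t")] & groups[("m2", "t")])

    def test_static_only_target_rejected(self):
        profiles = {("m1", "t"): profile("m1", "t", {"e1": "k"})}
        with pytest.raises(ValueError):
            dynamic_ecotype_groups(profiles, "t")
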