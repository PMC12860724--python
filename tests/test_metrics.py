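"""Graph metrics against hand computations and independent oracles."""

import itertools

import numpy as np
import networkx as nx
import pytest

from ccnet._errors import DataError, InvalidParameterError
from ccnet.connectome import WeightedNetwork, threshold_proportional
from ccnet.metrics import (
    MetricTable,
    aggregate_densities,
    average_clustering,
    average_degree,
    betweenness_all,
    compute_metric_table,
    global_efficiency,
    induced_subgraph,
    shortest_path_lengths,
    subnetwork_metrics,
    zstandardise,
)

import pandas as pd


def graph_from(w, labels=None):
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    labels = labels or tuple(f"n{i}" for i in range(n))
    net = WeightedNetwork(w, labels)
    return threshold_proportional(net, 1.0)


def complete(n, weight=1.0):
    w = weight * (np.ones((n, n)) - np.eye(n))
    return graph_from(w)


def path_graph(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return graph_from(w)


def star(n):
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return graph_from(w)


class TestDegree:
    def test_complete_graph(self):
        assert average_degree(complete(4)) == pytest.approx(3.0)

    def test_path(self):
        assert average_degree(path_graph(4)) == pytest.approx(1.5)

    def test_ceiling_rule_at_half_density(self, rng):
        w = np.triu(rng.random((5, 5)) + 0.1, 1)
        net = WeightedNetwork(w + w.T, tuple("abcde"))
        g = threshold_proportional(net, 0.5)  # K = ceil(5) = 5
        assert average_degree(g) == pytest.approx(2.0)


class TestClustering:
    @pytest.mark.parametrize("variant", ["binary", "onnela", "barrat"])
    def test_triangle_is_one(self, variant):
        assert average_clustering(complete(3), variant) == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["binary", "onnela", "barrat"])
    def test_star_has_no_triangles(self, variant):
        assert average_clustering(star(4), variant) == pytest.approx(0.0)

    def test_k4_minus_edge(self):
        w = np.ones((4, 4)) - np.eye(4)
        w[0, 1] = w[1, 0] = 0.0
        assert average_clustering(graph_from(w)) == pytest.approx(5 / 6)

    @pytest.mark.parametrize("variant", ["onnela", "barrat"])
    def test_weighted_reduces_to_binary_on_unit_weights(self, variant, rng):
        w = np.triu((rng.random((7, 7)) < 0.5).astype(float), 1)
        g = graph_from(w + w.T)
        assert average_clustering(g, variant) == pytest.approx(
            average_clustering(g, "binary")
        )

    def test_unknown_variant(self):
        with pytest.raises(InvalidParameterError):
            average_clustering(complete(3), "zhang")


class TestShortestPaths:
    def test_unit_path(self):
        sp = shortest_path_lengths(path_graph(3))
        assert sp[0, 2] == pytest.approx(2.0)

    def test_inverse_weight_route_choice(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 2.0
        w[1, 2] = w[2, 1] = 4.0
        w[0, 2] = w[2, 0] = 0.2
        sp = shortest_path_lengths(graph_from(w))
        assert sp[0, 2] == pytest.approx(0.75)  # min(5, 0.5 + 0.25)

    def test_disconnected_is_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        sp = shortest_path_lengths(graph_from(w))
        assert np.isinf(sp[0, 2])


class TestEfficiency:
    def test_complete_unit(self):
        assert global_efficiency(complete(5)) == pytest.approx(1.0)

    def test_unit_path_three_nodes(self):
        assert global_efficiency(path_graph(3)) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_edgeless(self):
        assert global_efficiency(graph_from(np.zeros((4, 4)))) == 0.0

    def test_monotone_in_density(self, rng):
        w = np.triu(rng.random((12, 12)), 1)
        net = WeightedNetwork(w + w.T, tuple(f"n{i}" for i in range(12)))
        effs = [
            global_efficiency(threshold_proportional(net, d))
            for d in (0.1, 0.2, 0.3, 0.5)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(effs, effs[1:]))


class TestBetweenness:
    def test_complete_graph_zero(self):
        assert np.allclose(betweenness_all(complete(4)), 0.0)

    def test_star_centre(self):
        bc = betweenness_all(star(4))
        assert bc[0] == pytest.approx(3.0)
        assert np.allclose(bc[1:], 0.0)

    def test_path_centre(self):
        assert betweenness_all(path_graph(3))[1] == pytest.approx(1.0)

    def test_normalisation(self):
        bc = betweenness_all(star(5), normalised=True)
        assert bc[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# independent-library oracle


def _random_graph(rng, n):
    w = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
    w = np.triu(w, 1)
    return graph_from(w + w.T)


@pytest.mark.parametrize("trial", range(8))
def test_metrics_match_networkx(trial, rng):
    """Our metric implementations agree with networkx on random graphs."""
    r = np.random.default_rng(600 + trial)
    g = _random_graph(r, int(r.integers(4, 9)))
    G = nx.from_numpy_array(g.weights)
    for _, _, d in G.edges(data=True):
        d["dist"] = 1.0 / d["weight"]
    assert average_clustering(g, "binary") == pytest.approx(nx.average_clustering(G))
    assert average_clustering(g, "onnela") == pytest.approx(
        nx.average_clustering(G, weight="weight")
    )
    bc_nx = nx.betweenness_centrality(G, weight="dist", normalized=False)
    assert betweenness_all(g) == pytest.approx(
        np.array([bc_nx[i] for i in range(g.n_nodes)])
    )
    sp_nx = dict(nx.all_pairs_dijkstra_path_length(G, weight="dist"))
    eff = np.mean(
        [
            1.0 / sp_nx[i][j] if j in sp_nx[i] else 0.0
            for i, j in itertools.combinations(range(g.n_nodes), 2)
        ]
    )
    assert global_efficiency(g) == pytest.approx(eff)


# ---------------------------------------------------------------------------
# subnetworks and tables


class TestSubnetwork:
    def test_full_subset_equals_full_graph(self, rng):
        g = _random_graph(rng, 6)
        m = subnetwork_metrics(g, list(g.labels))
        assert m["degree"] == pytest.approx(average_degree(g))
        assert m["clustering"] == pytest.approx(average_clustering(g))
        assert m["efficiency"] == pytest.approx(global_efficiency(g))

    def test_two_connected_nodes(self):
        g = complete(4)
        m = subnetwork_metrics(g, ["n0", "n1"])
        assert m["clustering"] == 0.0
        assert m["degree"] == pytest.approx(1.0)

    def test_unknown_label(self):
        with pytest.raises(DataError):
            induced_subgraph(complete(3), ["nope"])


class TestZStandardise:
    def test_sample_sd_convention(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = zstandardise(df)
        assert np.allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_idempotent_within_tolerance(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        z1 = zstandardise(df)
        z2 = zstandardise(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy())

    def test_pooled_group_means_oppose(self, rng):
        x = np.concatenate([rng.normal(1, 1, 40), rng.normal(-1, 1, 60)])
        z = zstandardise(pd.DataFrame({"a": x}))["a"].to_numpy()
        assert np.sign(z[:40].mean()) != np.sign(z[40:].mean())
        assert (40 * z[:40].mean() + 60 * z[40:].mean()) == pytest.approx(0, abs=1e-10)

    def test_zero_variance_is_error_naming_column(self):
        with pytest.raises(DataError, match="const"):
            zstandardise(pd.DataFrame({"const": [1.0, 1.0, 1.0]}))


class TestAggregateDensities:
    def _table(self, values):
        cols = pd.MultiIndex.from_tuples(
            [("clustering", d) for d in (0.1, 0.2)], names=["metric", "density"]
        )
        return MetricTable(pd.DataFrame(values, columns=cols), kind="z")

    def test_mean_of_two(self):
        t = self._table([[0.0, 1.0]])
        assert aggregate_densities(t).iloc[0, 0] == pytest.approx(0.5)

    def test_missing_cell_is_error(self):
        t = self._table([[0.0, np.nan]])
        with pytest.raises(DataError):
            aggregate_densities(t)


def test_metric_table_round_trips_csv(tmp_path, small_bundle):
    from ccnet.connectome import build_network

    nets = [build_network(r) for r in small_bundle.subjects[:5]]
    mt = compute_metric_table(nets, (0.2, 0.4))
    mt.to_csv(tmp_path / "m.csv")
    back = MetricTable.from_csv(tmp_path / "m.csv")
    assert np.allclose(back.data.to_numpy(), mt.data.to_numpy())
    assert list(back.data.columns) == list(mt.data.columns)
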