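"""Centrality definitions against independent oracles and exact identities."""

import heapq
import itertools

import networkx as nx
import numpy as np
import pytest

from lumenflow.centrality import (
    betweenness_centrality,
    mean_strength,
    node_strength,
    remodeling_metrics,
)

# ---------------------------------------------------------------------------
# Brute-force betweenness oracle: exhaustive Dijkstra with tie enumeration.
# Written independently of the implementation under test (no networkx).
# ---------------------------------------------------------------------------

def _dijkstra(adj, s):
    dist = {s: 0.0}
    heap = [(0.0, s)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist.get(v, np.inf) - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def _all_shortest_paths(adj, dist_s, s, t):
    """Enumerate every shortest s->t path by walking the shortest-path DAG."""
    paths = []

    def walk(u, path):
        if u == t:
            paths.append(list(path))
            return
        for v, w in adj[u]:
            if abs(dist_s[u] + w - dist_s.get(v, np.inf)) <= 1e-12:
                path.append(v)
                walk(v, path)
                path.pop()

    walk(s, [s])
    return paths


def brute_force_betweenness(g: nx.Graph, weight="w"):
    adj = {n: [] for n in g.nodes()}
    for u, v, d in g.edges(data=True):
        adj[u].append((v, d[weight]))
        adj[v].append((u, d[weight]))
    btw = {n: 0.0 for n in g.nodes()}
    for s, t in itertools.combinations(g.nodes(), 2):
        dist_s = _dijkstra(adj, s)
        if t not in dist_s:
            continue
        paths = _all_shortest_paths(adj, dist_s, s, t)
        sigma = len(paths)
        for v in g.nodes():
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            btw[v] += through / sigma
    return btw


def _random_connected_graph(seed: int) -> nx.MultiGraph:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    g = nx.MultiGraph()
    g.add_nodes_from(range(n))
    # random spanning tree first, then extra edges; gridded weights force ties
    nodes = list(rng.permutation(n))
    for i in range(1, n):
        j = int(rng.integers(i))
        g.add_edge(int(nodes[i]), int(nodes[j]), R_tau=float(rng.integers(1, 9)) / 8)
    for _ in range(int(rng.integers(0, n))):
        u, v = rng.integers(n, size=2)
        if u != v and not g.has_edge(int(u), int(v)):
            g.add_edge(int(u), int(v), R_tau=float(rng.integers(1, 9)) / 8)
    return g


class TestBetweenness:
    def test_path_graph_middle_node(self):
        g = nx.MultiGraph()
        g.add_edge("A", "B", R_tau=1.0)
        g.add_edge("B", "C", R_tau=1.0)
        b = betweenness_centrality(g)
        assert b["B"] == 1.0 and b["A"] == 0.0 and b["C"] == 0.0

    def test_star_center_is_leaf_pairs(self):
        g = nx.MultiGraph()
        for leaf in "abcd":
            g.add_edge("center", leaf, R_tau=1.0)
        b = betweenness_centrality(g)
        assert b["center"] == 6.0  # 4 choose 2
        assert all(b[l] == 0.0 for l in "abcd")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        g = _random_connected_graph(seed)
        ours = betweenness_centrality(g, weight="R_tau", variant="path_count")
        simple = nx.Graph()
        simple.add_nodes_from(g.nodes())
        for u, v, d in g.edges(data=True):
            if not simple.has_edge(u, v) or d["R_tau"] < simple[u][v]["w"]:
                simple.add_edge(u, v, w=d["R_tau"])
        oracle = brute_force_betweenness(simple)
        for n in g.nodes():
            assert ours[n] == pytest.approx(oracle[n], abs=1e-9)

    def test_invariant_under_uniform_weight_scaling(self):
        # tie-free weights: with exactly tied path costs, rounding under the
        # scaling could legitimately flip which paths count as shortest
        g = _random_connected_graph(99)
        rng = np.random.default_rng(99)
        for u, v, k in g.edges(keys=True):
            g[u][v][k]["R_tau"] = float(rng.uniform(0.1, 1.0))
        base = betweenness_centrality(g)
        for c in (0.1, 10.0):
            h = g.copy()
            for u, v, k in h.edges(keys=True):
                h[u][v][k]["R_tau"] *= c
            scaled = betweenness_centrality(h)
            assert scaled == pytest.approx(base)

    def test_equal_weights_reduce_to_unweighted_betweenness(self):
        g = _random_connected_graph(7)
        for u, v, k in g.edges(keys=True):
            g[u][v][k]["R_tau"] = 1.0
        ours = betweenness_centrality(g)
        simple = nx.Graph(g)
        ref = nx.betweenness_centrality(simple, normalized=False)
        assert ours == pytest.approx(ref)

    def test_negative_weight_rejected(self):
        g = nx.MultiGraph()
        g.add_edge(0, 1, R_tau=-0.5)
        with pytest.raises(ValueError, match="negative"):
            betweenness_centrality(g)

    def test_paper_text_variant_is_cost_ratio(self):
        # path a-b-c-d: shortest paths through b: (a,c) d=2, (a,d) d=3;
        # all pairs excluding b: (a,c)=2, (a,d)=3, (c,d)=1 -> 5/6
        g = nx.MultiGraph()
        for u, v in [("a", "b"), ("b", "c"), ("c", "d")]:
            g.add_edge(u, v, R_tau=1.0)
        b = betweenness_centrality(g, variant="paper_text")
        assert b["b"] == pytest.approx(5.0 / 6.0)


class TestStrength:
    def test_incident_sum(self):
        g = nx.MultiGraph()
        g.add_edge(0, 1, R_Q=0.3)
        g.add_edge(0, 2, R_Q=0.7)
        s = node_strength(g)
        assert s[0] == pytest.approx(1.0)

    def test_isolated_node_zero(self):
        g = nx.MultiGraph()
        g.add_node(42)
        assert node_strength(g)[42] == 0.0

    def test_self_loop_counts_twice(self):
        g = nx.MultiGraph()
        g.add_edge(0, 0, R_Q=0.25)
        assert node_strength(g)[0] == pytest.approx(0.5)

    def test_handshake_identity_random_graphs(self):
        for seed in range(5):
            g = _random_connected_graph(seed)
            for u, v, k in g.edges(keys=True):
                g[u][v][k]["R_Q"] = g[u][v][k]["R_tau"]
            s = node_strength(g)
            total = sum(d["R_Q"] for *_, d in g.edges(keys=True, data=True))
            assert sum(s.values()) == pytest.approx(2 * total)
            assert mean_strength(g) == pytest.approx(
                2 * total / g.number_of_nodes()
            )


class TestRemodelingMetrics:
    @staticmethod
    def _sample(sid, vals, days=None):
        import pandas as pd

        days = days if days is not None else list(range(len(vals)))
        return pd.DataFrame(
            {
                "sample_id": sid,
                "day": days,
                "area_um2": vals,
                "mean_betweenness": vals,
                "mean_strength": vals,
            }
        )

    def test_single_sample_mean_is_sample_ci_absent(self):
        m = remodeling_metrics([self._sample("a", [1.0, 2.0, 3.0])])
        assert list(m.summary["area_um2_mean"]) == [1.0, 2.0, 3.0]
        assert m.summary["area_um2_ci95"].isna().all()

    def test_two_identical_samples_zero_ci(self):
        m = remodeling_metrics(
            [self._sample("a", [1.0, 2.0]), self._sample("b", [1.0, 2.0])]
        )
        assert (m.summary["area_um2_ci95"] == 0.0).all()

    def test_nearby_days_aligned_within_half_day(self):
        m = remodeling_metrics(
            [
                self._sample("a", [1.0, 2.0], days=[0.0, 1.0]),
                self._sample("b", [3.0, 4.0], days=[0.4, 1.3]),
            ]
        )
        assert len(m.summary) == 2
        assert m.summary["n_samples"].tolist() == [2, 2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            remodeling_metrics([])
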