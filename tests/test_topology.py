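"""Centrality metrics against closed forms and a brute-force path-counting
oracle, and the median-based screening rule's invariants."""

from collections import deque

import numpy as np
import pytest

import networkx as nx

from netpharm.topology import HubRuleConfig, NodeMetrics, compute_metrics, screen_candidates


def brute_force_metrics(graph):
    """Independent all-pairs shortest-path metrics from raw adjacency.

    Counts shortest paths with the classic sigma DP over BFS orderings and
    accumulates pair dependencies directly; betweenness normalized by
    2/((m-1)(m-2)), closeness = reachable / sum-of-distances.
    """
    nodes = sorted(graph.nodes)
    adjacency = {u: sorted(graph.neighbors(u)) for u in nodes}
    m = len(nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adjacency[u]:
                if v not in d:
                    d[v] = d[u] + 1
                    sig[v] = 0
                    queue.append(v)
                if d[v] == d[u] + 1:
                    sig[v] += sig[u]
        dist[s] = d
        sigma[s] = sig
    betweenness = dict.fromkeys(nodes, 0.0)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    betweenness[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    scale = 2.0 / ((m - 1) * (m - 2)) if m > 2 else 0.0
    closeness = {}
    for s in nodes:
        reachable = len(dist[s]) - 1
        total = sum(dist[s].values())
        closeness[s] = reachable / total if total > 0 else 0.0
    return {
        s: (graph.degree(s), betweenness[s] * scale, closeness[s]) for s in nodes
    }


class TestComputeMetrics:
    def test_path_graph_closed_form(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        metrics = {m.node: m for m in compute_metrics(g)}
        assert metrics["B"].betweenness == pytest.approx(1.0)
        assert metrics["B"].closeness == pytest.approx(1.0)
        assert metrics["A"].betweenness == 0.0
        assert metrics["A"].closeness == pytest.approx(2 / 3)

    def test_five_node_star_closed_form(self):
        g = nx.star_graph(4)
        metrics = {m.node: m for m in compute_metrics(g)}
        assert metrics[0].betweenness == pytest.approx(1.0)
        assert metrics[0].closeness == pytest.approx(1.0)
        assert metrics[1].closeness == pytest.approx(4 / 7)
        assert metrics[1].betweenness == 0.0  # degree-1 node

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph([("A", "B")])
        g.add_node("Z")
        metrics = {m.node: m for m in compute_metrics(g)}
        assert metrics["Z"].closeness == 0.0 and metrics["Z"].degree == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_graphs_match_brute_force_oracle(self, seed):
        g = nx.gnp_random_graph(30, 0.12, seed=seed)
        expected = brute_force_metrics(g)
        for m in compute_metrics(g):
            deg, bet, clo = expected[m.node]
            assert m.degree == deg
            assert m.betweenness == pytest.approx(bet, abs=1e-12)
            assert m.closeness == pytest.approx(clo, abs=1e-12)

    def test_directed_and_multi_edge_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(nx.DiGraph([("A", "B")]))
        with pytest.raises(ValueError):
            compute_metrics(nx.MultiGraph([("A", "B"), ("A", "B")]))

    def test_protein_scope_restricts_to_protein_subgraph(self, toy_network):
        all_nodes = compute_metrics(toy_network, scope="all_nodes")
        proteins = compute_metrics(toy_network, scope="protein_nodes")
        assert {m.node for m in proteins} < {m.node for m in all_nodes}
        assert all(m.kind == "protein" for m in proteins)


def _metrics(rows):
    return [NodeMetrics(node=n, kind="protein", degree=d, betweenness=b, closeness=c)
            for n, d, b, c in rows]


class TestScreenCandidates:
    def test_degree_gate_median_rule_instance(self):
        degrees = [1, 1, 1, 1, 2, 2, 2, 9]  # median 1.5 -> gate at 3
        metrics = _metrics(
            [(f"n{i}", d, 0.5, 0.5) for i, d in enumerate(degrees)]
        )
        result = screen_candidates(metrics, HubRuleConfig())
        assert result.degree_threshold == pytest.approx(3.0)
        assert result.hubs == ("n7",)

    def test_identical_metrics_give_empty_candidates(self):
        metrics = _metrics([(f"n{i}", 3, 0.2, 0.4) for i in range(6)])
        result = screen_candidates(metrics, HubRuleConfig())
        assert result.candidates == ()

    def test_candidates_need_both_centralities_above_median(self):
        metrics = _metrics(
            [
                ("hub_ok", 10, 0.9, 0.9),
                ("hub_low_bet", 10, 0.0, 0.9),
                ("hub_low_clo", 10, 0.9, 0.0),
                ("a", 1, 0.1, 0.1),
                ("b", 1, 0.2, 0.2),
                ("c", 1, 0.3, 0.3),
                ("d", 1, 0.4, 0.4),
            ]
        )
        result = screen_candidates(metrics, HubRuleConfig())
        assert result.candidates == ("hub_ok",)

    def test_override_thresholds_are_reported_and_applied(self):
        metrics = _metrics([("x", 9, 0.001, 0.4), ("y", 8, 0.001, 0.4), ("z", 9, 0.0001, 0.4)])
        rule = HubRuleConfig(thresholds_override=(8, 0.0004, 0.3681))
        result = screen_candidates(metrics, rule)
        assert result.thresholds() == {
            "degree": 8.0,
            "betweenness": 0.0004,
            "closeness": 0.3681,
        }
        # strict >: y fails degree, z fails betweenness
        assert result.candidates == ("x",)

    def test_invariant_under_relabeling(self):
        g = nx.barabasi_albert_graph(60, 2, seed=4)
        mapping = {n: f"node_{(n * 17) % 60:02d}" for n in g.nodes}
        relabeled = nx.relabel_nodes(g, mapping)
        result = screen_candidates(compute_metrics(g), HubRuleConfig())
        relabeled_result = screen_candidates(compute_metrics(relabeled), HubRuleConfig())
        assert sorted(mapping[n] for n in result.candidates) == sorted(
            relabeled_result.candidates
        )
        assert relabeled_result.degree_threshold == result.degree_threshold

    def test_candidate_set_shrinks_as_multiplier_grows(self):
        g = nx.barabasi_albert_graph(80, 3, seed=8)
        metrics = compute_metrics(g)
        previous = None
        for mult in (1.0, 1.5, 2.0, 3.0, 5.0):
            cands = set(
                screen_candidates(metrics, HubRuleConfig(degree_multiplier=mult)).candidates
            )
            if previous is not None:
                assert cands <= previous
            previous = cands

    def test_matches_independent_rule_reimplementation(self):
        g = nx.barabasi_albert_graph(50, 2, seed=13)
        oracle = brute_force_metrics(g)
        degrees = sorted(d for d, _, _ in oracle.values())
        bets = sorted(b for _, b, _ in oracle.values())
        clos = sorted(c for _, _, c in oracle.values())

        def med(values):
            mid = len(values) // 2
            return (values[mid - 1] + values[mid]) / 2 if len(values) % 2 == 0 else values[mid]

        expected = sorted(
            n
            for n, (d, b, c) in oracle.items()
            if d > 2 * med(degrees) and b > med(bets) and c > med(clos)
        )
        result = screen_candidates(compute_metrics(g), HubRuleConfig())
        assert list(result.candidates) == expected

    def test_fractional_median_convention(self):
        # even-length input -> midpoint of the two central values
        metrics = _metrics([("a", 11, 0.1, 0.1), ("b", 12, 0.2, 0.2)])
        result = screen_candidates(metrics, HubRuleConfig(degree_multiplier=1.0))
        assert result.degree_threshold == pytest.approx(11.5)

    def test_empty_metrics_rejected(self):
        with pytest.raises(ValueError):
            screen_candidates([], HubRuleConfig())
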