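"""Node-centrality computation and the median-based hub-screening rule.

Candidate protein targets are nominated in two stages on the assembled
network: first the *hub* gate — degree strictly greater than a multiple
(default 2x) of the median degree of all scoped nodes — then hubs must also
exceed the median betweenness and the median closeness. All three medians
use the midpoint-of-two-central-values convention and all comparisons are
strict.

Conventions (NetworkAnalyzer-compatible):

* betweenness is pair-normalized to [0, 1] by 2/((m-1)(m-2)) where m is the
  number of nodes analyzed;
* closeness is component-restricted: (number of reachable nodes) / (sum of
  shortest-path distances to them), 0 for an isolated node.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Literal, Sequence

import networkx as nx

from .network import CTDNetwork

__all__ = ["NodeMetrics", "HubRuleConfig", "ScreenResult", "compute_metrics", "screen_candidates"]

Scope = Literal["all_nodes", "protein_nodes"]


@dataclass(frozen=True)
class NodeMetrics:
    """Degree, normalized betweenness and closeness for one node."""

    node: str
    kind: str
    degree: int
    betweenness: float
    closeness: float


@dataclass(frozen=True)
class HubRuleConfig:
    """Configuration of the hub-screening rule.

    With ``thresholds_override`` set to explicit (degree, betweenness,
    closeness) cutoffs the medians are skipped and the strict comparisons
    run against the given values — e.g. a previously published
    configuration such as (8, 0.0004, 0.3681).
    """

    degree_multiplier: float = 2.0
    scope: Scope = "all_nodes"
    thresholds_override: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.degree_multiplier <= 0:
            raise ValueError(f"degree_multiplier must be > 0, got {self.degree_multiplier}")
        if self.scope not in ("all_nodes", "protein_nodes"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the screening rule: thresholds, hubs and candidates."""

    degree_threshold: float
    betweenness_threshold: float
    closeness_threshold: float
    hubs: tuple[str, ...]
    candidates: tuple[str, ...]

    def thresholds(self) -> dict[str, float]:
        return {
            "degree": self.degree_threshold,
            "betweenness": self.betweenness_threshold,
            "closeness": self.closeness_threshold,
        }


def compute_metrics(net: CTDNetwork | nx.Graph, scope: Scope = "all_nodes") -> list[NodeMetrics]:
    """Exact degree, betweenness and closeness for every scoped node.

    ``scope="protein_nodes"`` analyzes the protein-induced subgraph instead
    of the full heterogeneous network. Output is sorted by node id.
    """
    graph = net.graph if isinstance(net, CTDNetwork) else net
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("metrics require a simple undirected graph")
    if scope == "protein_nodes":
        keep = [n for n, d in graph.nodes(data=True) if d.get("kind") == "protein"]
        graph = graph.subgraph(keep)
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    return [
        NodeMetrics(
            node=node,
            kind=graph.nodes[node].get("kind", "protein"),
            degree=graph.degree(node),
            betweenness=betweenness[node],
            closeness=closeness[node],
        )
        for node in sorted(graph.nodes)
    ]


def screen_candidates(metrics: Sequence[NodeMetrics], rule: HubRuleConfig) -> ScreenResult:
    """Apply the median-based hub rule and report the derived thresholds.

    Without an override, the degree cutoff is ``degree_multiplier x
    median(degree)`` and the betweenness/closeness cutoffs are the plain
    medians, all over the supplied metrics; candidates are hubs strictly
    above both centrality cutoffs.
    """
    if not metrics:
        raise ValueError("metrics must be non-empty")
    if rule.thresholds_override is not None:
        deg_thr, bet_thr, clo_thr = (float(v) for v in rule.thresholds_override)
    else:
        deg_thr = rule.degree_multiplier * median(m.degree for m in metrics)
        bet_thr = median(m.betweenness for m in metrics)
        clo_thr = median(m.closeness for m in metrics)
    hubs = tuple(sorted(m.node for m in metrics if m.degree > deg_thr))
    hub_set = set(hubs)
    candidates = tuple(
        sorted(
            m.node
            for m in metrics
            if m.node in hub_set and m.betweenness > bet_thr and m.closeness > clo_thr
        )
    )
    return ScreenResult(
        degree_threshold=deg_thr,
        betweenness_threshold=bet_thr,
        closeness_threshold=clo_thr,
        hubs=hubs,
        candidates=candidates,
    )
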