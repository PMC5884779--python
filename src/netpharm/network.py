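"""Assembly of the compound-target-disease (CTD) network.

The network is built in three steps: (1) threshold the docking predictions
at the fit-score cutoff and connect retained drug targets to compounds and
compounds to their herbs; (2) connect disease-database targets to the drug
targets through protein-protein interactions, discarding disease targets
that cannot be connected within the allowed number of hops; (3) the herbs,
compounds, drug targets, retained disease targets and any bridging
interaction proteins together form one simple undirected heterogeneous
graph stored in a :class:`networkx.Graph`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import DiseaseTargetDB, PPIEdgeList, PredictionRecord

__all__ = [
    "ConnectionConfig",
    "CTDNetwork",
    "filter_predictions",
    "build_drug_network",
    "connect_disease_targets",
]

logger = logging.getLogger(__name__)

NODE_KINDS = ("herb", "compound", "protein")
EDGE_KINDS = ("herb-compound", "compound-protein", "protein-protein")


@dataclass(frozen=True)
class ConnectionConfig:
    """Thresholds governing network assembly.

    ``score_threshold`` is inclusive (a prediction scoring exactly the
    threshold is retained). ``max_path_length`` is the number of PPI hops
    allowed between a disease target and a drug target for the disease
    target to count as connected; 1 means a direct interaction.
    """

    score_threshold: float = 4.0
    max_path_length: int = 1

    def __post_init__(self) -> None:
        if self.score_threshold < 0:
            raise ValueError(f"score_threshold must be >= 0, got {self.score_threshold}")
        if self.max_path_length < 1:
            raise ValueError(f"max_path_length must be >= 1, got {self.max_path_length}")


class CTDNetwork:
    """Typed heterogeneous compound-target-disease graph.

    Thin wrapper over an undirected simple :class:`networkx.Graph` whose
    nodes carry ``kind`` in {herb, compound, protein}; protein nodes carry
    ``is_drug_target`` and a (possibly empty) ``diseases`` frozenset.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        # Filled by connect_disease_targets.
        self.retained_disease_targets: frozenset[str] = frozenset()
        self.n_discarded_disease_targets: int = 0
        self.n_direct_overlap: int = 0
        self.n_ppi_connected: int = 0

    # -- construction helpers -------------------------------------------------

    def add_node(self, node: str, kind: str, **attrs: object) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        existing = self.graph.nodes.get(node)
        if existing is not None and existing["kind"] != kind:
            raise ValueError(
                f"node {node!r} already present with kind {existing['kind']!r}, "
                f"cannot re-add as {kind!r}"
            )
        if existing is None:
            if kind == "protein":
                attrs.setdefault("is_drug_target", False)
                attrs.setdefault("diseases", frozenset())
            self.graph.add_node(node, kind=kind, **attrs)
        else:
            # only explicitly passed attributes update an existing node
            existing.update(attrs)

    def add_edge(self, a: str, b: str, kind: str) -> None:
        if kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {kind!r}")
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        expected = tuple(kind.split("-"))
        kinds = (self.graph.nodes[a]["kind"], self.graph.nodes[b]["kind"])
        if kinds != expected and kinds != expected[::-1]:
            raise ValueError(
                f"edge kind {kind!r} incompatible with node kinds {kinds}"
            )
        self.graph.add_edge(a, b, kind=kind)

    # -- views ----------------------------------------------------------------

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == kind)

    @property
    def herbs(self) -> list[str]:
        return self.nodes_of_kind("herb")

    @property
    def compounds(self) -> list[str]:
        return self.nodes_of_kind("compound")

    @property
    def proteins(self) -> list[str]:
        return self.nodes_of_kind("protein")

    @property
    def drug_targets(self) -> frozenset[str]:
        return frozenset(
            n
            for n, d in self.graph.nodes(data=True)
            if d["kind"] == "protein" and d.get("is_drug_target")
        )

    def copy(self) -> "CTDNetwork":
        clone = CTDNetwork(self.graph.copy())
        clone.retained_disease_targets = self.retained_disease_targets
        clone.n_discarded_disease_targets = self.n_discarded_disease_targets
        clone.n_direct_overlap = self.n_direct_overlap
        clone.n_ppi_connected = self.n_ppi_connected
        return clone

    def summary_counts(self) -> dict[str, int]:
        kinds = nx.get_edge_attributes(self.graph, "kind")
        counts = {f"n_{k}_nodes": len(self.nodes_of_kind(k)) for k in NODE_KINDS}
        for ek in EDGE_KINDS:
            counts[f"n_{ek.replace('-', '_')}_edges"] = sum(
                1 for v in kinds.values() if v == ek
            )
        return counts


def filter_predictions(
    records: Sequence[PredictionRecord], config: ConnectionConfig
) -> list[PredictionRecord]:
    """Keep predictions with fit_score >= the threshold, preserving order.

    Idempotent: filtering an already-filtered list is a no-op.
    """
    return [r for r in records if r.fit_score >= config.score_threshold]


def build_drug_network(
    filtered: Sequence[PredictionRecord],
    herb_membership: Mapping[str, Sequence[str]],
) -> CTDNetwork:
    """Connect herbs, compounds and predicted drug targets into one graph.

    Every herb in ``herb_membership`` becomes a herb node. A compound node
    appears only if it carries at least one retained prediction; it is
    linked to every herb that lists it. Every predicted protein becomes a
    protein node flagged ``is_drug_target``.
    """
    compound_to_herbs: dict[str, list[str]] = {}
    for herb, compounds in herb_membership.items():
        for c in compounds:
            compound_to_herbs.setdefault(c, []).append(herb)

    net = CTDNetwork()
    for herb in herb_membership:
        net.add_node(herb, "herb")

    for rec in filtered:
        if rec.compound_id not in compound_to_herbs:
            raise ValueError(
                f"compound {rec.compound_id!r} has a retained prediction but "
                f"no herb membership"
            )
        if rec.compound_id not in net.graph:
            net.add_node(rec.compound_id, "compound")
            for herb in compound_to_herbs[rec.compound_id]:
                net.add_edge(herb, rec.compound_id, "herb-compound")
        if rec.target not in net.graph:
            net.add_node(rec.target, "protein", is_drug_target=True)
        else:
            net.graph.nodes[rec.target]["is_drug_target"] = True
        net.add_edge(rec.compound_id, rec.target, "compound-protein")

    counts = net.summary_counts()
    logger.info(
        "drug network: %d herbs, %d compounds, %d drug targets, %d compound-protein edges",
        counts["n_herb_nodes"],
        counts["n_compound_nodes"],
        counts["n_protein_nodes"],
        counts["n_compound_protein_edges"],
    )
    return net


def _multi_source_bfs(
    adjacency: Mapping[str, set[str]], sources: Iterable[str], max_depth: int
) -> dict[str, int]:
    """Distances (<= max_depth) from the nearest source over the adjacency."""
    dist = {s: 0 for s in sources if s in adjacency}
    frontier = list(dist)
    depth = 0
    while frontier and depth < max_depth:
        depth += 1
        nxt = []
        for u in frontier:
            for v in adjacency.get(u, ()):
                if v not in dist:
                    dist[v] = depth
                    nxt.append(v)
        frontier = nxt
    return dist


def connect_disease_targets(
    net: CTDNetwork,
    db: DiseaseTargetDB,
    ppi: PPIEdgeList,
    config: ConnectionConfig,
) -> CTDNetwork:
    """Attach connectable disease targets to the drug network via PPI.

    A disease target is retained iff it is itself a drug target, or a PPI
    path of length <= ``config.max_path_length`` links it to a drug target;
    all others are discarded. Retained targets are added as protein nodes
    annotated with their diseases (targets that are also drug targets keep
    the flag and gain the annotation — the "common targets" of drug and
    disease). For hop budgets above 1, bridging interaction proteins within
    distance max_path_length - 1 of a drug target are added so retained
    targets are topologically connected. Finally every PPI edge whose two
    endpoints are present is added. The input network is not mutated.
    """
    net = net.copy()
    drug_targets = net.drug_targets
    if not drug_targets:
        raise ValueError("network has no drug-target protein nodes")

    adjacency: dict[str, set[str]] = {}
    for a, b in ppi.edges:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    if not ppi.edges:
        warnings.warn(
            "empty PPI edge list: only disease targets that are themselves "
            "drug targets can be retained",
            stacklevel=2,
        )

    dist = _multi_source_bfs(adjacency, drug_targets, config.max_path_length)
    direct = db.universe & drug_targets
    via_ppi = {
        t
        for t in db.universe
        if t not in drug_targets and 0 < dist.get(t, config.max_path_length + 1) <= config.max_path_length
    }
    retained = direct | via_ppi
    bridges = {
        u
        for u, d in dist.items()
        if 0 < d <= config.max_path_length - 1 and u not in retained and u not in drug_targets
    }

    target_to_diseases: dict[str, set[str]] = {}
    for disease, members in db.entries.items():
        for t in members:
            target_to_diseases.setdefault(t, set()).add(disease)

    for t in sorted(retained):
        net.add_node(t, "protein", diseases=frozenset(target_to_diseases[t]))
    for u in sorted(bridges):
        net.add_node(u, "protein")

    present = set(net.proteins)
    for a, b in ppi.edges:
        if a in present and b in present:
            net.add_edge(a, b, "protein-protein")

    net.retained_disease_targets = frozenset(retained)
    net.n_discarded_disease_targets = db.n_universe - len(retained)
    net.n_direct_overlap = len(direct)
    net.n_ppi_connected = len(via_ppi)
    logger.info(
        "disease connection: N=%d universe, n=%d retained (%d direct drug-target "
        "overlap, %d via PPI), %d discarded, %d bridge proteins",
        db.n_universe,
        len(retained),
        len(direct),
        len(via_ppi),
        net.n_discarded_disease_targets,
        len(bridges),
    )
    return net
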