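"""Model/Results facade over the repositioning pipeline.

:class:`NetworkPharmacologyModel` is built from the four input tables
(predictions, herb membership, disease database, PPI); its :meth:`fit`
assembles the compound-target-disease network, runs the hypergeometric
disease enrichment, the centrality screen and the per-herb attribution, and
returns a :class:`RepositioningResults` carrying the ranked tables, the
derived thresholds and a text :meth:`~RepositioningResults.summary`.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import io
from .enrichment import (
    DiseaseEnrichmentRow,
    EnrichmentConfig,
    enrich_diseases,
    select_major_diseases,
)
from .herbs import HerbAttributionRow, attribute_herbs
from .io import DiseaseTargetDB, PPIEdgeList, PredictionRecord, format_pvalue
from .network import (
    ConnectionConfig,
    CTDNetwork,
    build_drug_network,
    connect_disease_targets,
    filter_predictions,
)
from .topology import HubRuleConfig, NodeMetrics, ScreenResult, compute_metrics, screen_candidates

__all__ = ["NetworkPharmacologyModel", "RepositioningResults"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentOptions:
    """User-tunable enrichment settings; N and n are derived from the data."""

    variant: str = "point"
    alpha: float = 0.05
    min_match: int = 2
    correction: str = "none"


class NetworkPharmacologyModel:
    """Compound-target-disease repositioning model for a multi-herb drug."""

    def __init__(
        self,
        predictions: list[PredictionRecord],
        herb_membership: dict[str, tuple[str, ...]],
        disease_db: DiseaseTargetDB,
        ppi: PPIEdgeList,
        connection: ConnectionConfig | None = None,
        enrichment: EnrichmentOptions | None = None,
        hub_rule: HubRuleConfig | None = None,
    ) -> None:
        self.predictions = predictions
        self.herb_membership = herb_membership
        self.disease_db = disease_db
        self.ppi = ppi
        self.connection = connection or ConnectionConfig()
        self.enrichment = enrichment or EnrichmentOptions()
        self.hub_rule = hub_rule or HubRuleConfig()

    @classmethod
    def from_files(
        cls,
        predictions_path: str,
        herb_membership_path: str,
        disease_gmt_path: str,
        ppi_path: str,
        ppi_format: str = "tsv",
        **kwargs: object,
    ) -> "NetworkPharmacologyModel":
        return cls(
            predictions=io.read_prediction_table(predictions_path),
            herb_membership=io.read_herb_membership(herb_membership_path),
            disease_db=io.read_gmt(disease_gmt_path),
            ppi=io.read_edge_list(ppi_path, format=ppi_format),
            **kwargs,  # type: ignore[arg-type]
        )

    def fit(self, compute_topology: bool = True) -> "RepositioningResults":
        """Run the full analysis and return the results object.

        ``compute_topology=False`` skips the all-pairs centrality stage
        (the expensive part) when only the disease ranking is needed.
        """
        retained = filter_predictions(self.predictions, self.connection)
        net = build_drug_network(retained, self.herb_membership)
        net = connect_disease_targets(net, self.disease_db, self.ppi, self.connection)

        n = len(net.retained_disease_targets)
        config = EnrichmentConfig(
            N=self.disease_db.n_universe,
            n=n,
            variant=self.enrichment.variant,  # type: ignore[arg-type]
            alpha=self.enrichment.alpha,
            min_match=self.enrichment.min_match,
            correction=self.enrichment.correction,  # type: ignore[arg-type]
        )
        disease_rows = enrich_diseases(
            self.disease_db, net.retained_disease_targets, config
        )
        major = select_major_diseases(disease_rows, config)

        metrics: list[NodeMetrics] = []
        screen: ScreenResult | None = None
        attribution: list[HerbAttributionRow] = []
        if compute_topology:
            metrics = compute_metrics(net, scope=self.hub_rule.scope)
            screen = screen_candidates(metrics, self.hub_rule)
            attribution = attribute_herbs(net, sorted(net.retained_disease_targets))
            logger.info(
                "screen thresholds: degree>%g betweenness>%g closeness>%g; "
                "%d hubs, %d candidates",
                screen.degree_threshold,
                screen.betweenness_threshold,
                screen.closeness_threshold,
                len(screen.hubs),
                len(screen.candidates),
            )

        return RepositioningResults(
            model=self,
            network=net,
            enrichment_config=config,
            disease_enrichment=disease_rows,
            major_diseases=major,
            node_metrics=metrics,
            screen=screen,
            herb_attribution=attribution,
        )


@dataclass
class RepositioningResults:
    """Fitted pipeline outputs: ranked tables, thresholds and diagnostics."""

    model: NetworkPharmacologyModel
    network: CTDNetwork
    enrichment_config: EnrichmentConfig
    disease_enrichment: list[DiseaseEnrichmentRow]
    major_diseases: list[DiseaseEnrichmentRow]
    node_metrics: list[NodeMetrics] = field(default_factory=list)
    screen: ScreenResult | None = None
    herb_attribution: list[HerbAttributionRow] = field(default_factory=list)

    # -- tabular views --------------------------------------------------------

    def disease_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.disease_enrichment])

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        hubs = set(self.screen.hubs) if self.screen else set()
        cands = set(self.screen.candidates) if self.screen else set()
        for m in self.node_metrics:
            d = asdict(m)
            d["is_hub"] = m.node in hubs
            d["is_candidate"] = m.node in cands
            rows.append(d)
        return pd.DataFrame(rows)

    def attribution_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.herb_attribution])

    @property
    def candidate_targets(self) -> tuple[str, ...]:
        """Candidate *protein* targets: screen survivors of protein kind.

        The medians of the screening rule are taken over every scoped node,
        but only proteins are nominated as drug targets.
        """
        if self.screen is None:
            return ()
        g = self.network.graph
        return tuple(
            n for n in self.screen.candidates if g.nodes[n]["kind"] == "protein"
        )

    def summary(self) -> str:
        """Plain-text report of the fitted pipeline, statsmodels-style."""
        cfg = self.enrichment_config
        counts = self.network.summary_counts()
        lines = [
            "Network pharmacology repositioning results",
            "=" * 58,
            f"Herbs: {counts['n_herb_nodes']}   Compounds: {counts['n_compound_nodes']}   "
            f"Proteins: {counts['n_protein_nodes']}",
            f"Disease-target universe N = {cfg.N}; connected n = {cfg.n} "
            f"({self.network.n_direct_overlap} direct, {self.network.n_ppi_connected} via PPI); "
            f"discarded {self.network.n_discarded_disease_targets}",
            f"Enrichment variant: {cfg.variant}; filter: p < {cfg.alpha}, match > {cfg.min_match}",
            "",
            f"Major predicted diseases ({len(self.major_diseases)}):",
        ]
        for r in self.major_diseases:
            lines.append(
                f"  {r.disease:<40s} {r.match:>4d}\\{r.total:<5d} p={format_pvalue(r.p_value)}"
            )
        if self.screen is not None:
            lines += [
                "",
                "Candidate-target screen (strict > thresholds):",
                f"  degree > {self.screen.degree_threshold:g}, "
                f"betweenness > {self.screen.betweenness_threshold:.6g}, "
                f"closeness > {self.screen.closeness_threshold:.6g}",
                f"  {len(self.screen.hubs)} hubs -> {len(self.candidate_targets)} protein candidates: "
                + ", ".join(self.candidate_targets[:12])
                + ("..." if len(self.candidate_targets) > 12 else ""),
            ]
        if self.herb_attribution:
            lines += ["", "Per-herb component-connectivity medians:"]
            seen: dict[str, float] = {}
            for r in self.herb_attribution:
                seen.setdefault(r.herb, r.herb_median)
            for herb, med in seen.items():
                n_major = sum(
                    1 for r in self.herb_attribution if r.herb == herb and r.is_major
                )
                lines.append(f"  {herb:<12s} median={med:g}  major targets={n_major}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------

    def save_reports(self, outdir: str) -> list[str]:
        """Write all result tables as deterministic TSV/JSON; returns paths."""
        import json
        import os

        os.makedirs(outdir, exist_ok=True)
        written: list[str] = []

        def _write(name: str, rows: list[dict], columns: list[str]) -> None:
            path = os.path.join(outdir, name)
            io.write_report(rows, path, columns)
            written.append(path)

        _write(
            "disease_enrichment.tsv",
            [asdict(r) for r in self.disease_enrichment],
            ["disease", "match", "total", "p_value"],
        )
        _write(
            "major_diseases.tsv",
            [asdict(r) for r in self.major_diseases],
            ["disease", "match", "total", "p_value"],
        )
        g = self.network.graph
        _write(
            "network_nodes.tsv",
            [
                {
                    "node": n,
                    "kind": d["kind"],
                    "is_drug_target": bool(d.get("is_drug_target", False)),
                    "diseases": ";".join(sorted(d.get("diseases", ()))),
                }
                for n, d in sorted(g.nodes(data=True))
            ],
            ["node", "kind", "is_drug_target", "diseases"],
        )
        _write(
            "network_edges.tsv",
            [
                {"source": a, "target": b, "kind": g.edges[a, b]["kind"]}
                for a, b in sorted(tuple(sorted(e)) for e in g.edges)
            ],
            ["source", "target", "kind"],
        )
        if self.node_metrics:
            df = self.metrics_table()
            _write(
                "node_metrics.tsv",
                df.to_dict("records"),
                ["node", "kind", "degree", "betweenness", "closeness", "is_hub", "is_candidate"],
            )
        if self.herb_attribution:
            _write(
                "herb_attribution.tsv",
                [asdict(r) for r in self.herb_attribution],
                ["herb", "target", "component_count", "herb_median", "is_major"],
            )
        if self.screen is not None:
            path = os.path.join(outdir, "thresholds.json")
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(self.screen.thresholds(), fh, sort_keys=True)
                fh.write("\n")
            written.append(path)
        return written
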