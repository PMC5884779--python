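"""One-shot pipeline orchestration with a YAML config and a run manifest.

Stages communicate only through files, so each CLI subcommand is
independently testable; :func:`run_pipeline` chains them in-process and
writes a JSON manifest recording input checksums, the effective
configuration and the derived quantities (universe size N, connected count
n, screening thresholds). Re-running on identical inputs reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from . import io
from .enrichment import EnrichmentConfig, enrich_from_counts
from .model import EnrichmentOptions, NetworkPharmacologyModel
from .network import ConnectionConfig
from .pathways import enrich_pathways
from .simulate import SyntheticConfig, SyntheticInputs, generate_inputs
from .topology import HubRuleConfig

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_inputs"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    Either the four input ``paths`` (predictions, herbs, disease_gmt, ppi)
    or a ``simulate`` block must be present. ``pathway_gmt`` is optional;
    when given, a pathway ORA of the candidate targets is added.
    """

    outdir: str
    paths: dict[str, str] = field(default_factory=dict)
    simulate: SyntheticConfig | None = None
    connection: ConnectionConfig = field(default_factory=ConnectionConfig)
    enrichment: EnrichmentOptions = field(default_factory=EnrichmentOptions)
    hub_rule: HubRuleConfig = field(default_factory=HubRuleConfig)
    pathway_gmt: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {"outdir": raw["outdir"]}
        if "paths" in raw:
            kwargs["paths"] = dict(raw["paths"])
        if "simulate" in raw:
            sim = dict(raw["simulate"])
            if "compounds_per_herb" in sim:
                sim["compounds_per_herb"] = tuple(sim["compounds_per_herb"])
            if "disease_size_range" in sim:
                sim["disease_size_range"] = tuple(sim["disease_size_range"])
            kwargs["simulate"] = SyntheticConfig(**sim)
        if "connection" in raw:
            kwargs["connection"] = ConnectionConfig(**raw["connection"])
        if "enrichment" in raw:
            kwargs["enrichment"] = EnrichmentOptions(**raw["enrichment"])
        if "hub_rule" in raw:
            hub = dict(raw["hub_rule"])
            if hub.get("thresholds_override") is not None:
                hub["thresholds_override"] = tuple(hub["thresholds_override"])
            kwargs["hub_rule"] = HubRuleConfig(**hub)
        for key in ("pathway_gmt", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_inputs(inputs: SyntheticInputs, outdir: str) -> dict[str, str]:
    """Write the four synthetic inputs in the formats the readers expect."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "predictions": os.path.join(outdir, "predictions.tsv"),
        "herbs": os.path.join(outdir, "herb_membership.tsv"),
        "disease_gmt": os.path.join(outdir, "disease_targets.gmt"),
        "ppi": os.path.join(outdir, "ppi_edges.tsv"),
    }
    io.write_prediction_table(inputs.predictions, paths["predictions"])
    io.write_herb_membership(inputs.herb_membership, paths["herbs"])
    io.write_gmt(inputs.disease_db, paths["disease_gmt"])
    io.write_edge_list(inputs.ppi, paths["ppi"])
    return paths


def _config_echo(config: PipelineConfig) -> dict[str, Any]:
    echo: dict[str, Any] = {
        "connection": asdict(config.connection),
        "enrichment": asdict(config.enrichment),
        "hub_rule": asdict(config.hub_rule),
        "pathway_gmt": config.pathway_gmt,
    }
    if config.simulate is not None:
        echo["simulate"] = asdict(config.simulate)
    return echo


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run simulate/load -> build -> enrich -> screen -> attribute -> report.

    Returns the manifest (also written to ``<outdir>/manifest.json``). Any
    stage failure removes partial outputs and raises :class:`PipelineError`
    naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    written: list[str] = []
    stage = "configure"
    try:
        if config.simulate is not None:
            stage = "simulate"
            inputs_dir = os.path.join(config.outdir, "inputs")
            inputs = generate_inputs(config.simulate)
            input_paths = write_inputs(inputs, inputs_dir)
            written.extend(input_paths.values())
        else:
            input_paths = dict(config.paths)
            missing = [k for k in ("predictions", "herbs", "disease_gmt", "ppi") if k not in input_paths]
            if missing:
                raise ValueError(f"missing input path(s): {missing}")

        stage = "load"
        model = NetworkPharmacologyModel.from_files(
            input_paths["predictions"],
            input_paths["herbs"],
            input_paths["disease_gmt"],
            input_paths["ppi"],
            ppi_format="sif" if input_paths["ppi"].endswith(".sif") else "tsv",
            connection=config.connection,
            enrichment=config.enrichment,
            hub_rule=config.hub_rule,
        )

        stage = "fit"
        results = model.fit()

        stage = "report"
        written.extend(results.save_reports(config.outdir))

        if config.pathway_gmt:
            stage = "enrich-pathways"
            pathway_db = io.read_gmt(config.pathway_gmt)
            query = set(results.candidate_targets) & pathway_db.universe
            rows = enrich_pathways(query, pathway_db)
            path = os.path.join(config.outdir, "pathway_enrichment.tsv")
            io.write_report(
                [asdict(r) for r in rows],
                path,
                ["pathway", "count", "pathway_size", "background_size", "p_value"],
            )
            written.append(path)

        stage = "manifest"
        cfg = results.enrichment_config
        manifest: dict[str, Any] = {
            "inputs": {k: _sha256(v) for k, v in sorted(input_paths.items())},
            "config": _config_echo(config),
            "derived": {
                "N": cfg.N,
                "n": cfg.n,
                "n_direct_overlap": results.network.n_direct_overlap,
                "n_ppi_connected": results.network.n_ppi_connected,
                "n_discarded_disease_targets": results.network.n_discarded_disease_targets,
                "n_major_diseases": len(results.major_diseases),
                "thresholds": results.screen.thresholds() if results.screen else None,
                "n_candidates": len(results.candidate_targets),
            },
            "outputs": sorted(os.path.relpath(p, config.outdir) for p in written),
        }
        manifest_path = os.path.join(config.outdir, "manifest.json")
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info(
            "pipeline complete: N=%d n=%d discarded=%d outputs=%d",
            cfg.N,
            cfg.n,
            results.network.n_discarded_disease_targets,
            len(written),
        )
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise PipelineError(stage, exc) from exc


def reference_report(outdir: str) -> str:
    """Recompute the published 34-disease ranking from its (k, K) inputs."""
    from .simulate import reference_fixture

    triples, cfg = reference_fixture()
    rows = enrich_from_counts(triples, cfg)
    os.makedirs(outdir, exist_ok=True)
    path = os.path.join(outdir, "disease_enrichment.tsv")
    io.write_report(
        [asdict(r) for r in rows],
        path,
        ["disease", "match", "total", "p_value"],
    )
    return path
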