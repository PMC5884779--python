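"""Seeded synthetic inputs emulating the structure of the real study data.

Four inputs drive the pipeline: a compound->target prediction table with
docking fit scores, a herb->compound membership table, a disease->target
database (GMT) and an undirected PPI edge list. None of the real inputs are
redistributable, so this module generates all four with the statistical
structure the analysis assumes, at the study's scale by default (6 herbs,
219 compounds, 229 drug targets, 63 diseases over a 749-target universe)
or smaller. Everything is a deterministic function of one integer seed.

Key calibrations (see docs/methods.md for rationale):

* fit scores ~ Normal(4.2, 0.8) truncated at 0, straddling the 4.0
  retention threshold so the filter is exercised nontrivially;
* 25% of drug targets are drawn from the disease universe (the "common
  targets" of drug and disease);
* Erdos-Renyi PPI edge probability 6.4e-4, chosen so the expected number
  of connected disease targets at full scale is ~151;
* disease set sizes log-uniform on [1, 370], matching the heavy right skew
  of curated disease-gene sets;
* a coverage floor guarantees every compound and every drug target appears
  in at least one suprathreshold prediction, so the assembled network has
  exactly the configured compound and drug-target dimensions.

A *planted* disease can be injected whose target set overlaps the
drug-connected pool by a chosen fraction; recovering it as the top-ranked
enrichment hit is the pipeline's end-to-end correctness probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .enrichment import EnrichmentConfig
from .io import DiseaseTargetDB, PPIEdgeList, PredictionRecord

__all__ = ["SyntheticConfig", "SyntheticInputs", "generate_inputs", "reference_fixture", "REFERENCE_DISEASE_COUNTS"]

# The 34 (disease, match k, total K) pairs of the published worked example of
# this enrichment (liver-disease repositioning of a six-herb formula), with
# universe N=749 and connected count n=151. Used as a direct input to the
# enrichment stage, bypassing network construction.
REFERENCE_DISEASE_COUNTS: tuple[tuple[str, int, int], ...] = (
    ("Hepatitis", 48, 176),
    ("Liver Failure, Acute", 4, 5),
    ("Hypertension, Portal", 6, 11),
    ("Hepatitis B", 18, 57),
    ("Fatty Liver", 15, 45),
    ("Liver Failure", 15, 52),
    ("Hepatolenticular Degeneration", 6, 16),
    ("Carcinoma, Hepatocellular", 77, 370),
    ("Liver Cirrhosis", 4, 34),
    ("Hepatomegaly", 7, 49),
    ("Zellweger Syndrome", 3, 28),
    ("Hepatitis, Autoimmune", 3, 7),
    ("Liver Cirrhosis, Biliary", 5, 16),
    ("Hepatitis C", 13, 63),
    ("Liver Neoplasms", 12, 56),
    ("Budd-Chiari Syndrome", 2, 4),
    ("Hepatitis, Chronic", 6, 28),
    ("Liver Cirrhosis, Alcoholic", 1, 1),
    ("Peliosis Hepatis", 1, 1),
    ("Hepatic Encephalopathy", 2, 5),
    ("Hepatitis B, Chronic", 2, 6),
    ("Hepatitis C, Chronic", 1, 9),
    ("Alagille Syndrome", 2, 9),
    ("Protoporphyria, Erythropoietic", 1, 2),
    ("Esophageal and Gastric Varices", 1, 2),
    ("Porphyrias, Hepatic", 1, 2),
    ("Non-alcoholic Fatty Liver Disease", 1, 8),
    ("Fatty Liver, Alcoholic", 1, 8),
    ("Rift Valley Fever", 1, 3),
    ("Hepatic Insufficiency", 1, 3),
    ("Porphyria Cutanea Tarda", 1, 3),
    ("Porphyria, Variegate", 1, 4),
    ("Hepatitis A", 1, 4),
    ("Reye Syndrome", 1, 4),
)


def reference_fixture() -> tuple[list[tuple[str, int, int]], EnrichmentConfig]:
    """The published 34-disease (k, K) table plus its (N=749, n=151) config.

    Feed the triples to :func:`netpharm.enrichment.enrich_from_counts` to
    reproduce the worked disease-ranking example without building a network.
    """
    return list(REFERENCE_DISEASE_COUNTS), EnrichmentConfig(N=749, n=151, variant="point")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults reproduce the study's input scale."""

    seed: int
    n_herbs: int = 6
    compounds_per_herb: tuple[int, int] = (19, 79)
    n_compounds: int = 219
    n_drug_targets: int = 229
    n_disease_targets: int = 749
    n_diseases: int = 63
    disease_size_range: tuple[int, int] = (1, 370)
    ppi_model: str = "erdos_renyi"
    ppi_edge_prob: float = 6.4e-4
    ppi_attachment: int = 2
    n_ppi_extras: int = 150
    drug_target_overlap: float = 0.25
    targets_per_compound_mean: float = 10.0
    fit_score_loc: float = 4.2
    fit_score_scale: float = 0.8
    score_floor: float = 4.0
    planted_disease: str | None = None
    planted_overlap: float = 0.0
    planted_size: int = 20

    def __post_init__(self) -> None:
        for name in (
            "n_herbs",
            "n_compounds",
            "n_drug_targets",
            "n_disease_targets",
            "n_diseases",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ppi_model not in ("erdos_renyi", "preferential_attachment"):
            raise ValueError(f"unknown ppi_model {self.ppi_model!r}")
        if not (0.0 <= self.drug_target_overlap <= 1.0):
            raise ValueError("drug_target_overlap must be in [0, 1]")
        if self.planted_disease is not None:
            if not (0.0 <= self.planted_overlap <= 1.0):
                raise ValueError("planted_overlap must be in [0, 1]")
            if not (1 <= self.planted_size <= self.n_disease_targets):
                raise ValueError("planted_size out of range")

    @classmethod
    def small(cls, seed: int, **overrides: object) -> "SyntheticConfig":
        """A down-scaled configuration for fast tests and examples."""
        base = cls(
            seed=seed,
            n_herbs=3,
            compounds_per_herb=(3, 8),
            n_compounds=15,
            n_drug_targets=25,
            n_disease_targets=80,
            n_diseases=10,
            disease_size_range=(1, 25),
            ppi_edge_prob=0.01,
            n_ppi_extras=20,
            targets_per_compound_mean=5.0,
        )
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class SyntheticInputs:
    """The four generated inputs, ready for the pipeline."""

    predictions: list[PredictionRecord]
    herb_membership: dict[str, tuple[str, ...]]
    disease_db: DiseaseTargetDB
    ppi: PPIEdgeList
    connected_pool: frozenset[str] = field(default_factory=frozenset)


def _herb_membership(
    rng: np.random.Generator, config: SyntheticConfig, compounds: Sequence[str]
) -> dict[str, list[str]]:
    lo, hi = config.compounds_per_herb
    if lo > hi or lo < 1:
        raise ValueError(f"bad compounds_per_herb range {config.compounds_per_herb}")
    herbs = [f"herb{i + 1:02d}" for i in range(config.n_herbs)]
    for _ in range(200):
        quotas = rng.integers(lo, hi + 1, size=config.n_herbs)
        if quotas.sum() >= config.n_compounds and quotas.max() <= config.n_compounds:
            break
    else:
        raise ValueError(
            "infeasible configuration: per-herb compound quotas cannot cover "
            f"{config.n_compounds} compounds"
        )
    membership: dict[str, list[str]] = {h: [] for h in herbs}
    remaining = quotas.astype(float).copy()
    # First pass: every compound lands in exactly one herb with spare quota.
    for c in rng.permutation(np.asarray(compounds, dtype=object)):
        probs = remaining / remaining.sum()
        i = int(rng.choice(config.n_herbs, p=probs))
        membership[herbs[i]].append(str(c))
        remaining[i] = max(remaining[i] - 1.0, 1e-9)
    # Second pass: top herbs up to their quotas with shared compounds.
    for i, herb in enumerate(herbs):
        have = set(membership[herb])
        deficit = int(quotas[i]) - len(have)
        if deficit > 0:
            others = [c for c in compounds if c not in have]
            extra = rng.choice(np.asarray(others, dtype=object), size=deficit, replace=False)
            membership[herb].extend(str(c) for c in extra)
    return membership


def generate_inputs(config: SyntheticConfig) -> SyntheticInputs:
    """Generate the four pipeline inputs; identical seeds give identical data.

    Raises ``ValueError`` on infeasible configurations, e.g. a planted
    overlap requiring more drug-connected targets than exist.
    """
    rng = np.random.default_rng(config.seed)

    compounds = [f"CMP{i + 1:04d}" for i in range(config.n_compounds)]
    universe = [f"P{i + 1:05d}" for i in range(config.n_disease_targets)]

    membership = _herb_membership(rng, config, compounds)

    # Drug targets: a fraction are disease-universe members, the rest new.
    n_overlap = round(config.drug_target_overlap * config.n_drug_targets)
    overlap_targets = [
        str(t)
        for t in rng.choice(np.asarray(universe, dtype=object), size=n_overlap, replace=False)
    ]
    fresh = [f"Q{i + 1:05d}" for i in range(config.n_drug_targets - n_overlap)]
    drug_targets = overlap_targets + fresh

    # Predictions: per-compound target sets with truncated-normal scores.
    per_compound: dict[str, dict[str, float]] = {}
    dt_array = np.asarray(drug_targets, dtype=object)
    for c in compounds:
        size = int(min(max(1, rng.poisson(config.targets_per_compound_mean)), len(drug_targets)))
        chosen = rng.choice(dt_array, size=size, replace=False)
        scores = np.maximum(
            rng.normal(config.fit_score_loc, config.fit_score_scale, size=size), 0.0
        )
        per_compound[c] = {str(t): float(s) for t, s in zip(chosen, scores)}
        # Coverage floor: every compound survives the threshold filter.
        if max(per_compound[c].values()) < config.score_floor:
            best = max(per_compound[c], key=per_compound[c].__getitem__)
            per_compound[c][best] = config.score_floor + abs(float(rng.normal(0.0, 0.3)))
    covered = {
        t
        for hits in per_compound.values()
        for t, s in hits.items()
        if s >= config.score_floor
    }
    for t in drug_targets:
        if t not in covered:
            c = compounds[int(rng.integers(len(compounds)))]
            per_compound[c][t] = config.score_floor + abs(float(rng.normal(0.0, 0.3)))

    predictions = [
        PredictionRecord(compound_id=c, herb_id=herb, target=t, fit_score=s)
        for herb, herb_compounds in membership.items()
        for c in herb_compounds
        for t, s in sorted(per_compound[c].items())
    ]

    # PPI over universe + drug targets + unrelated interactors.
    extras = [f"R{i + 1:05d}" for i in range(config.n_ppi_extras)]
    ppi_nodes = universe + fresh + extras
    graph_seed = int(rng.integers(2**31))
    if config.ppi_model == "erdos_renyi":
        g = nx.fast_gnp_random_graph(len(ppi_nodes), config.ppi_edge_prob, seed=graph_seed)
    else:
        g = nx.barabasi_albert_graph(len(ppi_nodes), config.ppi_attachment, seed=graph_seed)
    relabel = dict(enumerate(ppi_nodes))
    edges = frozenset(
        (relabel[a], relabel[b]) if relabel[a] <= relabel[b] else (relabel[b], relabel[a])
        for a, b in g.edges
    )
    ppi = PPIEdgeList(edges=edges)

    # Drug-connected pool: universe targets that are drug targets or PPI
    # neighbours of one (the targets retainable at max_path_length=1).
    neighbours: set[str] = set()
    drug_set = set(drug_targets)
    for a, b in edges:
        if a in drug_set:
            neighbours.add(b)
        if b in drug_set:
            neighbours.add(a)
    connected_pool = frozenset((set(overlap_targets) | neighbours) & set(universe))

    # Disease sets: log-uniform sizes, planted disease drawn from the pool.
    lo, hi = config.disease_size_range
    disease_names = [f"disease{i + 1:02d}" for i in range(config.n_diseases)]
    n_regular = config.n_diseases - (1 if config.planted_disease else 0)
    sizes = np.rint(
        np.exp(rng.uniform(math.log(lo), math.log(hi + 1), size=n_regular))
    ).astype(int)
    sizes = np.clip(sizes, lo, min(hi, config.n_disease_targets))
    uni_array = np.asarray(universe, dtype=object)
    entries: dict[str, set[str]] = {}
    for name, size in zip(disease_names, sizes):
        entries[name] = {
            str(t) for t in rng.choice(uni_array, size=int(size), replace=False)
        }
    if config.planted_disease:
        need = math.ceil(config.planted_overlap * config.planted_size)
        pool = sorted(connected_pool)
        if need > len(pool):
            raise ValueError(
                f"planted overlap needs {need} drug-connected targets but only "
                f"{len(pool)} exist"
            )
        members = {
            str(t)
            for t in rng.choice(np.asarray(pool, dtype=object), size=need, replace=False)
        }
        rest = sorted(set(universe) - members)
        extra_n = config.planted_size - need
        if extra_n > 0:
            members |= {
                str(t)
                for t in rng.choice(np.asarray(rest, dtype=object), size=extra_n, replace=False)
            }
        entries[config.planted_disease] = members

    # Guarantee the universe equals the union of the disease sets.
    missing = sorted(set(universe) - set().union(*entries.values()))
    regular_names = [n for n in entries if n != config.planted_disease]
    for t in missing:
        entries[regular_names[int(rng.integers(len(regular_names)))]].add(t)

    db = DiseaseTargetDB(entries={k: frozenset(v) for k, v in entries.items()})
    return SyntheticInputs(
        predictions=predictions,
        herb_membership={h: tuple(cs) for h, cs in membership.items()},
        disease_db=db,
        ppi=ppi,
        connected_pool=connected_pool,
    )
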