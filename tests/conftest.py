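import logging

import pytest

from netpharm.io import DiseaseTargetDB, PPIEdgeList, PredictionRecord
from netpharm.network import ConnectionConfig, build_drug_network
from netpharm.simulate import SyntheticConfig, generate_inputs

logging.getLogger("netpharm").setLevel(logging.WARNING)


@pytest.fixture
def toy_predictions():
    """2 herbs x 2 compounds x 3 targets; 4 compound-protein edges."""
    return [
        PredictionRecord("c1", "h1", "P00001", 5.0),
        PredictionRecord("c1", "h1", "P00002", 4.5),
        PredictionRecord("c2", "h2", "P00002", 6.0),
        PredictionRecord("c2", "h2", "P00003", 4.0),
    ]


@pytest.fixture
def toy_membership():
    return {"h1": ("c1",), "h2": ("c2",)}


@pytest.fixture
def toy_network(toy_predictions, toy_membership):
    return build_drug_network(toy_predictions, toy_membership)


@pytest.fixture
def toy_disease_db():
    return DiseaseTargetDB(
        entries={
            "liverA": frozenset({"P00001", "P00010"}),
            "liverB": frozenset({"P00002", "P00010", "P00011"}),
            "liverC": frozenset({"P00012"}),
        }
    )


@pytest.fixture
def toy_ppi():
    return PPIEdgeList(
        edges=frozenset(
            {
                ("P00001", "P00010"),  # disease target P00010 <-> drug target
                ("P00011", "P00020"),  # disease target <-> unrelated protein
            }
        )
    )


@pytest.fixture
def default_connection():
    return ConnectionConfig()


@pytest.fixture(scope="session")
def small_inputs():
    """Down-scaled synthetic inputs shared across tests (read-only)."""
    return generate_inputs(SyntheticConfig.small(seed=7))


@pytest.fixture(scope="session")
def paper_scale_inputs():
    """Study-scale synthetic inputs (219 compounds, 229 targets, 63x749)."""
    return generate_inputs(SyntheticConfig(seed=11))
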