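import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from stemtrace.datatypes import (
    AnalysisConfig,
    ExpressionMatrix,
    InteractionNetwork,
    OntologyAnnotation,
    edge,
)
from stemtrace.measures import compute_ic
from stemtrace.simulate import SimulationParams, simulate_all


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def toy_expr():
    """3 genes x 4 samples, two groups, easy numbers."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [10.0, 10.2, 8.0, 7.8],
                [5.0, 5.0, 5.0, 5.0],
                [6.0, 6.1, 6.9, 7.0],
            ]
        ),
        groups={"s1": "CSC", "s2": "CSC", "s3": "nonCSC", "s4": "nonCSC"},
    )


@pytest.fixture
def chain_ontology():
    """root <- t1 <- t2 with 4 annotated genes: 2 reach t1, 1 reaches t2."""
    onto = OntologyAnnotation(
        terms={"root", "t1", "t2"},
        parents={"t1": {"root"}, "t2": {"t1"}},
        root="root",
        gene2terms={
            "g1": {"t2"},
            "g2": {"t1"},
            "g3": {"root"},
            "g4": {"root"},
        },
    )
    return compute_ic(onto)


@pytest.fixture
def path_network():
    return InteractionNetwork(
        nodes={"a", "b", "c"}, edges={edge("a", "b"), edge("b", "c")}
    )


@pytest.fixture(scope="session")
def default_sim():
    """One full simulated bundle at the default study conditions."""
    return simulate_all(SimulationParams(seed=11))
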