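import pytest
from hypothesis import settings

settings.register_profile("fast", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("fast")

import kgmatch as km


@pytest.fixture
def toy_graph():
    """Six-participant consultation graph (one AP, TI, TC, PM; two TM)."""
    return km.consultation_data_graph()


@pytest.fixture
def pattern():
    """Five-role consultation pattern, thresholds 0.3 (nodes) / 0.2 (edges), k=2."""
    return km.reference_pattern()


def make_random_graph(seed, sizes=None, p=0.35, planted=0):
    """Small role-structured random graph for randomized suites."""
    spec = km.SynthSpec(
        nodes_per_role=sizes or {"AP": 3, "TI": 2, "TC": 3, "PM": 2, "TM": 2},
        edge_probability=p,
        planted_embeddings=planted,
        seed=seed,
    )
    return km.generate_data_graph(spec)


@pytest.fixture
def random_graph_factory():
    return make_random_graph
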