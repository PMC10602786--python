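import numpy as np
import pytest

from consortium_net import AbundanceTable, ConsortiumNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    """Relative-mode table, 6 taxa x 20 samples, generic random composition."""
    raw = rng.gamma(2.0, 1.0, size=(20, 6))
    rel = raw / raw.sum(axis=1, keepdims=True)
    return AbundanceTable(
        sample_ids=[f"s{i}" for i in range(20)],
        taxon_ids=[f"t{j}" for j in range(6)],
        values=rel,
        generations=["G1"] * 10 + ["G2"] * 10,
        replicates=list(range(1, 11)) * 2,
        mode="relative",
    )


@pytest.fixture
def toy_network():
    """Path A-B-C plus isolated D, unit weights."""
    return ConsortiumNetwork.from_edges(
        nodes=["A", "B", "C", "D"],
        edges=[("A", "B", "+", 1.0, 0.01), ("B", "C", "-", 1.0, 0.02)],
    )
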