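import numpy as np
import pytest

from mmgsa import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleMetadata,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def tiny_matrix():
    """3 genes x 6 samples, two batches, fixed values."""
    rng = np.random.default_rng(7)
    values = rng.normal(7.0, 0.5, size=(3, 6))
    genes = ["G1", "G2", "G3"]
    samples = [f"S{i}" for i in range(1, 7)]
    matrix = ExpressionMatrix(genes, samples, values)
    meta = SampleMetadata(
        samples,
        ["control", "control", "control", "case", "case", "case"],
        ["B1", "B2", "B1", "B2", "B1", "B2"],
        samples,
    )
    return matrix, meta


@pytest.fixture
def small_dataset():
    """Default-condition synthetic dataset (8 cases vs 4 controls, 20 sets)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture
def two_set_collection():
    return GeneSetCollection(
        [
            GeneSet("ALPHA", "na", ("G1", "G2", "G3")),
            GeneSet("BETA", "na", ("G2", "G4")),
        ]
    )
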