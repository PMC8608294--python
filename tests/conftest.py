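import numpy as np
import pytest

from katzsp import AssociationMatrix, DiseaseOntology, SyntheticConfig, generate_benchmark


@pytest.fixture(scope="session")
def toy_dataset():
    """6 lncRNAs x 6 diseases with 8 known pairs and two similarity blocks."""
    values = np.zeros((6, 6))
    pairs = [(0, 0), (0, 1), (1, 1), (1, 2), (2, 0), (3, 3), (4, 4), (5, 5)]
    for i, j in pairs:
        values[i, j] = 1.0
    ld = AssociationMatrix(
        values,
        [f"l{i}" for i in range(1, 7)],
        [f"d{j}" for j in range(1, 7)],
    )
    dag = DiseaseOntology(
        edges={
            ("d1", "d2"),
            ("d1", "d3"),
            ("d2", "d3"),
            ("d4", "d5"),
            ("d4", "d6"),
        }
    )
    return ld, dag


@pytest.fixture(scope="session")
def planted_benchmark():
    """Default planted-block benchmark (40x50, 4 blocks, strong signal)."""
    return generate_benchmark(SyntheticConfig(seed=1))
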