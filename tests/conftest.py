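import numpy as np
import pytest

from rcnet.fc_network import FCMatrix, WeightedNetwork
from rcnet.synthetic import CohortConfig


@pytest.fixture
def toy_net() -> WeightedNetwork:
    """Four-node network: edges (A,B)=1, (A,C)=3, (B,C)=2, (B,D)=3.

    Strengths: A=4, B=6, C=5, D=3.
    """
    return WeightedNetwork(
        node_ids=["A", "B", "C", "D"],
        node_hemisphere=["ipsi", "ipsi", "contra", "contra"],
        edge_i=np.array([0, 0, 1, 1]),
        edge_j=np.array([1, 2, 2, 3]),
        weights=np.array([1.0, 3.0, 2.0, 3.0]),
    )


def random_small_network(rng: np.random.Generator, max_nodes: int = 6) -> WeightedNetwork:
    """Random connected-ish weighted network with up to ``max_nodes`` nodes."""
    while True:
        n = int(rng.integers(3, max_nodes + 1))
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < 0.7
        if keep.sum() >= 2:
            break
    return WeightedNetwork(
        node_ids=[f"n{i}" for i in range(n)],
        node_hemisphere=["ipsi" if i < n // 2 else "contra" for i in range(n)],
        edge_i=iu[keep],
        edge_j=ju[keep],
        weights=rng.uniform(0.05, 1.0, int(keep.sum())),
    )


def fc_from_matrix(r: np.ndarray, condition: str = "pre") -> FCMatrix:
    n = r.shape[0]
    half = n // 2
    return FCMatrix(
        r=r,
        roi_labels=[f"R{i}" for i in range(n)],
        roi_hemisphere=["ipsi"] * half + ["contra"] * (n - half),
        condition=condition,
    )


@pytest.fixture
def small_cohort_config() -> CohortConfig:
    """Scaled-down cohort for fast end-to-end tests."""
    return CohortConfig(
        n_animals=3,
        n_rois_per_hemisphere=8,
        club_size=4,
        n_timepoints=500,
        seed=11,
    )
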