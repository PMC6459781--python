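import numpy as np
import pytest

from nbdacutoff import (
    AssociationNetwork,
    ObservationMatrix,
    SyntheticConfig,
    dyad_counts,
    generate_observations,
    sri_matrix,
)


@pytest.fixture
def tiny_obs() -> ObservationMatrix:
    """Three observations of three individuals (hand-enumerable)."""
    return ObservationMatrix(
        ("A", "B", "C"),
        np.array([[1, 1, 0], [1, 0, 1], [0, 1, 0]]),
    )


@pytest.fixture(scope="session")
def default_obs() -> ObservationMatrix:
    """One synthetic matrix at the generator defaults."""
    return generate_observations(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def default_net(default_obs) -> AssociationNetwork:
    """Error-free SRI network of the default synthetic data."""
    return sri_matrix(dyad_counts(default_obs))


def chain_network(n: int = 5, w: float = 1.0) -> AssociationNetwork:
    """Path graph 0-1-2-...-n with weight w on consecutive nodes."""
    m = np.zeros((n, n))
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = w
    return AssociationNetwork(tuple(f"n{i}" for i in range(n)), m)


def complete_network(n: int, w: float) -> AssociationNetwork:
    """Complete graph with every edge at weight w."""
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return AssociationNetwork(tuple(f"n{i}" for i in range(n)), m)


def random_network(n: int, rng: np.random.Generator) -> AssociationNetwork:
    m = np.triu(rng.uniform(0, 1, size=(n, n)), k=1)
    m = m + m.T
    return AssociationNetwork(tuple(f"n{i}" for i in range(n)), m)
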