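import numpy as np
import pytest

from cfmdnet.ising import IsingModel


@pytest.fixture
def two_node_coupled():
    """2-node model with tau=(0,0), omega12=1: P(1,1) = e/(3+e)."""
    return IsingModel(["a", "b"], [0.0, 0.0], [[0.0, 1.0], [1.0, 0.0]])


@pytest.fixture
def two_node_independent():
    return IsingModel(["a", "b"], [0.0, 0.0], np.zeros((2, 2)))


def random_small_model(rng: np.random.Generator, n: int, density: float = 0.5) -> IsingModel:
    """Random symmetric model for property tests."""
    omega = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                omega[i, j] = omega[j, i] = rng.normal(0, 0.8)
    tau = rng.normal(0, 0.7, size=n)
    return IsingModel([f"V{i + 1}" for i in range(n)], tau, omega)


@pytest.fixture
def toy_bridge_model():
    """6-node model (3 MD, 3 CF) with one strong positive CF->MD bridge.

    Small enough for exact enumeration; CF2-MD1 carries the planted bridge.
    """
    labels = ["MD1", "MD2", "MD3", "CF1", "CF2", "CF3"]
    omega = np.zeros((6, 6))
    pairs = {
        (0, 1): 0.8,  # MD1-MD2
        (1, 2): 0.5,  # MD2-MD3
        (3, 4): 0.6,  # CF1-CF2
        (4, 5): 0.4,  # CF2-CF3
        (0, 4): 1.5,  # MD1-CF2 planted bridge
    }
    for (i, j), w in pairs.items():
        omega[i, j] = omega[j, i] = w
    tau = np.array([-1.0, -0.8, -1.2, -0.6, -1.5, -0.9])
    partition = {lab: lab[:2] for lab in labels}
    return IsingModel(labels, tau, omega), partition
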