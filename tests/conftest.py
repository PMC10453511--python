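"""Shared fixtures: tiny synthetic systems and stub agents."""

from __future__ import annotations

import numpy as np
import pytest

import aesgrn


class StubAgent:
    """Deterministic agent computing an arbitrary function of the state."""

    def __init__(self, fn, n_genes: int, window: int, gene_index: int = 0):
        self._fn = fn
        self.gene_index = gene_index
        self.spec = type(
            "StubSpec", (), {"n_genes": n_genes, "window": window}
        )()

    def predict(self, state_values: np.ndarray) -> float:
        return float(self._fn(np.asarray(state_values)))


def copy_last_agents(n: int, m: int) -> list[StubAgent]:
    """Each gene copies its own last value: every state is a fixed point."""
    return [
        StubAgent(lambda X, i=i: X[i, -1], n, m, gene_index=i) for i in range(n)
    ]


@pytest.fixture
def stub_factory():
    return StubAgent


@pytest.fixture
def fixed_point_aes():
    n, m = 4, 5
    return aesgrn.AES(copy_last_agents(n, m)), n, m


@pytest.fixture(scope="session")
def small_system():
    return aesgrn.sample_network(10, 0.15, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_system):
    return aesgrn.simulate_dataset(small_system, b=21, k=5, sigma=0.02, seed=1)
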