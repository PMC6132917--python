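"""Shared fixtures: random graph factory and a tiny synthetic design."""

from __future__ import annotations

import numpy as np
import pytest

from painnet import CohortDesign


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_adjacency(
    rng: np.random.Generator, n: int, density: float = 0.7
) -> np.ndarray:
    """A random symmetric non-negative weighted adjacency with zero diagonal."""
    w = np.triu(rng.uniform(0.05, 1.0, (n, n)), 1)
    keep = np.triu(rng.random((n, n)) < density, 1)
    w = w * keep
    return w + w.T


@pytest.fixture()
def tiny_design() -> CohortDesign:
    """A fast-to-simulate design with a 8-node pain block in a 20-node brain."""
    return CohortDesign(
        n_patients=3,
        n_controls=3,
        n_nodes=20,
        n_frames=80,
        pain_nodes=tuple(range(8)),
        seed=99,
    )
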