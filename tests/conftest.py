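"""Shared fixtures: small genotype matrices built programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from snpresample.genotype import MISSING, GenotypeMatrix


def random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_loci: int,
    n_pops: int = 2,
    missing_rate: float = 0.1,
) -> GenotypeMatrix:
    """A random two-population dosage matrix with missingness."""
    calls = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int8)
    calls[rng.random((n_samples, n_loci)) < missing_rate] = MISSING
    pops = [f"P{(i * n_pops) // n_samples + 1}" for i in range(n_samples)]
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)],
        pops,
        [f"L{j}" for j in range(n_loci)],
        calls,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def small_two_pop(rng) -> GenotypeMatrix:
    return random_matrix(rng, n_samples=12, n_loci=30)


@pytest.fixture
def one_pop_matrix() -> GenotypeMatrix:
    """Deterministic single-population matrix with hand-checkable loci."""
    calls = np.array(
        [
            [0, 1, 2, MISSING],
            [1, 1, 2, 0],
            [2, 1, 2, 0],
            [0, 1, 2, MISSING],
            [1, 1, 2, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        [f"s{i}" for i in range(5)],
        ["A"] * 5,
        ["L0", "L1", "L2", "L3"],
        calls,
    )
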