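import numpy as np
import pytest

from cliffpop.genotypes import MISSING, GenotypeMatrix, PopulationMap


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """6 individuals x 4 loci with one missing cell."""
    g = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 2, 0],
            [2, 0, 2, 0],
            [0, 1, 1, MISSING],
            [1, 2, 1, 0],
            [2, 2, 1, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        g,
        tuple(f"ind{i}" for i in range(6)),
        ("L1", "L2", "L3", "L4"),
    )


@pytest.fixture
def two_pop_map() -> PopulationMap:
    return PopulationMap(
        {f"ind{i}": ("A" if i < 3 else "B") for i in range(6)}
    )


def random_matrix(rng: np.random.Generator, n_ind: int, n_loci: int,
                  missing_prob: float = 0.0) -> GenotypeMatrix:
    g = rng.integers(0, 3, size=(n_ind, n_loci)).astype(np.int8)
    if missing_prob:
        g[rng.random(g.shape) < missing_prob] = MISSING
    return GenotypeMatrix(
        g, tuple(f"i{k}" for k in range(n_ind)), tuple(f"L{k}" for k in range(n_loci))
    )
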