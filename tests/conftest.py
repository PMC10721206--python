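import numpy as np
import pytest
import scipy.sparse as sp

from meiomap.io import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix():
    """2 cells x 3 genes with entries (cell1, g1)=4 and (cell2, g3)=1."""
    counts = sp.csr_matrix(np.array([[4, 0, 0], [0, 0, 1]]))
    return CountMatrix(["cell1", "cell2"], ["g1", "g2", "g3"], counts)


@pytest.fixture
def labeled_matrix(rng):
    """60 cells in 3 clusters x 20 genes of Poisson noise, gene g0 elevated
    in cluster c1."""
    counts = rng.poisson(2.0, size=(60, 20))
    counts[:20, 0] += 20
    cells = [f"cell{i:02d}" for i in range(60)]
    clusters = {c: f"c{1 + i // 20}" for i, c in enumerate(cells)}
    return CountMatrix(
        cells, [f"g{j}" for j in range(20)], sp.csr_matrix(counts), clusters
    )
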