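import numpy as np
import pytest

from mdmr import (
    DataMatrix,
    DesignMatrix,
    compute_distance_matrix,
    gower_center,
)


@pytest.fixture
def anova_case():
    """The univariate worked example y=(1,2,3,5) with groups (0,0,1,1).

    Classical one-way ANOVA gives SSR=6.25, SSE=2.5, F=5.0; exhaustive
    enumeration of the 6 distinct group assignments gives permutation
    p = 2/6.
    """
    data = DataMatrix(np.array([[1.0], [2.0], [3.0], [5.0]]),
                      ["a", "b", "c", "d"], ["y"])
    design = DesignMatrix(np.array([0.0, 0.0, 1.0, 1.0]), ["group"])
    dm = compute_distance_matrix(data)
    return data, dm, gower_center(dm), design


def random_euclidean_gower(rng, n, p=3):
    """Gower matrix of a random Gaussian dataset (Euclidean distances)."""
    data = DataMatrix(rng.standard_normal((n, p)),
                      [f"s{i}" for i in range(n)],
                      [f"v{j}" for j in range(p)])
    return data, gower_center(compute_distance_matrix(data))
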