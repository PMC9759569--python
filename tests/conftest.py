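import numpy as np
import pytest
from scipy.linalg import hadamard

from commstab import CommunityMatrix


@pytest.fixture
def toy_values():
    """Two species with zero sample covariance: a=(2,4,2,4), b=(1,3,3,1)."""
    return np.column_stack([[2.0, 4.0, 2.0, 4.0], [1.0, 3.0, 3.0, 1.0]])


@pytest.fixture
def toy_community(toy_values):
    return CommunityMatrix(values=toy_values, species=["a", "b"],
                           times=[1, 2, 3, 4], plot_id="toy", site_id="site1")


@pytest.fixture
def rng():
    return np.random.default_rng(20220914)


def orthogonal_community(n_species: int, offset: float = 10.0, scale=None,
                         plot_id: str = "orth", site_id: str = "site1",
                         start_col: int = 1) -> CommunityMatrix:
    """Community whose species series are exactly mutually orthogonal.

    Columns of a Hadamard matrix are mean-zero (except the first) and
    pairwise orthogonal, so the sample covariances are exactly zero and,
    unless rescaled, all variances are equal.
    """
    T = 16
    H = hadamard(T).astype(float)
    cols = H[:, start_col:start_col + n_species]
    if scale is not None:
        cols = cols * np.asarray(scale)
    values = cols + offset
    return CommunityMatrix(values=values,
                           species=[f"s{j}" for j in range(n_species)],
                           times=list(range(T)), plot_id=plot_id, site_id=site_id)


def random_community(rng, S=None, T=None) -> CommunityMatrix:
    """Random non-degenerate community for fuzzing identities."""
    S = S or int(rng.integers(2, 9))
    T = T or int(rng.integers(5, 40))
    mu = rng.uniform(5, 100, S)
    sd = rng.uniform(0.5, 10, S)
    A = rng.standard_normal((S, S))
    corr_src = A @ A.T
    d = np.sqrt(np.diag(corr_src))
    L = np.linalg.cholesky(corr_src / np.outer(d, d) + 1e-9 * np.eye(S))
    x = mu + (rng.standard_normal((T, S)) @ L.T) * sd
    return CommunityMatrix(values=x, species=[f"sp{j}" for j in range(S)],
                           times=list(range(T)))
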