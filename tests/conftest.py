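import numpy as np
import pytest

from meansfield.spd import TrialCovarianceSet


def random_spd(rng: np.random.Generator, n: int, cond: float = 10.0) -> np.ndarray:
    """Random SPD matrix with eigenvalues log-uniform in [1/cond, cond]."""
    A = rng.normal(size=(n, n))
    Q, _ = np.linalg.qr(A)
    lam = np.exp(rng.uniform(-np.log(cond) / 2, np.log(cond) / 2, size=n))
    return (Q * lam) @ Q.T


def random_spd_set(
    rng: np.random.Generator, n_mats: int, dim: int, weights: bool = False
) -> TrialCovarianceSet:
    mats = np.stack([random_spd(rng, dim) for _ in range(n_mats)])
    w = None
    if weights:
        w = rng.uniform(0.5, 2.0, size=n_mats)
    return TrialCovarianceSet(mats, weights=w)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
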