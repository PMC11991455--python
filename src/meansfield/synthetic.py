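"""Synthetic SPD clouds and mixed-source epochs with known ground truth.

Two families of generators make every stage of the pipeline testable without
EEG recordings:

* ``sample_spd_cloud`` / ``make_two_class_set`` draw SPD trial covariances
  from a log-normal (tangent-space Gaussian) model around controllable class
  centers: trial = ``C^{1/2} exp(S) C^{1/2}`` with S a random symmetric
  matrix of scale sigma.  Center and dispersion are independently
  controllable, unlike a Wishart model; outliers are planted by inflating
  the dispersion of a fraction of trials (the noisy-trial failure mode the
  robust estimator targets), not by moving centers.
* ``make_mixed_source_epochs`` builds raw two-class epochs from latent
  sources whose variances differ by class on a designated subset (an
  event-related-desynchronization analogue), mixed by a random full-rank
  matrix plus white sensor noise, exercising covariance estimation and
  spatial filtering end to end.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spd import Epoch, TrialCovarianceSet, sym_expm, sym_sqrtm, validate_spd

__all__ = [
    "SimulationSpec",
    "sample_spd_cloud",
    "make_two_class_set",
    "make_mixed_source_epochs",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a two-class SPD cloud.

    ``dispersion`` is the tangent-space noise scale sigma (a scalar, or a
    pair for per-class dispersions); ``class_separation`` the geodesic
    distance between the class centers; outliers replace
    ``outlier_fraction`` of each class with trials drawn at
    ``outlier_magnitude`` times the class dispersion.
    """

    n_channels: int = 4
    n_trials_per_class: int = 40
    dispersion: float | tuple = 0.3
    class_separation: float = 1.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least 1 trial per class")
        disp = self.dispersion if isinstance(self.dispersion, tuple) else (self.dispersion,) * 2
        if any(s < 0 for s in disp):
            raise ValueError("dispersion must be nonnegative")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")
        if not 0 <= self.outlier_fraction < 0.5:
            raise ValueError("outlier_fraction must lie in [0, 0.5)")
        if self.outlier_fraction > 0 and self.outlier_magnitude <= 1:
            raise ValueError("outlier_magnitude must exceed 1")

    @property
    def class_dispersions(self) -> tuple[float, float]:
        d = self.dispersion
        return d if isinstance(d, tuple) else (float(d), float(d))


def _random_symmetric(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    A = rng.normal(scale=scale, size=(n, n))
    return (A + A.T) / 2.0


def sample_spd_cloud(
    center: np.ndarray, sigma: float, n: int, seed: int | np.random.Generator = 0
) -> TrialCovarianceSet:
    """n SPD trials log-normally scattered around a center with scale sigma.

    Each trial is ``center^{1/2} exp(S) center^{1/2}`` with S symmetric,
    independent Gaussian entries of scale sigma; sigma = 0 returns n exact
    copies of the center.
    """
    if n < 1:
        raise ValueError("need at least 1 sample")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    center = validate_spd(center, "center")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dim = center.shape[0]
    Ch = sym_sqrtm(center)
    mats = np.empty((n, dim, dim))
    for i in range(n):
        if sigma == 0:
            mats[i] = center
        else:
            mats[i] = Ch @ sym_expm(_random_symmetric(rng, dim, sigma)) @ Ch
            mats[i] = (mats[i] + mats[i].T) / 2.0
    return TrialCovarianceSet(mats)


def two_class_centers(spec: SimulationSpec, rng: np.random.Generator):
    """Class centers a geodesic distance ``class_separation`` apart: the
    identity, and ``exp(sep * V)`` for a random unit-norm symmetric V."""
    n = spec.n_channels
    c0 = np.eye(n)
    V = _random_symmetric(rng, n, 1.0)
    V /= np.linalg.norm(V)
    c1 = sym_expm(spec.class_separation * V)
    return c0, c1


def make_two_class_set(spec: SimulationSpec) -> TrialCovarianceSet:
    """Balanced two-class SPD cloud with optional planted outliers.

    Labels are 0/1; outlier trials (the first ``outlier_fraction`` share of
    each class, positions fixed by construction for ground-truth checks) are
    drawn with dispersion inflated by ``outlier_magnitude``.
    """
    rng = np.random.default_rng(spec.seed)
    c0, c1 = two_class_centers(spec, rng)
    disp = spec.class_dispersions
    m = spec.n_trials_per_class
    n_out = int(round(spec.outlier_fraction * m))
    mats, labels = [], []
    for cls, (center, sigma) in enumerate(zip((c0, c1), disp)):
        clean = sample_spd_cloud(center, sigma, m - n_out, rng)
        mats.append(clean.matrices)
        if n_out:
            noisy = sample_spd_cloud(
                center, sigma * spec.outlier_magnitude, n_out, rng
            )
            mats.append(noisy.matrices)
        labels.extend([cls] * m)
    return TrialCovarianceSet(np.concatenate(mats), np.asarray(labels))


def outlier_indices(spec: SimulationSpec) -> np.ndarray:
    """Indices of the planted outliers in :func:`make_two_class_set` output
    (the trailing block of each class)."""
    m = spec.n_trials_per_class
    n_out = int(round(spec.outlier_fraction * m))
    idx = []
    for cls in range(2):
        start = cls * m + (m - n_out)
        idx.extend(range(start, cls * m + m))
    return np.asarray(idx, dtype=int)


def make_mixed_source_epochs(
    n_channels: int = 30,
    n_sources: int = 8,
    n_trials_per_class: int = 40,
    n_samples: int = 256,
    snr: float = 2.0,
    n_discriminative: int = 2,
    seed: int = 0,
):
    """Two-class raw epochs from linearly mixed latent sources.

    The first ``n_discriminative`` sources carry the class contrast: source
    ``i`` has standard deviation ``2.0 * 0.75**i`` in class 1 versus 0.5 in
    class 0 (an event-related-desynchronization analogue; the decaying
    contrast keeps the discriminative directions non-degenerate); the
    remaining sources have unit variance in both classes.  Sources are mixed by a random full-rank
    ``n_channels x n_sources`` matrix; white sensor noise is scaled so the
    per-channel average signal-to-noise variance ratio equals ``snr``
    (``snr = inf`` means no noise).

    Returns ``(epochs, info)`` where ``epochs`` is a list of
    :class:`~meansfield.spd.Epoch` with labels 0/1 and ``info`` holds the
    ground-truth ``mixing`` matrix, its pseudoinverse ``unmixing``, and the
    discriminative source indices.
    """
    if n_sources > n_channels:
        raise ValueError("n_sources must not exceed n_channels")
    if n_discriminative > n_sources:
        raise ValueError("n_discriminative must not exceed n_sources")
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n_channels, n_sources))
    while np.linalg.matrix_rank(A) < n_sources:  # pragma: no cover
        A = rng.normal(size=(n_channels, n_sources))
    epochs = []
    for cls in (0, 1):
        sd = np.ones(n_sources)
        for i in range(n_discriminative):
            sd[i] = 2.0 * 0.75**i if cls == 1 else 0.5
        for _ in range(n_trials_per_class):
            S = rng.normal(size=(n_sources, n_samples)) * sd[:, None]
            X = A @ S
            if np.isfinite(snr):
                signal_var = np.mean(X**2)
                noise_sd = np.sqrt(signal_var / snr)
                X = X + rng.normal(scale=noise_sd, size=X.shape)
            epochs.append(Epoch(X, label=cls))
    info = {
        "mixing": A,
        "unmixing": np.linalg.pinv(A),
        "discriminative_sources": np.arange(n_discriminative),
    }
    return epochs, info
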