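"""Primitives on the manifold of symmetric positive-definite (SPD) matrices.

Trial covariance matrices of multichannel EEG epochs are SPD, and the whole
classification machinery in this package (power means, minimum-distance
classifiers, spatial filters) lives on the SPD manifold equipped with the
affine-invariant (Fisher–Rao) metric

    d(A, B) = || log(A^{-1/2} B A^{-1/2}) ||_F,

which is invariant under congruence ``C -> F C F^T`` (any invertible F) and
under matrix inversion.  All matrix functions are computed through the
symmetric eigendecomposition, which is exact and numerically stable for
symmetric matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "SPDValidationError",
    "Epoch",
    "TrialCovarianceSet",
    "validate_spd",
    "sym_funm",
    "sym_power",
    "sym_logm",
    "sym_expm",
    "sym_sqrtm",
    "sym_invsqrtm",
    "airm_distance",
    "geodesic_point",
    "congruence",
    "oas_covariance",
]

#: relative tolerance under which a slightly asymmetric matrix is symmetrized
#: rather than rejected
SYMMETRY_RTOL = 1e-10


class SPDValidationError(ValueError):
    """Raised when a matrix violates the SPD contract (asymmetry or a
    non-positive eigenvalue)."""


@dataclass
class Epoch:
    """One EEG trial: a channels x samples array plus its class label."""

    samples: np.ndarray
    label: object = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("epoch samples must be a 2-D channels x samples array")
        n_channels, n_samples = self.samples.shape
        if n_samples < 2:
            raise ValueError("epoch must contain at least 2 time samples")


@dataclass
class TrialCovarianceSet:
    """A labeled, optionally weighted collection of same-dimension SPD trials.

    ``matrices`` is an (n_trials, n, n) stack, ``labels`` one identifier per
    trial, ``weights`` positive per-trial weights (uniform by default).
    Weights are normalized to sum to one lazily by the consumers that need
    normalized weights, so subsetting keeps raw values meaningful.
    """

    matrices: np.ndarray
    labels: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be an (n_trials, n, n) stack")
        n = len(self.matrices)
        if n == 0:
            raise ValueError("empty trial set")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length does not match number of trials")
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != n:
                raise ValueError("weights length does not match number of trials")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def dim(self) -> int:
        return self.matrices.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("trial set has no labels")
        return np.unique(self.labels)

    def normalized_weights(self) -> np.ndarray:
        return self.weights / self.weights.sum()

    def subset(self, indices) -> "TrialCovarianceSet":
        indices = np.asarray(indices)
        return TrialCovarianceSet(
            self.matrices[indices],
            None if self.labels is None else self.labels[indices],
            self.weights[indices],
        )

    def class_subset(self, label) -> "TrialCovarianceSet":
        if self.labels is None:
            raise ValueError("trial set has no labels")
        return self.subset(np.flatnonzero(self.labels == label))


def validate_spd(S: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Check symmetry and positive-definiteness; return the symmetrized matrix.

    Asymmetry below ``SYMMETRY_RTOL`` (relative, Frobenius) is repaired by
    averaging with the transpose; larger asymmetry and non-positive spectra
    raise :class:`SPDValidationError` (no silent clipping anywhere).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise SPDValidationError(f"{name} must be square, got shape {S.shape}")
    norm = np.linalg.norm(S)
    asym = np.linalg.norm(S - S.T)
    if asym > SYMMETRY_RTOL * max(norm, 1.0):
        raise SPDValidationError(
            f"{name} is not symmetric (relative asymmetry {asym / max(norm, 1e-300):.3e})"
        )
    S = (S + S.T) / 2.0
    lmin = scipy.linalg.eigh(S, eigvals_only=True, subset_by_index=[0, 0])[0]
    if lmin <= 0:
        raise SPDValidationError(
            f"{name} is not positive definite (smallest eigenvalue {lmin:.6e})"
        )
    return S


def _eigh_validated(S: np.ndarray, name: str) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise SPDValidationError(f"{name} must be square, got shape {S.shape}")
    asym = np.linalg.norm(S - S.T)
    if asym > SYMMETRY_RTOL * max(np.linalg.norm(S), 1.0):
        raise SPDValidationError(f"{name} is not symmetric")
    lam, U = scipy.linalg.eigh((S + S.T) / 2.0)
    if lam[0] <= 0:
        raise SPDValidationError(
            f"{name} is not positive definite (smallest eigenvalue {lam[0]:.6e})"
        )
    return lam, U


def sym_funm(S: np.ndarray, fn, name: str = "matrix") -> np.ndarray:
    """Apply a scalar function to an SPD matrix through its eigendecomposition."""
    lam, U = _eigh_validated(S, name)
    out = (U * fn(lam)) @ U.T
    return (out + out.T) / 2.0


def sym_power(S: np.ndarray, t: float) -> np.ndarray:
    """Matrix power ``S^t`` of an SPD matrix, for any real exponent."""
    return sym_funm(S, lambda lam: lam**t)


def sym_logm(S: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix (symmetric result)."""
    return sym_funm(S, np.log)


def sym_expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (the result is SPD)."""
    S = np.asarray(S, dtype=float)
    asym = np.linalg.norm(S - S.T)
    if asym > SYMMETRY_RTOL * max(np.linalg.norm(S), 1.0):
        raise SPDValidationError("matrix exponential input is not symmetric")
    lam, U = scipy.linalg.eigh((S + S.T) / 2.0)
    out = (U * np.exp(lam)) @ U.T
    return (out + out.T) / 2.0


def sym_sqrtm(S: np.ndarray) -> np.ndarray:
    return sym_power(S, 0.5)


def sym_invsqrtm(S: np.ndarray) -> np.ndarray:
    return sym_power(S, -0.5)


def airm_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    # d^2 = sum log^2 of the generalized eigenvalues of (B, A); cheaper and
    # equivalent to forming A^{-1/2} B A^{-1/2} explicitly
    _eigh_validated(A, "A")
    _eigh_validated(B, "B")
    lam = scipy.linalg.eigh(B, A, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def airm_distances_to(mats: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Affine-invariant distances from a stack of SPD matrices to one
    reference matrix, via a single whitening by ``ref^{-1/2}`` and a batched
    eigendecomposition.  Inputs are assumed already validated."""
    mats = np.asarray(mats, dtype=float)
    Rih = sym_invsqrtm(ref)
    whitened = np.einsum("ai,kij,bj->kab", Rih, mats, Rih)
    lam = np.linalg.eigvalsh(whitened)
    return np.sqrt(np.sum(np.log(lam) ** 2, axis=1))


def geodesic_point(A: np.ndarray, B: np.ndarray, t: float) -> np.ndarray:
    """Point ``A #_t B`` on the affine-invariant geodesic from A (t=0) to B (t=1).

    ``A #_t B = A^{1/2} (A^{-1/2} B A^{-1/2})^t A^{1/2}``;  t = 1/2 is the
    two-matrix geometric mean.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    Ah = sym_sqrtm(A)
    Aih = sym_invsqrtm(A)
    mid = sym_power(Aih @ B @ Aih, t)
    out = Ah @ mid @ Ah
    return (out + out.T) / 2.0


def congruence(F: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Congruence transform ``F C F^T`` (symmetrized)."""
    out = F @ C @ F.T
    return (out + out.T) / 2.0


def oas_covariance(epoch: Epoch | np.ndarray) -> np.ndarray:
    """Oracle Approximating Shrinkage (OAS) covariance of one epoch.

    Returns ``(1 - rho) S + rho (tr S / n) I`` where ``S = X X^T / T`` is the
    sample covariance of the (assumed zero-mean, band-passed) epoch and the
    shrinkage weight uses the closed form

        rho = min{1, [(1 - 2/n) tr(S^2) + tr^2(S)]
                     / [(T + 1 - 2/n) (tr(S^2) - tr^2(S)/n)]}.

    Shrinkage toward the scaled identity guarantees a positive-definite output
    even for rank-deficient sample covariances (short epochs, many channels).
    """
    X = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch must be a 2-D channels x samples array")
    n, T = X.shape
    if T < 2:
        raise ValueError("epoch must contain at least 2 time samples")
    S = X @ X.T / T
    mu = np.trace(S) / n
    if mu <= 0:
        raise ValueError("constant zero epoch: covariance undefined")
    tr_S2 = np.sum(S * S)
    tr2_S = np.trace(S) ** 2
    denom = (T + 1 - 2.0 / n) * (tr_S2 - tr2_S / n)
    if denom <= 0:
        # sample covariance already proportional to identity: full shrinkage
        rho = 1.0
    else:
        rho = min(1.0, ((1 - 2.0 / n) * tr_S2 + tr2_S) / denom)
    out = (1 - rho) * S + rho * mu * np.eye(n)
    return (out + out.T) / 2.0


def oas_covariances(epochs, labels=None) -> TrialCovarianceSet:
    """OAS covariance for every epoch, as a :class:`TrialCovarianceSet`.

    ``epochs`` is an (n_trials, n_channels, n_samples) array or a sequence of
    :class:`Epoch`; labels default to the per-epoch labels when present.
    """
    if isinstance(epochs, np.ndarray):
        mats = np.stack([oas_covariance(e) for e in epochs])
    else:
        epochs = list(epochs)
        mats = np.stack([oas_covariance(e) for e in epochs])
        if labels is None and epochs and isinstance(epochs[0], Epoch):
            labels = [e.label for e in epochs]
    return TrialCovarianceSet(mats, None if labels is None else np.asarray(labels))
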