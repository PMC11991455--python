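"""Spatial filtering of trial covariances: CSP, Pham's approximate joint
diagonalization, and the two-stage Adaptive Double CSP (ADCSP).

Minimum-distance classifiers degrade on large covariance matrices, so a
dimensionality-reducing spatial filter ``W`` (applied by congruence,
``C -> W C W^T``) is fitted on training covariances.  ADCSP chains two CSP
stages: a fast Euclidean stage (arithmetic class means, generalized
eigendecomposition) entered when the dimension is at least ``stage1_entry``
(default 28) and reducing to that dimension, then a Riemannian stage
(geometric class means, Pham AJD) entered when the dimension is at least
``stage2_entry`` (default 10) and reducing to 10, so classified covariances
never exceed 10 x 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .means import FieldConfig, arithmetic_mean, geometric_mean
from .spd import TrialCovarianceSet, validate_spd

__all__ = [
    "SpatialFilter",
    "csp_filters",
    "pham_ajd",
    "adcsp_fit",
    "apply_filter",
    "ADCSP",
]


@dataclass
class SpatialFilter:
    """Rectangular projection ``weights`` (n_out x n_in) applied to SPD
    matrices by congruence; ``stage_log`` records the stages applied and the
    dimension after each."""

    weights: np.ndarray
    stage_log: list = field(default_factory=list)

    @property
    def n_out(self) -> int:
        return self.weights.shape[0]

    @property
    def n_in(self) -> int:
        return self.weights.shape[1]


def _normalize_rows(W: np.ndarray) -> np.ndarray:
    """Unit-normalize rows and fix signs (largest-magnitude entry positive)."""
    W = W / np.linalg.norm(W, axis=1, keepdims=True)
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(len(W)), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def _ajd_discriminability(B: np.ndarray, class_means) -> np.ndarray:
    """Per-component discriminability of AJD filters: the between-class
    variance of ``log(b_i^T M_c b_i)`` across the class means."""
    logs = np.stack(
        [np.log(np.einsum("ij,jk,ik->i", B, M, B)) for M in class_means]
    )  # (n_classes, n_components)
    return logs.var(axis=0)


def csp_filters(
    class_means, n_filters: int, method: str = "euclid_gevd"
) -> SpatialFilter:
    """Common-spatial-pattern filters from per-class mean covariances.

    ``euclid_gevd`` (2 classes): eigenvectors of ``M1 v = lambda (M1+M2) v``
    ranked by ``|lambda - 1/2|``; the ``n_filters`` most class-1-like and
    ``n_filters`` most class-2-like are kept (2 * n_filters rows).
    ``geom_ajd`` (any number of classes): Pham AJD of the class means, rows
    ranked by the log-variance discriminability score.
    """
    class_means = [np.asarray(M, dtype=float) for M in class_means]
    if len(class_means) < 2:
        raise ValueError("need at least 2 class means")
    n = class_means[0].shape[0]
    n_keep = n_filters * len(class_means)
    if n_keep > n:
        raise ValueError(
            f"{n_filters} filters x {len(class_means)} classes exceeds dimension {n}"
        )
    if method == "euclid_gevd":
        if len(class_means) != 2:
            raise ValueError("euclid_gevd is defined for exactly 2 classes")
        M1, M2 = class_means
        lam, V = scipy.linalg.eigh(M1, M1 + M2)
        # lam ascending in (0,1); most discriminative = farthest from 1/2.
        # stable tie-break: eigenvalue-index order within equal |lam - 1/2|
        order = np.argsort(-np.abs(lam - 0.5), kind="stable")
        low = [i for i in order if lam[i] <= 0.5][:n_filters]
        high = [i for i in order if lam[i] > 0.5][:n_filters]
        sel = sorted(high, key=lambda i: -lam[i]) + sorted(low, key=lambda i: lam[i])
        if len(sel) < n_keep:  # degenerate spectra: fall back to global ranking
            extra = [i for i in order if i not in sel]
            sel = sel + extra[: n_keep - len(sel)]
        W = V[:, sel].T
    elif method == "geom_ajd":
        B = pham_ajd(class_means)
        score = _ajd_discriminability(B, class_means)
        order = np.argsort(-score, kind="stable")[:n_keep]
        W = B[order]
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpatialFilter(_normalize_rows(W), stage_log=[{"method": method, "n_out": n_keep}])


def pham_ajd(
    matrices,
    weights=None,
    tol: float = 1e-8,
    max_sweeps: int = 100,
) -> np.ndarray:
    """Pham's approximate joint diagonalizer of a set of SPD matrices.

    Minimizes the log-likelihood joint-diagonality criterion
    ``sum_k w_k [log det diag(B C_k B^T) - log det(B C_k B^T)]`` by iterative
    2 x 2 pairwise transforms; the criterion is non-increasing across sweeps.
    Returns the invertible ``B`` with unit-norm rows.  Convergence is declared
    when the criterion decrease over a full sweep falls below ``tol``.
    """
    C = np.stack([np.asarray(M, dtype=float) for M in matrices])
    K, n, _ = C.shape
    if K < 2:
        raise ValueError("need at least 2 matrices to jointly diagonalize")
    w = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    B = np.eye(n)
    A = C.copy()  # transformed matrices B C_k B^T, updated in place

    for _ in range(max_sweeps):
        decrease = 0.0
        for i in range(1, n):
            for j in range(i):
                a_ii = A[:, i, i]
                a_jj = A[:, j, j]
                a_ij = A[:, i, j]
                g_ij = np.sum(w * a_ij / a_ii)
                g_ji = np.sum(w * a_ij / a_jj)
                om_ji = np.sum(w * a_ii / a_jj)
                om_ij = np.sum(w * a_jj / a_ii)
                om = np.sqrt(om_ij * om_ji)
                r = np.sqrt(om_ji / om_ij)
                t1 = (r * g_ij + g_ji) / (om + 1.0)
                t2 = (r * g_ij - g_ji) / max(om - 1.0, 1e-12)
                h_ij = t1 + t2
                h_ji = (t1 - t2) / r
                decrease += (g_ij * h_ij + g_ji * h_ji) / 2.0
                d = 1.0 + np.sqrt(max(1.0 - h_ij * h_ji, 1e-15))
                T = np.array([[1.0, -h_ij / d], [-h_ji / d, 1.0]])
                # apply the pair transform to rows and columns i, j of every A_k
                A[:, [i, j], :] = np.einsum("ab,kbn->kan", T, A[:, [i, j], :])
                A[:, :, [i, j]] = np.einsum("knb,ab->kna", A[:, :, [i, j]], T)
                B[[i, j], :] = T @ B[[i, j], :]
        if decrease < tol:
            return _normalize_rows(B)
    raise RuntimeError(
        f"Pham AJD did not converge in {max_sweeps} sweeps "
        f"(last sweep decrease {decrease:.3e})"
    )


def ajd_criterion(B: np.ndarray, matrices, weights=None) -> float:
    """Pham's joint-diagonality criterion (zero iff all ``B C_k B^T`` diagonal)."""
    mats = [np.asarray(M, float) for M in matrices]
    w = np.full(len(mats), 1.0 / len(mats)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    total = 0.0
    for wk, M in zip(w, mats):
        T = B @ M @ B.T
        total += wk * (np.sum(np.log(np.diag(T))) - np.linalg.slogdet(T)[1])
    return float(total)


def apply_filter(W: SpatialFilter | np.ndarray, C: np.ndarray) -> np.ndarray:
    """Filter an SPD matrix by congruence ``W C W^T`` and validate the result."""
    Wm = W.weights if isinstance(W, SpatialFilter) else np.asarray(W, float)
    C = np.asarray(C, dtype=float)
    if Wm.shape[1] != C.shape[0]:
        raise ValueError(
            f"filter expects dimension {Wm.shape[1]}, got {C.shape[0]}"
        )
    return validate_spd(Wm @ C @ Wm.T, "filtered covariance")


def adcsp_fit(
    cset: TrialCovarianceSet,
    cfg: FieldConfig | None = None,
    stage1_entry: int = 28,
    stage2_entry: int = 10,
) -> SpatialFilter:
    """Fit the two-stage ADCSP filter on a labeled covariance set.

    Stage 1 (entered iff dimension >= ``stage1_entry``): arithmetic class
    means, generalized eigendecomposition, reduce to ``stage1_entry``.
    Stage 2 (after stage 1, entered iff dimension >= ``stage2_entry``):
    geometric class means, Pham AJD, reduce to ``stage2_entry``.  Below both
    thresholds the identity filter is returned.
    """
    cfg = cfg or FieldConfig()
    classes = list(cset.classes)
    if len(classes) < 2:
        raise ValueError("ADCSP requires at least 2 classes")
    n = cset.dim
    W = np.eye(n)
    log: list = []
    mats = cset.matrices
    current_dim = n

    def _reduce(target: int, stage: str) -> np.ndarray:
        nonlocal current_dim
        filtered = [
            TrialCovarianceSet(
                np.einsum("ai,kij,bj->kab", Wc, cset.class_subset(c).matrices, Wc)
            )
            for c in classes
        ]
        if stage == "euclid":
            means = [arithmetic_mean(s) for s in filtered]
            if len(classes) == 2:
                lam, V = scipy.linalg.eigh(means[0], means[0] + means[1])
                order = np.argsort(-np.abs(lam - 0.5), kind="stable")[:target]
                Wstage = _normalize_rows(V[:, order].T)
            else:
                B = pham_ajd(means)
                score = _ajd_discriminability(B, means)
                Wstage = B[np.argsort(-score, kind="stable")[:target]]
        else:
            means = [geometric_mean(s, cfg) for s in filtered]
            B = pham_ajd(means)
            score = _ajd_discriminability(B, means)
            Wstage = B[np.argsort(-score, kind="stable")[:target]]
        current_dim = target
        return Wstage

    Wc = W
    if current_dim >= stage1_entry:
        W1 = _reduce(stage1_entry, "euclid")
        Wc = W1 @ Wc
        log.append({"stage": 1, "method": "euclid_gevd", "n_out": stage1_entry})
    if current_dim >= stage2_entry:
        W2 = _reduce(stage2_entry, "geom")
        Wc = W2 @ Wc
        log.append({"stage": 2, "method": "geom_ajd", "n_out": stage2_entry})
    if not log:
        log.append({"stage": 0, "method": "identity", "n_out": n})
    return SpatialFilter(_normalize_rows(Wc) if len(log) and log[0]["stage"] else Wc, stage_log=log)


class ADCSP(BaseEstimator, TransformerMixin):
    """Adaptive double CSP as a scikit-learn transformer on covariance stacks.

    Parameters
    ----------
    stage1_entry : int, default 28
        Dimension at or above which the Euclidean GEVD stage is entered (and
        the dimension it reduces to).
    stage2_entry : int, default 10
        Dimension at or above which the Riemannian AJD stage is entered (and
        the dimension it reduces to).
    tol, max_iter : solver settings for the geometric class means of stage 2.

    Attributes
    ----------
    filter_ : SpatialFilter
        The fitted composite projection with its stage log.
    """

    def __init__(
        self,
        stage1_entry: int = 28,
        stage2_entry: int = 10,
        tol: float = 1e-7,
        max_iter: int = 150,
    ):
        self.stage1_entry = stage1_entry
        self.stage2_entry = stage2_entry
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        cfg = FieldConfig(tolerance=self.tol, max_iterations=self.max_iter)
        self.filter_ = adcsp_fit(
            TrialCovarianceSet(X, np.asarray(y)),
            cfg,
            stage1_entry=self.stage1_entry,
            stage2_entry=self.stage2_entry,
        )
        return self

    def transform(self, X):
        if not hasattr(self, "filter_"):
            raise RuntimeError("ADCSP must be fitted before transform")
        X = np.asarray(X, dtype=float)
        W = self.filter_.weights
        out = np.einsum("ai,kij,bj->kab", W, X, W)
        return (out + out.transpose(0, 2, 1)) / 2.0
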