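"""Manifold classifiers over a field of power means.

Three classifiers acting directly on SPD trial covariances, all fully
deterministic (no randomness anywhere in fit or predict):

``MDM``
    minimum distance to mean — one geometric mean per class, a trial is
    assigned to the class of the nearest mean under the affine-invariant
    metric.
``MDMF``
    minimum distance to means field — one power mean per (class, h) pair; a
    trial goes to the class owning the globally nearest mean.
``MF``
    means field classifier — the squared affine-invariant distances from a
    trial to *every* mean in the field form its feature vector
    (class-major, h ascending), which is fed to a closed-form linear
    discriminant trained together with the field.  Unlike MDM/MDMF, which
    only ever look at the minimum distance, the discriminant can learn an
    arbitrary linear pattern over the whole field of distances.

All three optionally use robust (outlier-trimmed) mean estimation.  Binary
decision scores, used for AUC, are signed differences of (minimum) squared
distances for MDM/MDMF and the LDA score for MF; ties always break toward
the lower class index.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .means import (
    FieldConfig,
    MeansField,
    RobustConfig,
    compute_means_field,
    robust_means_field,
)
from .spd import TrialCovarianceSet, airm_distance, airm_distances_to

__all__ = [
    "MDM",
    "MDMF",
    "MF",
    "mf_features",
    "lda_fit",
    "mdm_fit",
    "mf_fit",
]


def mf_features(fld: MeansField, C: np.ndarray) -> np.ndarray:
    """Squared distances from one trial to every mean in the field, ordered
    class-major then h ascending."""
    return np.array(
        [
            airm_distance(C, fld.means[(cls, h)]) ** 2
            for cls in fld.classes
            for h in fld.h_values
        ]
    )


def _feature_table(fld: MeansField, X: np.ndarray) -> np.ndarray:
    """Squared-distance features for a whole trial stack (one whitening per
    mean instead of one per trial-mean pair)."""
    cols = [
        airm_distances_to(X, fld.means[(cls, h)]) ** 2
        for cls in fld.classes
        for h in fld.h_values
    ]
    return np.column_stack(cols)


def lda_fit(features: np.ndarray, labels: np.ndarray):
    """Closed-form two-class linear discriminant.

    Pooled within-class covariance (ridge 1e-6 * tr/p added when singular),
    direction ``Sigma_w^{-1} (mu_1 - mu_0)``, intercept from the class means
    and empirical log-prior ratio.  Returns ``(w, b, classes)``; the score
    ``w @ x + b`` is positive for the second class.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("lda_fit is binary; use MF for the multi-class wrapper")
    n, p = features.shape
    mus, counts = [], []
    cov = np.zeros((p, p))
    for cls in classes:
        Xi = features[labels == cls]
        if len(Xi) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        mu = Xi.mean(axis=0)
        mus.append(mu)
        counts.append(len(Xi))
        D = Xi - mu
        cov += D.T @ D
    cov /= n - 2
    try:
        w = np.linalg.solve(cov, mus[1] - mus[0])
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = cov + 1e-6 * (np.trace(cov) / p) * np.eye(p)
        w = np.linalg.solve(cov, mus[1] - mus[0])
    b = -w @ (mus[0] + mus[1]) / 2.0 + np.log(counts[1] / counts[0])
    return w, b, classes


class _FieldClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared field-fitting plumbing for the MDM family.

    ``X`` is an (n_trials, n, n) stack of SPD covariances; ``y`` the labels.
    ``robust=True`` switches on the outlier-trimmed mean estimation.
    """

    def __init__(
        self,
        tol: float = 1e-7,
        max_iter: int = 150,
        robust: bool = False,
        z_threshold: float = 2.5,
        max_refinements: int = 4,
        min_retained: int = 2,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.robust = robust
        self.z_threshold = z_threshold
        self.max_refinements = max_refinements
        self.min_retained = min_retained

    _h_grid: tuple = (0.0,)

    def _field_config(self) -> FieldConfig:
        return FieldConfig(
            h_values=tuple(self._h_grid),
            tolerance=self.tol,
            max_iterations=self.max_iter,
        )

    def _robust_config(self) -> RobustConfig:
        return RobustConfig(
            z_threshold=self.z_threshold,
            max_refinements=self.max_refinements,
            min_retained=self.min_retained,
        )

    def _fit_field(self, X, y) -> MeansField:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be an (n_trials, n, n) covariance stack")
        cset = TrialCovarianceSet(X, np.asarray(y))
        if len(cset.classes) < 2:
            raise ValueError("need at least 2 classes")
        cfg = self._field_config()
        if self.robust:
            return robust_means_field(cset, cfg, self._robust_config())
        return compute_means_field(cset, cfg)

    def fit(self, X, y):
        self.field_ = self._fit_field(X, y)
        self.classes_ = np.asarray(self.field_.classes)
        return self

    # distances (n_trials, n_classes, n_h) to every mean of the fitted field
    def _sq_distances(self, X) -> np.ndarray:
        check_is_fitted(self, "field_")
        X = np.asarray(X, dtype=float)
        fld = self.field_
        out = np.empty((len(X), len(fld.classes), len(fld.h_values)))
        for i, cls in enumerate(fld.classes):
            for j, h in enumerate(fld.h_values):
                out[:, i, j] = airm_distances_to(X, fld.means[(cls, h)]) ** 2
        return out

    def _min_sq_distances(self, X) -> np.ndarray:
        return self._sq_distances(X).min(axis=2)  # (n_trials, n_classes)

    def predict(self, X):
        d = self._min_sq_distances(X)
        return self.classes_[np.argmin(d, axis=1)]  # argmin: lower index wins ties

    def decision_function(self, X):
        """Binary score ``d^2(C, class_0 side) - d^2(C, class_1 side)``:
        positive favors ``classes_[1]``.  Multi-class: negated distances."""
        d = self._min_sq_distances(X)
        if d.shape[1] == 2:
            return d[:, 0] - d[:, 1]
        return -d

    def transform(self, X):
        """Squared distances to every mean in the field (feature map)."""
        d = self._sq_distances(X)
        return d.reshape(len(d), -1)


class MDM(_FieldClassifierBase):
    """Minimum distance to mean: one geometric mean per class, nearest-mean
    assignment under the affine-invariant metric.

    Attributes: ``field_`` (the per-class geometric means, an h = {0} field),
    ``classes_``.
    """

    _h_grid = (0.0,)


class MDMF(_FieldClassifierBase):
    """Minimum distance to means field: nearest mean among all (class, h)
    power means; the exponent grid defaults to the 11-point field."""

    def __init__(
        self,
        h_values=None,
        tol: float = 1e-7,
        max_iter: int = 150,
        robust: bool = False,
        z_threshold: float = 2.5,
        max_refinements: int = 4,
        min_retained: int = 2,
    ):
        super().__init__(tol, max_iter, robust, z_threshold, max_refinements, min_retained)
        self.h_values = h_values

    @property
    def _h_grid(self):
        from .means import DEFAULT_H_VALUES

        return DEFAULT_H_VALUES if self.h_values is None else tuple(self.h_values)


class MF(MDMF):
    """Means field classifier: linear discriminant on the squared distances
    to every mean of the power-means field.

    Binary problems use the closed-form LDA of :func:`lda_fit`; more than two
    classes use one-versus-rest discriminants with argmax assignment (lower
    class index wins exact ties).  Fitting is entirely deterministic.

    Attributes
    ----------
    field_ : MeansField
        The fitted per-(class, h) power means.
    lda_weights_, lda_intercept_ : discriminant direction(s) and intercept(s).
    classes_ : ordered class identifiers.
    """

    def fit(self, X, y):
        super().fit(X, y)
        F = _feature_table(self.field_, np.asarray(X, dtype=float))
        y = np.asarray(y)
        if len(self.classes_) == 2:
            w, b, _ = lda_fit(F, y)
            self.lda_weights_ = w
            self.lda_intercept_ = b
        else:
            ws, bs = [], []
            for cls in self.classes_:
                w, b, _ = lda_fit(F, (y == cls).astype(int))
                ws.append(w)
                bs.append(b)
            self.lda_weights_ = np.stack(ws)
            self.lda_intercept_ = np.asarray(bs)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "lda_weights_")
        F = _feature_table(self.field_, np.asarray(X, dtype=float))
        if len(self.classes_) == 2:
            return F @ self.lda_weights_ + self.lda_intercept_
        return F @ self.lda_weights_.T + self.lda_intercept_

    def predict(self, X):
        s = self.decision_function(X)
        if s.ndim == 1:
            return self.classes_[(s > 0).astype(int)]
        return self.classes_[np.argmax(s, axis=1)]


# ---------------------------------------------------------------------------
# thin functional wrappers mirroring the operation-style surface


def mdm_fit(
    cset: TrialCovarianceSet,
    cfg: FieldConfig | None = None,
    rcfg: RobustConfig | None = None,
) -> MeansField:
    """Per-class geometric means (an h = {0} means field), robust if ``rcfg``."""
    cfg = cfg or FieldConfig()
    cfg0 = FieldConfig(h_values=(0.0,), tolerance=cfg.tolerance,
                       max_iterations=cfg.max_iterations)
    if rcfg is not None:
        return robust_means_field(cset, cfg0, rcfg)
    return compute_means_field(cset, cfg0)


def mdm_predict(fld: MeansField, C: np.ndarray):
    """Nearest-geometric-mean class and the binary signed-distance score."""
    d2 = [airm_distance(C, fld.means[(cls, 0.0)]) ** 2 for cls in fld.classes]
    cls = fld.classes[int(np.argmin(d2))]
    score = d2[0] - d2[1] if len(d2) == 2 else -np.asarray(d2)
    return cls, score


def mdmf_predict(fld: MeansField, C: np.ndarray):
    """Class of the globally nearest mean in the field, plus the binary score
    (difference of per-class minimum squared distances)."""
    mins = [
        min(airm_distance(C, fld.means[(cls, h)]) ** 2 for h in fld.h_values)
        for cls in fld.classes
    ]
    cls = fld.classes[int(np.argmin(mins))]
    score = mins[0] - mins[1] if len(mins) == 2 else -np.asarray(mins)
    return cls, score


def mf_fit(
    cset: TrialCovarianceSet,
    cfg: FieldConfig | None = None,
    rcfg: RobustConfig | None = None,
) -> MF:
    """Fit the MF classifier on a labeled covariance set."""
    cfg = cfg or FieldConfig()
    clf = MF(h_values=cfg.h_values, tol=cfg.tolerance, max_iter=cfg.max_iterations,
             robust=rcfg is not None)
    if rcfg is not None:
        clf.set_params(z_threshold=rcfg.z_threshold,
                       max_refinements=rcfg.max_refinements,
                       min_retained=rcfg.min_retained)
    return clf.fit(cset.matrices, cset.labels)
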