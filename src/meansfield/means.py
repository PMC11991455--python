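"""Power means of SPD matrices: fixed-point solvers, the means field, and
robust (outlier-trimming) estimation.

The power mean ``P_h`` of SPD matrices ``{C_k}`` with weights ``{w_k}`` is the
unique SPD solution of the self-consistency equation

    P = sum_k w_k (P #_h C_k),        h in (0, 1],

where ``#_h`` is the affine-invariant geodesic.  ``h = 1`` is the arithmetic
mean, ``h = -1`` (through the duality ``P_{-h}({C_k}) = P_h({C_k^{-1}})^{-1}``)
the harmonic mean, and the geometric (Karcher) mean is the limit ``h -> 0``
from either side.  A *means field* is the collection of power means, one per
(class, h) pair, sampled on a grid of exponents in [-1, 1]; it is the training
state of the MDMF and MF classifiers.

Solvers
-------
``power_mean``  multiplicative fixed-point iteration on a square-root factor
    X of P^{-1}: with step ``phi = 0.375 / |h|``, iterate
    ``H = sum_k w_k (X C_k X^T)^h``, ``X <- H^{-phi} X`` until
    ``||H - I||_F / sqrt(n) < tol``; then ``P = (X^T X)^{-1}``.
``geometric_mean``  Karcher-flow fixed point
    ``G <- G^{1/2} exp(eps * sum_k w_k log(G^{-1/2} C_k G^{-1/2})) G^{1/2}``
    with initial step eps = 1, halved whenever the gradient norm increases.

Robust estimation trims trials whose standardized geodesic distance from the
current mean exceeds a z-threshold, then re-estimates, up to a fixed number of
refinement passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spd import (
    TrialCovarianceSet,
    airm_distances_to,
    geodesic_point,
    sym_expm,
    sym_invsqrtm,
    sym_power,
    sym_sqrtm,
    validate_spd,
)

__all__ = [
    "DEFAULT_H_VALUES",
    "FieldConfig",
    "RobustConfig",
    "MeansField",
    "MeanConvergenceError",
    "arithmetic_mean",
    "harmonic_mean",
    "geometric_mean",
    "power_mean",
    "compute_means_field",
    "standardized_distances",
    "robust_mean",
    "robust_means_field",
]

#: default exponent grid of the means field: 11 power means per class
DEFAULT_H_VALUES: tuple[float, ...] = (
    -1.0, -0.75, -0.5, -0.25, -0.1, 0.0, 0.1, 0.25, 0.5, 0.75, 1.0,
)


def _batch_sym_apply(mats: np.ndarray, fn) -> np.ndarray:
    """Apply a scalar spectral function to a stack of symmetric matrices via
    one batched eigendecomposition."""
    lam, U = np.linalg.eigh(mats)
    out = np.einsum("kin,kn,kjn->kij", U, fn(lam), U)
    return (out + out.transpose(0, 2, 1)) / 2.0


class MeanConvergenceError(RuntimeError):
    """A fixed-point solver failed to reach its tolerance; carries the final
    residual in ``residual``."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (final residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class FieldConfig:
    """Exponent grid and solver settings for a means field.

    ``tolerance`` is the convergence tolerance of the fixed-point iterations
    (dimension-normalized Frobenius residual) and ``max_iterations`` the
    iteration cap per mean.
    """

    h_values: tuple[float, ...] = DEFAULT_H_VALUES
    tolerance: float = 1e-7
    max_iterations: int = 150

    def __post_init__(self) -> None:
        hs = tuple(float(h) for h in self.h_values)
        if len(set(hs)) != len(hs):
            raise ValueError("h_values must be distinct")
        if any(h < -1 or h > 1 for h in hs):
            raise ValueError("every h must lie in [-1, 1]")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if not self.max_iterations >= 1:
            raise ValueError("max_iterations must be >= 1")
        object.__setattr__(self, "h_values", hs)


@dataclass(frozen=True)
class RobustConfig:
    """Settings of the robust trimming loop: trials whose standardized geodesic
    distance exceeds ``z_threshold`` are discarded, over at most
    ``max_refinements`` passes, never leaving fewer than ``min_retained``
    trials."""

    z_threshold: float = 2.5
    max_refinements: int = 4
    min_retained: int = 2

    def __post_init__(self) -> None:
        if not self.z_threshold > 0:
            raise ValueError("z_threshold must be positive")
        if self.max_refinements < 1:
            raise ValueError("max_refinements must be >= 1")
        if self.min_retained < 1:
            raise ValueError("min_retained must be >= 1")


@dataclass
class MeansField:
    """Per-class map from power-mean exponent h to an SPD mean matrix.

    ``means[(cls, h)]`` is the class-``cls`` power mean with exponent ``h``;
    ``diagnostics[(cls, h)]`` records (iterations, final residual);
    ``retained`` optionally maps class -> indices (within that class's trials)
    surviving the robust screen.
    """

    means: dict
    classes: list
    h_values: tuple[float, ...]
    diagnostics: dict = field(default_factory=dict)
    retained: dict | None = None

    @property
    def dim(self) -> int:
        return next(iter(self.means.values())).shape[0]

    def class_means(self, cls) -> list[np.ndarray]:
        return [self.means[(cls, h)] for h in self.h_values]


# ---------------------------------------------------------------------------
# closed-form endpoints


def arithmetic_mean(cset: TrialCovarianceSet) -> np.ndarray:
    """Weighted arithmetic (Euclidean) mean; the power mean at h = 1."""
    w = cset.normalized_weights()
    out = np.einsum("k,kij->ij", w, cset.matrices)
    return (out + out.T) / 2.0


def harmonic_mean(cset: TrialCovarianceSet) -> np.ndarray:
    """Weighted harmonic mean ``(sum_k w_k C_k^{-1})^{-1}``; the power mean at
    h = -1."""
    w = cset.normalized_weights()
    acc = np.einsum("k,kij->ij", w, _batch_sym_apply(cset.matrices, lambda l: 1.0 / l))
    return sym_power((acc + acc.T) / 2.0, -1.0)


# ---------------------------------------------------------------------------
# fixed-point solvers


def geometric_mean(
    cset: TrialCovarianceSet,
    cfg: FieldConfig | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Geometric (Karcher) mean: the SPD matrix whose weighted tangent-space
    gradient ``sum_k w_k log(G^{-1/2} C_k G^{-1/2})`` vanishes.

    Solved by the Karcher flow with adaptive step (halved whenever the
    gradient norm increases).  Initialization defaults to the geodesic
    midpoint of the arithmetic and harmonic means; the solution is unique on
    the SPD manifold, so the initialization affects speed only.
    """
    cfg = cfg or FieldConfig()
    w = cset.normalized_weights()
    mats = cset.matrices
    n = cset.dim
    if len(mats) == 1:
        return validate_spd(mats[0])
    if init is None:
        G = geodesic_point(arithmetic_mean(cset), harmonic_mean(cset), 0.5)
    else:
        G = validate_spd(init, "init")
    step = 1.0
    prev_res = np.inf
    for it in range(1, cfg.max_iterations + 1):
        Gh = sym_sqrtm(G)
        Gih = sym_invsqrtm(G)
        whitened = np.einsum("ai,kij,bj->kab", Gih, mats, Gih)
        grad = np.einsum("k,kij->ij", w, _batch_sym_apply(whitened, np.log))
        res = np.linalg.norm(grad) / np.sqrt(n)
        if res < cfg.tolerance:
            _LAST_ITERS["geometric"] = (it, res)
            return (G + G.T) / 2.0
        if res > prev_res:
            step = max(step / 2.0, 1e-3)
        prev_res = res
        G = Gh @ sym_expm(step * grad) @ Gh
        G = (G + G.T) / 2.0
    raise MeanConvergenceError(
        f"geometric mean did not converge in {cfg.max_iterations} iterations", prev_res
    )


# scratch pad for per-solve diagnostics picked up by compute_means_field
_LAST_ITERS: dict = {}


def power_mean(
    cset: TrialCovarianceSet,
    h: float,
    cfg: FieldConfig | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Power mean ``P_h`` of an SPD set for ``h`` in [-1, 1].

    ``h = 0`` dispatches to :func:`geometric_mean`; negative exponents use the
    duality ``P_{-|h|}({C_k}) = P_{|h|}({C_k^{-1}})^{-1}`` (with a
    correspondingly inverted warm start).  Endpoints h = +1/-1 short-circuit
    to the closed-form arithmetic/harmonic means.
    """
    cfg = cfg or FieldConfig()
    h = float(h)
    if not -1.0 <= h <= 1.0:
        raise ValueError(f"h must lie in [-1, 1], got {h}")
    if h == 0.0:
        return geometric_mean(cset, cfg, init)
    if h == 1.0:
        _LAST_ITERS["power"] = (0, 0.0)
        return arithmetic_mean(cset)
    if h == -1.0:
        _LAST_ITERS["power"] = (0, 0.0)
        return harmonic_mean(cset)
    if h < 0:
        dual = TrialCovarianceSet(
            _batch_sym_apply(cset.matrices, lambda l: 1.0 / l),
            cset.labels,
            cset.weights,
        )
        dual_init = None if init is None else sym_power(init, -1.0)
        return sym_power(power_mean(dual, -h, cfg, dual_init), -1.0)

    w = cset.normalized_weights()
    mats = cset.matrices
    n = cset.dim
    if init is None:
        init = arithmetic_mean(cset)
    else:
        init = validate_spd(init, "init")
    X = sym_invsqrtm(init)
    phi = 0.375 / h
    res = np.inf
    for it in range(1, cfg.max_iterations + 1):
        whitened = np.einsum("ai,kij,bj->kab", X, mats, X)
        H = np.einsum("k,kij->ij", w, _batch_sym_apply(whitened, lambda l: l**h))
        res = np.linalg.norm(H - np.eye(n)) / np.sqrt(n)
        if res < cfg.tolerance:
            _LAST_ITERS["power"] = (it, res)
            P = np.linalg.inv(X.T @ X)
            return (P + P.T) / 2.0
        X = sym_power(H, -phi) @ X
    raise MeanConvergenceError(
        f"power mean (h={h}) did not converge in {cfg.max_iterations} iterations", res
    )


# ---------------------------------------------------------------------------
# the field


def _class_field(
    cset: TrialCovarianceSet, cfg: FieldConfig
) -> tuple[dict, dict]:
    """All power means of one class with warm starts along the exponent grid.

    Positive exponents are solved in decreasing order from the closed-form
    h = 1; negative exponents in increasing order from h = -1; each solve is
    initialized at the previous solution.  h = 0 is initialized from the mean
    at the smallest available |h| (positive side wins ties).
    """
    hs = sorted(cfg.h_values)
    pos = [h for h in hs if h > 0][::-1]          # 1, 0.75, ..., descending
    neg = [h for h in hs if h < 0]                # -1, -0.75, ..., ascending
    means: dict = {}
    diags: dict = {}

    def solve(h, init):
        m = power_mean(cset, h, cfg, init)
        means[h] = m
        diags[h] = _LAST_ITERS.get("power" if h != 0 else "geometric", (0, 0.0))

    prev = None
    if pos and pos[0] != 1.0:
        prev = arithmetic_mean(cset)  # warm start even when 1 not on the grid
    for h in pos:
        solve(h, prev)
        prev = means[h]
    prev = None
    if neg and neg[0] != -1.0:
        prev = harmonic_mean(cset)
    for h in neg:
        solve(h, prev)
        prev = means[h]
    if 0.0 in hs:
        nonzero = [h for h in hs if h != 0]
        init = None
        if nonzero:
            # smallest |h| already solved; tie between +/- goes to the positive
            h_near = min(nonzero, key=lambda h: (abs(h), h < 0))
            init = means[h_near]
        m = geometric_mean(cset, cfg, init)
        means[0.0] = m
        diags[0.0] = _LAST_ITERS.get("geometric", (0, 0.0))
    return means, diags


def compute_means_field(
    cset: TrialCovarianceSet, cfg: FieldConfig | None = None
) -> MeansField:
    """One power mean per (class, h) pair, warm-started along the h grid."""
    cfg = cfg or FieldConfig()
    classes = list(cset.classes)
    means: dict = {}
    diags: dict = {}
    for cls in classes:
        sub = cset.class_subset(cls)
        if len(sub) == 0:
            raise ValueError(f"class {cls!r} has no trials")
        cmeans, cdiags = _class_field(sub, cfg)
        for h, m in cmeans.items():
            means[(cls, h)] = m
            diags[(cls, h)] = cdiags[h]
    return MeansField(means, classes, tuple(sorted(cfg.h_values)), diags)


# ---------------------------------------------------------------------------
# robust estimation


def standardized_distances(
    cset: TrialCovarianceSet, center: np.ndarray
) -> np.ndarray:
    """Standardized geodesic distances ``z_k = (d_k - mean d) / sd d`` of every
    trial from a center, with the sample sd (divisor n-1).  A degenerate
    spread (sd < 1e-12) yields all zeros, so no trial is ever flagged."""
    if len(cset) < 2:
        raise ValueError("need at least 2 trials to standardize distances")
    d = airm_distances_to(cset.matrices, center)
    sd = d.std(ddof=1)
    if sd < 1e-12:
        return np.zeros(len(d))
    return (d - d.mean()) / sd


def robust_mean(
    cset: TrialCovarianceSet,
    h: float = 0.0,
    cfg: FieldConfig | None = None,
    rcfg: RobustConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trimmed power mean: alternate (estimate mean, drop trials with
    standardized geodesic z above threshold) for at most ``max_refinements``
    passes.  Returns the final mean and the surviving trial indices (into the
    original set).  Trimming that would leave fewer than ``min_retained``
    trials is skipped and iteration stops."""
    cfg = cfg or FieldConfig()
    rcfg = rcfg or RobustConfig()
    if len(cset) < rcfg.min_retained:
        raise ValueError(
            f"need at least min_retained={rcfg.min_retained} trials, got {len(cset)}"
        )
    keep = np.arange(len(cset))
    current = cset
    mean = power_mean(current, h, cfg)
    for _ in range(rcfg.max_refinements):
        if len(current) < 2:
            break
        z = standardized_distances(current, mean)
        out_mask = z > rcfg.z_threshold
        if not out_mask.any():
            break
        if len(current) - out_mask.sum() < rcfg.min_retained:
            break  # removal skipped, not partially applied
        keep = keep[~out_mask]
        current = cset.subset(keep)
        mean = power_mean(current, h, cfg)
    return mean, keep


def robust_means_field(
    cset: TrialCovarianceSet,
    cfg: FieldConfig | None = None,
    rcfg: RobustConfig | None = None,
) -> MeansField:
    """Robust means field: per class, one outlier screen against that class's
    geometric mean, then the full field computed on the surviving trials (with
    weights renormalized over survivors)."""
    cfg = cfg or FieldConfig()
    rcfg = rcfg or RobustConfig()
    classes = list(cset.classes)
    means: dict = {}
    diags: dict = {}
    retained: dict = {}
    for cls in classes:
        sub = cset.class_subset(cls)
        _, keep = robust_mean(sub, 0.0, cfg, rcfg)
        retained[cls] = keep
        cleaned = sub.subset(keep)
        cmeans, cdiags = _class_field(cleaned, cfg)
        for hval, m in cmeans.items():
            means[(cls, hval)] = m
            diags[(cls, hval)] = cdiags[hval]
    return MeansField(
        means, classes, tuple(sorted(cfg.h_values)), diags, retained=retained
    )
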