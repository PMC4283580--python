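"""Functional normalization engine on empirical quantile functions.

The model: each sample's marginal intensity distribution is summarized by
its empirical quantile function q_i^emp evaluated on a dense grid of H+1
equidistant points on [0, 1].  Pointwise on the grid,

    q_i^emp(r) = alpha(r) + sum_j Z_ij * beta_j(r) + eps_i(r),

an ordinary least-squares fit at each grid point (a function-on-scalar
regression made trivial by the grid).  Normalization removes only the part
of each quantile function explained by the covariates:

    q_i^norm(r) = q_i^emp(r) - sum_j Z_ij * betahat_j(r),

and each sample's raw values are pushed through the map
q_i^norm((q_i^emp)^-1(.)), so the normalized values have (up to
interpolation) q_i^norm as their quantile function while their within-sample
ranks are untouched.

Two limits anchor the method: with no covariates nothing is removed and the
data pass through unchanged; with a saturated covariate matrix everything
but the mean is removed, which is exactly quantile normalization
(q_i = alphahat for every sample).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ValidationError


@dataclasses.dataclass(frozen=True)
class QuantileGrid:
    """H+1 equidistant evaluation points {d/H : d = 0..H} on [0, 1]."""

    H: int = 500

    def __post_init__(self) -> None:
        if self.H < 2:
            raise ValidationError("grid needs H >= 2")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.H + 1)


@dataclasses.dataclass
class QuantileFunctionSet:
    """Per-sample empirical (and optionally normalized) quantile functions,
    rows = samples, columns = grid points."""

    grid: QuantileGrid
    q_emp: np.ndarray
    q_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.q_emp, dtype=float)
        if q.ndim != 2 or q.shape[1] != self.grid.H + 1:
            raise ValidationError("q_emp must be samples x (H+1)")
        if (np.diff(q, axis=1) < -1e-9 * (1 + np.abs(q[:, :1]))).any():
            raise ValidationError("empirical quantile functions must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return self.q_emp.shape[0]


@dataclasses.dataclass
class CoefficientFunctions:
    """Fitted intercept/coefficient functions and residuals on the grid."""

    alpha: np.ndarray      # (H+1,)
    betas: np.ndarray      # (m, H+1)
    residuals: np.ndarray  # (n, H+1)


def empirical_quantiles(values: np.ndarray, grid: QuantileGrid) -> np.ndarray:
    """Empirical quantile function on the grid.

    Continuous order-statistic interpolation (the common "type 7" rule):
    q(p) interpolates linearly between adjacent order statistics, with
    q(0) = min and q(1) = max.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("need a 1-D vector with at least 2 values")
    if not np.isfinite(values).all():
        raise ValidationError("values must be finite")
    return np.quantile(values, grid.points, method="linear")


def quantile_functions(values_matrix: np.ndarray,
                       grid: QuantileGrid) -> QuantileFunctionSet:
    """Empirical quantile functions of each column of a values x samples
    matrix."""
    V = np.asarray(values_matrix, dtype=float)
    if not np.isfinite(V).all():
        raise ValidationError("values must be finite")
    q = np.quantile(V, grid.points, axis=0, method="linear").T
    return QuantileFunctionSet(grid, q)


def _centered(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValidationError("Z must be 2-D (samples x covariates)")
    if Z.shape[1] == 0:
        return Z
    return Z - Z.mean(axis=0)


def fit_quantile_model(Q: QuantileFunctionSet, Z: np.ndarray) -> CoefficientFunctions:
    """Pointwise OLS of the quantile functions on an intercept plus centered
    covariates; between grid points the coefficient functions are defined by
    linear interpolation.

    With ``m = 0`` covariates, alpha is the pointwise mean of the empirical
    quantile functions and there are no betas.
    """
    Zc = _centered(Z)
    n, m = Zc.shape
    if Q.n_samples != n:
        raise ValidationError("Z and quantile set disagree on sample count")
    if n <= m:
        raise ValidationError(f"need more samples ({n}) than covariates ({m})")
    X = np.column_stack([np.ones(n), Zc])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dependent = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                dependent.append(j - 1)
        raise ValidationError(
            f"covariate matrix is rank deficient (dependent columns: {dependent})")
    coef, *_ = np.linalg.lstsq(X, Q.q_emp, rcond=None)
    residuals = Q.q_emp - X @ coef
    return CoefficientFunctions(alpha=coef[0], betas=coef[1:], residuals=residuals)


def remove_covariate_effects(Q: QuantileFunctionSet,
                             Z: np.ndarray,
                             coef: CoefficientFunctions,
                             monotonize: bool = True) -> QuantileFunctionSet:
    """Subtract the covariate-explained part from each quantile function.

    Z is column-centered (enforced here, matching the fit), so the
    across-sample mean quantile function is preserved at every grid point.
    Subtraction can break monotonicity in rare cases; by default each
    normalized row is repaired by sorting, which is the pool-adjacent fix in
    one dimension and preserves the row's value multiset.
    """
    Zc = _centered(Z)
    if Zc.shape[0] != Q.n_samples:
        raise ValidationError("Z and quantile set disagree on sample count")
    if Zc.shape[1] != coef.betas.shape[0]:
        raise ValidationError("Z and fitted coefficients disagree on covariates")
    q_norm = Q.q_emp - Zc @ coef.betas
    if monotonize:
        q_norm = np.sort(q_norm, axis=1)
    return QuantileFunctionSet(Q.grid, Q.q_emp, q_norm)


def quantile_normalize(Q: QuantileFunctionSet) -> QuantileFunctionSet:
    """Replace every quantile function by the across-sample mean (the
    saturated-covariate limit)."""
    if Q.n_samples < 1:
        raise ValidationError("need at least one sample")
    mean_q = Q.q_emp.mean(axis=0)
    q_norm = np.tile(mean_q, (Q.n_samples, 1))
    return QuantileFunctionSet(Q.grid, Q.q_emp, q_norm)


def transform_values(values: np.ndarray,
                     q_emp_i: np.ndarray,
                     q_norm_i: np.ndarray,
                     grid: QuantileGrid) -> np.ndarray:
    """Push values through q_norm((q_emp)^-1(y)).

    The inverse of the piecewise-linear q_emp maps a value to its grid
    position r; ties (flat stretches of q_emp) map to the midpoint of the
    plateau.  Values outside [q_emp(0), q_emp(1)] are clamped to the
    endpoints.  Rank order within the sample is preserved.
    """
    p = grid.points
    v = np.asarray(q_emp_i, dtype=float)
    w = np.asarray(q_norm_i, dtype=float)
    if v.shape != p.shape or w.shape != p.shape:
        raise ValidationError("quantile functions must be evaluated on the grid")
    if (np.diff(v) < 0).any() or (np.diff(w) < 0).any():
        raise ValidationError("input quantile functions must be non-decreasing")
    y = np.clip(np.asarray(values, dtype=float), v[0], v[-1])

    left = np.searchsorted(v, y, side="left")
    right = np.searchsorted(v, y, side="right")
    r = np.empty_like(y)

    exact = right > left  # y equals one or more grid values: plateau midpoint
    if exact.any():
        r[exact] = 0.5 * (p[left[exact]] + p[right[exact] - 1])
    interp = ~exact
    if interp.any():
        j = left[interp]  # in 1..H because y is clamped into [v[0], v[-1]]
        lo = v[j - 1]
        hi = v[j]
        frac = (y[interp] - lo) / (hi - lo)
        r[interp] = p[j - 1] + frac * (p[j] - p[j - 1])
    return np.interp(r, p, w)


def funnorm_matrix(values_matrix: np.ndarray,
                   Z: np.ndarray,
                   grid: QuantileGrid,
                   monotonize: bool = True) -> np.ndarray:
    """Functional normalization of a values x samples matrix: fit the
    quantile model, remove covariate effects, transform every column."""
    V = np.asarray(values_matrix, dtype=float)
    Q = quantile_functions(V, grid)
    coef = fit_quantile_model(Q, Z)
    Qn = remove_covariate_effects(Q, Z, coef, monotonize=monotonize)
    out = np.empty_like(V)
    for i in range(V.shape[1]):
        out[:, i] = transform_values(V[:, i], Q.q_emp[i], Qn.q_norm[i], grid)
    return out


def quantile_normalize_matrix(values_matrix: np.ndarray,
                              grid: QuantileGrid) -> np.ndarray:
    """Plain quantile normalization of a values x samples matrix through
    the same transform machinery."""
    V = np.asarray(values_matrix, dtype=float)
    Q = quantile_functions(V, grid)
    Qn = quantile_normalize(Q)
    out = np.empty_like(V)
    for i in range(V.shape[1]):
        out[:, i] = transform_values(V[:, i], Q.q_emp[i], Qn.q_norm[i], grid)
    return out
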