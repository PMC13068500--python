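"""Smooth elevational trends, spatial autocorrelation, and the
three-model spatial decision procedure.

The smoother is a penalized cubic B-spline regression (Gaussian family,
second-difference penalty, smoothing parameter minimizing GCV) with an
optional 1/SE weight vector; a tensor-product spline provides the 2-D
spatial smooth. Moran's I uses a row-standardized k-nearest-neighbour
weight matrix on great-circle distances with a two-tailed permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "GAMResult",
    "MoranResult",
    "TrendModelChoice",
    "fit_elevation_gam",
    "morans_i",
    "spatial_decision",
    "classify_peak",
]

_LAMBDA_GRID = np.logspace(-6, 8, 57)


# ---------------------------------------------------------------------------
# Penalized spline machinery

def _bspline_basis(x: np.ndarray, k: int, xmin: float, xmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with k basis functions over [xmin, xmax].

    Returns (basis, knots); interior knots at quantile positions of x.
    """
    if k < 4:
        raise ValueError("basis dimension k must be >= 4 for cubic splines")
    degree = 3
    n_interior = k - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        interior = np.clip(interior, xmin + 1e-9, xmax - 1e-9)
    else:
        interior = np.array([])
    knots = np.concatenate([[xmin] * (degree + 1), interior, [xmax] * (degree + 1)])
    xc = np.clip(x, xmin, xmax)
    basis = BSpline.design_matrix(xc, knots, degree).toarray()
    return basis, knots


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


@dataclass
class _PenalizedFit:
    """Internal solved penalized least-squares state."""

    beta: np.ndarray
    fitted: np.ndarray
    edf: float
    rss: float
    gcv: float
    lambdas: tuple[float, ...]


def _solve_penalized(
    design: np.ndarray,
    penalties: Sequence[np.ndarray],
    y: np.ndarray,
    w: np.ndarray,
    lambdas: Sequence[float],
) -> _PenalizedFit:
    """Solve min_beta ||sqrt(w)(y - X b)||^2 + sum_j lam_j b' P_j b."""
    n = len(y)
    xw = design * w[:, None]
    a = design.T @ xw
    pen = sum(lam * p for lam, p in zip(lambdas, penalties))
    m = a.shape[0]
    # relative ridge: the design can be rank-deficient (e.g. tensor basis on
    # near-collinear coordinates) and the penalty has a null space
    ridge = 1e-9 * (np.trace(a) / m + 1.0)
    lhs = a + pen + ridge * np.eye(m)
    rhs = design.T @ (w * y)
    try:
        beta = np.linalg.solve(lhs, rhs)
        inv_a = np.linalg.solve(lhs, a)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        inv_a = np.linalg.lstsq(lhs, a, rcond=None)[0]
    fitted = design @ beta
    rss = float(np.sum(w * (y - fitted) ** 2))
    # edf = tr(X (X'WX + P)^-1 X'W)
    edf = float(np.trace(inv_a))
    denom = max(n - edf, 1e-8)
    gcv = n * rss / denom**2
    return _PenalizedFit(beta, fitted, edf, rss, gcv, tuple(lambdas))


def _gcv_search(design, penalties, y, w, grids) -> _PenalizedFit:
    best: _PenalizedFit | None = None
    if len(penalties) == 1:
        candidates = [(lam,) for lam in grids[0]]
    else:
        candidates = [(l1, l2) for l1 in grids[0] for l2 in grids[1]]
    for lams in candidates:
        fit = _solve_penalized(design, penalties, y, w, lams)
        if best is None or fit.gcv < best.gcv:
            best = fit
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Public GAM interface

@dataclass
class GAMResult:
    response_name: str
    r2: float
    r2_adj: float
    p_smooth: float
    gcv: float
    edf: float
    k: int
    fitted: np.ndarray
    residuals: np.ndarray
    peak_elevation: Optional[float]
    grid_x: np.ndarray = field(repr=False)
    grid_fit: np.ndarray = field(repr=False)


def fit_elevation_gam(
    y,
    elevation,
    weights=None,
    k: int = 5,
    response_name: str = "y",
    n_grid: int = 512,
) -> GAMResult:
    """Penalized cubic-spline smooth of a response on elevation.

    Gaussian family; the smoothing parameter minimizes GCV over a wide
    log-spaced grid; ``weights`` (e.g. 1/SE) enter the squared-error loss.
    ``p_smooth`` tests the smooth term against the (weighted) constant
    model with an F-test on the unpenalized k-dimensional basis (fixed
    degrees of freedom k-1, n-k), which is exactly F-distributed under the
    Gaussian null; a test based on the GCV-selected effective degrees of
    freedom would be anti-conservative because it ignores the smoothing
    selection. ``peak_elevation`` is the argmax of the fitted curve on a
    dense grid, or None when the maximum sits at either end of the
    gradient (monotone at grid resolution).
    """
    y = np.asarray(y, float)
    x = np.asarray(elevation, float)
    n = len(y)
    if not np.isfinite(y).all():
        raise ValueError("non-finite response values")
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 = {k + 2}, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if (w <= 0).any() or not np.isfinite(w).all():
            raise ValueError("weights must be positive and finite")
        w = w / w.mean()  # scale-free

    xmin, xmax = float(x.min()), float(x.max())
    basis, knots = _bspline_basis(x, k, xmin, xmax)
    centred = basis - basis.mean(axis=0)  # sum-to-zero: constant via intercept only
    design = np.column_stack([np.ones(n), centred])
    pen = np.zeros((k + 1, k + 1))
    pen[1:, 1:] = _diff_penalty(k)
    fit = _gcv_search(design, [pen], y, w, [_LAMBDA_GRID])

    mu0 = np.sum(w * y) / np.sum(w)
    rss0 = float(np.sum(w * (y - mu0) ** 2))
    r2 = 1.0 - fit.rss / rss0 if rss0 > 0 else 1.0
    r2_adj = 1.0 - (fit.rss / max(n - fit.edf, 1e-8)) / (rss0 / (n - 1)) if rss0 > 0 else 1.0

    # exact fixed-df F-test on the unpenalized basis (see docstring)
    sw = np.sqrt(w)
    beta_u, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    rss_u = float(np.sum(w * (y - design @ beta_u) ** 2))
    df_smooth, df_resid = k - 1, n - k
    if rss_u <= 0:
        p_smooth = 0.0
    elif rss0 > rss_u:
        f_stat = ((rss0 - rss_u) / df_smooth) / (rss_u / df_resid)
        p_smooth = float(stats.f.sf(f_stat, df_smooth, df_resid))
    else:
        p_smooth = 1.0

    grid_x = np.linspace(xmin, xmax, n_grid)
    gb = BSpline.design_matrix(grid_x, knots, 3).toarray() - basis.mean(axis=0)
    grid_fit = fit.beta[0] + gb @ fit.beta[1:]
    argmax = int(np.argmax(grid_fit))
    peak = float(grid_x[argmax]) if 0 < argmax < n_grid - 1 else None

    return GAMResult(
        response_name=response_name,
        r2=float(np.clip(r2, 0.0, 1.0)),
        r2_adj=float(min(r2_adj, 1.0)),
        p_smooth=p_smooth,
        gcv=fit.gcv,
        edf=fit.edf,
        k=k,
        fitted=fit.fitted,
        residuals=y - fit.fitted,
        peak_elevation=peak,
        grid_x=grid_x,
        grid_fit=grid_fit,
    )


def classify_peak(result: GAMResult, drop_frac: float = 0.10, alpha: float = 0.05) -> str:
    """Label the fitted elevational shape as 'none', 'weak' or 'strong'.

    'none' when the curve is monotone at grid resolution or the drop from
    the peak to the high-elevation end is below ``drop_frac`` of the fitted
    range; otherwise 'strong' iff the smooth term is significant at
    ``alpha``, else 'weak'. This operationalization is a package convention,
    not an externally defined rule.
    """
    if result.peak_elevation is None:
        return "none"
    fitted_range = float(result.grid_fit.max() - result.grid_fit.min())
    if fitted_range <= 0:
        return "none"
    drop = float(result.grid_fit.max() - result.grid_fit[-1])
    if drop < drop_frac * fitted_range:
        return "none"
    return "strong" if result.p_smooth < alpha else "weak"


def _fit_spatial_gam(y, coords, w, k: int = 4) -> _PenalizedFit:
    """2-D tensor-product spline smooth of a response on (lon, lat)."""
    coords = np.asarray(coords, float)
    n = len(y)
    bx, _ = _bspline_basis(coords[:, 0], k, coords[:, 0].min(), coords[:, 0].max())
    by, _ = _bspline_basis(coords[:, 1], k, coords[:, 1].min(), coords[:, 1].max())
    tensor = np.einsum("ij,ik->ijk", bx, by).reshape(n, -1)
    centred = tensor - tensor.mean(axis=0)
    design = np.column_stack([np.ones(n), centred])
    p1 = np.kron(_diff_penalty(k), np.eye(k)) + np.kron(np.eye(k), _diff_penalty(k))
    pen = np.zeros((k * k + 1, k * k + 1))
    pen[1:, 1:] = p1
    return _gcv_search(design, [pen], y, w, [_LAMBDA_GRID])


def _fit_combined_gam(y, x, coords, w, k_elev: int = 5, k_space: int = 4) -> _PenalizedFit:
    """Elevation smooth plus 2-D spatial smooth, separate penalties."""
    coords = np.asarray(coords, float)
    n = len(y)
    be, _ = _bspline_basis(np.asarray(x, float), k_elev, float(np.min(x)), float(np.max(x)))
    bx, _ = _bspline_basis(coords[:, 0], k_space, coords[:, 0].min(), coords[:, 0].max())
    by, _ = _bspline_basis(coords[:, 1], k_space, coords[:, 1].min(), coords[:, 1].max())
    tensor = np.einsum("ij,ik->ijk", bx, by).reshape(n, -1)
    c1 = be - be.mean(axis=0)
    c2 = tensor - tensor.mean(axis=0)
    design = np.column_stack([np.ones(n), c1, c2])
    m = design.shape[1]
    pen1 = np.zeros((m, m))
    pen1[1:1 + k_elev, 1:1 + k_elev] = _diff_penalty(k_elev)
    pen2 = np.zeros((m, m))
    block = np.kron(_diff_penalty(k_space), np.eye(k_space)) + np.kron(
        np.eye(k_space), _diff_penalty(k_space)
    )
    pen2[1 + k_elev:, 1 + k_elev:] = block
    coarse = np.logspace(-6, 8, 15)
    return _gcv_search(design, [pen1, pen2], y, w, [coarse, coarse])


def _penalized_r2(fit: _PenalizedFit, y, w) -> float:
    mu0 = np.sum(w * y) / np.sum(w)
    rss0 = float(np.sum(w * (y - mu0) ** 2))
    return float(np.clip(1.0 - fit.rss / rss0, 0.0, 1.0)) if rss0 > 0 else 1.0


# ---------------------------------------------------------------------------
# Moran's I

@dataclass
class MoranResult:
    I: float
    expected: float
    p_perm: float
    n_perm: int
    k_neighbors: int


def _haversine_matrix(coords: np.ndarray) -> np.ndarray:
    lon = np.radians(coords[:, 0])
    lat = np.radians(coords[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * 6_371_000.0 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def knn_weights(coords, k_neighbors: int = 5) -> np.ndarray:
    """Row-standardized k-nearest-neighbour weights on great-circle distance.

    Coincident points are jittered deterministically (warned) so every site
    has k distinct neighbours.
    """
    coords = np.asarray(coords, float).copy()
    n = len(coords)
    if n <= k_neighbors:
        raise ValueError(f"need n > k_neighbors, got n={n}, k={k_neighbors}")
    _, uniq_idx = np.unique(coords, axis=0, return_index=True)
    if len(uniq_idx) < n:
        warnings.warn("coincident coordinates jittered deterministically", stacklevel=2)
        jit = np.random.default_rng(12345).normal(scale=1e-6, size=coords.shape)
        dup = np.ones(n, bool)
        dup[uniq_idx] = False
        coords[dup] += jit[dup]
    dist = _haversine_matrix(coords)
    np.fill_diagonal(dist, np.inf)
    w = np.zeros((n, n))
    nearest = np.argsort(dist, axis=1)[:, :k_neighbors]
    rows = np.repeat(np.arange(n), k_neighbors)
    w[rows, nearest.ravel()] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def morans_i(
    values, coords, k_neighbors: int = 5, n_perm: int = 999, seed: int = 0,
    weights_matrix: np.ndarray | None = None,
) -> MoranResult:
    """Moran's I with a two-tailed Monte-Carlo permutation test.

    p = (1 + #{perm : |I_perm - E| >= |I_obs - E|}) / (n_perm + 1) with
    E = -1/(n-1). Constant input has undefined I and raises.
    """
    values = np.asarray(values, float)
    n = len(values)
    z = values - values.mean()
    denom = float(z @ z)
    scale = float(np.abs(values).max()) + 1.0
    if denom <= n * (1e-10 * scale) ** 2:
        raise ValueError("zero variance: Moran's I undefined for constant values")
    w = knn_weights(coords, k_neighbors) if weights_matrix is None else weights_matrix
    s0 = w.sum()

    def stat(zmat: np.ndarray) -> np.ndarray:
        num = np.einsum("ij,kj->ki", w, zmat)  # W z for each row of zmat
        return (n / s0) * np.sum(zmat * num, axis=1) / np.sum(zmat * zmat, axis=1)

    i_obs = float(stat(z[None, :])[0])
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    i_perm = stat(perms)
    extreme = np.abs(i_perm - expected) >= np.abs(i_obs - expected) - 1e-12
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)
    return MoranResult(i_obs, expected, p, n_perm, k_neighbors)


# ---------------------------------------------------------------------------
# Three-model decision procedure

@dataclass
class TrendModelChoice:
    r2_m1: float
    r2_m2: Optional[float]
    r2_m3: Optional[float]
    moran_on_m1: MoranResult
    decision: str  # baseline | baseline_spatial_byproduct | spatial_controlled
    model1: GAMResult


def spatial_decision(
    y,
    elevation,
    coords,
    weights=None,
    k: int = 5,
    k_neighbors: int = 5,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    theta: float = 0.5,
    response_name: str = "y",
) -> TrendModelChoice:
    """Elevation-only model, residual Moran test, and the escalation rule.

    Fit the elevation smooth (Model 1) and test its residuals for spatial
    autocorrelation. If non-significant, keep the baseline. Otherwise fit a
    space-only smooth (Model 2) and the combined model (Model 3): when
    Model 2 explains less than ``theta`` of Model 1's variance the spatial
    signal is treated as a byproduct of the elevational trend; otherwise
    the spatially controlled Model 3 is reported.
    """
    y = np.asarray(y, float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float) / np.mean(weights)
    m1 = fit_elevation_gam(y, elevation, weights=weights, k=k, response_name=response_name)
    moran = morans_i(m1.residuals, coords, k_neighbors=k_neighbors, n_perm=n_perm, seed=seed)
    if moran.p_perm >= alpha:
        return TrendModelChoice(m1.r2, None, None, moran, "baseline", m1)
    f2 = _fit_spatial_gam(y, coords, w)
    f3 = _fit_combined_gam(y, elevation, coords, w, k_elev=k)
    r2_m2 = _penalized_r2(f2, y, w)
    r2_m3 = _penalized_r2(f3, y, w)
    if r2_m2 < theta * m1.r2:
        decision = "baseline_spatial_byproduct"
    else:
        decision = "spatial_controlled"
    return TrendModelChoice(m1.r2, r2_m2, r2_m3, moran, decision, m1)
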