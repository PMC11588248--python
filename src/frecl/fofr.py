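"""Function-on-function linear regression with multiple functional predictors.

The cluster-level model is

    Y_i(t) = beta_0(t) + sum_j  int  beta_j(t, s) X_ij(s) ds + eps_i(t),

fitted by penalized least squares after expanding the intercept curve in a
B-spline basis over t and each coefficient surface in a tensor-product
B-spline basis over (t, s). Integrals are trapezoid quadrature on the
observation grid. The roughness penalty is a second-difference penalty on
the basis coefficients (over t for every term, additionally over s for the
surfaces), with the penalty weight chosen per fit by generalized
cross-validation unless fixed by the caller.

The normal equations have Kronecker structure: writing z_ij = Bs' W x_ij
for the quadrature-projected predictor scores and u_i = (1, z_i1', ...,
z_ip')', the Gram matrix is kron(U'U, Bt' W Bt). Fits therefore never
materialize the stacked design; :func:`build_design` builds it explicitly
for oracle-style verification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .functional import CurveSet, FRDataset, TimeGrid, lp_norm, trapezoid_weights

logger = logging.getLogger("frecl")

__all__ = [
    "BasisSpec",
    "FoFModel",
    "bspline_design",
    "build_design",
    "fit_fofr",
    "predict_fof",
    "predict_fof_many",
    "residual_norm",
    "residual_norms_many",
    "write_model",
    "read_model",
]


@dataclass(frozen=True)
class BasisSpec:
    """Tensor-product B-spline basis and penalty settings for one fit.

    Parameters
    ----------
    n_basis_t, n_basis_s
        Basis sizes over the output argument t and the input argument s.
    order
        B-spline order (4 = cubic).
    penalty
        Fixed penalty weight lambda >= 0; ``None`` selects lambda per fit
        by generalized cross-validation over ``lambda_grid``.
    lambda_grid
        Candidate penalty weights for GCV.
    lambda_floor
        Ridge floor always added to the normal equations; keeps fits on
        clusters smaller than the effective degrees of freedom well posed.
    """

    n_basis_t: int = 8
    n_basis_s: int = 8
    order: int = 4
    penalty: float | None = None
    lambda_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
    lambda_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_basis_t < self.order or self.n_basis_s < self.order:
            raise ValueError("n_basis must be >= order")
        if self.penalty is not None and self.penalty < 0:
            raise ValueError("penalty must be nonnegative")


@dataclass
class FoFModel:
    """A fitted cluster model: intercept curve and coefficient surfaces.

    ``intercept[q]`` is beta_0(t_q); ``surfaces[j][q, r]`` is
    beta_j(t_q, t_r), both evaluated on the observation grid (the form
    the clustering consumes). ``coefs`` retains the basis coefficients.
    """

    intercept: np.ndarray
    surfaces: list[np.ndarray]
    basis: BasisSpec
    grid: TimeGrid
    coefs: np.ndarray | None = None
    lambda_: float | None = None

    def __post_init__(self) -> None:
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.surfaces = [np.asarray(s, dtype=float) for s in self.surfaces]
        T = self.grid.T
        if self.intercept.shape != (T,):
            raise ValueError("intercept must be a length-T vector on the grid")
        for s in self.surfaces:
            if s.shape != (T, T):
                raise ValueError("each surface must be T x T on the grid")
            if not np.all(np.isfinite(s)):
                raise ValueError("surface entries must be finite")

    @property
    def p(self) -> int:
        return len(self.surfaces)


# ---------------------------------------------------------------------------
# basis construction


def bspline_design(x: np.ndarray, n_basis: int, order: int = 4,
                   domain: tuple[float, float] | None = None) -> np.ndarray:
    """Evaluate an open-uniform B-spline basis at points ``x``.

    Knots: ``order`` copies of each endpoint with ``n_basis - order``
    equally spaced interior knots, i.e. the conventional basis with
    equally spaced knots on the domain.
    """
    x = np.asarray(x, dtype=float)
    a, b = domain if domain is not None else (x.min(), x.max())
    if n_basis < order:
        raise ValueError("n_basis must be >= order")
    degree = order - 1
    interior = np.linspace(a, b, n_basis - order + 2)[1:-1]
    knots = np.concatenate([np.full(order, a), interior, np.full(order, b)])
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def _second_difference_penalty(k: int) -> np.ndarray:
    """D2' D2 for a length-k coefficient vector (k >= 3)."""
    d2 = np.diff(np.eye(k), n=2, axis=0)
    return d2.T @ d2


def _predictor_scores(predictors: Sequence[CurveSet], grid: TimeGrid,
                      basis: BasisSpec, m: int | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (U, Bt, Bs): augmented score matrix and basis evaluations.

    U has rows u_i = (1, z_i1', ..., z_ip') with z_ij = Bs' W x_ij, the
    trapezoid quadrature of the predictor against the s-basis.
    """
    t = grid.points
    w = trapezoid_weights(grid)
    Bt = bspline_design(t, basis.n_basis_t, basis.order, (grid.a, grid.b))
    Bs = bspline_design(t, basis.n_basis_s, basis.order, (grid.a, grid.b))
    if m is None:
        m = predictors[0].n if predictors else 1
    blocks = [np.ones((m, 1))]
    for cs in predictors:
        if cs.n != m:
            raise ValueError("predictor CurveSets disagree on observation count")
        blocks.append((cs.values * w) @ Bs)  # m x Ks
    U = np.hstack(blocks)
    return U, Bt, Bs


def build_design(predictors: Sequence[CurveSet], basis: BasisSpec,
                 grid: TimeGrid | None = None) -> np.ndarray:
    """Materialize the stacked design matrix mapping basis coefficients to
    fitted curves.

    Rows are ordered observation-major ((i=0, t_1..t_T), (i=1, ...)); the
    coefficient layout is the intercept t-basis block followed, for each
    predictor j and each s-basis function b, by a t-basis block. With
    coefficient vector theta, row block i evaluates the conditional-mean
    operator at the grid points. An intercept-only design (no predictors)
    reduces to vertically stacked copies of the t-basis evaluation matrix.
    """
    if grid is None:
        if not predictors:
            raise ValueError("grid is required for an intercept-only design")
        grid = predictors[0].grid
    U, Bt, _ = _predictor_scores(predictors, grid, basis)
    if predictors and basis.n_basis_t * U.shape[1] > predictors[0].n * grid.T:
        warnings.warn("basis larger than is identifiable from the data; "
                      "regularization still proceeds", stacklevel=2)
    # row block i is kron(u_i, Bt)
    m, cu = U.shape
    T, Kt = Bt.shape
    D = (U[:, None, :, None] * Bt[None, :, None, :]).reshape(m * T, cu * Kt)
    return D


# ---------------------------------------------------------------------------
# fitting


def _penalty_matrix(p: int, basis: BasisSpec) -> np.ndarray:
    """Second-difference penalty over t for every block, plus over s for
    each surface, in the kron(u-block, t-basis) coefficient layout."""
    Kt, Ks = basis.n_basis_t, basis.n_basis_s
    cu = 1 + p * Ks
    Pt = _second_difference_penalty(Kt)
    Ps = _second_difference_penalty(Ks)
    P = np.kron(np.eye(cu), Pt)
    for j in range(p):
        sl = slice((1 + j * Ks) * Kt, (1 + (j + 1) * Ks) * Kt)
        P[sl, sl] += np.kron(Ps, np.eye(Kt))
    return P


def fit_fofr(data: FRDataset | CurveSet, basis: BasisSpec | None = None,
             indices: np.ndarray | Sequence[int] | None = None) -> FoFModel:
    """Fit the function-on-function model to a dataset (or cluster subset).

    Minimizes the quadrature-weighted squared error

        sum_i sum_q w_q (Y_i(t_q) - Phi_i(t_q))^2  +  lambda * pen(theta)

    over tensor-product B-spline coefficients theta. ``data`` may be a
    full :class:`FRDataset` or a bare :class:`CurveSet` (intercept-only
    model with no predictors). Deterministic given its inputs.

    Raises
    ------
    ValueError
        If the (sub)cluster is empty.
    """
    basis = basis or BasisSpec()
    if isinstance(data, CurveSet):
        response, predictors = data, []
    else:
        response, predictors = data.response, data.predictors
    if indices is not None:
        idx = np.asarray(indices)
        response = response.subset(idx)
        predictors = [x.subset(idx) for x in predictors]
    if response.n == 0:
        raise ValueError("cannot fit a model on an empty cluster")

    grid = response.grid
    w = trapezoid_weights(grid)
    Y = response.values
    U, Bt, Bs = _predictor_scores(predictors, grid, basis, m=response.n)
    p = len(predictors)
    Kt = basis.n_basis_t
    m, cu = U.shape

    M = Bt.T @ (w[:, None] * Bt)                    # Kt x Kt
    S = U.T @ U                                     # cu x cu
    G = np.kron(S, M)                               # Gram of the weighted design
    R = Bt.T @ (w[:, None] * Y.T) @ U               # Kt x cu
    rhs = R.T.reshape(-1)
    yy = float(np.sum((Y * Y) @ w))
    P = _penalty_matrix(p, basis)
    floor = basis.lambda_floor * (1.0 + np.trace(G) / G.shape[0])
    I = np.eye(G.shape[0])

    def _solve(lam: float) -> tuple[np.ndarray, np.ndarray]:
        A = G + lam * P + floor * I
        c, low = cho_factor(A, check_finite=False)
        theta = cho_solve((c, low), rhs, check_finite=False)
        Ainv_G = cho_solve((c, low), G, check_finite=False)
        return theta, Ainv_G

    if basis.penalty is not None:
        lam = float(basis.penalty)
        theta, _ = _solve(lam)
    else:
        n_eff = m * grid.T
        best = None
        for lam in basis.lambda_grid:
            try:
                theta_l, Ainv_G = _solve(lam)
            except np.linalg.LinAlgError:
                continue
            rss = yy - 2.0 * theta_l @ rhs + theta_l @ (G @ theta_l)
            edf = float(np.trace(Ainv_G))
            denom = max(n_eff - edf, 1e-8)
            gcv = n_eff * max(rss, 0.0) / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam, theta_l)
        if best is None:
            raise np.linalg.LinAlgError(
                "penalized system singular for every candidate lambda; "
                f"cluster size {m}, coefficient count {G.shape[0]}")
        _, lam, theta = best

    Theta = theta.reshape(cu, Kt).T                 # Kt x cu
    intercept = Bt @ Theta[:, 0]
    Ks = basis.n_basis_s
    surfaces = [Bt @ Theta[:, 1 + j * Ks: 1 + (j + 1) * Ks] @ Bs.T for j in range(p)]
    return FoFModel(intercept, surfaces, basis, grid, coefs=theta, lambda_=lam)


# ---------------------------------------------------------------------------
# prediction and residuals


def predict_fof(model: FoFModel, x: Sequence[np.ndarray]) -> np.ndarray:
    """Evaluate the fitted conditional mean for one observation.

    ``x`` is the list of p length-T predictor curves; the integral against
    each stored surface uses trapezoid quadrature on the model grid.
    """
    if len(x) != model.p:
        raise ValueError(f"expected {model.p} predictor curves, got {len(x)}")
    w = trapezoid_weights(model.grid)
    out = model.intercept.copy()
    for surf, xj in zip(model.surfaces, x):
        xj = np.asarray(xj, dtype=float)
        if xj.shape != (model.grid.T,):
            raise ValueError("predictor curve not aligned to the model grid")
        out += surf @ (w * xj)
    return out


def predict_fof_many(model: FoFModel, predictors: Sequence[CurveSet]) -> np.ndarray:
    """Vectorized :func:`predict_fof` over all rows of the predictor sets."""
    if len(predictors) != model.p:
        raise ValueError(f"expected {model.p} predictor CurveSets")
    w = trapezoid_weights(model.grid)
    m = predictors[0].n if predictors else 1
    out = np.tile(model.intercept, (m, 1))
    for surf, cs in zip(model.surfaces, predictors):
        if cs.grid != model.grid:
            raise ValueError("predictor CurveSet not on the model grid")
        out = out + (cs.values * w) @ surf.T
    return out


def residual_norm(model: FoFModel, y: np.ndarray, x: Sequence[np.ndarray],
                  norm: int = 2) -> float:
    """Residual norm r_hat of one observation under a fitted model."""
    y = np.asarray(y, dtype=float)
    if y.shape != (model.grid.T,):
        raise ValueError("response curve not aligned to the model grid")
    return float(lp_norm(y - predict_fof(model, x), model.grid, p=norm))


def residual_norms_many(model: FoFModel, data: FRDataset, norm: int = 2) -> np.ndarray:
    """Residual norms of every observation in ``data`` under ``model``."""
    pred = predict_fof_many(model, data.predictors)
    return np.asarray(lp_norm(data.response.values - pred, model.grid, p=norm))


# ---------------------------------------------------------------------------
# serialization: flat (t, s, value) tables, exact round trip


def write_model(path, model: FoFModel) -> None:
    """Serialize a model as TSV tables: intercept plus one flat table per
    surface, concatenated with a ``component`` column."""
    t = model.grid.points
    frames = [pd.DataFrame({"component": "intercept", "t": t,
                            "s": np.nan, "value": model.intercept})]
    for j, surf in enumerate(model.surfaces, start=1):
        tt, ss = np.meshgrid(t, t, indexing="ij")
        frames.append(pd.DataFrame({"component": f"surface_{j}",
                                    "t": tt.ravel(), "s": ss.ravel(),
                                    "value": surf.ravel()}))
    pd.concat(frames).to_csv(path, sep="\t", index=False,
                             float_format="%.17g")


def read_model(path, basis: BasisSpec | None = None) -> FoFModel:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    inter = df[df["component"] == "intercept"].sort_values("t")
    grid = TimeGrid(inter["t"].to_numpy())
    T = grid.T
    surfaces = []
    names = sorted(c for c in df["component"].unique() if c != "intercept")
    for name in sorted(names, key=lambda s: int(s.split("_")[1])):
        sub = df[df["component"] == name].sort_values(["t", "s"])
        surfaces.append(sub["value"].to_numpy().reshape(T, T))
    return FoFModel(inter["value"].to_numpy(), surfaces,
                    basis or BasisSpec(), grid)
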