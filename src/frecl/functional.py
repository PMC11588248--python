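"""Discretized-curve containers, quadrature, Lp norms, LOESS smoothing,
and the expression preprocessing pipeline.

Gene-expression time courses are treated as curves sampled on a shared
time grid (hours). A :class:`CurveSet` holds one condition's curves
(genes x time points); an :class:`FRDataset` bundles the response
condition with one or more predictor conditions, aligned gene-by-gene.
All integrals are composite-trapezoid quadrature on the observed grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("frecl")

__all__ = [
    "TimeGrid",
    "CurveSet",
    "FRDataset",
    "trapezoid_weights",
    "lp_norm",
    "loess_smooth",
    "preprocess_expression",
    "read_curves",
    "write_curves",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times on a compact interval.

    Parameters
    ----------
    points
        Ordered real times (hours), length T >= 3. The domain is the
        closed interval [points[0], points[-1]].
    """

    points: np.ndarray

    def __init__(self, points: Iterable[float]):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 1 or pts.size < 3:
            raise ValueError("TimeGrid needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("TimeGrid points must be finite")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("TimeGrid points must be strictly increasing")
        object.__setattr__(self, "points", pts)
        pts.setflags(write=False)

    @property
    def T(self) -> int:
        return self.points.size

    @property
    def a(self) -> float:
        return float(self.points[0])

    @property
    def b(self) -> float:
        return float(self.points[-1])

    @property
    def length(self) -> float:
        """Domain length b - a."""
        return self.b - self.a

    def __eq__(self, other) -> bool:
        return isinstance(other, TimeGrid) and np.array_equal(self.points, other.points)

    def __hash__(self) -> int:
        return hash(self.points.tobytes())


def trapezoid_weights(grid: TimeGrid | np.ndarray) -> np.ndarray:
    """Composite-trapezoid quadrature weights on a grid.

    ``sum(w * f)`` equals the trapezoid rule for the integral of ``f``
    over the grid's domain; the weights sum to the domain length.
    """
    pts = grid.points if isinstance(grid, TimeGrid) else np.asarray(grid, dtype=float)
    if pts.ndim != 1 or pts.size < 2:
        raise ValueError("quadrature needs a grid with at least 2 points")
    gaps = np.diff(pts)
    w = np.zeros(pts.size)
    w[:-1] += gaps / 2.0
    w[1:] += gaps / 2.0
    return w


@dataclass
class CurveSet:
    """n discretized curves on a common :class:`TimeGrid`.

    ``values[i, q]`` is curve *i* evaluated at ``grid.points[q]``. Rows are
    identified by ``ids`` (e.g. gene identifiers), unique and ordered.
    """

    ids: list[str]
    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d (n x T) matrix")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count must equal number of ids")
        if self.values.shape[1] != self.grid.T:
            raise ValueError("column count must match the grid")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite (no missing values)")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, index: np.ndarray | Sequence[int]) -> "CurveSet":
        idx = np.asarray(index)
        return CurveSet([self.ids[i] for i in idx], self.values[idx], self.grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.grid.points)


@dataclass
class FRDataset:
    """One response :class:`CurveSet` plus p >= 1 predictor CurveSets.

    All member CurveSets must share identical ids (same order) and an
    identical TimeGrid; this is the unit the clustering operates on.
    """

    response: CurveSet
    predictors: list[CurveSet]

    def __post_init__(self) -> None:
        if len(self.predictors) < 1:
            raise ValueError("FRDataset requires at least one predictor CurveSet")
        for cs in self.predictors:
            if cs.ids != self.response.ids:
                raise ValueError("predictor ids must match response ids (same order)")
            if cs.grid != self.response.grid:
                raise ValueError("all CurveSets must share one TimeGrid")

    @property
    def ids(self) -> list[str]:
        return self.response.ids

    @property
    def m(self) -> int:
        return self.response.n

    @property
    def p(self) -> int:
        return len(self.predictors)

    @property
    def grid(self) -> TimeGrid:
        return self.response.grid

    def subset(self, index: np.ndarray | Sequence[int]) -> "FRDataset":
        return FRDataset(self.response.subset(index),
                         [x.subset(index) for x in self.predictors])


# ---------------------------------------------------------------------------
# norms and smoothing


def lp_norm(values: np.ndarray, grid: TimeGrid, p: int = 2) -> float | np.ndarray:
    """L1 or L2 norm of discretized curve(s) under trapezoid quadrature.

    ``values`` may be a single length-T vector or an (n x T) matrix, in
    which case one norm per row is returned.

    L1 = sum_q w_q |f_q|;  L2 = (sum_q w_q f_q^2)^(1/2).
    """
    w = trapezoid_weights(grid)
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != grid.T:
        raise ValueError("values not aligned to grid")
    if p == 1:
        out = np.abs(v) @ w
    elif p == 2:
        out = np.sqrt((v * v) @ w)
    else:
        raise ValueError(f"unsupported norm p={p!r}; use 1 or 2")
    return float(out) if np.ndim(out) == 0 else out


def loess_smooth(y: np.ndarray, grid: TimeGrid, span: float = 0.5) -> np.ndarray:
    """LOESS with local quadratic polynomials and tricube weights.

    For each grid point the ``ceil(span * T)`` nearest neighbours are
    weighted by the tricube kernel and a degree-2 weighted least-squares
    polynomial is evaluated at that point. Exact (idempotent) for inputs
    that are globally constant, linear or quadratic in time.

    Parameters
    ----------
    y
        Length-T vector (or n x T matrix, smoothed row-wise).
    span
        Fraction of points in each local window, in (0, 1].
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    t = grid.points
    T = t.size
    q = int(np.ceil(span * T))
    if q < 3:
        raise ValueError(
            f"span {span} gives a {q}-point window; a local quadratic needs >= 3")
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        return _loess_1d(y, t, q)
    return np.vstack([_loess_1d(row, t, q) for row in y])


def _loess_1d(y: np.ndarray, t: np.ndarray, q: int) -> np.ndarray:
    T = t.size
    out = np.empty(T)
    for j in range(T):
        d = np.abs(t - t[j])
        idx = np.argsort(d, kind="stable")[:q]
        dl = d[idx]
        dmax = dl[-1]
        if dmax == 0:  # degenerate window
            out[j] = y[j]
            continue
        w = (1.0 - (dl / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-12)  # keep the boundary point weakly informative
        x = t[idx] - t[j]
        X = np.column_stack([np.ones(q), x, x * x])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y[idx] * sw, rcond=None)
        out[j] = coef[0]
    return out


# ---------------------------------------------------------------------------
# preprocessing pipeline


def preprocess_expression(
    raw: Mapping[str, pd.DataFrame],
    response: str,
    predictors: Sequence[str],
    tpm_threshold: float = 5.0,
    min_timepoints: int = 20,
    span: float = 0.5,
) -> FRDataset:
    """Replicate medians -> expression filter -> centering -> LOESS.

    Parameters
    ----------
    raw
        Mapping from condition name to a long-format table with columns
        ``gene``, ``time``, ``replicate``, ``tpm``. All conditions must
        cover the same genes and the same time grid.
    response, predictors
        Which conditions play the role of Y and of X_1..X_p.
    tpm_threshold, min_timepoints
        A gene is kept only if its median TPM strictly exceeds
        ``tpm_threshold`` at ``min_timepoints`` or more time points in
        *every* condition. Setting ``min_timepoints = T - 5`` gives the
        "above threshold except at most 5 time points" variant.
    span
        LOESS span for the final smoothing step.

    Pipeline order: (1) median over replicates per time point per
    condition; (2) expression filter; (3) per condition and time point,
    subtract the across-gene mean; (4) LOESS-smooth each gene's curve and
    evaluate at the original time points.
    """
    conditions = [response, *predictors]
    missing = [c for c in conditions if c not in raw]
    if missing:
        raise KeyError(f"conditions not present in raw data: {missing}")

    medians: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        tab = raw[cond]
        piv = tab.pivot_table(index="gene", columns="time", values="tpm",
                              aggfunc="median", observed=True)
        piv = piv.sort_index(axis=0).sort_index(axis=1)
        if piv.isna().any().any():
            raise ValueError(f"condition {cond!r}: missing gene/time combinations")
        medians[cond] = piv

    ref = medians[response]
    for cond in conditions[1:]:
        if not np.array_equal(medians[cond].columns.to_numpy(dtype=float),
                              ref.columns.to_numpy(dtype=float)):
            raise ValueError(f"condition {cond!r}: time grid differs from response")
        if not medians[cond].index.equals(ref.index):
            raise ValueError(f"condition {cond!r}: gene universe differs from response")

    grid = TimeGrid(ref.columns.to_numpy(dtype=float))

    keep = np.ones(len(ref.index), dtype=bool)
    for cond in conditions:
        n_above = (medians[cond].to_numpy() > tpm_threshold).sum(axis=1)
        keep &= n_above >= min_timepoints
    if not keep.any():
        raise ValueError("no genes survive the expression filter")
    genes = list(ref.index[keep])
    logger.info("preprocess: %d of %d genes pass the TPM filter", len(genes),
                len(ref.index))

    curvesets: dict[str, CurveSet] = {}
    for cond in conditions:
        vals = medians[cond].loc[genes].to_numpy(dtype=float)
        vals = vals - vals.mean(axis=0, keepdims=True)  # across-gene centering
        vals = loess_smooth(vals, grid, span=span)
        curvesets[cond] = CurveSet(genes, vals, grid)

    return FRDataset(curvesets[response], [curvesets[c] for c in predictors])


# ---------------------------------------------------------------------------
# I/O


def write_curves(path, curves: CurveSet) -> None:
    """Write a CurveSet as TSV: first column id, remaining columns times."""
    curves.to_frame().to_csv(path, sep="\t")


def read_curves(path) -> CurveSet:
    """Read a CurveSet from TSV written by :func:`write_curves`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    grid = TimeGrid(np.asarray([float(c) for c in df.columns]))
    return CurveSet([str(i) for i in df.index], df.to_numpy(dtype=float), grid)
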