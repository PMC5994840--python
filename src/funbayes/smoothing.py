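"""Per-curve least-squares smoothing and knot-number selection.

Each observed curve x_i = (x_i(t_1), ..., x_i(t_m)) is projected onto a shared
basis by least squares, c_hat_i = (Phi' Phi)^{-1} Phi' x_i — the smoother (hat)
matrix applied to the raw values.  The number of interior knots of a B-spline
smoother can be chosen by generalized cross-validation,

    GCV(K) = (RSS / m) / (1 - L / m)^2,   L = q + 1 + K,

or as the smallest K whose fit attains R^2 = 1 - RSS/TSS above a threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .basis import BasisSystem, MeasurementGrid, evaluate_basis, make_bspline_system
from .exceptions import ConditioningError, DataError, DimensionError, ParameterError

__all__ = [
    "FunctionalDataset",
    "SmoothFit",
    "KnotSelection",
    "fit_curve_coefficients",
    "select_knot_count",
]

_COND_LIMIT = 1e10


@dataclass
class FunctionalDataset:
    """n curves sampled on a shared grid, with an optional scalar response.

    ``X`` is n x m (rows are curves), ``y`` the length-n phenotype (e.g. grain
    yield BLUEs) when present.
    """

    grid: MeasurementGrid
    X: np.ndarray
    y: np.ndarray | None = None
    ids: list | None = None

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.shape[1] != self.grid.m:
            raise DimensionError(
                f"curve rows have {X.shape[1]} values but the grid has {self.grid.m}"
            )
        if X.shape[0] < 1:
            raise DataError("need at least one curve")
        if not np.all(np.isfinite(X)):
            raise DataError("curve matrix contains non-finite values")
        self.X = X
        if self.y is not None:
            y = np.asarray(self.y, dtype=float).ravel()
            if y.size != X.shape[0]:
                raise DimensionError("response length must equal the number of curves")
            if not np.all(np.isfinite(y)):
                raise DataError("response contains non-finite values")
            self.y = y

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.grid.m


@dataclass
class SmoothFit:
    """Result of projecting curves on a basis: coefficients and fitted curves."""

    basis: BasisSystem
    grid: MeasurementGrid
    C_hat: np.ndarray  # n x L
    fitted: np.ndarray  # n x m
    residual_sd: np.ndarray  # per curve


def _solve_coefficients(Phi: np.ndarray, X: np.ndarray, what: str) -> np.ndarray:
    """Least-squares coefficients for every row of X (QR-backed lstsq)."""
    m, L = Phi.shape
    if L > m:
        raise DimensionError(f"{what}: L={L} basis functions exceed m={m} points")
    if np.linalg.cond(Phi) > _COND_LIMIT:
        raise ConditioningError(
            f"{what}: basis matrix is numerically rank deficient "
            f"(cond > {_COND_LIMIT:.0e}); check L, period and grid density"
        )
    C, *_ = linalg.lstsq(Phi, X.T)
    return C.T  # n x L


def fit_curve_coefficients(
    data: FunctionalDataset,
    basis: BasisSystem,
    check_normal_equations: bool = False,
) -> SmoothFit:
    """Fit c_hat_i = (Phi'Phi)^{-1} Phi' x_i for every curve.

    Solved by a QR/SVD least-squares factorization for stability; with
    ``check_normal_equations=True`` the explicit normal-equations solution is
    computed too and the two are asserted to agree (well-conditioned case).
    """
    Phi = evaluate_basis(basis, data.grid).values
    C = _solve_coefficients(Phi, data.X, f"{basis.family} L={basis.L}")
    if check_normal_equations:
        G = Phi.T @ Phi
        C_ne = linalg.solve(G, Phi.T @ data.X.T, assume_a="pos").T
        if not np.allclose(C, C_ne, atol=1e-8 * max(1.0, np.abs(C).max())):
            raise ConditioningError("QR and normal-equations solutions disagree")
    fitted = C @ Phi.T
    resid = data.X - fitted
    dof = max(data.m - basis.L, 1)
    residual_sd = np.sqrt((resid**2).sum(axis=1) / dof)
    return SmoothFit(basis=basis, grid=data.grid, C_hat=C, fitted=fitted,
                     residual_sd=residual_sd)


@dataclass
class KnotSelection:
    """Chosen knot count plus the full per-candidate score table for audit."""

    K: int
    criterion: str
    table: pd.DataFrame = field(repr=False)
    threshold_attained: bool = True


def select_knot_count(
    curves: np.ndarray,
    grid: MeasurementGrid,
    degree: int,
    candidates: list[int],
    criterion: str = "gcv",
    r2_threshold: float = 0.99,
    knot_method: str = "uniform",
) -> KnotSelection:
    """Choose the number of interior knots of a B-spline smoother.

    ``curves`` may be a single curve (length m) or an n x m stack; scores are
    summed over curves (dataset-level selection).  ``gcv`` picks the minimizing
    K; ``r2`` the smallest K attaining ``r2_threshold`` (falling back to the
    largest candidate, with a warning, when unattainable).  Ties break toward
    smaller K.
    """
    X = np.atleast_2d(np.asarray(curves, dtype=float))
    if X.shape[1] != grid.m:
        raise DimensionError("curve length must equal the grid size")
    if criterion not in ("gcv", "r2"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    cands = sorted(set(int(K) for K in candidates))
    if not cands:
        raise ParameterError("candidate knot list is empty")
    m = grid.m
    tss = float(((X - X.mean(axis=1, keepdims=True)) ** 2).sum())
    rows = []
    for K in cands:
        if K < 0:
            raise ParameterError("knot counts must be >= 0")
        L = degree + 1 + K
        if L > m:
            raise ParameterError(f"candidate K={K} infeasible: q+1+K={L} > m={m}")
        system = make_bspline_system(
            (grid.lo, grid.hi), degree, K, knot_method=knot_method, grid=grid
        )
        Phi = evaluate_basis(system, grid).values
        C = _solve_coefficients(Phi, X, f"bspline K={K}")
        rss = float(((X - C @ Phi.T) ** 2).sum())
        gcv = (rss / m) / (1.0 - L / m) ** 2
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        rows.append({"K": K, "L": L, "rss": rss, "gcv": gcv, "r2": r2})
    table = pd.DataFrame(rows)
    attained = True
    if criterion == "gcv":
        chosen = int(table.loc[table["gcv"].idxmin(), "K"])
    else:
        ok = table[table["r2"] >= r2_threshold]
        if len(ok):
            chosen = int(ok.iloc[0]["K"])
        else:
            chosen = int(table.iloc[-1]["K"])
            attained = False
            warnings.warn(
                f"R^2 threshold {r2_threshold} unattainable; "
                f"returning largest candidate K={chosen}",
                stacklevel=2,
            )
    return KnotSelection(K=chosen, criterion=criterion, table=table,
                         threshold_attained=attained)
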