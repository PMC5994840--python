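"""Functional regression design matrices (methods M1-M7).

Starting from the scalar-on-function model y_i = int x_i(t) beta(t) dt + e_i,
expanding x_i on a basis phi and beta on a basis psi (S = L here) yields three
equivalent-in-fit design constructions, each paired with a B-spline or Fourier
basis:

=======  ==============================  =========  =========
method   design                          basis      columns
=======  ==============================  =========  =========
M1       Z = X (raw band matrix)         none       m
M2 / M3  W = X Phi (Phi'Phi)^{-1} J      B-sp / F   S
M4 / M5  X* = X Phi (Phi'Phi)^{-1} Phi'  B-sp / F   m (rank L)
M6 / M7  X** = X Phi                     B-sp / F   L
=======  ==============================  =========  =========

J is the cross-basis integral matrix J_ls = int phi_l(t) psi_s(t) dt.  Under
the ``grid_sum`` convention J = Phi' Psi exactly, which realizes the
same-basis approximation J ~= Phi'Phi as an identity and makes W coincide
with X**; the ``trapezoid`` rule carries physical dt units instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .basis import (
    BasisSystem,
    MeasurementGrid,
    _evaluate_points,
    evaluate_basis,
    make_bspline_system,
    make_fourier_system,
)
from .exceptions import ConditioningError, DimensionError, ParameterError
from .smoothing import FunctionalDataset, _COND_LIMIT

__all__ = [
    "CrossIntegral",
    "DesignBundle",
    "DesignConfig",
    "cross_integral",
    "build_W",
    "build_Xstar",
    "build_Xstarstar",
    "build_method_design",
    "METHODS",
]

METHODS = ("M1", "M2", "M3", "M4", "M5", "M6", "M7")
_BSPLINE_METHODS = {"M2", "M4", "M6"}
_FOURIER_METHODS = {"M3", "M5", "M7"}


@dataclass(frozen=True)
class CrossIntegral:
    """J_ls = int phi_l(t) psi_s(t) dt under a stated quadrature convention."""

    J: np.ndarray
    rule: str
    refine: int
    phi: BasisSystem
    psi: BasisSystem


def _refined_grid(points: np.ndarray, refine: int) -> np.ndarray:
    """Insert `refine` sub-intervals into every grid interval."""
    segs = [
        np.linspace(points[i], points[i + 1], refine + 1)[:-1]
        for i in range(points.size - 1)
    ]
    return np.concatenate(segs + [points[-1:]])


def cross_integral(
    phi: BasisSystem,
    psi: BasisSystem,
    grid: MeasurementGrid,
    rule: str = "grid_sum",
    refine: int = 10,
) -> CrossIntegral:
    """Compute the L x S cross-basis integral matrix J.

    ``grid_sum``: J_ls = sum_j phi_l(t_j) psi_s(t_j) on the raw grid (no dt
    factor), i.e. J = Phi' Psi exactly.  ``trapezoid``: composite trapezoid on
    the grid refined ``refine``-fold, carrying physical dt units.
    """
    if (phi.lo, phi.hi) != (psi.lo, psi.hi):
        raise ParameterError("phi and psi systems must share the same domain")
    if rule == "grid_sum":
        Phi = _evaluate_points(phi, grid.points)
        Psi = _evaluate_points(psi, grid.points)
        J = Phi.T @ Psi
    elif rule == "trapezoid":
        if refine < 1:
            raise ParameterError("refinement factor must be >= 1")
        fine = _refined_grid(grid.points, refine)
        w = np.empty_like(fine)
        d = np.diff(fine)
        w[0] = d[0] / 2
        w[-1] = d[-1] / 2
        w[1:-1] = (d[:-1] + d[1:]) / 2
        Phi = _evaluate_points(phi, fine)
        Psi = _evaluate_points(psi, fine)
        J = (Phi * w[:, None]).T @ Psi
    else:
        raise ParameterError(f"unknown quadrature rule {rule!r}")
    return CrossIntegral(J=J, rule=rule, refine=refine, phi=phi, psi=psi)


@dataclass
class DesignBundle:
    """A regression design matrix plus the metadata to rebuild it.

    ``mapping`` is the m x p matrix such that Z = X @ mapping (identity,
    i.e. None, for M1); held-out curves are mapped through it, then centered
    with the training column means, so train and test live in one coordinate
    system with no leakage.
    """

    method: str
    Z: np.ndarray
    grid: MeasurementGrid
    phi: BasisSystem | None = None
    psi: BasisSystem | None = None
    J: CrossIntegral | None = None
    mapping: np.ndarray | None = field(default=None, repr=False)
    col_means: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    def design_for(self, X_new: np.ndarray) -> np.ndarray:
        """Map new raw curves into this bundle's design coordinates."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.grid.m:
            raise DimensionError(
                f"new curves have {X_new.shape[1]} points, expected {self.grid.m}"
            )
        Z_new = X_new if self.mapping is None else X_new @ self.mapping
        if self.col_means is not None:
            Z_new = Z_new - self.col_means
        return Z_new

    def center(self) -> "DesignBundle":
        """Column-center Z in place, storing the means for prediction."""
        if self.col_means is None:
            self.col_means = self.Z.mean(axis=0)
            self.Z = self.Z - self.col_means
        return self


def _projection_pieces(phi: BasisSystem, grid: MeasurementGrid):
    Phi = evaluate_basis(phi, grid).values
    if Phi.shape[1] > Phi.shape[0]:
        raise DimensionError(f"L={Phi.shape[1]} exceeds m={Phi.shape[0]}")
    if np.linalg.cond(Phi) > _COND_LIMIT:
        raise ConditioningError(
            f"Phi'Phi ill conditioned for {phi.family} L={phi.L}"
        )
    G = Phi.T @ Phi
    # (Phi'Phi)^{-1} Phi'  (smoother matrix H)
    H = linalg.solve(G, Phi.T, assume_a="pos")
    return Phi, H


def build_W(
    data: FunctionalDataset,
    phi: BasisSystem,
    psi: BasisSystem | None = None,
    rule: str = "grid_sum",
    refine: int = 10,
) -> DesignBundle:
    """Integral design W = X Phi (Phi'Phi)^{-1} J (methods M2/M3)."""
    psi = phi if psi is None else psi
    Phi, H = _projection_pieces(phi, data.grid)
    ci = cross_integral(phi, psi, data.grid, rule=rule, refine=refine)
    mapping = H.T @ ci.J  # m x S
    method = "M2" if phi.family == "bspline" else "M3"
    return DesignBundle(
        method=method, Z=data.X @ mapping, grid=data.grid,
        phi=phi, psi=psi, J=ci, mapping=mapping,
    )


def build_Xstar(data: FunctionalDataset, phi: BasisSystem) -> DesignBundle:
    """Smoothed full-dimension design X* = X Phi (Phi'Phi)^{-1} Phi' (M4/M5)."""
    Phi, H = _projection_pieces(phi, data.grid)
    mapping = Phi @ H  # m x m projection, rank L
    method = "M4" if phi.family == "bspline" else "M5"
    return DesignBundle(
        method=method, Z=data.X @ mapping, grid=data.grid, phi=phi,
        mapping=mapping,
    )


def build_Xstarstar(data: FunctionalDataset, phi: BasisSystem) -> DesignBundle:
    """Reduced design X** = X Phi of order n x L (M6/M7)."""
    Phi = evaluate_basis(phi, data.grid).values
    method = "M6" if phi.family == "bspline" else "M7"
    return DesignBundle(
        method=method, Z=data.X @ Phi, grid=data.grid, phi=phi,
        mapping=Phi,
    )


@dataclass
class DesignConfig:
    """Basis and construction choices for build_method_design.

    Either ``L`` (with ``degree`` fixing K = L - degree - 1 for B-splines) or
    ``n_knots`` specifies the basis size.  ``period`` applies to Fourier
    methods ("auto" = hi - lo).  ``center=True`` column-centers the design and
    stores the means for prediction.
    """

    L: int | None = None
    degree: int = 3
    n_knots: int | None = None
    period: float | str = "auto"
    knot_method: str = "uniform"
    rule: str = "grid_sum"
    refine: int = 10
    center: bool = True
    family: str | None = None  # optional guard against method mismatch


def _config_bspline(config: DesignConfig, grid: MeasurementGrid) -> BasisSystem:
    if config.n_knots is not None:
        K = config.n_knots
    elif config.L is not None:
        K = config.L - config.degree - 1
        if K < 0:
            raise ParameterError(
                f"L={config.L} incompatible with degree {config.degree}"
            )
    else:
        raise ParameterError("B-spline methods need L or n_knots")
    return make_bspline_system(
        (grid.lo, grid.hi), config.degree, K,
        knot_method=config.knot_method, grid=grid,
    )


def _config_fourier(config: DesignConfig, grid: MeasurementGrid) -> BasisSystem:
    if config.L is None:
        raise ParameterError("Fourier methods need L")
    return make_fourier_system((grid.lo, grid.hi), config.L, config.period)


def build_method_design(
    method: str, data: FunctionalDataset, config: DesignConfig | None = None
) -> DesignBundle:
    """Dispatch to the design construction of one of the seven methods."""
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; expected M1..M7")
    config = config or DesignConfig()
    if config.family is not None:
        want = (
            None if method == "M1"
            else "bspline" if method in _BSPLINE_METHODS
            else "fourier"
        )
        if want is not None and config.family != want:
            raise ParameterError(
                f"method {method} requires a {want} basis, got {config.family}"
            )
        if method == "M1" and config.family is not None:
            raise ParameterError("M1 uses the raw band matrix; no basis applies")
    if method == "M1":
        bundle = DesignBundle(method="M1", Z=data.X.copy(), grid=data.grid)
    else:
        phi = (
            _config_bspline(config, data.grid)
            if method in _BSPLINE_METHODS
            else _config_fourier(config, data.grid)
        )
        if method in ("M2", "M3"):
            bundle = build_W(data, phi, rule=config.rule, refine=config.refine)
        elif method in ("M4", "M5"):
            bundle = build_Xstar(data, phi)
        else:
            bundle = build_Xstarstar(data, phi)
    if config.center:
        bundle.center()
    return bundle
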