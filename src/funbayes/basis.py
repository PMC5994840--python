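"""B-spline and Fourier basis systems on measurement grids.

A smooth curve x(t) observed at discrete points t_1 < ... < t_m is represented
as a linear combination of L basis functions, x(t) = sum_l c_l phi_l(t).  Two
families are supported:

* clamped B-splines of degree ``q`` with ``K`` interior knots, giving
  ``L = q + 1 + K`` basis functions (partition of unity, compact support);
* the Fourier system {1, sin(2*pi*t/T), cos(2*pi*t/T), sin(4*pi*t/T), ...}
  of period ``T``, suited to periodic signals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import DomainError, ParameterError

__all__ = [
    "MeasurementGrid",
    "BasisSystem",
    "BasisMatrix",
    "place_knots",
    "make_bspline_system",
    "make_fourier_system",
    "evaluate_basis",
]


@dataclass(frozen=True)
class MeasurementGrid:
    """Ordered discretization points of the continuum.

    ``points`` are the m sampling locations (wavelengths in nm, time, ...);
    ``lo``/``hi`` bound the domain and default to the first/last point.
    Duplicate points are rejected: they would duplicate rows of the basis
    matrix and silently over-weight those locations in least squares.
    """

    points: np.ndarray
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ParameterError("grid needs a 1-D array of at least two points")
        if not np.all(np.isfinite(pts)):
            raise ParameterError("grid points must be finite")
        if np.any(np.diff(pts) <= 0):
            raise ParameterError(
                "grid points must be strictly increasing (duplicates rejected)"
            )
        lo = float(pts[0]) if self.lo is None else float(self.lo)
        hi = float(pts[-1]) if self.hi is None else float(self.hi)
        if lo > pts[0] or hi < pts[-1]:
            raise ParameterError("domain [lo, hi] must cover the grid points")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def m(self) -> int:
        return int(self.points.size)

    @classmethod
    def equispaced(cls, lo: float, hi: float, m: int) -> "MeasurementGrid":
        return cls(np.linspace(lo, hi, m))


@dataclass(frozen=True)
class BasisSystem:
    """A concrete basis family with its parameters.

    For B-splines ``L = degree + 1 + len(interior_knots)`` and boundary knots
    sit at the domain endpoints with multiplicity ``degree + 1`` (clamped),
    which guarantees the partition-of-unity property on [lo, hi].
    """

    family: str  # "bspline" | "fourier"
    L: int
    lo: float
    hi: float
    degree: int | None = None
    interior_knots: np.ndarray | None = None
    period: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("bspline", "fourier"):
            raise ParameterError(f"unknown basis family {self.family!r}")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ParameterError("basis domain must satisfy lo < hi")
        if self.family == "bspline":
            if self.degree is None or self.degree < 1:
                raise ParameterError("B-spline degree must be an integer >= 1")
            knots = np.asarray(
                self.interior_knots if self.interior_knots is not None else [],
                dtype=float,
            )
            if knots.size and (np.any(knots <= self.lo) or np.any(knots >= self.hi)):
                raise ParameterError("interior knots must lie strictly inside (lo, hi)")
            if knots.size and np.any(np.diff(knots) < 0):
                raise ParameterError("interior knots must be non-decreasing")
            object.__setattr__(self, "interior_knots", knots)
            if self.L != self.degree + 1 + knots.size:
                raise ParameterError("B-spline invariant L = q + 1 + K violated")
        else:
            if self.L < 1:
                raise ParameterError("Fourier basis needs L >= 1")
            if self.period is None or self.period <= 0:
                raise ParameterError("Fourier period T must be positive")

    @property
    def knot_vector(self) -> np.ndarray:
        """Full clamped knot vector (B-spline only)."""
        if self.family != "bspline":
            raise ParameterError("knot_vector is defined for B-spline systems only")
        q = self.degree
        return np.concatenate(
            [np.full(q + 1, self.lo), self.interior_knots, np.full(q + 1, self.hi)]
        )


@dataclass(frozen=True)
class BasisMatrix:
    """Basis functions evaluated on a grid: values[j, l] = phi_l(t_j)."""

    values: np.ndarray
    grid: MeasurementGrid
    basis: BasisSystem

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.m, self.basis.L):
            raise ParameterError("basis matrix shape must be m x L")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("basis matrix entries must be finite")
        object.__setattr__(self, "values", vals)


def place_knots(grid: MeasurementGrid, K: int, method: str = "uniform") -> np.ndarray:
    """Place K interior knots inside the grid domain.

    ``uniform`` spaces them equally in (lo, hi); ``quantile`` puts them at the
    empirical quantiles of the grid points at probabilities k/(K+1), k=1..K
    (linear interpolation), so dense regions of the grid receive more knots.
    """
    if K < 0:
        raise ParameterError("knot count K must be >= 0")
    if K == 0:
        return np.empty(0)
    if method == "uniform":
        knots = grid.lo + (grid.hi - grid.lo) * np.arange(1, K + 1) / (K + 1)
        if np.any(np.diff(knots) <= 0):
            raise ParameterError(f"K={K} too large: uniform knots collide")
    elif method == "quantile":
        probs = np.arange(1, K + 1) / (K + 1)
        knots = np.quantile(grid.points, probs)
    else:
        raise ParameterError(f"unknown knot placement method {method!r}")
    if np.any(knots <= grid.lo) or np.any(knots >= grid.hi):
        raise ParameterError(
            f"K={K} produces knots colliding with the domain boundary"
        )
    return knots


def make_bspline_system(
    domain: tuple[float, float],
    degree: int,
    n_knots: int,
    knot_method: str = "uniform",
    grid: MeasurementGrid | None = None,
    knots: np.ndarray | None = None,
) -> BasisSystem:
    """Build a clamped B-spline system with L = degree + 1 + n_knots functions.

    Quantile placement needs ``grid`` (the empirical point distribution);
    explicit ``knots`` override placement entirely.
    """
    lo, hi = float(domain[0]), float(domain[1])
    if degree < 1:
        raise ParameterError("B-spline degree must be >= 1")
    if knots is None:
        if knot_method == "quantile":
            if grid is None:
                raise ParameterError("quantile knot placement requires a grid")
            ref = grid
        else:
            ref = MeasurementGrid(np.array([lo, hi]))
        knots = place_knots(ref, n_knots, knot_method)
    else:
        knots = np.asarray(knots, dtype=float)
    return BasisSystem(
        family="bspline",
        L=degree + 1 + knots.size,
        lo=lo,
        hi=hi,
        degree=degree,
        interior_knots=knots,
    )


def make_fourier_system(
    domain: tuple[float, float], L: int, period: float | str = "auto"
) -> BasisSystem:
    """Build a Fourier system {1, sin, cos, ...} of period T on the domain.

    ``period="auto"`` resolves to hi - lo, the span of the measured continuum.
    An even L truncates the sequence after the final sine (warned, since the
    pair structure is broken).
    """
    lo, hi = float(domain[0]), float(domain[1])
    if period == "auto":
        T = hi - lo
    else:
        T = float(period)
    if T <= 0:
        raise ParameterError("Fourier period T must be positive")
    if L >= 2 and L % 2 == 0:
        warnings.warn(
            f"even Fourier basis count L={L}: truncating after the final sine",
            stacklevel=2,
        )
    return BasisSystem(family="fourier", L=L, lo=lo, hi=hi, period=T)


def _evaluate_points(basis: BasisSystem, t: np.ndarray) -> np.ndarray:
    """Evaluate the basis at raw points; returns len(t) x L array."""
    t = np.asarray(t, dtype=float)
    if basis.family == "bspline":
        eps = 1e-10 * (basis.hi - basis.lo)
        if np.any(t < basis.lo - eps) or np.any(t > basis.hi + eps):
            raise DomainError(
                f"B-spline evaluation outside [{basis.lo}, {basis.hi}]"
            )
        tc = np.clip(t, basis.lo, basis.hi)
        design = BSpline.design_matrix(
            tc, basis.knot_vector, basis.degree, extrapolate=False
        )
        return design.toarray()
    # Fourier, evaluated at raw t (no rescaling; phase only differs)
    omega = 2.0 * np.pi / basis.period
    cols = [np.ones_like(t)]
    r = 1
    while len(cols) < basis.L:
        cols.append(np.sin(omega * r * t))
        if len(cols) < basis.L:
            cols.append(np.cos(omega * r * t))
        r += 1
    return np.column_stack(cols)


def evaluate_basis(basis: BasisSystem, grid: MeasurementGrid) -> BasisMatrix:
    """Evaluate every basis function on the grid, returning the m x L matrix."""
    return BasisMatrix(_evaluate_points(basis, grid.points), grid, basis)
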