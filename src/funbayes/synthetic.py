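"""Synthetic data generators with known ground truth.

Three generators cover the inputs the rest of the package consumes:

* ``simulate_sine`` — the classic smoothing testbed: f(t) = sin(1 + t) sampled
  at 100 uniform draws on [10, 20] with N(0, 0.5^2) measurement noise;
* ``simulate_curves`` — hyperspectral-like curve panels: smooth per-sample
  truth curves f_i = Phi_truth c_i, c_i ~ N(0, coef_sd^2 I), observed with
  i.i.d. Gaussian noise on a shared equispaced grid;
* ``simulate_phenotypes`` — scalar responses from the functional linear model
  y_i = int f_i(t) beta(t) dt + e_i (trapezoid quadrature of the noise-free
  truth curves, so the target signal is exactly the functional model).

Every generator is a pure function of its parameters and seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .basis import BasisSystem, MeasurementGrid, evaluate_basis, make_bspline_system
from .exceptions import ParameterError
from .smoothing import FunctionalDataset

__all__ = [
    "SineSimulation",
    "SyntheticTruth",
    "simulate_sine",
    "simulate_curves",
    "simulate_phenotypes",
    "default_truth_basis",
]

WHEAT_DOMAIN = (392.0, 851.0)
WHEAT_M = 250
WHEAT_N = 976


@dataclass
class SineSimulation:
    """One noisy sine curve: sorted points, observations and the truth."""

    t: np.ndarray
    x: np.ndarray
    truth: np.ndarray  # f(t) = sin(1 + t) at the sorted points
    original_order: np.ndarray  # positions of the sorted points in draw order
    noise_sd: float
    seed: int

    @property
    def grid(self) -> MeasurementGrid:
        return MeasurementGrid(self.t)


def simulate_sine(n_points: int = 100, seed: int = 0, noise_sd: float = 0.5,
                  interval: tuple[float, float] = (10.0, 20.0)) -> SineSimulation:
    """Sample the sine testbed: t ~ U(interval), x = sin(1 + t) + noise.

    Points are stored sorted (basis evaluation needs a monotone grid); the
    original draw order is retained as metadata.
    """
    if n_points < 2:
        raise ParameterError("need at least two points")
    rng = np.random.default_rng(seed)
    t_raw = rng.uniform(interval[0], interval[1], n_points)
    order = np.argsort(t_raw, kind="stable")
    t = t_raw[order]
    f = np.sin(1.0 + t)
    x = f + rng.normal(0.0, noise_sd, n_points)[order]
    return SineSimulation(t=t, x=x, truth=f, original_order=np.argsort(order),
                          noise_sd=noise_sd, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset."""

    curves: np.ndarray  # n x m noise-free f_i(t_j)
    coefficients: np.ndarray  # n x L_truth
    truth_basis: BasisSystem
    noise_sd: float
    seed: int
    beta: Callable[[np.ndarray], np.ndarray] | None = None
    residual_sd: float | None = None
    y_signal: np.ndarray | None = None


def default_truth_basis(domain: tuple[float, float] = WHEAT_DOMAIN,
                        L: int = 15, degree: int = 3) -> BasisSystem:
    """Cubic B-spline truth basis (L = 15 by default) on the domain."""
    return make_bspline_system(domain, degree, L - degree - 1)


def simulate_curves(
    n: int,
    m: int = WHEAT_M,
    domain: tuple[float, float] = WHEAT_DOMAIN,
    truth_basis: BasisSystem | None = None,
    coef_sd: float | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[FunctionalDataset, SyntheticTruth]:
    """Smooth random curves plus i.i.d. Gaussian measurement noise.

    ``coef_sd=None`` scales the coefficients so the pointwise curve variance
    averages ~1 over the grid (unit-variance curves after centering, akin to
    standardized reflectance panels).
    """
    if n < 1 or m < 2:
        raise ParameterError("need n >= 1 curves and m >= 2 points")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    basis = truth_basis or default_truth_basis(domain)
    grid = MeasurementGrid.equispaced(domain[0], domain[1], m)
    Phi = evaluate_basis(basis, grid).values
    if coef_sd is None:
        coef_sd = 1.0 / np.sqrt(float((Phi**2).sum(axis=1).mean()))
    rng = np.random.default_rng(seed)
    C = rng.normal(0.0, coef_sd, size=(n, basis.L))
    F = C @ Phi.T
    X = F + rng.normal(0.0, noise_sd, size=F.shape) if noise_sd > 0 else F.copy()
    data = FunctionalDataset(grid=grid, X=X)
    truth = SyntheticTruth(curves=F, coefficients=C, truth_basis=basis,
                           noise_sd=noise_sd, seed=seed)
    return data, truth


def simulate_phenotypes(
    data: FunctionalDataset,
    truth: SyntheticTruth,
    beta_spec: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    residual_sd: float,
    seed: int = 0,
) -> tuple[FunctionalDataset, SyntheticTruth]:
    """Responses y_i = trapezoid(f_i * beta, t) + N(0, residual_sd^2).

    The integral uses the noise-free truth curves, so the signal is exactly
    the functional linear model; measurement noise only perturbs the
    predictors.  Returns a new dataset carrying y and the augmented truth.
    """
    if residual_sd < 0:
        raise ParameterError("residual_sd must be >= 0")
    t = data.grid.points
    beta_vals = beta_spec(t) if callable(beta_spec) else np.asarray(beta_spec, float)
    if beta_vals.shape != t.shape:
        raise ParameterError("beta values must match the grid length")
    signal = np.trapezoid(truth.curves * beta_vals, t, axis=1)
    rng = np.random.default_rng(seed)
    y = signal + (rng.normal(0.0, residual_sd, signal.size) if residual_sd > 0
                  else 0.0)
    out = FunctionalDataset(grid=data.grid, X=data.X, y=y, ids=data.ids)
    new_truth = SyntheticTruth(
        curves=truth.curves, coefficients=truth.coefficients,
        truth_basis=truth.truth_basis, noise_sd=truth.noise_sd, seed=truth.seed,
        beta=beta_spec if callable(beta_spec) else None,
        residual_sd=residual_sd, y_signal=signal,
    )
    return out, new_truth
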