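"""Cross-validated prediction accuracy across methods, bases and priors.

Mirrors the standard phenotype-prediction protocol: a random balanced k-fold
partition (k = 3 by default, i.e. two folds train / one fold tests, predicting
a third of the lines), Pearson correlation between observed and predicted
responses in the held-out fold, and fold mean +/- standard error per
configuration.  Designs for held-out curves are rebuilt from training-fold
bases and centering means only, so no test information leaks into training.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes
from .design import DesignConfig, build_method_design
from .exceptions import DataError, ParameterError
from .smoothing import FunctionalDataset

__all__ = ["CVPlan", "CVResult", "make_folds", "pearson", "run_cv"]


@dataclass(frozen=True)
class CVPlan:
    """A balanced random fold assignment (labels 1..k)."""

    k: int
    seed: int
    assignment: np.ndarray

    @property
    def n(self) -> int:
        return self.assignment.size

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, test) index arrays for one fold."""
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def make_folds(n: int, k: int, seed: int) -> CVPlan:
    """Random balanced partition of n samples into k folds (sizes differ by <= 1)."""
    if k < 2:
        raise ParameterError("need at least k = 2 folds")
    if k > n:
        raise ParameterError(f"k={k} folds exceed n={n} samples")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, k + 1), np.diff(np.linspace(0, n, k + 1).astype(int)))
    assignment = labels[rng.permutation(n)]
    return CVPlan(k=k, seed=seed, assignment=assignment)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation; errors on degenerate inputs."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise DataError("pearson needs two equal-length vectors of length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DataError("pearson undefined: zero variance input")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class CVResult:
    """Per-cell fold correlations plus the mean +/- SE aggregation."""

    cells: pd.DataFrame = field(repr=False)

    def aggregate(self) -> pd.DataFrame:
        """Mean and SE (sd over folds / sqrt(k)) per configuration."""
        grp = self.cells.groupby(
            ["method", "prior", "L", "degree", "period"], dropna=False
        )["r"]
        out = grp.agg(
            mean_r="mean",
            se=lambda s: s.std(ddof=1) / np.sqrt(s.notna().sum()),
            n_folds="count",
        ).reset_index()
        return out

    def to_csv(self, cells_path, summary_path) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.aggregate().to_csv(summary_path, index=False)


def _cell_seed(base: int, idx: int, fold: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=(idx, fold))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_cv(
    data: FunctionalDataset,
    methods: list[str],
    priors: list,
    configs: list[DesignConfig],
    plan: CVPlan,
    mcmc: bayes.McmcConfig | None = None,
) -> CVResult:
    """Full sweep: every (method, prior, basis config) cell over every fold.

    ``priors`` entries may be PriorSpec objects or family-name strings.  A
    failing cell is recorded as NaN with a warning rather than aborting the
    sweep; aggregation then averages the folds that completed.
    """
    if data.y is None:
        raise DataError("cross-validation needs a response vector")
    if plan.n != data.n:
        raise ParameterError("fold plan size does not match the dataset")
    mcmc = mcmc or bayes.McmcConfig()
    priors = [
        p if isinstance(p, bayes.PriorSpec) else bayes.PriorSpec(family=p)
        for p in priors
    ]
    rows = []
    idx = 0
    for config in configs:
        for method in methods:
            for prior in priors:
                for fold in range(1, plan.k + 1):
                    train, test = plan.fold_indices(fold)
                    seed = _cell_seed(mcmc.seed, idx, fold)
                    cell_mcmc = bayes.McmcConfig(
                        n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                        thin=mcmc.thin, seed=seed,
                    )
                    r = np.nan
                    try:
                        train_data = FunctionalDataset(
                            grid=data.grid, X=data.X[train], y=data.y[train]
                        )
                        bundle = build_method_design(method, train_data, config)
                        fit = bayes.fit(
                            train_data.y, bundle.Z, prior, cell_mcmc, bundle=bundle
                        )
                        yhat = fit.predict_curves(data.X[test])
                        r = pearson(data.y[test], yhat)
                    except Exception as err:  # noqa: BLE001 - sweep must survive
                        warnings.warn(
                            f"CV cell failed ({method}, {prior.family}, "
                            f"L={config.L}, fold {fold}): {err}",
                            stacklevel=2,
                        )
                    rows.append(
                        {
                            "method": method,
                            "prior": prior.family,
                            "L": config.L,
                            "degree": config.degree if method != "M1" else np.nan,
                            "period": (
                                config.period if method in ("M3", "M5", "M7") else np.nan
                            ),
                            "fold": fold,
                            "r": r,
                        }
                    )
                idx += 1
    return CVResult(cells=pd.DataFrame(rows))
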