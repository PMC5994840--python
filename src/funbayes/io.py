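"""CSV band-table I/O, result export and the JSON run manifest.

A band table is a CSV with one optional identifier column, one optional
response column (e.g. grain yield) and m numeric band columns whose headers
are the measurement points (wavelengths in nm).  Floats are written at full
17-significant-digit precision, so write-then-read reproduces values bitwise.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .basis import MeasurementGrid
from .bayes import BetaCurve, PosteriorFit
from .evaluation import CVResult
from .exceptions import DataError, ParameterError
from .smoothing import FunctionalDataset, SmoothFit

__all__ = [
    "read_band_table",
    "write_band_table",
    "write_predictions",
    "write_posterior_summary",
    "write_beta_curve",
    "write_cv_result",
    "write_manifest",
]


def read_band_table(
    path,
    response_column: str | None = None,
    id_column: str | None = None,
) -> FunctionalDataset:
    """Parse a band-table CSV into a FunctionalDataset.

    Band columns are recognized by numeric headers; they must parse to a
    strictly increasing grid and contain no missing cells.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    special = {c for c in (response_column, id_column) if c is not None}
    for c in special:
        if c not in df.columns:
            raise ParameterError(f"column {c!r} not found in {path}")
    band_cols: list[str] = []
    band_vals: list[float] = []
    for c in df.columns:
        if c in special:
            continue
        try:
            band_vals.append(float(c))
            band_cols.append(c)
        except ValueError as err:
            raise DataError(
                f"non-numeric band header {c!r} in {path} (pass it as the "
                "id/response column if it is not a band)"
            ) from err
    if len(band_cols) < 2:
        raise DataError(f"{path}: found fewer than two band columns")
    grid_vals = np.asarray(band_vals)
    if np.any(np.diff(grid_vals) <= 0):
        raise DataError(f"{path}: band headers are not strictly increasing")
    X = df[band_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        r, c = np.argwhere(~np.isfinite(X))[0]
        raise DataError(
            f"{path}: missing/non-finite value at row {r} column {band_cols[c]!r}"
        )
    y = None
    if response_column is not None:
        y = df[response_column].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            row = int(np.flatnonzero(~np.isfinite(y))[0])
            raise DataError(
                f"{path}: missing response {response_column!r} at row {row}"
            )
    ids = df[id_column].tolist() if id_column is not None else None
    return FunctionalDataset(grid=MeasurementGrid(grid_vals), X=X, y=y, ids=ids)


def write_band_table(
    path, data: FunctionalDataset,
    response_column: str = "y", id_column: str = "id",
) -> None:
    """Write a FunctionalDataset back to the band-table CSV dialect."""
    cols = {}
    cols[id_column] = data.ids if data.ids is not None else list(range(data.n))
    if data.y is not None:
        cols[response_column] = data.y
    for j, t in enumerate(data.grid.points):
        cols[repr(float(t))] = data.X[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_predictions(path, observed, predicted, ids=None) -> None:
    observed = np.asarray(observed, float).ravel()
    predicted = np.asarray(predicted, float).ravel()
    if observed.size != predicted.size:
        raise ParameterError("observed and predicted lengths differ")
    ids = ids if ids is not None else list(range(observed.size))
    pd.DataFrame(
        {"id": ids, "observed": observed, "predicted": predicted}
    ).to_csv(path, index=False)


def write_posterior_summary(path, fit: PosteriorFit) -> None:
    """Term-by-term posterior mean, sd and central 95% quantiles."""
    rows = [("intercept", fit.mu_draws)]
    rows += [(f"coef_{j}", fit.theta_draws[:, j]) for j in range(fit.p)]
    rows.append(("sigma2", fit.sigma2_draws))
    recs = []
    for term, draws in rows:
        recs.append(
            {
                "term": term,
                "mean": float(np.mean(draws)),
                "sd": float(np.std(draws, ddof=1)),
                "q2.5": float(np.quantile(draws, 0.025)),
                "q97.5": float(np.quantile(draws, 0.975)),
            }
        )
    pd.DataFrame(recs).to_csv(path, index=False)


def write_beta_curve(path, curve: BetaCurve) -> None:
    pd.DataFrame(
        {
            "t": curve.t,
            "estimate": curve.estimate,
            "lower": curve.lower,
            "upper": curve.upper,
        }
    ).to_csv(path, index=False)


def write_smooth_fit(path, fit: SmoothFit) -> None:
    cols = {repr(float(t)): fit.fitted[:, j] for j, t in enumerate(fit.grid.points)}
    pd.DataFrame(cols).to_csv(path, index=False)


def write_cv_result(cells_path, summary_path, result: CVResult) -> None:
    result.to_csv(cells_path, summary_path)


def write_manifest(path, config: dict, seed: int | None = None) -> None:
    """JSON run manifest: config, seed and software version."""
    manifest = {
        "package": "funbayes",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
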