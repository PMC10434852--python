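"""Random-forest regression SDM: extraction, tuning, LOOCV, prediction, thresholding.

Abundance observations (trapline indices or transect scores) are joined to
the EO proxy layers by sampling the pixel containing each unit's location.
A regression random forest is tuned over a small hyperparameter grid by
leave-one-out cross-validation R^2, refit on all units, applied predictively
to every unmasked pixel, and converted to a binary optimal-habitat map by
thresholding at the mean predicted abundance of the training units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .grid import Raster

__all__ = [
    "HyperParams",
    "DEFAULT_GRID",
    "SDMResult",
    "build_feature_table",
    "loocv",
    "tune_hyperparameters",
    "fit_and_predict",
    "optimal_habitat",
    "area_stats",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HyperParams:
    """Random-forest regression hyperparameters.

    ``variables_per_split`` is either an integer count or the string "sqrt"
    (the square-root-of-p rule); ``max_nodes=None`` means unlimited tree
    size; ``bag_fraction`` is the per-tree bootstrap sample fraction.
    """

    n_trees: int = 200
    min_leaf_population: int = 1
    max_nodes: int | None = None
    variables_per_split: int | str = "sqrt"
    bag_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_leaf_population < 1:
            raise ValueError("n_trees and min_leaf_population must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")

    def make_forest(self, seed: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_leaf_population,
            max_leaf_nodes=self.max_nodes,
            max_features=self.variables_per_split,
            bootstrap=True,
            max_samples=None if self.bag_fraction == 1.0 else self.bag_fraction,
            random_state=seed,
            n_jobs=1,
        )


#: the tuning grid: a small superset of the reported optimum
#: (200 trees, min leaf 1, unlimited nodes, sqrt-p variables per split, bag 0.7)
DEFAULT_GRID = [
    HyperParams(n_trees=nt, min_leaf_population=ml, max_nodes=mn)
    for nt in (100, 200)
    for ml in (1, 5)
    for mn in (None, 50)
]


def build_feature_table(
    layers: dict[str, Raster],
    observations: pd.DataFrame,
) -> pd.DataFrame:
    """Sample every proxy layer at each observation's location.

    ``observations`` needs columns unit_id, x, y, value.  Units whose pixel
    is masked in any layer are dropped (count logged).  Returns a DataFrame
    with unit_id, x, y, value ("response") and one column per layer.
    """
    if observations.empty:
        raise ValueError("no observations")
    x = observations["x"].to_numpy(dtype=float)
    y = observations["y"].to_numpy(dtype=float)
    first = next(iter(layers.values()))
    if not np.all(first.grid.contains(x, y)):
        raise ValueError("observation coordinate outside grid")
    out = observations[["unit_id", "x", "y", "value"]].copy()
    keep = np.ones(len(out), dtype=bool)
    for name, r in layers.items():
        vals = np.asarray(r.sample(x, y), dtype=float)
        row, col = r.grid.rowcol(x, y)
        keep &= r.mask[row, col] & np.isfinite(vals)
        out[name] = vals
    dropped = int((~keep).sum())
    if dropped:
        log.info("build_feature_table: dropped %d units on masked pixels", dropped)
    if not keep.any():
        raise ValueError("all units fall on masked pixels")
    return out[keep].reset_index(drop=True)


def _split_xy(table: pd.DataFrame, covariates=None):
    cov = covariates or [c for c in table.columns if c not in ("unit_id", "x", "y", "value")]
    return table[list(cov)].to_numpy(dtype=float), table["value"].to_numpy(dtype=float), list(cov)


def loocv(table: pd.DataFrame, params: HyperParams, seed: int = 0, covariates=None) -> dict:
    """Leave-one-out cross-validation of a regression forest.

    Each unit is predicted by a forest trained on the remaining n-1 units
    with a per-fold seed derived from the master seed (results independent
    of fold order).  Returns observed/predicted pairs, the coefficient of
    determination R^2 = 1 - SSE/SST (primary) and the squared Pearson
    correlation (for comparison).
    """
    X, y, cov = _split_xy(table, covariates)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 units")
    if np.allclose(y, y[0]):
        raise ValueError("constant response: R^2 undefined")
    fold_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    pred = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        forest = params.make_forest(int(fold_seeds[i]))
        forest.fit(X[tr], y[tr])
        pred[i] = forest.predict(X[i : i + 1])[0]
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst
    if np.std(pred) > 0:
        r2_pearson = float(stats.pearsonr(y, pred)[0] ** 2)
    else:
        r2_pearson = 0.0
    return {
        "observed": y,
        "predicted": pred,
        "r2": r2,
        "r2_pearson": r2_pearson,
        "n": n,
        "covariates": cov,
    }


def tune_hyperparameters(
    table: pd.DataFrame,
    grid=None,
    seed: int = 0,
    covariates=None,
) -> tuple[HyperParams, pd.DataFrame]:
    """Grid search maximizing LOOCV R^2.

    Ties are broken toward fewer trees, then smaller minimum leaf
    population.  Returns the winning HyperParams and the full tuning table.
    """
    grid = list(grid) if grid is not None else list(DEFAULT_GRID)
    if not grid:
        raise ValueError("empty tuning grid")
    rows = []
    for hp in grid:
        cv = loocv(table, hp, seed=seed, covariates=covariates)
        rows.append(
            {
                "n_trees": hp.n_trees,
                "min_leaf_population": hp.min_leaf_population,
                "max_nodes": hp.max_nodes,
                "variables_per_split": hp.variables_per_split,
                "bag_fraction": hp.bag_fraction,
                "r2": cv["r2"],
                "r2_pearson": cv["r2_pearson"],
            }
        )
    tab = pd.DataFrame(rows)
    order = tab.sort_values(
        ["r2", "n_trees", "min_leaf_population"], ascending=[False, True, True], kind="stable"
    )
    best = grid[order.index[0]]
    return best, tab


def fit_and_predict(
    table: pd.DataFrame,
    params: HyperParams,
    layers: dict[str, Raster],
    seed: int = 0,
    covariates=None,
) -> tuple[RandomForestRegressor, Raster, np.ndarray]:
    """Fit on all units and predict at every unmasked pixel.

    Returns (fitted forest, predicted-abundance raster, training-unit
    predictions).  Masked pixels in any covariate layer stay masked.
    """
    X, y, cov = _split_xy(table, covariates)
    missing = [c for c in cov if c not in layers]
    if missing:
        raise ValueError(f"missing covariate rasters: {missing}")
    forest = params.make_forest(seed)
    forest.fit(X, y)
    train_pred = forest.predict(X)

    first = layers[cov[0]]
    mask = np.ones(first.grid.shape, dtype=bool)
    for c in cov:
        mask &= layers[c].mask & np.isfinite(layers[c].values)
    rr, cc = np.nonzero(mask)
    design = np.column_stack([np.asarray(layers[c].values, dtype=float)[rr, cc] for c in cov])
    vals = np.full(first.grid.shape, np.nan)
    if rr.size:
        vals[rr, cc] = forest.predict(design)
    pred = Raster(vals, first.grid, mask=mask, band_names=["predicted_abundance"])
    return forest, pred, train_pred


def optimal_habitat(prediction: Raster, train_predictions) -> tuple[Raster, float]:
    """Binary optimal-habitat map by mean-prediction thresholding.

    The threshold is the arithmetic mean of the model's predictions on the
    training units; a pixel is optimal iff its predicted abundance strictly
    exceeds the threshold.  Masked pixels stay masked.
    """
    train_predictions = np.asarray(train_predictions, dtype=float)
    if train_predictions.size == 0:
        raise ValueError("empty training predictions")
    threshold = float(train_predictions.mean())
    binary = np.zeros(prediction.grid.shape, dtype=np.uint8)
    vals = np.asarray(prediction.values, dtype=float)
    binary[(vals > threshold) & prediction.mask] = 1
    return (
        Raster(binary, prediction.grid, mask=prediction.mask.copy(), band_names=["optimal"],
               meta={"threshold": threshold}),
        threshold,
    )


def area_stats(binary: Raster, pixel_size: float | None = None) -> dict:
    """Optimal-habitat area in km^2 and % of total (unmasked) land."""
    px = pixel_size if pixel_size is not None else binary.grid.pixel_size
    if px <= 0:
        raise ValueError("pixel size must be positive")
    vals = np.asarray(binary.values)
    if vals.size == 0:
        raise ValueError("empty map")
    n_opt = int(np.sum((vals == 1) & binary.mask))
    n_tot = int(binary.mask.sum())
    km2 = n_opt * px**2 / 1e6
    pct = 100.0 * n_opt / n_tot if n_tot else np.nan
    return {"optimal_km2": km2, "optimal_pct": pct, "n_optimal": n_opt, "n_land": n_tot}


@dataclass
class SDMResult:
    """End-to-end SDM product for one species."""

    species: str
    source: str  # trapline | transect
    selected_covariates: list[str]
    params: HyperParams
    loocv_r2: float
    loocv_r2_pearson: float
    loocv_observed: np.ndarray
    loocv_predicted: np.ndarray
    prediction: Raster
    threshold: float
    optimal_map: Raster
    area: dict
    tuning_table: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]
    boruta: object = field(default=None, repr=False)

    def report_row(self) -> dict:
        """One row of the Table-5-style report."""
        return {
            "species": self.species,
            "method": self.source,
            "r2": round(self.loocv_r2, 3),
            "threshold": round(self.threshold, 3),
            "optimal_km2": round(self.area["optimal_km2"], 1),
            "pct_total_land": round(self.area["optimal_pct"], 1),
        }
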