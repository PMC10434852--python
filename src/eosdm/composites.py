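"""Temporal percentile metrics and median composites of masked time series.

A year of cloud-masked scenes is collapsed per pixel into percentiles of the
valid observations (5th, 10th, 25th, 50th, 75th, 90th, 95th), the full range
(max - min) and the 75-25, 90-10 and 95-5 inter-percentile ranges.  These
capture the amplitude and shape of the phenological response while being
insensitive to the exact timing of acquisitions or of the season itself.
Percentiles use linear interpolation between closest order statistics;
pixels with fewer than ``min_obs`` valid observations are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Raster
from .scene import BAND_ORDER, Scene

__all__ = ["PERCENTILES", "RANGE_PAIRS", "PercentileMetrics", "mask_scene", "percentile_metrics", "median_composite"]

PERCENTILES = (5, 10, 25, 50, 75, 90, 95)
RANGE_PAIRS = ((75, 25), (90, 10), (95, 5))


def mask_scene(scene: Scene, mask: np.ndarray) -> Scene:
    """Apply an additional validity mask (True = valid) to a scene."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != scene.grid.shape:
        raise ValueError("mask grid mismatch")
    return Scene(
        {k: v.copy() for k, v in scene.bands.items()},
        scene.grid,
        doy=scene.doy,
        year=scene.year,
        sensor=scene.sensor,
        mask=scene.mask & mask,
        meta=dict(scene.meta),
    )


@dataclass
class PercentileMetrics:
    """Per-pixel percentile summary of one index across an acquisition period."""

    index: str
    layers: dict[str, np.ndarray]  # p5..p95, range, r75_25, r90_10, r95_5
    count: np.ndarray
    grid: object
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def layer_names(self) -> list[str]:
        return list(self.layers)

    def raster(self, name: str) -> Raster:
        return Raster(self.layers[name], self.grid, mask=self.mask, band_names=[f"{self.index}_{name}"])

    def as_rasters(self) -> dict[str, Raster]:
        return {f"{self.index}_{n}": self.raster(n) for n in self.layers}


def _stack_series(rasters: list[Raster]) -> np.ndarray:
    """(n_obs, rows, cols) float stack with invalid pixels as NaN."""
    if not rasters:
        raise ValueError("empty collection")
    grid = rasters[0].grid
    out = np.empty((len(rasters),) + grid.shape)
    for i, r in enumerate(rasters):
        if r.grid.shape != grid.shape:
            raise ValueError("grid mismatch in series")
        out[i] = r.masked()
    return out


def percentile_metrics(rasters: list[Raster], min_obs: int = 3, index: str | None = None) -> PercentileMetrics:
    """Collapse a masked index time series into percentile metrics.

    Percentiles are computed per pixel over the valid observations with
    linear interpolation between order statistics; ``range`` is max - min
    and the named inter-percentile ranges are differences of the percentile
    layers.  Pixels with fewer than ``min_obs`` valid observations are
    masked in every output layer.
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    series = _stack_series(rasters)
    count = np.isfinite(series).sum(axis=0)
    valid = count >= min_obs
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels are masked below
        pcts = np.nanpercentile(series, PERCENTILES, axis=0, method="linear")
        rng = np.nanmax(series, axis=0) - np.nanmin(series, axis=0)
    layers = {f"p{p}": pcts[i] for i, p in enumerate(PERCENTILES)}
    layers["range"] = rng
    for hi, lo in RANGE_PAIRS:
        layers[f"r{hi}_{lo}"] = layers[f"p{hi}"] - layers[f"p{lo}"]
    for arr in layers.values():
        arr[~valid] = np.nan
    name = index or (rasters[0].band_names[0] if rasters[0].band_names else "index")
    return PercentileMetrics(name, layers, count, rasters[0].grid, mask=valid)


def median_composite(scenes: list[Scene], min_obs: int = 1) -> Raster:
    """Per-band median of the valid observations across scenes.

    Definitionally the p50 path of :func:`percentile_metrics` applied to the
    raw bands; used as the cloud-free composite for classification.
    """
    if not scenes:
        raise ValueError("empty collection")
    grid = scenes[0].grid
    bands = []
    for bname in BAND_ORDER:
        series = percentile_metrics(
            [Raster(s.bands[bname], s.grid, mask=s.mask, band_names=[bname]) for s in scenes],
            min_obs=min_obs,
            index=bname,
        )
        bands.append(series.layers["p50"])
    stack = np.stack(bands)
    mask = np.isfinite(stack).all(axis=0)
    return Raster(stack, grid, mask=mask, band_names=[f"median_{b}" for b in BAND_ORDER])
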