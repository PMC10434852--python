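"""Terrain derivatives, classification stack, RF land cover and focal proportions.

The land-cover classification follows the standard EO workflow: a 12-layer
stack (six median reflectance bands, NDVI p10/p90/90-10 range, elevation,
slope, aspect) is sampled within per-class training polygons (random
stratified sampling, up to 5000 pixels per class) and classified with a
200-tree random forest into the eight classes grassland, woodland, arable,
bushes, built-up, bare, water, snow.  Fractional presence of the habitat
classes is then derived with circular moving windows of 50-500 m radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import contains_xy
from sklearn.ensemble import RandomForestClassifier

from .grid import GridSpec, Raster
from .synthetic import CLASS_NAMES

__all__ = [
    "terrain_derivatives",
    "FeatureStack",
    "assemble_stack",
    "rasterize_polygons",
    "classify_landcover",
    "confusion_matrix",
    "focal_proportion",
    "proportion_layers",
]

ASPECT_FLAT = -1.0
DEFAULT_KERNELS_M = tuple(range(50, 501, 50))


def terrain_derivatives(dem: Raster | np.ndarray, pixel_size: float | None = None) -> tuple[Raster, Raster]:
    """Slope (degrees) and aspect (degrees clockwise from north) from a DEM.

    Horn's eight-neighbour finite differences; edge cells use edge-replicated
    neighbourhoods.  Aspect is the downslope compass direction; flat cells
    (zero gradient) carry the sentinel -1.
    """
    if isinstance(dem, Raster):
        grid = dem.grid
        z = np.asarray(dem.values, dtype=float)
        px = grid.pixel_size
    else:
        z = np.asarray(dem, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required for bare-array DEM")
        px = pixel_size
        grid = GridSpec(*z.shape, pixel_size=px)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")

    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * px)
    # rows increase southwards: northward derivative flips the row difference
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * px)

    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[slope == 0] = ASPECT_FLAT
    return (
        Raster(slope, grid, band_names=["slope"]),
        Raster(aspect, grid, band_names=["aspect"]),
    )


@dataclass
class FeatureStack:
    """Named co-registered feature layers with a combined validity mask."""

    names: list[str]
    values: np.ndarray  # (n_layers, rows, cols)
    mask: np.ndarray  # True = usable in training/classification/prediction
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def layer(self, name: str) -> np.ndarray:
        return self.values[self.names.index(name)]

    def table(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) design matrix at pixel indices."""
        return self.values[:, rows, cols].T


def stack_from_rasters(layers: dict[str, Raster]) -> FeatureStack:
    """Combine named rasters into a FeatureStack (masks intersected)."""
    if not layers:
        raise ValueError("no layers")
    grids = {r.grid.shape for r in layers.values()}
    if len(grids) != 1:
        raise ValueError("grid mismatch across layers")
    names = list(layers)
    first = next(iter(layers.values()))
    vals = np.stack([np.asarray(layers[n].values, dtype=float) for n in names])
    mask = np.ones(first.grid.shape, dtype=bool)
    for n in names:
        mask &= layers[n].mask & np.isfinite(layers[n].values)
    return FeatureStack(names, vals, mask, first.grid)


def assemble_stack(median: Raster, ndvi_metrics, terrain) -> FeatureStack:
    """The 12-layer classification stack.

    Six median reflectance bands + NDVI p10, p90 and 90-10 range + elevation,
    slope and aspect, with a manifest of layer names in documented order.
    ``terrain`` is the triple ``(slope, aspect, elevation)`` of rasters.
    Pixels masked in any layer are excluded from training and classification.
    """
    layers: dict[str, Raster] = {}
    for bname in median.band_names:
        layers[bname] = Raster(median.band(bname), median.grid, mask=median.mask, band_names=[bname])
    for key in ("p10", "p90", "r90_10"):
        layers[f"ndvi_{key}"] = ndvi_metrics.raster(key)
    try:
        slope, aspect, elev = terrain
    except ValueError:
        raise ValueError("terrain must be (slope, aspect, elevation)") from None
    layers["elevation"] = elev
    layers["slope"] = slope
    layers["aspect"] = aspect
    order = list(median.band_names) + ["ndvi_p10", "ndvi_p90", "ndvi_r90_10", "elevation", "slope", "aspect"]
    stack = stack_from_rasters({n: layers[n] for n in order})
    stack.meta["manifest"] = order
    return stack


def rasterize_polygons(polygons, grid: GridSpec) -> np.ndarray:
    """Class-code raster (0 = background) by pixel-centre containment."""
    out = np.zeros(grid.shape, dtype=np.int32)
    rows = np.arange(grid.rows)
    cols = np.arange(grid.cols)
    cc, rr = np.meshgrid(cols, rows)
    xs, ys = grid.xy(rr.ravel(), cc.ravel())
    for poly, code in polygons:
        minx, miny, maxx, maxy = poly.bounds
        sel = (xs >= minx) & (xs <= maxx) & (ys >= miny) & (ys <= maxy)
        if not sel.any():
            continue
        inside = contains_xy(poly, xs[sel], ys[sel])
        idx = np.flatnonzero(sel)[inside]
        out.ravel()[idx] = code
    return out


def classify_landcover(
    stack: FeatureStack,
    training_polygons,
    n_per_class: int = 5000,
    n_trees: int = 200,
    seed: int = 0,
) -> Raster:
    """Random-forest land-cover classification.

    Per class, up to ``n_per_class`` valid pixels are drawn by random
    stratified sampling within that class's training polygons (with
    replacement when fewer are available); a ``n_trees``-tree random forest
    is fit and applied to every valid stack pixel.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    train_map = rasterize_polygons(training_polygons, stack.grid)
    train_map[~stack.mask] = 0
    codes = sorted(int(c) for c in np.unique(train_map) if c != 0)
    wanted = sorted({int(code) for _, code in training_polygons})
    empty = [c for c in wanted if c not in codes]
    if empty:
        raise ValueError(f"classes with zero valid training pixels: {empty}")
    X_parts, y_parts = [], []
    for code in codes:
        pool = np.flatnonzero(train_map.ravel() == code)
        take = rng.choice(pool, size=n_per_class, replace=pool.size < n_per_class)
        r, c = np.unravel_index(take, stack.grid.shape)
        X_parts.append(stack.table(r, c))
        y_parts.append(np.full(take.size, code))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
    )
    clf.fit(X, y)
    out = np.zeros(stack.grid.shape, dtype=np.uint8)
    rr, cc = np.nonzero(stack.mask)
    out[rr, cc] = clf.predict(stack.table(rr, cc))
    return Raster(
        out,
        stack.grid,
        mask=stack.mask.copy(),
        band_names=["landcover"],
        meta={
            "legend": {int(k): v for k, v in CLASS_NAMES.items()},
            "stack_manifest": stack.meta.get("manifest", stack.names),
            "training": {"n_per_class": n_per_class, "n_trees": n_trees, "classes": codes},
        },
    )


def confusion_matrix(landcover: Raster, reference: pd.DataFrame) -> dict:
    """Confusion matrix and accuracies against reference points.

    ``reference`` needs columns x, y, class_code.  Returns a dict with the
    K x K count matrix (rows = reference, cols = mapped), overall accuracy
    and per-class producer's/user's accuracies.
    """
    grid = landcover.grid
    if not np.all(grid.contains(reference["x"].to_numpy(), reference["y"].to_numpy())):
        raise ValueError("reference point off-grid")
    mapped = np.asarray(landcover.sample(reference["x"].to_numpy(), reference["y"].to_numpy())).astype(int)
    true = reference["class_code"].to_numpy().astype(int)
    codes = sorted(int(c) for c in set(true) | set(mapped))
    k = len(codes)
    pos = {c: i for i, c in enumerate(codes)}
    mat = np.zeros((k, k), dtype=int)
    for t, m in zip(true, mapped):
        mat[pos[t], pos[m]] += 1
    total = mat.sum()
    overall = float(np.trace(mat)) / total if total else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        producers = np.where(mat.sum(axis=1) > 0, np.diag(mat) / mat.sum(axis=1), np.nan)
        users = np.where(mat.sum(axis=0) > 0, np.diag(mat) / mat.sum(axis=0), np.nan)
    return {
        "codes": codes,
        "matrix": pd.DataFrame(mat, index=codes, columns=codes),
        "overall_accuracy": overall,
        "producers_accuracy": {c: float(producers[pos[c]]) for c in codes},
        "users_accuracy": {c: float(users[pos[c]]) for c in codes},
        "n": int(total),
    }


def _disc_footprint(kernel_m: float, pixel_size: float) -> np.ndarray:
    """Boolean footprint of pixel offsets whose centre distance <= kernel_m."""
    r = int(np.floor(kernel_m / pixel_size))
    offs = np.arange(-r, r + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return (np.hypot(dx, dy) * pixel_size) <= kernel_m


def focal_proportion(landcover: Raster, class_code: int, kernel_m: float) -> Raster:
    """Fractional presence of a class within a circular moving window.

    Per pixel: the fraction of pixels of ``class_code`` among pixels whose
    centres lie within ``kernel_m`` metres of the focal pixel centre.
    Border pixels use the truncated neighbourhood.
    """
    px = landcover.grid.pixel_size
    if kernel_m < px:
        raise ValueError("kernel smaller than one pixel")
    foot = _disc_footprint(kernel_m, px).astype(float)
    target = (np.asarray(landcover.values) == class_code).astype(float)
    num = ndimage.convolve(target, foot, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(target), foot, mode="constant", cval=0.0)
    prop = num / den
    return Raster(
        prop,
        landcover.grid,
        mask=landcover.mask.copy(),
        band_names=[f"prop_{CLASS_NAMES.get(class_code, class_code)}_{int(kernel_m)}m"],
    )


def proportion_layers(
    landcover: Raster,
    classes=("grassland", "woodland", "arable"),
    kernels_m=DEFAULT_KERNELS_M,
) -> dict[str, Raster]:
    """Nested focal-proportion layers for the habitat classes.

    One layer per (class, kernel) pair; classes absent from the map are
    skipped (e.g. woodland-free sites yield 20 layers instead of 30).
    """
    from .synthetic import CLASS_CODES

    present = np.unique(np.asarray(landcover.values))
    out: dict[str, Raster] = {}
    for cname in classes:
        code = CLASS_CODES[cname]
        if code not in present:
            continue
        for k in kernels_m:
            r = focal_proportion(landcover, code, k)
            out[r.band_names[0]] = r
    return out
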