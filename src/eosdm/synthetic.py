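"""Synthetic landscapes, scene collections and small-mammal surveys.

Every downstream stage of the workflow (indices, composites, classification,
abundance indices, feature selection, SDM) is exercised against data from
this module, for which the ground truth is known by construction:

* a landscape = smooth correlated random fields thresholded into an 8-class
  land-cover map (grassland, woodland, arable, bushes, built-up, bare, water,
  snow) plus a DEM;
* a year of satellite scenes = per-class seasonal NDVI trajectories
  (Gaussian bump over day-of-year) inverted to six reflectance bands, with
  multiplicative lognormal noise and spatially coherent cloud gaps;
* species truth = a log-linear abundance surface over named covariates;
* surveys = Poisson trapline captures (trap-type, night and random trapline
  effects, effort offset) and Bernoulli transect interval presences.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit
from shapely.geometry import box

from .grid import GridSpec, Raster
from .scene import Scene

__all__ = [
    "CLASS_NAMES",
    "CLASS_CODES",
    "PhenologyParams",
    "DEFAULT_PHENOLOGY",
    "LandscapeTruth",
    "SpeciesEffectSpec",
    "generate_landscape",
    "generate_scene_collection",
    "generate_species_truth",
    "generate_trapline_survey",
    "generate_transect_survey",
    "training_polygons_from_truth",
    "reference_points_from_truth",
]

# class codes 1..8
CLASS_NAMES = {
    1: "grassland",
    2: "woodland",
    3: "arable",
    4: "bushes",
    5: "built_up",
    6: "bare",
    7: "water",
    8: "snow",
}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

#: classes a trap or transect can physically be placed in
LAND_CLASSES = (1, 2, 3, 4, 5, 6)
#: open-habitat classes walked by transects
OPEN_CLASSES = (1, 3)

DEFAULT_FRACTIONS = {
    "grassland": 0.55,
    "woodland": 0.10,
    "arable": 0.10,
    "bushes": 0.05,
    "built_up": 0.04,
    "bare": 0.12,
    "water": 0.02,
    "snow": 0.02,
}

# low -> high position along the suitability field used for thresholding;
# water sits in the wettest/lowest end, snow at the highest.
_CLASS_FIELD_ORDER = ("water", "arable", "built_up", "grassland", "bushes", "woodland", "bare", "snow")


@dataclass(frozen=True)
class PhenologyParams:
    """Seasonal reflectance behaviour of one land-cover class.

    NDVI follows a Gaussian bump over day-of-year,
    ``ndvi(t) = base_ndvi + amp_ndvi * exp(-((t - peak_doy) / width_doy)**2)``,
    which is inverted to band reflectances: red is fixed per class, NIR comes
    from the NDVI identity, blue/green scale from red and the SWIR bands
    scale from NIR.  ``noise_sd`` is the sd of multiplicative lognormal
    per-band noise.
    """

    base_ndvi: float
    amp_ndvi: float
    peak_doy: float
    width_doy: float
    red_reflectance: float
    swir_factor: float
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.base_ndvi + self.amp_ndvi >= 1.0:
            raise ValueError("invalid phenology: NDVI trajectory reaches >= 1")
        if not 0 < self.red_reflectance < 1:
            raise ValueError("red reflectance must be in (0, 1)")
        if self.width_doy <= 0:
            raise ValueError("width_doy must be positive")

    def ndvi(self, doy) -> np.ndarray:
        t = np.asarray(doy, dtype=float)
        return self.base_ndvi + self.amp_ndvi * np.exp(-(((t - self.peak_doy) / self.width_doy) ** 2))


DEFAULT_PHENOLOGY: dict[int, PhenologyParams] = {
    CLASS_CODES["grassland"]: PhenologyParams(0.15, 0.55, 200.0, 60.0, 0.08, 1.10),
    CLASS_CODES["woodland"]: PhenologyParams(0.35, 0.40, 190.0, 80.0, 0.05, 0.80),
    CLASS_CODES["arable"]: PhenologyParams(0.10, 0.60, 170.0, 40.0, 0.10, 1.00),
    CLASS_CODES["bushes"]: PhenologyParams(0.25, 0.35, 195.0, 70.0, 0.07, 0.90),
    CLASS_CODES["built_up"]: PhenologyParams(0.08, 0.05, 180.0, 90.0, 0.18, 1.30),
    CLASS_CODES["bare"]: PhenologyParams(0.05, 0.05, 180.0, 90.0, 0.25, 1.50),
    CLASS_CODES["water"]: PhenologyParams(-0.30, 0.0, 180.0, 60.0, 0.06, 0.25),
    CLASS_CODES["snow"]: PhenologyParams(-0.05, 0.0, 180.0, 60.0, 0.55, 0.15),
}


@dataclass
class LandscapeTruth:
    """Ground-truth landscape: grid, DEM, land cover and class parameters."""

    grid: GridSpec
    dem: np.ndarray
    landcover: np.ndarray
    class_params: dict[int, PhenologyParams] = field(default_factory=lambda: dict(DEFAULT_PHENOLOGY))

    def __post_init__(self) -> None:
        self.dem = np.asarray(self.dem, dtype=float)
        self.landcover = np.asarray(self.landcover)
        if self.dem.shape != self.grid.shape or self.landcover.shape != self.grid.shape:
            raise ValueError("dem/landcover shape mismatch with grid")
        if not np.all(np.isfinite(self.dem)):
            raise ValueError("dem must be finite everywhere")
        codes = np.unique(self.landcover)
        if codes.min() < 1 or codes.max() > 8:
            raise ValueError("land-cover codes must be in 1..8")

    def class_fractions(self) -> dict[str, float]:
        n = self.landcover.size
        return {CLASS_NAMES[c]: float(np.sum(self.landcover == c)) / n for c in range(1, 9)}

    def dem_raster(self) -> Raster:
        return Raster(self.dem, self.grid, band_names=["elevation"])

    def landcover_raster(self) -> Raster:
        return Raster(self.landcover.astype(np.uint8), self.grid, band_names=["landcover"])


@dataclass(frozen=True)
class SpeciesEffectSpec:
    """Known ground-truth effect structure of one simulated species.

    ``terms`` map covariate names (which must exist in the feature set handed
    to :func:`generate_species_truth`) to log-scale coefficients applied to
    z-scored covariates.  The trapline observation model is Poisson with
    trap-type and night fixed effects plus a N(0, trapline_sd^2) random
    trapline intercept; the transect model is Bernoulli per interval with
    logit p = transect_intercept + transect_slope * abundance.
    """

    name: str
    terms: tuple[tuple[str, float], ...]
    baseline: float = -1.2
    trap_type_effect: float = 0.7
    night_effect: float = -0.2
    trapline_sd: float = 0.3
    transect_intercept: float = -2.0
    transect_slope: float = 4.0

    def __post_init__(self) -> None:
        if self.trapline_sd < 0:
            raise ValueError("trapline_sd must be >= 0")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Standardized smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(
    rows: int,
    cols: int,
    fractions: dict[str, float] | None = None,
    seed: int = 0,
    pixel_size: float = 30.0,
    elevation_range: tuple[float, float] = (2900.0, 3450.0),
    snow_min_elevation: float = 3350.0,
    correlation_length_px: float = 8.0,
    dem_correlation: float = 0.6,
    class_params: dict[int, PhenologyParams] | None = None,
) -> LandscapeTruth:
    """Generate a ground-truth landscape.

    The DEM is a smoothed Gaussian random field rescaled to
    ``elevation_range``.  Land cover is obtained by ranking a second field
    (correlated with the DEM by ``dem_correlation``) and cutting it at the
    cumulative requested class fractions, so realized fractions match the
    request up to integer rounding; snow below ``snow_min_elevation`` is
    reassigned to bare ground.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("dimensions must be positive")
    fractions = dict(DEFAULT_FRACTIONS if fractions is None else fractions)
    unknown = set(fractions) - set(CLASS_CODES)
    if unknown:
        raise ValueError(f"unknown class names: {sorted(unknown)}")
    vals = np.array([fractions.get(name, 0.0) for name in _CLASS_FIELD_ORDER])
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("fractions must lie in [0, 1]")
    if abs(vals.sum() - 1.0) > 0.01:
        raise ValueError("fractions must sum to ~1")
    vals = vals / vals.sum()

    rng = np.random.default_rng(seed)
    grid = GridSpec(rows, cols, pixel_size)
    dem_field = _smooth_field(rng, (rows, cols), correlation_length_px)
    lo, hi = elevation_range
    span = dem_field.max() - dem_field.min()
    dem = lo + (dem_field - dem_field.min()) / (span if span > 0 else 1.0) * (hi - lo)

    g = _smooth_field(rng, (rows, cols), correlation_length_px)
    suit = dem_correlation * dem_field + np.sqrt(max(0.0, 1 - dem_correlation**2)) * g

    # exact-count assignment: rank pixels by suitability, cut at cumulative counts
    n = rows * cols
    counts = np.floor(vals * n).astype(int)
    counts[np.argmax(counts)] += n - counts.sum()
    order = np.argsort(suit, axis=None, kind="stable")
    codes_flat = np.empty(n, dtype=np.uint8)
    start = 0
    for name, c in zip(_CLASS_FIELD_ORDER, counts):
        codes_flat[order[start : start + c]] = CLASS_CODES[name]
        start += c
    landcover = codes_flat.reshape(rows, cols)

    low_snow = (landcover == CLASS_CODES["snow"]) & (dem < snow_min_elevation)
    landcover[low_snow] = CLASS_CODES["bare"]

    return LandscapeTruth(grid, dem, landcover, dict(class_params or DEFAULT_PHENOLOGY))


def _bands_from_ndvi(ndvi: np.ndarray, params: PhenologyParams) -> dict[str, np.ndarray]:
    """Invert an NDVI field to the six reflectance bands (noise-free)."""
    if np.any(ndvi >= 1.0):
        raise ValueError("NDVI trajectory reaches >= 1; cannot invert to reflectance")
    red = np.full_like(ndvi, params.red_reflectance, dtype=float)
    nir = red * (1.0 + ndvi) / (1.0 - ndvi)
    return {
        "blue": 0.5 * red,
        "green": 0.8 * red,
        "red": red,
        "nir": nir,
        "swir1": params.swir_factor * nir,
        "swir2": 0.85 * params.swir_factor * nir,
    }


def _cloud_mask(rng: np.random.Generator, shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Spatially coherent invalid-pixel mask covering ~``fraction`` of pixels.

    Blobs grow from random seed pixels by morphological dilation; the final
    dilation ring is subsampled so the target pixel count is hit exactly.
    Returns a boolean array, True = cloudy (invalid).
    """
    n = shape[0] * shape[1]
    target = int(round(fraction * n))
    cloud = np.zeros(shape, dtype=bool)
    if target == 0:
        return cloud
    n_seeds = max(1, int(round(target / 200.0)))
    idx = rng.choice(n, size=min(n_seeds, target), replace=False)
    cloud.flat[idx] = True
    struct = ndimage.generate_binary_structure(2, 2)
    while cloud.sum() < target:
        grown = ndimage.binary_dilation(cloud, structure=struct)
        ring = grown & ~cloud
        n_ring = int(ring.sum())
        need = target - int(cloud.sum())
        if n_ring == 0:  # saturated
            break
        if n_ring <= need:
            cloud = grown
        else:
            ring_idx = np.flatnonzero(ring.ravel())
            keep = rng.choice(ring_idx, size=need, replace=False)
            cloud.flat[keep] = True
    return cloud


def generate_scene_collection(
    truth: LandscapeTruth,
    dates: list[int],
    cloud_fraction: float = 0.2,
    seed: int = 0,
    sensor: str = "OLI",
    year: int = 2014,
) -> list[Scene]:
    """Simulate one scene per acquisition date over the landscape.

    Per pixel, reflectances follow the pixel class's phenology at the scene
    date with multiplicative lognormal noise (sd = class ``noise_sd``);
    contiguous cloud blobs flag ~``cloud_fraction`` of pixels invalid.
    """
    dates = list(dates)
    if any(not 1 <= d <= 366 for d in dates):
        raise ValueError("dates must be days-of-year in 1..366")
    if not 0 <= cloud_fraction < 1:
        raise ValueError("cloud_fraction must be in [0, 1)")
    shape = truth.grid.shape
    child_seeds = np.random.SeedSequence(seed).spawn(len(dates))
    scenes = []
    for doy, ss in zip(dates, child_seeds):
        rng = np.random.default_rng(ss)
        bands = {b: np.empty(shape) for b in ("blue", "green", "red", "nir", "swir1", "swir2")}
        for code, params in truth.class_params.items():
            sel = truth.landcover == code
            if not sel.any():
                continue
            clean = _bands_from_ndvi(np.array(params.ndvi(doy)), params)
            for name in bands:
                if params.noise_sd > 0:
                    noise = rng.lognormal(mean=0.0, sigma=params.noise_sd, size=int(sel.sum()))
                else:
                    noise = 1.0
                bands[name][sel] = np.clip(clean[name] * noise, 1e-4, 1.0)
        mask = ~_cloud_mask(rng, shape, cloud_fraction)
        scenes.append(Scene(bands, truth.grid, doy=int(doy), year=year, sensor=sensor, mask=mask))
    return scenes


def generate_species_truth(
    truth: LandscapeTruth,
    features: dict[str, Raster | np.ndarray],
    spec: SpeciesEffectSpec,
) -> Raster:
    """True abundance surface A(x) = exp(baseline + sum coef * z(covariate)).

    Covariates are z-scored over land pixels (water and snow excluded);
    non-finite covariate values are replaced by the land mean before scoring
    so A is finite everywhere.
    """
    land = np.isin(truth.landcover, LAND_CLASSES)
    eta = np.full(truth.grid.shape, spec.baseline, dtype=float)
    for name, coef in spec.terms:
        if name not in features:
            raise KeyError(f"unknown covariate {name!r} in species spec")
        f = features[name]
        arr = np.asarray(f.values if isinstance(f, Raster) else f, dtype=float).copy()
        finite = np.isfinite(arr)
        mu = arr[land & finite].mean()
        sd = arr[land & finite].std()
        arr[~finite] = mu
        z = (arr - mu) / (sd if sd > 0 else 1.0)
        eta += coef * z
    A = np.exp(eta)
    return Raster(A, truth.grid, band_names=[f"abundance_{spec.name}"])


def _stratified_sites(
    rng: np.random.Generator,
    landcover: np.ndarray,
    classes: tuple[int, ...],
    n_sites: int,
) -> np.ndarray:
    """Flat pixel indices of survey sites, stratified by land-cover class.

    Sites are allocated to classes proportionally to class area (each class
    present gets at least one where the budget allows) and drawn uniformly
    without replacement within class.
    """
    present = [c for c in classes if np.any(landcover == c)]
    if not present:
        raise ValueError("no pixels of the requested classes")
    areas = np.array([np.sum(landcover == c) for c in present], dtype=float)
    alloc = np.maximum(1, np.round(areas / areas.sum() * n_sites).astype(int))
    while alloc.sum() > n_sites:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_sites:
        alloc[np.argmax(areas / alloc)] += 1
    chosen = []
    for c, k in zip(present, alloc):
        pool = np.flatnonzero(landcover.ravel() == c)
        k = min(k, pool.size)
        chosen.append(rng.choice(pool, size=k, replace=False))
    return np.concatenate(chosen)


def generate_trapline_survey(
    abundance: Raster,
    truth: LandscapeTruth,
    n_traplines: int,
    spec: SpeciesEffectSpec,
    seed: int = 0,
    nights: int = 3,
    traps_per_line: int = 25,
) -> pd.DataFrame:
    """Simulate trapline trap-night capture records.

    One row per trapline x night with columns
    ``line_id, x, y, habitat, trap_type, night, captures, accessible, species``.
    Captures are Poisson with mean
    ``accessible * A(x) * exp(b_type*I[bbbt] + b_night*(night-1) + u_line)``,
    truncated at the number of accessible traps.  Traps are re-set every
    morning and sprung-empty traps are not modelled, so ``accessible`` equals
    the full complement each night.
    """
    if n_traplines < 1:
        raise ValueError("need at least one trapline")
    rng = np.random.default_rng(seed)
    sites = _stratified_sites(rng, truth.landcover, LAND_CLASSES, n_traplines)
    rows_idx, cols_idx = np.unravel_index(sites, truth.grid.shape)
    x, y = truth.grid.xy(rows_idx, cols_idx)
    A = np.asarray(abundance.values)[rows_idx, cols_idx]
    u = rng.normal(0.0, spec.trapline_sd, size=len(sites))
    records = []
    for l, (xi, yi) in enumerate(zip(x, y)):
        trap_type = "bbbt" if l % 2 else "sbbt"
        habitat = CLASS_NAMES[int(truth.landcover[rows_idx[l], cols_idx[l]])]
        for night in range(1, nights + 1):
            accessible = traps_per_line
            lam = accessible * A[l] * np.exp(
                spec.trap_type_effect * (trap_type == "bbbt")
                + spec.night_effect * (night - 1)
                + u[l]
            )
            captures = min(int(rng.poisson(lam)), accessible)
            records.append(
                {
                    "line_id": f"L{l:03d}",
                    "x": float(xi),
                    "y": float(yi),
                    "habitat": habitat,
                    "trap_type": trap_type,
                    "night": night,
                    "captures": captures,
                    "accessible": accessible,
                    "species": spec.name,
                }
            )
    return pd.DataFrame.from_records(records)


def generate_transect_survey(
    abundance: Raster,
    truth: LandscapeTruth,
    n_transects: int,
    spec: SpeciesEffectSpec,
    seed: int = 0,
    intervals: int = 20,
    pace_m: float = 0.8,
    paces_per_interval: int = 10,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Simulate transect interval presence records.

    One row per transect x interval with columns
    ``transect_id, interval, x, y, presence, species``.  Transects start at a
    random open-habitat pixel (grassland/arable), run on a random heading
    with interval midpoints ``paces_per_interval * pace_m`` apart, and are
    re-drawn if they would leave the grid.  Presence per interval is
    Bernoulli(logistic(a + b * A)).
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    open_pool = np.flatnonzero(np.isin(truth.landcover, OPEN_CLASSES).ravel())
    if open_pool.size == 0:
        raise ValueError("no open-habitat pixels for transects")
    step = pace_m * paces_per_interval
    records = []
    for t in range(n_transects):
        for _ in range(max_tries):
            site = rng.choice(open_pool)
            r0, c0 = np.unravel_index(site, grid.shape)
            x0, y0 = grid.xy(r0, c0)
            theta = rng.uniform(0, 2 * np.pi)
            d = (np.arange(intervals) + 0.5) * step
            xs = x0 + d * np.cos(theta)
            ys = y0 + d * np.sin(theta)
            if np.all(grid.contains(xs, ys)):
                break
        else:
            raise RuntimeError("could not place transect inside the grid")
        A = abundance.sample(xs, ys)
        p = expit(spec.transect_intercept + spec.transect_slope * np.asarray(A, dtype=float))
        pres = rng.random(intervals) < p
        for i in range(intervals):
            records.append(
                {
                    "transect_id": f"T{t:03d}",
                    "interval": i + 1,
                    "x": float(xs[i]),
                    "y": float(ys[i]),
                    "presence": int(pres[i]),
                    "species": spec.name,
                }
            )
    return pd.DataFrame.from_records(records)


def generate_feature_response(
    n: int = 60,
    p: int = 40,
    k_informative: int = 5,
    r2: float = 0.9,
    seed: int = 0,
):
    """Plain regression table with a known informative subset.

    Generates ``n`` units with ``p`` standard-normal covariates of which the
    first ``k_informative`` carry a linear signal; the informative block is
    orthonormalized and the noise made orthogonal to the signal and scaled so
    the realized coefficient of determination is exactly ``r2`` — each
    informative covariate then carries its nominal, detectable share of the
    signal rather than a luck-of-the-draw realization.  Used to exercise
    feature selection with known ground truth.

    Returns ``(DataFrame with columns v0..v{p-1}, response array,
    list of informative column names)``.
    """
    import pandas as pd

    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    if k_informative < 1 or k_informative >= min(n, p):
        raise ValueError("k_informative must be in [1, min(n, p))")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Q, _ = np.linalg.qr(X[:, :k_informative])
    Xk = Q * np.sqrt(n)
    X[:, :k_informative] = Xk
    signal = Xk.sum(axis=1)
    eps = rng.standard_normal(n)
    eps -= Xk @ (Xk.T @ eps) / n  # orthogonal to the signal block
    eps *= np.sqrt(signal.var() * (1 / r2 - 1)) / eps.std()
    y = signal + eps
    cols = [f"v{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y, cols[:k_informative]


def training_polygons_from_truth(
    truth: LandscapeTruth,
    n_per_class: int = 5,
    seed: int = 0,
):
    """Single-pixel training polygons sampled from the true land cover.

    Emulates field-digitized training areas: for each class present, up to
    ``n_per_class`` pixel-footprint squares drawn around randomly chosen
    pixels of that class.  Returns a list of ``(shapely polygon, class_code)``.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    polys = []
    half = grid.pixel_size / 2.0
    for code in sorted(np.unique(truth.landcover)):
        pool = np.flatnonzero((truth.landcover == code).ravel())
        take = rng.choice(pool, size=min(n_per_class, pool.size), replace=False)
        for idx in np.atleast_1d(take):
            r, c = np.unravel_index(idx, grid.shape)
            x, y = grid.xy(r, c)
            polys.append((box(x - half, y - half, x + half, y + half), int(code)))
    return polys


def reference_points_from_truth(
    truth: LandscapeTruth,
    n_per_class: int = 50,
    seed: int = 0,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Random per-class reference points (x, y, class_code) for validation."""
    rng = np.random.default_rng(seed)
    rows = []
    for code in sorted(np.unique(truth.landcover)):
        sel = truth.landcover == code
        if exclude is not None:
            sel = sel & ~exclude
        pool = np.flatnonzero(sel.ravel())
        if pool.size == 0:
            continue
        take = rng.choice(pool, size=min(n_per_class, pool.size), replace=False)
        r, c = np.unravel_index(np.atleast_1d(take), truth.grid.shape)
        x, y = truth.grid.xy(r, c)
        for xi, yi in zip(np.atleast_1d(x), np.atleast_1d(y)):
            rows.append({"x": float(xi), "y": float(yi), "class_code": int(code)})
    return pd.DataFrame.from_records(rows)
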