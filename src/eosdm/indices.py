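"""Vegetation and water index suite plus the tasselled-cap transform.

Twelve per-scene layers are used by the workflow: NDVI, NDWI, MNDWI, EVI,
GRVI, DVI, TVI, SVVI, SAVI and the tasselled-cap brightness, greenness and
wetness components.  All are pixelwise functions of the six reflectance
bands; pixels where a normalized-difference denominator vanishes are masked
rather than clamped, and the scene's cloud mask is inherited.
"""

from __future__ import annotations

import numpy as np

from .grid import Raster
from .scene import BAND_ORDER, Scene

__all__ = ["INDEX_NAMES", "compute_index", "tasseled_cap", "TASSELED_CAP_COEFFS"]

INDEX_NAMES = ("ndvi", "ndwi", "mndwi", "evi", "grvi", "dvi", "tvi", "svvi", "savi")

# Published reflectance-space tasselled-cap coefficients, band order
# blue, green, red, nir, swir1, swir2.
# TM: Crist (1985); OLI: Baig et al. (2014).
TASSELED_CAP_COEFFS = {
    "TM": {
        "tcb": (0.2043, 0.4158, 0.5524, 0.5741, 0.3124, 0.2303),
        "tcg": (-0.1603, -0.2819, -0.4934, 0.7940, -0.0002, -0.1446),
        "tcw": (0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109),
    },
    "OLI": {
        "tcb": (0.3029, 0.2786, 0.4733, 0.5599, 0.5080, 0.1872),
        "tcg": (-0.2941, -0.2430, -0.5424, 0.7276, 0.0713, -0.1608),
        "tcw": (0.1511, 0.1973, 0.3283, 0.3407, -0.7117, -0.4559),
    },
}


def _norm_diff(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(a-b)/(a+b) with zero-denominator pixels flagged invalid."""
    den = a + b
    bad = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, (a - b) / np.where(bad, 1.0, den))
    return out, ~bad


def compute_index(scene: Scene, name: str) -> Raster:
    """Compute one spectral index for a scene.

    ``name`` is case-insensitive and must be one of :data:`INDEX_NAMES`
    (plus ``ndwi_mcfeeters`` for the green-NIR water-index variant).  The
    returned raster inherits the scene mask, further masking any pixel with
    a vanishing denominator.
    """
    key = name.lower()
    b = scene.bands
    extra_valid = np.ones(scene.grid.shape, dtype=bool)
    if key == "ndvi":
        vals, extra_valid = _norm_diff(b["nir"], b["red"])
    elif key == "ndwi":  # Gao vegetation-moisture variant (NIR - SWIR1)
        vals, extra_valid = _norm_diff(b["nir"], b["swir1"])
    elif key == "ndwi_mcfeeters":
        vals, extra_valid = _norm_diff(b["green"], b["nir"])
    elif key == "mndwi":
        vals, extra_valid = _norm_diff(b["green"], b["swir1"])
    elif key == "evi":
        den = b["nir"] + 6.0 * b["red"] - 7.5 * b["blue"] + 1.0
        bad = den == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(bad, np.nan, 2.5 * (b["nir"] - b["red"]) / np.where(bad, 1.0, den))
        extra_valid = ~bad
    elif key == "grvi":
        vals, extra_valid = _norm_diff(b["green"], b["red"])
    elif key == "dvi":
        vals = b["nir"] - b["red"]
    elif key == "tvi":
        vals = 0.5 * (120.0 * (b["nir"] - b["green"]) - 200.0 * (b["red"] - b["green"]))
    elif key == "svvi":
        stack6 = scene.band_stack()
        stack_ir = np.stack([b["nir"], b["swir1"], b["swir2"]])
        vals = stack6.std(axis=0) - stack_ir.std(axis=0)
    elif key == "savi":
        L = 0.5
        den = b["nir"] + b["red"] + L
        bad = den == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(bad, np.nan, (1.0 + L) * (b["nir"] - b["red"]) / np.where(bad, 1.0, den))
        extra_valid = ~bad
    else:
        raise ValueError(f"unknown index {name!r}")
    mask = scene.mask & extra_valid
    return Raster(vals, scene.grid, mask=mask, band_names=[key], meta={"doy": scene.doy})


def tasseled_cap(scene: Scene) -> dict[str, Raster]:
    """Tasselled-cap brightness/greenness/wetness for a scene.

    Linear combinations of the six reflectance bands using the published
    sensor-specific coefficient set selected by ``scene.sensor``.
    Returns ``{"tcb": ..., "tcg": ..., "tcw": ...}``.
    """
    try:
        coeffs = TASSELED_CAP_COEFFS[scene.sensor]
    except KeyError:
        raise ValueError(f"unknown sensor tag {scene.sensor!r}") from None
    stack = scene.band_stack()
    out = {}
    for comp, c in coeffs.items():
        vals = np.tensordot(np.asarray(c), stack, axes=(0, 0))
        out[comp] = Raster(vals, scene.grid, mask=scene.mask.copy(), band_names=[comp], meta={"doy": scene.doy})
    return out


def compute_index_suite(scene: Scene, names=None) -> dict[str, Raster]:
    """All requested indices for one scene (tasselled-cap included)."""
    names = [n.lower() for n in (names or list(INDEX_NAMES) + ["tcb", "tcg", "tcw"])]
    out: dict[str, Raster] = {}
    tc_wanted = [n for n in names if n in ("tcb", "tcg", "tcw")]
    if tc_wanted:
        tc = tasseled_cap(scene)
        out.update({n: tc[n] for n in tc_wanted})
    for n in names:
        if n not in ("tcb", "tcg", "tcw"):
            out[n] = compute_index(scene, n)
    return out
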