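"""The Scene container: one dated multi-band surface-reflectance observation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

BAND_ORDER = ("blue", "green", "red", "nir", "swir1", "swir2")

__all__ = ["Scene", "BAND_ORDER"]


@dataclass
class Scene:
    """A six-band surface-reflectance raster with a validity mask.

    Bands are unitless surface reflectance, nominally in [0, 1].  ``mask`` is
    True where the pixel is usable (cloud-, shadow- and snow-free); masked
    pixels are excluded from every downstream statistic.  ``sensor`` selects
    sensor-specific coefficient sets (tasselled cap): "TM" or "OLI".
    """

    bands: dict[str, np.ndarray]
    grid: GridSpec
    doy: int
    year: int = 2014
    sensor: str = "OLI"
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [b for b in BAND_ORDER if b not in self.bands]
        if missing:
            raise ValueError(f"scene missing bands: {missing}")
        shape = self.grid.shape
        for name, arr in self.bands.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"band {name!r} shape {arr.shape} != grid {shape}")
            self.bands[name] = arr
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValueError("mask shape mismatch")
        if not 1 <= self.doy <= 366:
            raise ValueError("day-of-year must be in 1..366")

    def band_stack(self) -> np.ndarray:
        """(6, rows, cols) array in canonical band order."""
        return np.stack([self.bands[b] for b in BAND_ORDER])

    def valid_fraction(self) -> float:
        return float(self.mask.mean())
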