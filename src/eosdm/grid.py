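"""Regular-grid raster containers.

Everything in the package lives on a single regular, axis-aligned grid in
projected metre coordinates (the 30 m working resolution of the Landsat/SRTM
stack the workflow emulates).  Pixel (0, 0) is the upper-left pixel; the
pixel-centre coordinate convention is used throughout: the centre of pixel
(row, col) sits at ``(x0 + (col + 0.5) * px, y0 - (row + 0.5) * px)`` where
``(x0, y0)`` is the upper-left corner of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "Raster"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the working grid.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions.
    pixel_size : float
        Side of a square pixel in metres (> 0).
    x0, y0 : float
        Projected coordinates of the grid's upper-left *corner*.
    crs : str
        Free-text label of the projected CRS (metadata only).
    """

    rows: int
    cols: int
    pixel_size: float = 30.0
    x0: float = 0.0
    y0: float = 0.0
    crs: str = "local-metres"

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size**2

    def xy(self, row, col):
        """Centre coordinates of pixel(s) (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.pixel_size
        y = self.y0 - (row + 0.5) * self.pixel_size
        return x, y

    def rowcol(self, x, y):
        """Pixel indices containing point(s) (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.pixel_size).astype(int)
        row = np.floor((self.y0 - y) / self.pixel_size).astype(int)
        return row, col

    def contains(self, x, y):
        row, col = self.rowcol(x, y)
        return (row >= 0) & (row < self.rows) & (col >= 0) & (col < self.cols)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "pixel_size": self.pixel_size,
            "x0": self.x0,
            "y0": self.y0,
            "crs": self.crs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class Raster:
    """One or more co-registered bands plus a shared validity mask.

    ``values`` has shape (rows, cols) for a single band or
    (bands, rows, cols) for a stack; ``mask`` is boolean (rows, cols),
    True = valid.  Statistics downstream never touch invalid pixels.
    """

    values: np.ndarray
    grid: GridSpec
    mask: np.ndarray | None = None
    band_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            shape = self.values.shape
        elif self.values.ndim == 3:
            shape = self.values.shape[1:]
        else:
            raise ValueError("raster values must be 2-D or 3-D")
        if shape != self.grid.shape:
            raise ValueError(f"values shape {shape} != grid shape {self.grid.shape}")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise ValueError("mask shape mismatch")
        if not self.band_names:
            n = 1 if self.values.ndim == 2 else self.values.shape[0]
            self.band_names = [f"band_{i + 1}" for i in range(n)]

    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    def band(self, name: str) -> np.ndarray:
        """2-D array of the named band."""
        if self.values.ndim == 2:
            if name != self.band_names[0]:
                raise KeyError(name)
            return self.values
        try:
            i = self.band_names.index(name)
        except ValueError:
            raise KeyError(name) from None
        return self.values[i]

    def masked(self, fill=np.nan) -> np.ndarray:
        """Values with invalid pixels replaced by ``fill`` (float output)."""
        out = np.asarray(self.values, dtype=float).copy()
        if out.ndim == 2:
            out[~self.mask] = fill
        else:
            out[:, ~self.mask] = fill
        return out

    def sample(self, x, y):
        """Value(s) at the pixel containing each point; no interpolation."""
        row, col = self.grid.rowcol(x, y)
        inside = (row >= 0) & (row < self.grid.rows) & (col >= 0) & (col < self.grid.cols)
        if not np.all(inside):
            raise ValueError("coordinate outside grid")
        if self.values.ndim == 2:
            return self.values[row, col]
        return self.values[:, row, col]
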