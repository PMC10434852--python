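"""Raster, survey-table and configuration I/O.

Rasters are written as tiled float/int TIFFs with the georeferencing carried
in the GeoTIFF ModelPixelScale/ModelTiepoint tags and a JSON payload in the
image description (band names, nodata, CRS label, free-form metadata).  The
write -> read cycle is bit-exact for integer rasters and exact to float32
resolution for float rasters; nodata pixels round-trip as mask.

Survey tables are plain CSV with the documented column schemas:

* trapline: line_id, x, y, habitat, trap_type {sbbt,bbbt}, night {1..3},
  captures, accessible, species
* transect: transect_id, interval {1..20}, x, y, presence {0,1}, species
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grid import GridSpec, Raster

__all__ = ["write_raster", "read_raster", "write_survey", "read_survey", "load_config", "save_config"]

_FLOAT_NODATA = float(np.float32(-3.4e38))

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

TRAPLINE_COLUMNS = ["line_id", "x", "y", "habitat", "trap_type", "night", "captures", "accessible", "species"]
TRANSECT_COLUMNS = ["transect_id", "interval", "x", "y", "presence", "species"]


def write_raster(path, raster: Raster, nodata=None) -> None:
    """Write a raster (single- or multi-band) as a georeferenced TIFF."""
    path = Path(path)
    vals = np.asarray(raster.values)
    is_float = np.issubdtype(vals.dtype, np.floating)
    if nodata is None:
        nodata = _FLOAT_NODATA if is_float else 0
    out = vals.astype(np.float32) if is_float else vals
    out = out.copy()
    if out.ndim == 2:
        out[~raster.mask] = nodata
    else:
        out[:, ~raster.mask] = nodata
    g = raster.grid
    desc = json.dumps(
        {
            "band_names": raster.band_names,
            "nodata": nodata,
            "grid": g.to_dict(),
            "meta": _jsonable(raster.meta),
        }
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (g.pixel_size, g.pixel_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x0, g.y0, 0.0)),
    ]
    tifffile.imwrite(path, out, description=desc, extratags=extratags, photometric="minisblack")


def read_raster(path) -> Raster:
    """Read a raster written by :func:`write_raster`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        desc = page.description
        vals = tif.asarray()
    info = json.loads(desc)
    grid = GridSpec.from_dict(info["grid"])
    nodata = info["nodata"]
    if vals.ndim == 2:
        mask = vals != nodata
    else:
        mask = np.all(vals != nodata, axis=0)
    if np.issubdtype(np.asarray(vals).dtype, np.floating):
        vals = vals.astype(float)
        if vals.ndim == 2:
            vals[~mask] = np.nan
        else:
            vals[:, ~mask] = np.nan
    return Raster(vals, grid, mask=mask, band_names=list(info["band_names"]), meta=info.get("meta", {}))


def write_survey(path, table: pd.DataFrame, kind: str) -> None:
    """Write a trapline or transect table as CSV with the documented schema."""
    cols = {"trapline": TRAPLINE_COLUMNS, "transect": TRANSECT_COLUMNS}[kind]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns: {missing}")
    table[cols].to_csv(path, index=False)


def read_survey(path, kind: str) -> pd.DataFrame:
    """Read a survey CSV, validating the documented schema."""
    cols = {"trapline": TRAPLINE_COLUMNS, "transect": TRANSECT_COLUMNS}[kind]
    df = pd.read_csv(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns: {missing}")
    return df


def load_config(path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
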