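"""Species-specific abundance indices from trapline and transect records.

Traplines: a Poisson mixed model with trap-type and control-night fixed
effects, a random trapline intercept and a log(accessible traps) effort
offset is fitted per species.  Where trap type or night has a statistically
significant effect (Wald test, alpha = 0.05) the per-trapline mean of the
response-scale residuals (observed - population-level fitted) is used as the
relative abundance index; otherwise the index falls back to raw captures
per 100 trap-nights.  The decision path is recorded in the result.

Transects: the relative abundance score of a 20-interval transect is simply
the number of intervals with a presence indicator for the species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glmm import PoissonGLMMResult, fit_poisson_glmm

__all__ = [
    "CaptureModelFit",
    "transect_scores",
    "fit_capture_model",
    "abundance_indices",
]

ALPHA = 0.05


def transect_scores(records: pd.DataFrame, intervals: int = 20, allow_partial: bool = False) -> pd.DataFrame:
    """Per-transect relative abundance scores.

    ``records`` needs columns transect_id, interval, x, y, presence (and
    optionally species).  The score is the count of positive intervals
    (0..``intervals``); the transect location is the mean of its interval
    coordinates.  Transects without exactly ``intervals`` records are
    rejected unless ``allow_partial``, in which case scores are pro-rated to
    the full interval count.
    """
    required = {"transect_id", "interval", "x", "y", "presence"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    species = records["species"].iloc[0] if "species" in records.columns else None
    for tid, g in records.groupby("transect_id", sort=True):
        n = len(g)
        if n != intervals:
            if not allow_partial or n == 0:
                raise ValueError(f"transect {tid} has {n} intervals, expected {intervals}")
            score = float(g["presence"].sum()) * intervals / n
        else:
            score = float(g["presence"].sum())
        out.append(
            {
                "unit_id": tid,
                "x": float(g["x"].mean()),
                "y": float(g["y"].mean()),
                "species": species,
                "value": score,
                "source": "transect",
            }
        )
    return pd.DataFrame.from_records(out)


@dataclass
class CaptureModelFit:
    """Capture-model fit plus the significance gate used downstream."""

    model: PoissonGLMMResult | None
    species: str | None
    effects: dict
    significant: bool
    fallback: bool
    fallback_reason: str | None = None
    table: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]


def _trapline_design(table: pd.DataFrame):
    ttype = (table["trap_type"] == "bbbt").to_numpy(dtype=float)
    night = table["night"].to_numpy(dtype=float) - 1.0
    X = np.column_stack([np.ones(len(table)), ttype, night])
    names = ["intercept", "trap_type[bbbt]", "night"]
    return X, names


def fit_capture_model(table: pd.DataFrame, species: str | None = None) -> CaptureModelFit:
    """Fit the Poisson GLMM to trap-night records of one species.

    ``table`` needs columns line_id, trap_type, night, captures, accessible
    (one row per trapline x night).  Night enters as a linear control-night
    effect (night 1 = 0) and log(accessible) as the offset.  If the species
    was never captured no model is fitted and the raw-total fallback is
    flagged.
    """
    if species is not None and "species" in table.columns:
        table = table[table["species"] == species]
    table = table.reset_index(drop=True)
    if table["line_id"].nunique() < 2:
        raise ValueError("need at least two traplines")
    y = table["captures"].to_numpy()
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("captures must be non-negative integers")
    if np.any(table["captures"] > table["accessible"]):
        raise ValueError("captures exceed accessible traps")
    if y.sum() == 0:
        return CaptureModelFit(None, species, {}, False, True, "all-zero captures", table)
    X, names = _trapline_design(table)
    res = fit_poisson_glmm(
        y,
        X,
        table["line_id"].to_numpy(),
        offset=np.log(table["accessible"].to_numpy(dtype=float)),
        exog_names=names,
    )
    effects = res.summary_table()
    significant = bool(
        effects["trap_type[bbbt]"]["p"] < ALPHA or effects["night"]["p"] < ALPHA
    )
    return CaptureModelFit(res, species, effects, significant, False, None, table)


def abundance_indices(fit: CaptureModelFit, traps_per_line: int = 25, residual_type: str = "response") -> pd.DataFrame:
    """Per-trapline abundance index from a capture-model fit.

    If any controlled effect (trap type, night) is significant the index is
    the trapline mean of residuals (``residual_type`` "response":
    observed - fitted; "pearson": scaled by sqrt(fitted)); the fitted values
    are population-level (random effect at zero) so between-line abundance
    variation is retained in the index.  Otherwise — or when no model could
    be fitted — the index is total captures per 100 trap-nights.  The path
    taken is recorded in the ``method`` column.
    """
    table = fit.table
    if fit.fallback or not fit.significant:
        method = "captures_per_100_trap_nights"
        grouped = table.groupby("line_id", sort=True)
        vals = grouped["captures"].sum() / (grouped.size() * traps_per_line) * 100.0
    else:
        method = f"glmm_{residual_type}_residual"
        fitted = fit.model.fittedvalues(conditional=False)
        resid = table["captures"].to_numpy() - fitted
        if residual_type == "pearson":
            resid = resid / np.sqrt(fitted)
        elif residual_type != "response":
            raise ValueError("residual_type must be 'response' or 'pearson'")
        vals = pd.Series(resid, index=table.index).groupby(table["line_id"]).mean()
    coords = table.groupby("line_id", sort=True)[["x", "y"]].first()
    out = pd.DataFrame(
        {
            "unit_id": vals.index,
            "x": coords.loc[vals.index, "x"].to_numpy(),
            "y": coords.loc[vals.index, "y"].to_numpy(),
            "species": fit.species,
            "value": vals.to_numpy(dtype=float),
            "source": "trapline",
        }
    ).reset_index(drop=True)
    out.attrs["method"] = method
    return out
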