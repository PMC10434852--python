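"""End-to-end pipeline: simulate -> indices -> composites -> classify ->
proportions -> survey -> select -> tune -> fit -> predict -> threshold -> report.

A single configuration dictionary (YAML-compatible; see
:data:`DEMO_CONFIG`) carries every stage's parameters and one master seed,
which is fanned out deterministically per stage (stage-name hashing), so a
rerun with the same config reproduces identical outputs; the run manifest
records parameters, derived seeds and SHA-256 hashes of every stage output,
and manifest equality is the pipeline's regression/determinism test.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from . import composites, indices, landcover, sdm, survey, synthetic
from .grid import Raster

__all__ = ["DEMO_CONFIG", "derive_seed", "run_pipeline"]

log = logging.getLogger(__name__)

DEMO_CONFIG = {
    "grid": {"rows": 120, "cols": 120, "pixel_size": 30.0},
    "landscape": {
        "fractions": dict(synthetic.DEFAULT_FRACTIONS),
        "elevation_range": [2900.0, 3450.0],
        "snow_min_elevation": 3350.0,
    },
    "scenes": {
        "dates": [30, 60, 105, 135, 160, 185, 215, 250, 290, 330],
        "cloud_fraction": 0.2,
        "sensor": "OLI",
    },
    "indices": ["ndvi", "ndwi", "savi"],
    "min_obs": 3,
    "kernels_m": [50, 100, 150, 200, 250, 300, 350, 400, 450, 500],
    "classification": {"n_polygons_per_class": 6, "n_per_class": 5000, "n_trees": 200,
                       "n_reference_per_class": 40},
    "species": [
        {
            "name": "grassland_vole",
            "survey": "trapline",
            "n_units": 60,
            "terms": {"prop_grassland_250m": 1.0, "ndvi_p90": 0.6},
            "baseline": -1.2,
            "trap_type_effect": 0.7,
            "night_effect": -0.2,
            "trapline_sd": 0.3,
        },
        {
            "name": "mole_vole",
            "survey": "transect",
            "n_units": 60,
            "terms": {"prop_grassland_250m": 0.8, "ndwi_p50": -0.6},
            "baseline": -1.0,
            "transect_intercept": -2.0,
            "transect_slope": 4.0,
        },
    ],
    "boruta": {"alpha": 0.01, "max_iter": 50, "n_trees": 300},
    "sdm": {
        "grid": [
            {"n_trees": 200, "min_leaf_population": 1, "max_nodes": None},
            {"n_trees": 100, "min_leaf_population": 5, "max_nodes": None},
        ]
    },
    "autocorr": {"radius_m": 1500.0, "n_permutations": 999},
    "master_seed": 0,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    return int(
        np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31 - 1)
    )


def _hash_array(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        a = np.asarray(a)
        h.update(str(a.dtype).encode())
        h.update(str(a.shape).encode())
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _species_spec(cfg: dict) -> synthetic.SpeciesEffectSpec:
    return synthetic.SpeciesEffectSpec(
        name=cfg["name"],
        terms=tuple((k, float(v)) for k, v in cfg["terms"].items()),
        baseline=float(cfg.get("baseline", -1.2)),
        trap_type_effect=float(cfg.get("trap_type_effect", 0.7)),
        night_effect=float(cfg.get("night_effect", -0.2)),
        trapline_sd=float(cfg.get("trapline_sd", 0.3)),
        transect_intercept=float(cfg.get("transect_intercept", -2.0)),
        transect_slope=float(cfg.get("transect_slope", 4.0)),
    )


def run_pipeline(config: dict | None = None) -> dict:
    """Run the whole workflow on a synthetic landscape.

    Returns ``{"results": {species: SDMResult}, "manifest": {...},
    "truth": ..., "landcover": ..., "accuracy": ...}``.  Every stage logs
    its derived seed and output hashes into the manifest; identical configs
    produce identical manifests.
    """
    cfg = json.loads(json.dumps(DEMO_CONFIG if config is None else config))
    master = int(cfg["master_seed"])
    manifest: dict = {"master_seed": master, "stages": {}}

    def record(stage, seed=None, **outputs):
        manifest["stages"][stage] = {"seed": seed, **outputs}
        log.info("stage %s done", stage)

    # -- simulate ----------------------------------------------------------
    g = cfg["grid"]
    lc_cfg = cfg["landscape"]
    seed = derive_seed(master, "landscape")
    truth = synthetic.generate_landscape(
        g["rows"], g["cols"], fractions=lc_cfg["fractions"], seed=seed,
        pixel_size=g["pixel_size"],
        elevation_range=tuple(lc_cfg["elevation_range"]),
        snow_min_elevation=lc_cfg["snow_min_elevation"],
    )
    record("landscape", seed, dem=_hash_array(truth.dem), landcover=_hash_array(truth.landcover))

    sc = cfg["scenes"]
    seed = derive_seed(master, "scenes")
    scenes = synthetic.generate_scene_collection(
        truth, sc["dates"], cloud_fraction=sc["cloud_fraction"], seed=seed, sensor=sc["sensor"]
    )
    record("scenes", seed, bands=_hash_array(*[s.band_stack() for s in scenes]),
           masks=_hash_array(*[s.mask for s in scenes]))

    # -- indices + composites ---------------------------------------------
    metric_layers: dict[str, Raster] = {}
    for name in cfg["indices"]:
        per_scene = [indices.compute_index(s, name) for s in scenes]
        pm = composites.percentile_metrics(per_scene, min_obs=cfg["min_obs"], index=name)
        metric_layers.update(pm.as_rasters())
    ndvi_scenes = [indices.compute_index(s, "ndvi") for s in scenes]
    ndvi_pm = composites.percentile_metrics(ndvi_scenes, min_obs=cfg["min_obs"], index="ndvi")
    median = composites.median_composite(scenes, min_obs=cfg["min_obs"])
    record("composites", None,
           metrics=_hash_array(*[m.values for m in metric_layers.values()]),
           median=_hash_array(median.values))

    # -- terrain + classification -----------------------------------------
    slope, aspect = landcover.terrain_derivatives(truth.dem_raster())
    terrain = (slope, aspect, truth.dem_raster())
    stack = landcover.assemble_stack(median, ndvi_pm, terrain)
    cl = cfg["classification"]
    seed = derive_seed(master, "training")
    polys = synthetic.training_polygons_from_truth(truth, n_per_class=cl["n_polygons_per_class"], seed=seed)
    cseed = derive_seed(master, "classify")
    lc_map = landcover.classify_landcover(
        stack, polys, n_per_class=cl["n_per_class"], n_trees=cl["n_trees"], seed=cseed
    )
    rseed = derive_seed(master, "reference")
    ref = synthetic.reference_points_from_truth(truth, n_per_class=cl["n_reference_per_class"], seed=rseed)
    ref = ref[lc_map.mask[truth.grid.rowcol(ref["x"].to_numpy(), ref["y"].to_numpy())]]
    acc = landcover.confusion_matrix(lc_map, ref)
    record("classify", cseed, map=_hash_array(lc_map.values), overall_accuracy=acc["overall_accuracy"])

    # -- focal proportions -------------------------------------------------
    props = landcover.proportion_layers(lc_map, kernels_m=cfg["kernels_m"])
    true_props = landcover.proportion_layers(truth.landcover_raster(), kernels_m=cfg["kernels_m"])
    record("proportions", None, layers=_hash_array(*[p.values for p in props.values()]))

    feature_layers = dict(metric_layers)
    feature_layers.update(props)
    feature_layers["elevation"] = truth.dem_raster()
    feature_layers["slope"] = slope
    feature_layers["aspect"] = aspect

    # ground-truth abundance uses the *true* proportions; the model only
    # ever sees the classified-map versions
    truth_layers = dict(metric_layers)
    truth_layers.update(true_props)
    truth_layers["elevation"] = truth.dem_raster()
    truth_layers["slope"] = slope
    truth_layers["aspect"] = aspect

    # -- per-species survey + SDM -----------------------------------------
    results: dict[str, sdm.SDMResult] = {}
    truths: dict[str, Raster] = {}
    autocorr_reports: dict[str, dict] = {}
    for sp_cfg in cfg["species"]:
        spec = _species_spec(sp_cfg)
        abundance = synthetic.generate_species_truth(truth, truth_layers, spec)
        truths[spec.name] = abundance
        sseed = derive_seed(master, f"survey:{spec.name}")
        if sp_cfg["survey"] == "trapline":
            table = synthetic.generate_trapline_survey(abundance, truth, sp_cfg["n_units"], spec, seed=sseed)
            fit = survey.fit_capture_model(table, spec.name)
            obs = survey.abundance_indices(fit)
        else:
            table = synthetic.generate_transect_survey(abundance, truth, sp_cfg["n_units"], spec, seed=sseed)
            obs = survey.transect_scores(table)
        record(f"survey:{spec.name}", sseed, table=_hash_df(table), indices=_hash_df(obs))

        from .autocorr import morans_i

        ac_cfg = cfg["autocorr"]
        try:
            autocorr_reports[spec.name] = morans_i(
                obs["value"].to_numpy(), obs[["x", "y"]].to_numpy(),
                radius=ac_cfg["radius_m"], n_permutations=ac_cfg["n_permutations"],
                seed=derive_seed(master, f"autocorr:{spec.name}"),
            )
        except ValueError as exc:  # constant index or no neighbour pairs
            autocorr_reports[spec.name] = {"error": str(exc)}

        feat = sdm.build_feature_table(feature_layers, obs)
        bseed = derive_seed(master, f"boruta:{spec.name}")
        b_cfg = cfg["boruta"]
        from .boruta import boruta_select

        bres = boruta_select(
            feat.drop(columns=["unit_id", "x", "y", "value"]),
            feat["value"].to_numpy(),
            alpha=b_cfg["alpha"], max_iter=b_cfg["max_iter"], n_trees=b_cfg["n_trees"], seed=bseed,
        )
        selected = bres.selected()
        if not selected:  # degenerate: keep best-ranked tentative features
            selected = bres.tentative or list(feat.columns[4:])
        record(f"boruta:{spec.name}", bseed, selected=sorted(selected), iterations=bres.iterations)

        tseed = derive_seed(master, f"tune:{spec.name}")
        grid_cfg = cfg["sdm"]["grid"]
        hp_grid = [
            sdm.HyperParams(
                n_trees=c["n_trees"], min_leaf_population=c["min_leaf_population"],
                max_nodes=c["max_nodes"],
            )
            for c in grid_cfg
        ]
        best, tuning = sdm.tune_hyperparameters(feat, grid=hp_grid, seed=tseed, covariates=selected)
        cv = sdm.loocv(feat, best, seed=tseed, covariates=selected)
        fseed = derive_seed(master, f"fit:{spec.name}")
        model, pred, train_pred = sdm.fit_and_predict(feat, best, feature_layers, seed=fseed, covariates=selected)
        opt, thr = sdm.optimal_habitat(pred, train_pred)
        area = sdm.area_stats(opt)
        results[spec.name] = sdm.SDMResult(
            species=spec.name,
            source=sp_cfg["survey"],
            selected_covariates=selected,
            params=best,
            loocv_r2=cv["r2"],
            loocv_r2_pearson=cv["r2_pearson"],
            loocv_observed=cv["observed"],
            loocv_predicted=cv["predicted"],
            prediction=pred,
            threshold=thr,
            optimal_map=opt,
            area=area,
            tuning_table=tuning,
            boruta=bres,
        )
        record(f"sdm:{spec.name}", tseed, r2=round(cv["r2"], 6), threshold=round(thr, 6),
               prediction=_hash_array(pred.masked()), optimal=_hash_array(opt.values),
               optimal_pct=round(area["optimal_pct"], 6))

    report = pd.DataFrame([r.report_row() for r in results.values()])
    manifest["report"] = report.to_dict(orient="records")
    return {
        "results": results,
        "manifest": manifest,
        "truth": truth,
        "abundance_truth": truths,
        "landcover": lc_map,
        "accuracy": acc,
        "autocorrelation": autocorr_reports,
        "report": report,
    }
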