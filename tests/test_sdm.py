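"""Feature extraction, LOOCV, tuning, prediction and thresholding."""

import numpy as np
import pandas as pd
import pytest

from eosdm.grid import GridSpec, Raster
from eosdm.sdm import (
    HyperParams,
    area_stats,
    build_feature_table,
    fit_and_predict,
    loocv,
    optimal_habitat,
    tune_hyperparameters,
)


@pytest.fixture()
def layers():
    grid = GridSpec(12, 12, 30.0)
    rng = np.random.default_rng(0)
    return {
        "a": Raster(rng.normal(size=grid.shape), grid),
        "b": Raster(np.full(grid.shape, 3.5), grid),
    }


def obs_frame(grid, n=10, seed=1):
    rng = np.random.default_rng(seed)
    r = rng.integers(0, grid.rows, n)
    c = rng.integers(0, grid.cols, n)
    x, y = grid.xy(r, c)
    return pd.DataFrame(
        {"unit_id": [f"U{i}" for i in range(n)], "x": x, "y": y, "value": rng.normal(size=n)}
    ), r, c


class TestFeatureTable:
    def test_pixel_centre_exact_lookup(self, layers):
        grid = layers["a"].grid
        obs, r, c = obs_frame(grid)
        table = build_feature_table(layers, obs)
        np.testing.assert_allclose(table["a"], layers["a"].values[r, c])
        assert (table["b"] == 3.5).all()

    def test_masked_units_dropped(self, layers):
        grid = layers["a"].grid
        obs, r, c = obs_frame(grid)
        mask = np.ones(grid.shape, bool)
        mask[r[0], c[0]] = False
        layers = dict(layers)
        layers["a"] = Raster(layers["a"].values, grid, mask=mask)
        table = build_feature_table(layers, obs)
        assert "U0" not in set(table["unit_id"])

    def test_offgrid_rejected(self, layers):
        obs = pd.DataFrame({"unit_id": ["U0"], "x": [1e9], "y": [0.0], "value": [1.0]})
        with pytest.raises(ValueError):
            build_feature_table(layers, obs)


def linear_table(n=30, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = 2 * x1 + rng.normal(0, noise, n)
    return pd.DataFrame({"unit_id": range(n), "x": 0.0, "y": 0.0, "value": y, "x1": x1, "x2": x2})


class TestLoocv:
    def test_strong_signal_r2_high(self):
        cv = loocv(linear_table(), HyperParams(n_trees=100), seed=0)
        assert cv["r2"] > 0.6
        assert 0 <= cv["r2_pearson"] <= 1

    def test_constant_response_rejected(self):
        t = linear_table()
        t["value"] = 1.0
        with pytest.raises(ValueError):
            loocv(t, HyperParams(n_trees=10))

    def test_fold_never_sees_held_out_response(self):
        """Permuting one row's response does not change that fold's prediction."""
        t = linear_table(n=15)
        cv1 = loocv(t, HyperParams(n_trees=50), seed=3)
        t2 = t.copy()
        t2.loc[4, "value"] += 100.0
        cv2 = loocv(t2, HyperParams(n_trees=50), seed=3)
        assert cv2["predicted"][4] == pytest.approx(cv1["predicted"][4])

    def test_r2_definition_null_and_perfect(self):
        """R^2 = 1 - SSE/SST: 0 for the mean predictor, 1 for a perfect one."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        sst = np.sum((y - y.mean()) ** 2)
        assert 1 - np.sum((y - y.mean()) ** 2) / sst == pytest.approx(0.0)
        assert 1 - 0.0 / sst == pytest.approx(1.0)


class TestTuning:
    def test_single_cell_grid_returned(self):
        hp = HyperParams(n_trees=20)
        best, tab = tune_hyperparameters(linear_table(), grid=[hp], seed=0)
        assert best == hp and len(tab) == 1

    def test_tie_breaks_toward_fewer_trees(self, monkeypatch):
        import eosdm.sdm as sdm_mod

        monkeypatch.setattr(sdm_mod, "loocv", lambda *a, **k: {"r2": 0.5, "r2_pearson": 0.5})
        grid = [HyperParams(n_trees=200), HyperParams(n_trees=100, min_leaf_population=2),
                HyperParams(n_trees=100, min_leaf_population=1)]
        best, _ = tune_hyperparameters(linear_table(), grid=grid, seed=0)
        assert best.n_trees == 100 and best.min_leaf_population == 1

    def test_argmax_property(self):
        grid = [HyperParams(n_trees=50), HyperParams(n_trees=50, min_leaf_population=10)]
        best, tab = tune_hyperparameters(linear_table(noise=0.5), grid=grid, seed=1)
        assert tab["r2"].max() == tab.loc[
            (tab["n_trees"] == best.n_trees)
            & (tab["min_leaf_population"] == best.min_leaf_population), "r2"
        ].iloc[0]


class TestPredictionAndThreshold:
    def test_constant_covariates_predict_mean(self):
        grid = GridSpec(6, 6, 30.0)
        layers = {"c": Raster(np.full(grid.shape, 2.0), grid)}
        t = pd.DataFrame(
            {"unit_id": range(6), "x": 15.0, "y": -15.0, "value": [1.0, 2, 3, 4, 5, 6], "c": 2.0}
        )
        _, pred, train_pred = fit_and_predict(t, HyperParams(n_trees=50, bag_fraction=1.0), layers, seed=0)
        assert np.allclose(pred.values, np.mean([1, 2, 3, 4, 5, 6]), atol=0.7)

    def test_predictions_bounded_by_response_range(self):
        t = linear_table(n=25)
        grid = GridSpec(8, 8, 30.0)
        rng = np.random.default_rng(2)
        layers = {
            "x1": Raster(rng.normal(0, 3, grid.shape), grid),
            "x2": Raster(rng.normal(0, 3, grid.shape), grid),
        }
        _, pred, _ = fit_and_predict(t, HyperParams(n_trees=60), layers, seed=0)
        assert pred.values.min() >= t["value"].min() - 1e-9
        assert pred.values.max() <= t["value"].max() + 1e-9

    def test_threshold_is_training_mean_with_strict_inequality(self):
        grid = GridSpec(4, 4, 30.0)
        pred = Raster(np.full(grid.shape, 2.0), grid)
        binary, thr = optimal_habitat(pred, [1.0, 2.0, 3.0])
        assert thr == pytest.approx(2.0)
        assert binary.values.sum() == 0  # equality is not optimal
        above = Raster(np.full(grid.shape, 2.1), grid)
        binary2, _ = optimal_habitat(above, [1.0, 2.0, 3.0])
        assert binary2.values.sum() == 16

    def test_empty_training_predictions_rejected(self):
        grid = GridSpec(2, 2, 30.0)
        with pytest.raises(ValueError):
            optimal_habitat(Raster(np.zeros(grid.shape), grid), [])


class TestAreaStats:
    def test_worked_example(self):
        """100x100 pixels at 30 m, half optimal -> 4.5 km^2 and 50%."""
        grid = GridSpec(100, 100, 30.0)
        vals = np.zeros(grid.shape, dtype=np.uint8)
        vals[:50] = 1
        out = area_stats(Raster(vals, grid))
        assert out["optimal_km2"] == pytest.approx(4.5)
        assert out["optimal_pct"] == pytest.approx(50.0)

    def test_empty_and_masked_denominator(self):
        grid = GridSpec(10, 10, 30.0)
        vals = np.zeros(grid.shape, dtype=np.uint8)
        out = area_stats(Raster(vals, grid))
        assert out["optimal_km2"] == 0 and out["optimal_pct"] == 0
        # masked pixels leave the denominator
        vals[0, :5] = 1
        mask = np.ones(grid.shape, bool)
        half = Raster(vals, grid, mask=mask)
        base = area_stats(half)["optimal_pct"]
        mask2 = mask.copy()
        mask2[9, :] = False  # mask non-optimal pixels
        masked = Raster(vals, grid, mask=mask2)
        assert area_stats(masked)["optimal_pct"] > base
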