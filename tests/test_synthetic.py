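"""Ground-truth generators: determinism, stated distributions, invariants."""

import numpy as np
import pytest
from scipy import stats

from eosdm import synthetic
from eosdm.grid import Raster
from eosdm.synthetic import (
    DEFAULT_PHENOLOGY,
    PhenologyParams,
    SpeciesEffectSpec,
    generate_landscape,
    generate_scene_collection,
    generate_species_truth,
    generate_trapline_survey,
    generate_transect_survey,
)


class TestLandscape:
    def test_degenerate_fraction_all_grassland(self):
        t = generate_landscape(20, 20, fractions={"grassland": 1.0}, seed=0)
        assert np.all(t.landcover == 1)

    def test_determinism(self):
        a = generate_landscape(40, 40, seed=5)
        b = generate_landscape(40, 40, seed=5)
        np.testing.assert_array_equal(a.landcover, b.landcover)
        np.testing.assert_array_equal(a.dem, b.dem)

    def test_realized_fractions_close_to_request(self):
        t = generate_landscape(200, 200, seed=7)
        for name, want in synthetic.DEFAULT_FRACTIONS.items():
            got = t.class_fractions()[name]
            assert abs(got - want) <= 0.05, name

    def test_snow_only_above_elevation_rule(self):
        t = generate_landscape(100, 100, seed=3)
        snow = t.landcover == 8
        if snow.any():
            assert t.dem[snow].min() >= 3350.0

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_landscape(0, 10)
        with pytest.raises(ValueError):
            generate_landscape(10, 10, fractions={"grassland": 0.5, "bare": 0.2})
        with pytest.raises(ValueError):
            generate_landscape(10, 10, fractions={"grassland": 1.5, "bare": -0.5})


class TestScenes:
    def test_no_clouds_all_valid(self, truth):
        scenes = generate_scene_collection(truth, [180], cloud_fraction=0.0, seed=0)
        assert scenes[0].mask.all()

    def test_water_nir_identity_noise_free(self):
        """Noise-free water with NDVI -0.3: NIR = red * 0.7 / 1.3 exactly."""
        params = {k: PhenologyParams(
            p.base_ndvi, p.amp_ndvi, p.peak_doy, p.width_doy, p.red_reflectance, p.swir_factor, 0.0
        ) for k, p in DEFAULT_PHENOLOGY.items()}
        t = generate_landscape(10, 10, fractions={"water": 1.0}, seed=0, class_params=params)
        s = generate_scene_collection(t, [180], cloud_fraction=0.0, seed=0)[0]
        red = params[7].red_reflectance
        assert np.allclose(s.bands["nir"], red * 0.7 / 1.3, atol=1e-12)

    def test_cloud_fraction_realized(self, truth):
        scenes = generate_scene_collection(truth, list(range(30, 331, 30)), cloud_fraction=0.3, seed=9)
        masked = np.mean([1.0 - s.mask.mean() for s in scenes])
        assert abs(masked - 0.3) <= 0.05

    def test_determinism(self, truth):
        a = generate_scene_collection(truth, [100, 200], cloud_fraction=0.2, seed=4)
        b = generate_scene_collection(truth, [100, 200], cloud_fraction=0.2, seed=4)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.mask, s2.mask)
            for k in s1.bands:
                np.testing.assert_array_equal(s1.bands[k], s2.bands[k])

    def test_class_separability_at_peak(self, truth):
        """Grassland vs bare mean NDVI at peak differs by >= 0.3."""
        s = generate_scene_collection(truth, [200], cloud_fraction=0.0, seed=1)[0]
        ndvi = (s.bands["nir"] - s.bands["red"]) / (s.bands["nir"] + s.bands["red"])
        grass = ndvi[truth.landcover == 1].mean()
        bare = ndvi[truth.landcover == 6].mean()
        assert grass - bare >= 0.3

    def test_invalid_phenology_rejected(self):
        with pytest.raises(ValueError):
            PhenologyParams(0.6, 0.5, 200, 60, 0.1, 1.0)


class TestSpeciesTruth:
    def test_null_model_constant(self, truth):
        spec = SpeciesEffectSpec("sp", terms=(("elevation", 0.0),), baseline=-1.0)
        A = generate_species_truth(truth, {"elevation": truth.dem_raster()}, spec)
        assert np.allclose(A.values, np.exp(-1.0))

    def test_monotone_in_single_term(self, truth):
        rng = np.random.default_rng(0)
        cov = Raster(rng.normal(size=truth.grid.shape), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=(("c", 2.0),))
        A = generate_species_truth(truth, {"c": cov}, spec)
        flat_c = cov.values.ravel()
        flat_a = A.values.ravel()
        order = np.argsort(flat_c)
        assert np.all(np.diff(flat_a[order]) >= 0)

    def test_matches_direct_formula(self, truth):
        rng = np.random.default_rng(1)
        c1 = rng.normal(size=truth.grid.shape)
        c2 = rng.normal(size=truth.grid.shape)
        spec = SpeciesEffectSpec("sp", terms=(("a", 0.8), ("b", -0.5)), baseline=-1.2)
        A = generate_species_truth(
            truth, {"a": Raster(c1, truth.grid), "b": Raster(c2, truth.grid)}, spec
        )
        land = np.isin(truth.landcover, synthetic.LAND_CLASSES)
        z1 = (c1 - c1[land].mean()) / c1[land].std()
        z2 = (c2 - c2[land].mean()) / c2[land].std()
        np.testing.assert_allclose(A.values, np.exp(-1.2 + 0.8 * z1 - 0.5 * z2), atol=1e-12)

    def test_unknown_covariate_rejected(self, truth):
        spec = SpeciesEffectSpec("sp", terms=(("missing", 1.0),))
        with pytest.raises(KeyError):
            generate_species_truth(truth, {"elevation": truth.dem_raster()}, spec)


class TestTraplineSurvey:
    def test_zero_intensity_all_zero(self, truth):
        A = Raster(np.zeros(truth.grid.shape), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=())
        table = generate_trapline_survey(A, truth, 10, spec, seed=0)
        assert (table["captures"] == 0).all()

    def test_determinism(self, truth):
        A = Raster(np.full(truth.grid.shape, 0.2), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=())
        a = generate_trapline_survey(A, truth, 20, spec, seed=6)
        b = generate_trapline_survey(A, truth, 20, spec, seed=6)
        assert a.equals(b)

    def test_poisson_mean_recovered(self, truth):
        """sigma_u=0, betas=0, constant A: captures/trap-night -> A."""
        a0 = 0.12
        A = Raster(np.full(truth.grid.shape, a0), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=(), trap_type_effect=0.0, night_effect=0.0, trapline_sd=0.0)
        tables = [generate_trapline_survey(A, truth, 60, spec, seed=s) for s in range(20)]
        total = sum(t["captures"].sum() for t in tables)
        nights = sum(len(t) * 25 for t in tables)
        # ~10^4 trap-nights: Poisson MC error ~ 2 sd
        se = np.sqrt(a0 / nights)
        assert total / nights == pytest.approx(a0, abs=4 * se)

    def test_poisson_marginal_gof(self, truth):
        """Chi-square goodness of fit of trap-night counts to Poisson(25*A)."""
        a0 = 0.12
        A = Raster(np.full(truth.grid.shape, a0), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=(), trap_type_effect=0.0, night_effect=0.0, trapline_sd=0.0)
        counts = np.concatenate(
            [generate_trapline_survey(A, truth, 60, spec, seed=s)["captures"].to_numpy() for s in range(56)]
        )  # ~10^4 trap-night draws of Poisson(3)
        mu = 25 * a0
        kmax = 10
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax), mu)
        probs = np.append(probs, 1 - probs.sum())
        chi2 = stats.chisquare(obs, probs * obs.sum())
        assert chi2.pvalue > 0.01

    def test_schema_and_invariants(self, truth):
        A = Raster(np.full(truth.grid.shape, 0.3), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=())
        t = generate_trapline_survey(A, truth, 15, spec, seed=2)
        assert set(t["night"]) == {1, 2, 3}
        assert (t["captures"] <= t["accessible"]).all()
        assert (t["accessible"] <= 25).all()
        assert set(t["trap_type"]) <= {"sbbt", "bbbt"}


class TestTransectSurvey:
    def test_score_bounds_and_zero_probability_limit(self, truth):
        A = Raster(np.full(truth.grid.shape, 0.5), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=(), transect_intercept=-30.0, transect_slope=0.0)
        t = generate_transect_survey(A, truth, 10, spec, seed=0)
        assert (t["presence"] == 0).all()

    def test_binomial_mean_at_half(self, truth):
        """b=0, a=0: interval presence is Bernoulli(0.5), mean score -> 10."""
        A = Raster(np.full(truth.grid.shape, 0.5), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=(), transect_intercept=0.0, transect_slope=0.0)
        t = generate_transect_survey(A, truth, 100, spec, seed=1)
        scores = t.groupby("transect_id")["presence"].sum()
        assert scores.between(0, 20).all()
        assert scores.mean() == pytest.approx(10.0, abs=0.5)

    def test_binomial_marginal_gof(self, truth):
        A = Raster(np.full(truth.grid.shape, 0.5), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=(), transect_intercept=0.0, transect_slope=0.0)
        t = generate_transect_survey(A, truth, 500, spec, seed=3)
        scores = t.groupby("transect_id")["presence"].sum().to_numpy()
        lo, hi = 5, 15  # pool tails
        obs = np.bincount(np.clip(scores, lo, hi) - lo, minlength=hi - lo + 1)
        pk = stats.binom.pmf(np.arange(21), 20, 0.5)
        probs = np.array([pk[:lo + 1].sum()] + list(pk[lo + 1 : hi]) + [pk[hi:].sum()])
        chi2 = stats.chisquare(obs, probs * obs.sum())
        assert chi2.pvalue > 0.01

    def test_interval_spacing_eight_metres(self, truth):
        A = Raster(np.full(truth.grid.shape, 0.5), truth.grid)
        spec = SpeciesEffectSpec("sp", terms=())
        t = generate_transect_survey(A, truth, 3, spec, seed=5)
        one = t[t["transect_id"] == "T000"].sort_values("interval")
        d = np.hypot(one["x"].diff().dropna(), one["y"].diff().dropna())
        assert np.allclose(d, 8.0)
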