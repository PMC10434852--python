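"""Abundance indices, the capture GLMM and spatial autocorrelation checks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from eosdm.autocorr import empirical_semivariogram, morans_i
from eosdm.glmm import fit_poisson_glmm
from eosdm.survey import abundance_indices, fit_capture_model, transect_scores


def make_transect(tid, presences, species="vole"):
    return pd.DataFrame(
        {
            "transect_id": tid,
            "interval": np.arange(1, 21),
            "x": 100.0 + 8 * np.arange(20),
            "y": 50.0,
            "presence": presences,
            "species": species,
        }
    )


def make_trapline_table(rng, n_lines=40, rate=0.1, btype=0.0, bnight=0.0, sigma=0.0, accessible=25):
    rows = []
    u = rng.normal(0, sigma, n_lines)
    for l in range(n_lines):
        ttype = "bbbt" if l % 2 else "sbbt"
        for night in (1, 2, 3):
            lam = accessible * rate * np.exp(btype * (ttype == "bbbt") + bnight * (night - 1) + u[l])
            rows.append(
                {
                    "line_id": f"L{l:02d}",
                    "x": float(l * 200.0),
                    "y": float((l % 7) * 300.0),
                    "habitat": "grassland",
                    "trap_type": ttype,
                    "night": night,
                    "captures": int(min(rng.poisson(lam), accessible)),
                    "accessible": accessible,
                    "species": "vole",
                }
            )
    return pd.DataFrame(rows)


class TestTransectScores:
    def test_bounds_and_counts(self):
        all_pos = transect_scores(make_transect("T1", np.ones(20, dtype=int)))
        assert all_pos["value"].iloc[0] == 20
        alternating = transect_scores(make_transect("T2", np.tile([1, 0], 10)))
        assert alternating["value"].iloc[0] == 10
        never = transect_scores(make_transect("T3", np.zeros(20, dtype=int)))
        assert never["value"].iloc[0] == 0

    def test_location_is_interval_mean(self):
        out = transect_scores(make_transect("T1", np.ones(20, dtype=int)))
        assert out["x"].iloc[0] == pytest.approx(100.0 + 8 * 9.5)

    def test_partial_transect_rejected_unless_allowed(self):
        partial = make_transect("T1", np.ones(20, dtype=int)).iloc[:15]
        with pytest.raises(ValueError):
            transect_scores(partial)
        out = transect_scores(partial, allow_partial=True)
        assert out["value"].iloc[0] == pytest.approx(20.0)  # 15/15 pro-rated


class TestCaptureModel:
    def test_offset_identity(self):
        """Doubling accessible traps with a fixed rate doubles expected captures."""
        rng = np.random.default_rng(1)
        t25 = make_trapline_table(rng, n_lines=300, rate=0.08, accessible=25)
        t50 = make_trapline_table(np.random.default_rng(1), n_lines=300, rate=0.08, accessible=50)
        f25 = fit_capture_model(t25, "vole")
        f50 = fit_capture_model(t50, "vole")
        # same per-trap rate recovered despite doubled effort
        assert f25.model.params[0] == pytest.approx(f50.model.params[0], abs=0.1)
        assert t50["captures"].mean() / t25["captures"].mean() == pytest.approx(2.0, rel=0.15)

    def test_matches_glm_without_random_effect(self):
        """With sigma_u = 0 truth the marginal fit agrees with a Poisson GLM."""
        rng = np.random.default_rng(7)
        table = make_trapline_table(rng, n_lines=60, rate=0.15, btype=0.6, bnight=-0.3)
        fit = fit_capture_model(table, "vole")
        ttype = (table["trap_type"] == "bbbt").astype(float)
        X = np.column_stack([np.ones(len(table)), ttype, table["night"] - 1])
        glm = sm.GLM(
            table["captures"], X, family=sm.families.Poisson(),
            offset=np.log(table["accessible"]),
        ).fit()
        assert np.allclose(fit.model.params, glm.params, atol=0.02)

    def test_all_zero_species_falls_back(self):
        rng = np.random.default_rng(3)
        table = make_trapline_table(rng, n_lines=5, rate=0.0)
        fit = fit_capture_model(table, "vole")
        assert fit.fallback and not fit.significant
        idx = abundance_indices(fit)
        assert np.all(idx["value"] == 0.0)
        assert idx.attrs["method"] == "captures_per_100_trap_nights"

    def test_non_integer_counts_rejected(self):
        rng = np.random.default_rng(3)
        table = make_trapline_table(rng, n_lines=5, rate=0.1)
        table["captures"] = table["captures"].astype(float)
        table.loc[0, "captures"] = 1.5
        with pytest.raises(ValueError):
            fit_capture_model(table, "vole")


class TestAbundanceIndex:
    def test_fallback_arithmetic(self):
        """6 captures over 75 trap-nights -> 8.0 per 100 trap-nights."""
        rng = np.random.default_rng(11)
        table = make_trapline_table(rng, n_lines=10, rate=0.0)
        table.loc[table["line_id"] == "L00", "captures"] = 2  # 3 nights x 2 = 6
        fit = fit_capture_model(table, "vole")
        fit.significant = False  # force fallback path
        fit.fallback = fit.model is None
        idx = abundance_indices(fit)
        assert idx.loc[idx["unit_id"] == "L00", "value"].iloc[0] == pytest.approx(8.0)

    def test_residual_path_mean_zero_overall(self):
        rng = np.random.default_rng(5)
        table = make_trapline_table(rng, n_lines=60, rate=0.15, btype=0.8)
        fit = fit_capture_model(table, "vole")
        assert fit.significant  # strong trap-type effect
        idx = abundance_indices(fit)
        assert idx.attrs["method"] == "glmm_response_residual"
        # response residuals average out near zero across traplines
        assert abs(idx["value"].mean()) < 1.0

    def test_index_tracks_latent_abundance(self):
        """Spearman correlation between index and latent line rate >= 0.7."""
        from scipy import stats

        rng = np.random.default_rng(17)
        n_lines = 60
        rates = rng.uniform(0.02, 0.5, n_lines)
        rows = []
        for l, r in enumerate(rates):
            ttype = "bbbt" if l % 2 else "sbbt"
            for night in (1, 2, 3):
                lam = 25 * r * np.exp(0.5 * (ttype == "bbbt") - 0.2 * (night - 1))
                rows.append(
                    {
                        "line_id": f"L{l:02d}", "x": l * 100.0, "y": 0.0,
                        "habitat": "grassland", "trap_type": ttype, "night": night,
                        "captures": int(min(rng.poisson(lam), 25)), "accessible": 25,
                        "species": "vole",
                    }
                )
        fit = fit_capture_model(pd.DataFrame(rows), "vole")
        idx = abundance_indices(fit)
        order = [f"L{l:02d}" for l in range(n_lines)]
        vals = idx.set_index("unit_id").loc[order, "value"].to_numpy()
        assert stats.spearmanr(vals, rates)[0] >= 0.7


class TestMoransI:
    def test_matches_naive_oracle(self):
        """Vectorized Moran's I equals a naive O(n^2) double loop to 1e-12."""
        rng = np.random.default_rng(2)
        n = 40
        coords = rng.uniform(0, 1000, (n, 2))
        vals = rng.normal(size=n)
        radius = 300.0
        out = morans_i(vals, coords, radius, n_permutations=9, seed=0)
        xbar = vals.mean()
        num = den = W = 0.0
        for i in range(n):
            den += (vals[i] - xbar) ** 2
            for j in range(n):
                if i == j:
                    continue
                d = np.hypot(*(coords[i] - coords[j]))
                if d <= radius:
                    W += 1
                    num += (vals[i] - xbar) * (vals[j] - xbar)
        assert out["I"] == pytest.approx(n / W * num / den, abs=1e-12)
        assert out["expected"] == pytest.approx(-1 / (n - 1))

    def test_gradient_detected(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 1000, (50, 2))
        vals = coords[:, 0].copy()
        out = morans_i(vals, coords, 300.0, n_permutations=999, seed=1)
        assert out["I"] > 0
        assert out["p"] <= 0.001

    def test_constant_values_rejected(self):
        coords = np.random.default_rng(0).uniform(0, 100, (10, 2))
        with pytest.raises(ValueError):
            morans_i(np.ones(10), coords, 50.0)


class TestSemivariogram:
    def test_two_point_hand_example(self):
        """Values 1 and 3 -> single-pair bin gamma = 0.5 * 4 = 2."""
        out = empirical_semivariogram([1.0, 3.0], [[0.0, 0.0], [10.0, 0.0]], bin_width=20.0)
        assert out["semivariance"][0] == pytest.approx(2.0)
        assert out["pair_counts"][0] == 1

    def test_constant_values_zero_everywhere(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 500, (20, 2))
        out = empirical_semivariogram(np.full(20, 3.3), coords, bin_width=100.0)
        valid = out["pair_counts"] > 0
        assert np.allclose(out["semivariance"][valid], 0.0)

    def test_pair_counts_conserved(self):
        rng = np.random.default_rng(1)
        n = 25
        coords = rng.uniform(0, 500, (n, 2))
        out = empirical_semivariogram(rng.normal(size=n), coords, bin_width=50.0)
        assert out["pair_counts"].sum() == n * (n - 1) // 2
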