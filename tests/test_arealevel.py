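import numpy as np
import pandas as pd
import pytest

from lifegap.arealevel import (
    AreaTableError,
    assemble_area_table,
    distance_matrix,
    fit_spatial_gls,
    simulate_area_model,
    stepwise_select,
    years_lost,
)


def area_skeleton(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "area_id": [f"A{i:02d}" for i in range(n)],
            "sled_se": rng.uniform(0.05, 0.2, n),
            "exposure": rng.uniform(12, 38, n),
            "x_km": rng.uniform(0, 300, n),
            "y_km": rng.uniform(0, 300, n),
        }
    )


class TestAssemble:
    def _inputs(self):
        est = pd.DataFrame({"area_id": ["A", "B"], "sled": [0.5, -0.2], "sled_se": [0.1, 0.2]})
        exp = pd.DataFrame({"area_id": ["A", "B"], "exposure": [20.0, 30.0]})
        cov = pd.DataFrame({"area_id": ["A", "B"], "college_pct": [3.0, 1.5]})
        coo = pd.DataFrame({"area_id": ["A", "B"], "x_km": [0.0, 10.0], "y_km": [0.0, 0.0]})
        return est, exp, cov, coo

    def test_hand_join_row_for_row(self):
        table = assemble_area_table(*self._inputs())
        assert list(table["area_id"]) == ["A", "B"]
        assert table.loc[1, "exposure"] == 30.0
        assert table.loc[0, "college_pct"] == 3.0

    def test_duplicate_area_raises(self):
        est, exp, cov, coo = self._inputs()
        est = pd.concat([est, est.iloc[[0]]], ignore_index=True)
        with pytest.raises(AreaTableError, match="duplicate"):
            assemble_area_table(est, exp, cov, coo)

    def test_missing_area_raises_with_ids(self):
        est, exp, cov, coo = self._inputs()
        with pytest.raises(AreaTableError, match="B"):
            assemble_area_table(est, exp.iloc[[0]], cov, coo)

    def test_nonpositive_se_rejected(self):
        est, exp, cov, coo = self._inputs()
        est.loc[0, "sled_se"] = 0.0
        with pytest.raises(AreaTableError):
            assemble_area_table(est, exp, cov, coo)


class TestStepwise:
    def test_strong_candidate_nearly_always_selected(self):
        base = area_skeleton(63, seed=3)
        hits = 0
        for r in range(20):
            rng = np.random.default_rng(200 + r)
            tab = base.copy()
            tab["cov1"] = rng.normal(0, 1, 63)
            sim = simulate_area_model(
                tab, {"const": 0.5, "exposure": -0.034, "cov1": 1.0}, 50.0, 1.0, rng
            )
            hits += "cov1" in stepwise_select(sim, ["cov1"])
        assert hits >= 19

    def test_noise_candidates_rarely_selected(self):
        base = area_skeleton(63, seed=3)
        counts = []
        for r in range(20):
            rng = np.random.default_rng(400 + r)
            tab = base.copy()
            noise = [f"n{j}" for j in range(8)]
            for c in noise:
                tab[c] = rng.normal(0, 1, 63)
            # independent errors: what the stepwise working model assumes
            sim = simulate_area_model(
                tab, {"const": 0.5, "exposure": -0.034}, 1e-6, 1.0, rng
            )
            counts.append(len(stepwise_select(sim, noise)))
        assert np.mean(counts) < 1.5

    def test_no_candidates_returns_empty(self):
        tab = area_skeleton(12, seed=1)
        tab["sled"] = 0.0
        assert stepwise_select(tab, []) == []

    def test_constant_candidate_dropped_with_warning(self):
        tab = area_skeleton(12, seed=1)
        tab["sled"] = np.random.default_rng(0).normal(0, 1, 12)
        tab["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            assert stepwise_select(tab, ["flat"]) == []

    def test_too_few_areas_rejected(self):
        tab = area_skeleton(5, seed=1)
        tab["sled"] = 0.0
        with pytest.raises(AreaTableError):
            stepwise_select(tab, [])


class TestSpatialGLS:
    def test_tiny_range_equals_weighted_least_squares(self):
        import statsmodels.api as sm

        tab = area_skeleton(40, seed=5)
        sim = simulate_area_model(
            tab, {"const": 1.0, "exposure": -0.034}, 50.0, 1.0, np.random.default_rng(5)
        )
        fit = fit_spatial_gls(sim, [], delta_bounds_km=(1e-6, 1.0001e-6))
        X = sm.add_constant(sim[["exposure"]].to_numpy())
        wls = sm.WLS(sim["sled"], X, weights=1.0 / sim["sled_se"] ** 2).fit()
        assert fit.params["exposure"] == pytest.approx(wls.params[1], abs=1e-6)
        assert fit.params["const"] == pytest.approx(wls.params[0], abs=1e-6)

    def test_three_area_fixture_matches_hand_linear_algebra(self):
        tab = pd.DataFrame(
            {
                "area_id": ["A", "B", "C"],
                "sled": [1.0, 0.2, -0.5],
                "sled_se": [0.1, 0.2, 0.15],
                "exposure": [15.0, 25.0, 35.0],
                "x_km": [0.0, 30.0, 0.0],
                "y_km": [0.0, 0.0, 40.0],
            }
        )
        delta = 50.0
        fit = fit_spatial_gls(tab, [], delta_bounds_km=(delta, delta * 1.0000001))
        # independent GLS: beta = (X' V^-1 X)^-1 X' V^-1 y with explicit V
        d = distance_matrix(tab)
        s = tab["sled_se"].to_numpy()
        V = np.exp(-d / delta) * np.outer(s, s)
        X = np.column_stack([np.ones(3), tab["exposure"]])
        y = tab["sled"].to_numpy()
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert fit.params["const"] == pytest.approx(beta[0], rel=1e-6)
        assert fit.params["exposure"] == pytest.approx(beta[1], rel=1e-6)

    def test_known_coefficients_recovered_across_replicates(self):
        tab = area_skeleton(63, seed=0)
        tab["cov1"] = np.random.default_rng(1).normal(0, 1, 63)
        est = []
        for r in range(20):
            rng = np.random.default_rng(100 + r)
            sim = simulate_area_model(
                tab, {"const": 1.0, "exposure": -0.034, "cov1": 0.5}, 50.0, 1.0, rng
            )
            est.append(fit_spatial_gls(sim, ["cov1"]).params["exposure"])
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - (-0.034)) < 2 * mc_se

    def test_interval_coverage_at_scaled_replication(self):
        tab = area_skeleton(30, seed=2)
        covered = 0
        for r in range(20):
            rng = np.random.default_rng(900 + r)
            sim = simulate_area_model(
                tab, {"const": 1.0, "exposure": -0.034}, 50.0, 1.0, rng
            )
            lo, hi = fit_spatial_gls(sim, []).conf_int("exposure")
            covered += lo <= -0.034 <= hi
        assert covered >= 17  # >= 85% of 20

    def test_confounder_biases_unadjusted_slope_and_adjustment_recovers(self):
        # spatially clustered confounder anti-correlated with exposure
        tab = area_skeleton(63, seed=8)
        rng = np.random.default_rng(8)
        tab["ses"] = (30.0 - tab["exposure"]) / 10.0 + rng.normal(0, 0.3, 63)
        sim = simulate_area_model(
            tab, {"const": 1.0, "exposure": -0.034, "ses": 0.4}, 50.0, 1.0, rng
        )
        naive = fit_spatial_gls(sim, []).params["exposure"]
        adjusted = fit_spatial_gls(sim, ["ses"]).params["exposure"]
        assert naive < adjusted  # omitting the confounder exaggerates harm
        assert adjusted == pytest.approx(-0.034, abs=0.01)
        assert naive < -0.05


class TestYearsLost:
    def test_worst_area_arithmetic(self):
        out = years_lost(-0.034, 28.6, reference_le=15.9)
        assert round(out["years_lost"], 2) == 0.97
        assert round(out["relative_loss_pct"], 1) == 6.1

    def test_zero_excess_gives_zero(self):
        assert years_lost(-0.034, 0.0)["years_lost"] == 0.0

    def test_negative_excess_rejected(self):
        with pytest.raises(ValueError):
            years_lost(-0.034, -1.0)
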