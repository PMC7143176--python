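import dataclasses

import numpy as np
import pytest
from scipy.special import expit, logit

from lifegap.curves import SurvivalCurve
from lifegap.extrapolation import (
    DegenerateCohortError,
    ExtrapolationConfig,
    RelativeSurvival,
    compose_survival,
    estimate_cohort,
    km_estimate,
    life_expectancy,
    rcs_basis,
    relative_survival,
    rolling_extrapolate,
    sled,
)
from lifegap.synthetic import simulate_cohort, true_mix_life_expectancy
from .conftest import build_cohort


class TestKaplanMeier:
    def test_uncensored_deaths_give_empirical_survival(self):
        coh = build_cohort([1, 2, 3, 4], [1, 1, 1, 1])
        km = km_estimate(coh)
        np.testing.assert_allclose(km.s, [1.0, 0.75, 0.5, 0.25, 0.0])

    def test_all_censored_gives_flat_curve(self):
        coh = build_cohort([12, 12, 12], [0, 0, 0])
        km = km_estimate(coh)
        np.testing.assert_allclose(km.s, 1.0)

    def test_mixed_censoring_matches_hand_product_limit(self, tiny_cohort):
        # deaths at 2 and 5, censored at 3 and 6: S = (1 - 1/4)(1 - 1/2) = 3/8
        km = km_estimate(tiny_cohort)
        assert km.s[2] == pytest.approx(0.75)
        assert km.s[5] == pytest.approx(0.375)

    def test_degenerate_cohort_raises(self):
        with pytest.raises(DegenerateCohortError):
            km_estimate(build_cohort([0, 0], [0, 0]))


class TestRelativeSurvival:
    def test_identical_curves_clamp_just_below_one(self):
        s = SurvivalCurve(np.linspace(1, 0.6, 20))
        rel = relative_survival(s, s, epsilon=1e-4)
        np.testing.assert_allclose(rel.w, 1 - 1e-4)
        assert np.ptp(rel.logit_w) == 0

    def test_logit_midpoint(self):
        s_obs = SurvivalCurve(np.array([1.0, 0.45]))
        sh = SurvivalCurve(np.array([1.0, 0.9]))
        rel = relative_survival(s_obs, sh)
        assert rel.w[1] == pytest.approx(0.5)
        assert rel.logit_w[1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_reference_within_range_raises(self):
        s_obs = SurvivalCurve(np.array([1.0, 0.5, 0.2]))
        sh = SurvivalCurve(np.array([1.0, 0.5, 0.0]))
        with pytest.raises(ZeroDivisionError):
            relative_survival(s_obs, sh)

    def test_constant_excess_hazard_slope_recovered(self):
        # S = Sh * exp(-dh t): in the deep tail (w << 1) logit w -> log w,
        # so a least-squares line there recovers the excess hazard dh
        dh = 0.02
        t = np.arange(301)
        sh = SurvivalCurve(np.exp(-0.001 * t))
        s_obs = SurvivalCurve(np.exp(-(0.001 + dh) * t))
        rel = relative_survival(s_obs, sh)
        tail = rel.w < 0.05
        slope = np.polyfit(t[tail], rel.logit_w[tail], 1)[0]
        assert slope == pytest.approx(-dh, rel=0.05)


class TestSplineBasis:
    def test_linear_tails_beyond_boundary_knots(self):
        knots = np.array([10.0, 50.0, 90.0])
        x = np.array([95.0, 100.0, 105.0])
        B = rcs_basis(x, knots)
        # second differences of every column vanish beyond the last knot
        assert np.allclose(B[2] - 2 * B[1] + B[0], 0.0, atol=1e-9)

    def test_reproduces_line_exactly(self):
        x = np.arange(100, dtype=float)
        y = 3.0 - 0.02 * x
        knots = np.quantile(x, [0.1, 0.5, 0.9])
        B = rcs_basis(x, knots)
        beta, *_ = np.linalg.lstsq(B, y, rcond=None)
        pred = rcs_basis(np.array([150.0]), knots) @ beta
        assert pred[0] == pytest.approx(3.0 - 0.02 * 150.0, abs=1e-8)


class TestRollingExtrapolation:
    def test_linear_input_continues_on_the_line(self):
        t = np.arange(120.0)
        lw = 2.0 - 0.01 * t
        rel = RelativeSurvival(t, expit(lw), lw)
        full = rolling_extrapolate(rel, ExtrapolationConfig(), 360)
        np.testing.assert_allclose(full, 2.0 - 0.01 * np.arange(361.0), atol=1e-6)

    def test_constant_input_continues_constant(self):
        t = np.arange(60.0)
        lw = np.full(60, 1.5)
        rel = RelativeSurvival(t, expit(lw), lw)
        full = rolling_extrapolate(rel, ExtrapolationConfig(), 200)
        np.testing.assert_allclose(full, 1.5)

    def test_window_shorter_than_observation_allowed(self):
        t = np.arange(120.0)
        lw = 1.0 - 0.005 * t
        rel = RelativeSurvival(t, expit(lw), lw)
        full = rolling_extrapolate(rel, ExtrapolationConfig(window=48), 240)
        np.testing.assert_allclose(full, 1.0 - 0.005 * np.arange(241.0), atol=1e-6)

    def test_truncate_and_extrapolate_recovers_held_out_survival(
        self, scenario, life_table
    ):
        """Cut follow-up at 10 of 16 years, extrapolate back out, and compare
        restricted mean survival with the full-data estimate."""
        from lifegap.pipeline import validate_extrapolation

        sc = dataclasses.replace(scenario, n_per_area=20000)
        cohorts = [
            simulate_cohort(dataclasses.replace(sc, seed=700 + r), life_table, f"C{r}", 0.2)
            for r in range(3)
        ]
        rep = validate_extrapolation(cohorts, life_table, 120, 192, seed=4)
        assert rep["relative_abs_error"].mean() < 0.01
        assert np.all(np.abs(rep["difference_months"]) < 4.0)


class TestComposeAndIntegrate:
    def test_w_near_one_recovers_reference(self):
        sh = SurvivalCurve(np.exp(-0.01 * np.arange(200)))
        lw = np.full(200, logit(1 - 1e-4))
        s = compose_survival(lw, sh)
        np.testing.assert_allclose(s.s[1:], sh.s[1:] * (1 - 1e-4), rtol=1e-9)

    def test_monotonicity_enforced(self):
        sh = SurvivalCurve(np.linspace(1, 0.5, 50))
        lw = np.linspace(2.0, 1.0, 50)
        lw[20] = 8.0  # wiggle that would push the product up
        s = compose_survival(lw, sh)
        assert np.all(np.diff(s.s) <= 1e-12)

    def test_exponential_le_is_inverse_rate(self):
        lam = 0.1  # per year
        t = np.arange(100 * 12 + 1)
        s = SurvivalCurve(np.exp(-lam * t / 12.0))
        assert life_expectancy(s) == pytest.approx(10.0, abs=0.05)

    def test_rectangle_le_is_plateau_length(self):
        s = np.ones(241)
        s[121:] = 0.0
        le = life_expectancy(SurvivalCurve(s), warn_tail=1.0)
        assert le == pytest.approx(120.0 / 12, abs=0.05)

    def test_step_curve_matches_hand_trapezoid(self):
        km = km_estimate(build_cohort([1, 2, 3, 4], [1, 1, 1, 1]))
        # trapezoid over [1, .75, .5, .25, 0] = .875+.625+.375+.125 = 2 months
        assert life_expectancy(km, warn_tail=1.0) == pytest.approx(2.0 / 12)

    def test_sled_zero_for_identical_and_positive_for_dominating(self):
        a = SurvivalCurve(np.linspace(1, 0.2, 100))
        b = SurvivalCurve(np.linspace(1, 0.4, 100) ** 2)
        assert sled(a, a) == 0.0
        hi, lo = (a, b) if np.trapezoid(a.s) > np.trapezoid(b.s) else (b, a)
        assert sled(hi, lo) > 0


class TestEstimateCohort:
    def test_oracle_equivalence_full_follow_up(self, scenario, life_table):
        """With no censoring and follow-up to extinction, the pipeline LE
        equals the sample mean survival time within half a month."""
        sc = dataclasses.replace(
            scenario,
            n_per_area=3000,
            annual_loss_rate=0.0,
            admin_horizon_years=51.0,  # past the life-table cap for 60-year-olds
        )
        coh = simulate_cohort(sc, life_table, "A00", 0.1)
        df = coh.to_frame()
        assert df["event"].all()
        est = estimate_cohort(coh, life_table, ExtrapolationConfig(), bootstrap=False)
        assert est.le_years * 12 == pytest.approx(df["follow_months"].mean(), abs=0.5)

    def test_le_recovery_within_two_percent_for_excess_cohorts(
        self, scenario, life_table
    ):
        """Full-lifetime LE recovery for constant-excess-hazard cohorts at
        n = 20,000: mean relative error across replicates within 2%.  A single
        realization is noisier — KM noise in the window's end slope is
        amplified over the ~400 extrapolated months — which the bootstrap SE
        reflects."""
        errs = []
        for r in range(5):
            sc = dataclasses.replace(scenario, n_per_area=20000, seed=60 + r)
            coh = simulate_cohort(sc, life_table, "A00", 0.3)
            est = estimate_cohort(
                coh, life_table, ExtrapolationConfig(), np.random.default_rng(3),
                bootstrap=False,
            )
            truth = true_mix_life_expectancy(sc, life_table, 0.3) / 12.0
            errs.append((est.le_years - truth) / truth)
        assert np.mean(np.abs(errs)) < 0.02

    def test_epsilon_halving_changes_le_under_half_percent(self, scenario, life_table):
        coh = simulate_cohort(scenario, life_table, "A01", 0.25)
        les = []
        for eps in (1e-4, 5e-5):
            est = estimate_cohort(
                coh, life_table, ExtrapolationConfig(epsilon=eps),
                np.random.default_rng(11), bootstrap=False,
            )
            les.append(est.le_years)
        assert abs(les[0] - les[1]) / les[0] < 0.005

    def test_degenerate_resample_free_bootstrap_se_is_zero(self, life_table):
        # every participant identical: resampling cannot change the data, so
        # the only replicate variation is healthy-draw noise below the W clamp
        coh = build_cohort([60] * 40, [1] * 40, age=70)
        est = estimate_cohort(
            coh, life_table, ExtrapolationConfig(bootstrap_b=3), np.random.default_rng(0)
        )
        assert est.le_se == pytest.approx(0.0, abs=1e-6)
        assert est.sled_se == pytest.approx(0.0, abs=1e-6)

    def test_bootstrap_se_shrinks_with_cohort_size(self, scenario, life_table):
        ses = {}
        for n in (1000, 8000):
            sc = dataclasses.replace(scenario, n_per_area=n)
            coh = simulate_cohort(sc, life_table, "A00", 0.2)
            est = estimate_cohort(
                coh, life_table, ExtrapolationConfig(bootstrap_b=10),
                np.random.default_rng(21),
            )
            ses[n] = est.le_se
        assert ses[8000] < ses[1000]
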