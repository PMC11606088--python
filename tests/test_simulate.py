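"""Cohort simulator: determinism, calibration, violation switches."""

import numpy as np
import pytest

from gxagechange.assoc import fit_g_age, fit_gxage
from gxagechange.simulate import (
    SimConfig,
    apply_violation,
    calibrate_noise,
    config_to_design,
    fixed_effect_variance,
    monte_carlo_power,
    simulate_cohort,
)


class TestGeneration:
    def test_identical_seeds_identical_cohorts(self):
        cfg = SimConfig(n_individuals=2000, beta_gxage=0.01, seed=9)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.visits.equals(b.visits)
        assert a.samples.equals(b.samples)

    def test_different_seeds_distinct_noise_same_moments(self):
        cfg = SimConfig(n_individuals=30_000, sd_y=2.0, seed=1)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg, seed=2)
        assert not np.array_equal(a.genotypes, b.genotypes)
        ya, yb = a.baseline()["y"], b.baseline()["y"]
        assert ya.std() == pytest.approx(yb.std(), rel=0.03)
        assert a.genotypes.mean() == pytest.approx(b.genotypes.mean(), abs=0.02)

    def test_hardy_weinberg_frequencies(self):
        cfg = SimConfig(n_individuals=50_000, n_variants=3, allele_freq=(0.1, 0.3, 0.5), seed=4)
        c = simulate_cohort(cfg)
        assert np.allclose(c.genotypes.mean(axis=0) / 2, [0.1, 0.3, 0.5], atol=0.01)
        # genotype class proportions follow p^2 / 2pq / q^2
        g = c.genotypes[:, 1]
        obs = [np.mean(g == k) for k in (0, 1, 2)]
        assert np.allclose(obs, [0.49, 0.42, 0.09], atol=0.01)

    def test_noiseless_slope_identity(self):
        cfg = SimConfig(
            n_individuals=400,
            beta_age=0.05,
            beta_gxage=0.1,
            intercept_sd=0.0,
            visit_sd=0.0,
            r_y1y2=None,
            followup_fraction=1.0,
            seed=5,
        )
        c = simulate_cohort(cfg)
        long = c.longitudinal()
        g = c.dosages(long["id"])
        assert np.allclose(long["annual_change"], 0.05 + 0.1 * g, atol=1e-10)

    def test_birthyear_age_collinearity(self):
        c = simulate_cohort(SimConfig(n_individuals=20_000, seed=6))
        r = np.corrcoef(c.samples["age"], c.samples["birthyear"])[0, 1]
        assert r < -0.985

    def test_cross_sectional_partition(self):
        c = simulate_cohort(SimConfig(n_individuals=5000, followup_fraction=0.3, seed=7))
        cross = set(c.cross_sectional(exclude_longitudinal=True)["id"])
        long = set(c.longitudinal_ids())
        assert cross.isdisjoint(long)
        assert cross | long == set(c.samples["id"])


class TestNoiseCalibration:
    def test_closed_form_split(self):
        sd_b, sd_e = calibrate_noise(0.8, 7.5, signal_var=0.1, total_var=2.0)
        assert sd_b**2 + sd_e**2 + 0.1 == pytest.approx(2.0)
        assert (0.1 + sd_b**2) / 2.0 == pytest.approx(0.8)

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError):
            calibrate_noise(0.05, 7.5, signal_var=0.5, total_var=1.0)
        with pytest.raises(ValueError):
            calibrate_noise(1.2, 7.5, signal_var=0.0)

    @pytest.mark.parametrize("target_r", [0.91, 0.65])
    def test_simulated_test_retest_correlation(self, target_r):
        cfg = SimConfig(
            n_individuals=50_000,
            beta_g=0.1,
            beta_age=0.02,
            sd_y=1.0,
            r_y1y2=target_r,
            followup_fraction=1.0,
            seed=11,
        )
        long = simulate_cohort(cfg).longitudinal()
        r = np.corrcoef(long["y1"], long["y2"])[0, 1]
        assert r == pytest.approx(target_r, abs=0.01)

    def test_gap_independence_without_slope_randomness(self):
        # the calibration has no gap dependence: same split either way
        assert calibrate_noise(0.7, 2.0, 0.05) == calibrate_noise(0.7, 10.0, 0.05)

    def test_fixed_variance_matches_empirical(self):
        cfg = SimConfig(
            n_individuals=200_000,
            beta_g=0.3,
            beta_age=0.05,
            beta_gxage=0.02,
            sex_effect=0.4,
            intercept_sd=0.0,
            visit_sd=0.0,
            r_y1y2=None,
            seed=12,
        )
        y = simulate_cohort(cfg).baseline()["y"]
        assert y.var() == pytest.approx(fixed_effect_variance(cfg), rel=0.02)


class TestViolations:
    def test_zero_magnitude_is_identity(self, small_cohort):
        for switch in ("calendar_time_effect", "birthyear_effect_on_g", "quadratic_age_effect"):
            out = apply_violation(small_cohort, switch, 0.0)
            assert out is small_cohort

    def test_unknown_switch_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            apply_violation(small_cohort, "lunar_phase", 1.0)

    def test_af_drift_induces_genotype_age_association(self):
        # 0.005/birthyear drift over a ~29-year birth window is detectable
        cfg = SimConfig(
            n_individuals=100_000, seed=13, violations={"birthyear_effect_on_g": 0.005}
        )
        c = simulate_cohort(cfg)
        base = c.baseline()
        rec = fit_g_age(base, c.dosages(base["id"]))
        assert rec["p_g_age"] < 0.05 / 44
        assert rec["beta_g_age"] < 0  # age = assess - birthyear, so drift flips sign

    def test_nonselective_dropout_keeps_test_calibrated(self):
        # genotype-independent dropout: G~Age rejects at ~alpha across seeds
        hits = 0
        for s in range(40):
            cfg = SimConfig(n_individuals=4000, followup_fraction=0.0, seed=100 + s)
            c = simulate_cohort(cfg)
            keep = np.random.default_rng(s).uniform(size=c.n) > 0.2
            base = c.baseline()[keep]
            rec = fit_g_age(base, c.dosages(base["id"]))
            hits += rec["p_g_age"] < 0.05
        assert hits <= 7  # Binom(40, 0.05): P(X > 7) < 1e-3

    def test_genotype_dependent_dropout_removes_older_carriers(self):
        cfg = SimConfig(n_individuals=50_000, seed=14)
        c = simulate_cohort(cfg)
        out = apply_violation(c, "genotype_dependent_dropout", 0.01, seed=15)
        assert out.n < c.n
        base = out.baseline()
        rec = fit_g_age(base, out.dosages(base["id"]))
        assert rec["beta_g_age"] < 0 and rec["p_g_age"] < 1e-4

    def test_calendar_trend_shifts_change_intercept_not_slope(self):
        # an additive calendar-time trend accrues over the follow-up gap:
        # it biases the mean annual change (intercept) but, being independent
        # of genotype, leaves the genetic change effect intact
        kappa = 0.05
        cfg = SimConfig(
            n_individuals=50_000, beta_age=0.02, beta_gxage=0.01, sd_y=1.0,
            r_y1y2=0.91, followup_fraction=0.3, seed=15,
            violations={"calendar_time_effect": kappa},
        )
        c = simulate_cohort(cfg)
        long = c.longitudinal()
        g = c.dosages(long["id"])
        X = np.column_stack([np.ones(len(long)), g])
        beta = np.linalg.lstsq(X, long["annual_change"].to_numpy(), rcond=None)[0]
        assert beta[0] == pytest.approx(0.02 + kappa, abs=0.01)
        assert beta[1] == pytest.approx(0.01, abs=0.006)

    def test_quadratic_switch_bends_genotype_trajectory(self):
        cfg = SimConfig(
            n_individuals=60_000,
            beta_gxage=0.01,
            sd_y=1.0,
            r_y1y2=0.91,
            followup_fraction=0.0,
            seed=16,
            violations={"quadratic_age_effect": 0.003},
        )
        c = simulate_cohort(cfg)
        cross = c.cross_sectional()
        rec = fit_gxage(cross, c.dosages(cross["id"]))
        # linear-model interaction slope still estimates ~beta_gxage at the
        # (symmetric) mean age; the curvature shows up as a G x age^2 signal
        assert rec["beta_gxage"] == pytest.approx(0.01, abs=4 * rec["se_gxage"])
        age_c = cross["age"] - cross["age"].mean()
        resid_design = cross.assign(agec2=age_c**2)
        rec2 = fit_gxage(resid_design, c.dosages(cross["id"]) * age_c**2, covariates=["agec2"])
        assert rec2["p_marginal"] < 1e-10  # G*age^2 term present


class TestMonteCarlo:
    def test_null_rejection_rate_matches_alpha(self):
        cfg = SimConfig(n_individuals=1500, beta_gxage=0.0, sd_y=1.0,
                        followup_fraction=0.0, seed=17)
        res = monte_carlo_power(cfg, "gxage", reps=400, alpha=0.05, seed=18)
        assert res["ci_low"] <= 0.05 <= res["ci_high"]

    def test_noiseless_change_power_is_one(self):
        cfg = SimConfig(
            n_individuals=200,
            beta_gxage=0.05,
            intercept_sd=0.0,
            visit_sd=0.0,
            r_y1y2=None,
            followup_fraction=0.5,
            seed=19,
        )
        res = monte_carlo_power(cfg, "change", reps=20, alpha=5e-8, seed=20)
        assert res["power"] == 1.0

    def test_change_analysis_requires_longitudinal_data(self):
        cfg = SimConfig(n_individuals=100, followup_fraction=0.0)
        with pytest.raises(ValueError):
            monte_carlo_power(cfg, "change", reps=10)


class TestConfigToDesign:
    def test_design_moments_match_generative_model(self):
        cfg = SimConfig(
            n_individuals=80_000,
            beta_g=0.1,
            beta_gxage=0.01,
            sd_y=1.0,
            r_y1y2=0.91,
            followup_fraction=0.25,
            seed=21,
        )
        d = config_to_design(cfg)
        c = simulate_cohort(cfg)
        long = c.longitudinal()
        assert d.n_cross == 60_000 and d.n_long == 20_000
        assert long["annual_change"].std() == pytest.approx(d.sd_change, rel=0.05)
        assert c.baseline()["y"].std() <= 1.02  # sd_y is the residual-scale SD
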