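"""Power engine: published-value checks, inversion oracles, invariants."""

import numpy as np
import pytest
from scipy import stats

from gxagechange.designs import AlphaScheme, TraitDesign, load_design_table
from gxagechange import power as pw

# printed reference cells: trait -> (three power columns, three min-effect
# columns) for the 1-stage GxAge / 2-stage / 1-stage Change approaches at an
# effect of 10% of the medium marginal effect
REFERENCE_TABLE = {
    "Weight": ((0.99, 0.98, 0.87), (0.024, 0.025, 0.029)),
    "BMI": ((1.00, 0.98, 0.78), (0.0069, 0.0078, 0.010)),
    "DBP": ((0.92, 0.17, 0.01), (0.018, 0.041, 0.057)),
    "SBP": ((0.99, 0.25, 0.02), (0.032, 0.071, 0.098)),
    "PP": ((1.00, 0.26, 0.02), (0.022, 0.053, 0.073)),
    "HDL_ln": ((0.97, 0.05, 0.00), (4.2e-4, 0.0019, 0.0026)),
    "LDL": ((1.00, 0.04, 0.00), (0.055, 0.34, 0.46)),
    "TG_ln": ((0.99, 0.03, 0.00), (7.9e-4, 0.0047, 0.0065)),
}
APPROACH_ORDER = ("gxage_1stage", "gxagechange_2stage", "change_1stage")


def toy_design(**kw) -> TraitDesign:
    base = dict(
        trait_name="toy",
        n_cross=100_000,
        n_long=20_000,
        sd_y=10.0,
        sd_change=1.0,
        medium_marginal=0.3,
        allele_freq=0.3,
        var_age=60.0,
    )
    base.update(kw)
    return TraitDesign(**base)


class TestR2Explained:
    @pytest.mark.parametrize(
        "beta,p,sd_change,expected_pct",
        [(0.03, 0.30, 0.9, 0.047), (0.01, 0.30, 0.32, 0.041)],
    )
    def test_change_variance_fraction_matches_published(self, beta, p, sd_change, expected_pct):
        d = toy_design(sd_change=sd_change, allele_freq=p)
        r2 = pw.r2_explained(beta, d, "change")
        assert 100 * r2 == pytest.approx(expected_pct, abs=5e-4)

    def test_null_effect_explains_nothing(self):
        d = toy_design()
        assert all(pw.r2_explained(0.0, d, t) == 0 for t in ("marginal", "gxage", "change"))

    def test_interaction_term_scales_with_age_variance(self):
        lo, hi = toy_design(var_age=30.0), toy_design(var_age=60.0)
        assert pw.r2_explained(0.01, hi, "gxage") == pytest.approx(
            2 * pw.r2_explained(0.01, lo, "gxage")
        )

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            toy_design(sd_y=-1.0)


class TestPowerSingle:
    def test_size_under_the_null(self):
        assert pw.power_single(0.0, 10_000, 0.05, sided=2) == pytest.approx(0.05)
        assert pw.power_single(0.0, 10_000, 0.05, sided=1) == pytest.approx(0.05)

    def test_one_sided_inversion_identity(self):
        # ncp = (z_alpha + z_power)^2 gives exactly the target power
        alpha, target = 1e-4, 0.8
        ncp = (stats.norm.isf(alpha) + stats.norm.ppf(target)) ** 2
        n = 50_000
        r2 = ncp / (n + ncp)
        assert pw.power_single(r2, n, alpha, sided=1) == pytest.approx(target, abs=1e-10)

    def test_sensitivity_scan_detectable_variance(self):
        # a variant explaining ~0.005% of age variance is detectable at 80%
        # power in 350k individuals at the 0.05/44 multiplicity level
        assert pw.power_single(4.79e-5, 350_000, 0.05 / 44, sided=2) == pytest.approx(0.80, abs=0.005)

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            pw.power_single(0.01, 1000, 1.5)

    def test_monotone_in_n_and_effect(self):
        vals_n = [pw.power_single(1e-4, n, 5e-8) for n in (1e4, 1e5, 1e6)]
        vals_r = [pw.power_single(r2, 1e5, 5e-8) for r2 in (1e-5, 1e-4, 1e-3)]
        assert vals_n == sorted(vals_n) and vals_r == sorted(vals_r)


class TestApproachComposition:
    def test_union_bounds(self, designs):
        for d in designs.values():
            res = pw.power_1stage(d, 0.1 * d.medium_marginal, "gxage")
            assert res.power >= max(res.power_gws, res.power_2step) - 1e-12
            assert res.power <= res.power_gws + res.power_2step + 1e-12

    def test_two_stage_never_beats_discovery(self, designs):
        for d in designs.values():
            for frac in (0.05, 0.1, 0.2):
                beta = frac * d.medium_marginal
                assert (
                    pw.power_2stage(d, beta).power
                    <= pw.power_1stage(d, beta, "gxage").power + 1e-12
                )

    def test_null_effect_power_bounded_by_alpha_budget(self):
        d = toy_design()
        scheme = AlphaScheme()
        res = pw.power_1stage(d, 0.0, "gxage", scheme)
        assert res.power <= scheme.alpha_gws + scheme.alpha_2step
        assert pw.power_2stage(d, 0.0, scheme).power <= res.power * scheme.alpha_validation * 20

    def test_change_requires_longitudinal_sample(self):
        d = toy_design(n_long=0)
        with pytest.raises(ValueError):
            pw.power_1stage(d, 0.01, "change")


class TestReferenceTable:
    def test_power_columns_reproduced(self, designs):
        for trait, (powers, _) in REFERENCE_TABLE.items():
            d = designs[trait]
            beta = 0.1 * d.medium_marginal
            got = [pw.power_approach(d, beta, a).power for a in APPROACH_ORDER]
            assert got == pytest.approx(powers, abs=0.0105), trait

    def test_min_effect_columns_reproduced(self, designs):
        for trait, (_, mins) in REFERENCE_TABLE.items():
            d = designs[trait]
            got = [pw.min_detectable_effect(d, a) for a in APPROACH_ORDER]
            for g, m in zip(got, mins):
                assert g == pytest.approx(m, rel=0.05), trait

    def test_recovered_age_variance_consistent_with_printed_r2(self, designs):
        table = load_design_table().set_index("trait")
        for trait, d in designs.items():
            r2_pct = 100 * pw.r2_explained(0.1 * d.medium_marginal, d, "gxage")
            assert r2_pct == pytest.approx(table.loc[trait, "r2_gxage_pct"], abs=5.5e-4), trait


class TestInversionOracles:
    @pytest.mark.parametrize("approach", APPROACH_ORDER)
    def test_min_effect_inverts_to_target_power(self, designs, approach):
        for d in designs.values():
            beta = pw.min_detectable_effect(d, approach)
            assert pw.power_approach(d, beta, approach).power == pytest.approx(0.8, abs=1e-4)

    def test_required_n_is_sharp(self):
        d = toy_design(sd_change=2.06, allele_freq=0.3)
        for sided in (1, 2):
            n = pw.required_n(d, 0.021, term="change", alpha=0.05 / 26, sided=sided)
            assert pw.power_single(pw.r2_explained(0.021, d, "change"), n, 0.05 / 26, sided) >= 0.8
            assert pw.power_single(pw.r2_explained(0.021, d, "change"), n - 1, 0.05 / 26, sided) < 0.8

    def test_longitudinal_n_for_pulse_pressure_validation(self):
        # ~340k individuals needed to detect a 0.021 mmHg/year/allele change
        # effect at 80% power under a 26-locus Bonferroni level
        d = toy_design(sd_change=2.06, allele_freq=0.3)
        n1 = pw.required_n(d, 0.021, term="change", alpha=0.05 / 26, sided=1)
        n2 = pw.required_n(d, 0.021, term="change", alpha=0.05 / 26, sided=2)
        assert 300_000 < n1 < 340_000 < n2 < 380_000

    def test_required_n_rejects_null_effect(self):
        with pytest.raises(ValueError):
            pw.required_n(toy_design(), 0.0)

    def test_quadrupling_n_halves_minimum_effect(self):
        # small-r2 scaling law for the single genome-wide test: ncp ~ n * beta^2
        # (medium_marginal=0 disables the 2-step route, which scales differently)
        d1 = toy_design(n_cross=50_000, n_long=0, medium_marginal=0.0)
        d4 = toy_design(n_cross=200_000, n_long=0, medium_marginal=0.0)
        m1 = pw.min_detectable_effect(d1, "gxage_1stage")
        m4 = pw.min_detectable_effect(d4, "gxage_1stage")
        assert m4 == pytest.approx(m1 / 2, rel=0.02)


class TestKippingAndDominance:
    def test_kipping_point_is_ncp_crossing(self, designs):
        # at the crossing, the interaction and change noncentralities match,
        # giving the closed form f* = r2_gxage / (r2_gxage + r2_change)
        for trait in ("BMI", "LDL", "PP"):
            d = designs[trait]
            beta = 0.1 * d.medium_marginal
            r2g = pw.r2_explained(beta, d, "gxage")
            r2c = pw.r2_explained(beta, d, "change")
            kp = pw.kipping_point(d)
            assert kp.f == pytest.approx(r2g / (r2g + r2c), abs=5e-3)

    def test_no_crossing_reports_dominant_approach(self):
        # a change test with enormous noise never overtakes the interaction test
        d = toy_design(sd_change=500.0)
        kp = pw.kipping_point(d, beta=0.03)
        assert kp.f is None and kp.dominant == "gxage_1stage"

    def test_dominance_trivial_limits(self):
        assert pw.dominance_condition(60.0, 0.0, 0.9).gxage_wins
        res = pw.dominance_condition(60.0, 7.5, 1.0)
        assert res.degenerate and not res.gxage_wins

    def test_dominance_sign_matches_direct_power_comparison(self):
        # controlled scenario: equal n, equal alpha, equal effect
        n, alpha, beta, p = 200_000, 5e-8, 0.02, 0.3
        vg = 2 * p * (1 - p)
        sd_y = 10.0
        for var_age in (30.0, 56.0, 90.0):
            for age_diff in (2.0, 7.5):
                for r in (0.6, 0.91):
                    sd_change = np.sqrt(2 * sd_y**2 * (1 - r)) / age_diff
                    p_gx = pw.power_single(beta**2 * vg * var_age / sd_y**2, n, alpha)
                    p_ch = pw.power_single(beta**2 * vg / sd_change**2, n, alpha)
                    cond = pw.dominance_condition(var_age, age_diff, r)
                    if abs(p_gx - p_ch) > 1e-9:
                        assert cond.gxage_wins == (p_gx > p_ch), (var_age, age_diff, r)


class TestVarAgeRecovery:
    def test_r2_and_min_effect_recoveries_agree_roughly(self, designs):
        table = load_design_table().set_index("trait")
        for trait, d in designs.items():
            va_r2 = pw.recover_var_age_from_r2(d, table.loc[trait, "r2_gxage_pct"] / 100)
            # the one-digit r2 recovery lands within its rounding band
            assert va_r2 == pytest.approx(d.var_age, rel=0.08), trait

    def test_min_effect_recovery_round_trips(self, designs):
        d = designs["PP"]
        me = pw.min_detectable_effect(d, "gxage_1stage")
        assert pw.recover_var_age_from_min_effect(d, me) == pytest.approx(d.var_age, rel=1e-6)
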