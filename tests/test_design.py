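"""Design engine: spending function, boundaries, effect size, margins."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gspilot.design import (DesignSpec, expected_sample_size,
                            fixed_sample_theta, hsd_spend, margin_of_error,
                            quantile_substitute, solve_boundaries)


class TestHsdSpend:
    @pytest.mark.parametrize("t,gamma,total,expected", [
        (1.0, -4.0, 0.025, 0.025),               # exhausts total at t=1
        (0.5, 0.0, 0.025, 0.0125),               # linear limit
        (0.5, -4.0, 0.025,
         0.025 * (1 - math.e ** 2) / (1 - math.e ** 4)),  # closed form
        (0.0, -4.0, 0.025, 0.0),
    ])
    def test_values(self, t, gamma, total, expected):
        assert hsd_spend(t, gamma, total) == pytest.approx(expected, abs=1e-12)

    def test_continuous_at_gamma_zero(self):
        # the near-zero branch must agree with linear spending to 8 digits
        for gamma in (1e-6, -1e-6):
            for t in (0.1, 0.5, 0.9):
                assert hsd_spend(t, gamma, 0.025) == pytest.approx(
                    0.025 * t, rel=1e-8)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_t(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert hsd_spend(lo, -4.0, 0.025) <= hsd_spend(hi, -4.0, 0.025) + 1e-15

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hsd_spend(1.5, -4.0, 0.025)


class TestQuantileSubstitution:
    @pytest.mark.parametrize("z,df,expected", [
        (0.40, 30, 0.404),
        (2.75, 30, 2.960),
        (1.96, 62, 1.999),
        (0.0, 30, 0.0),
    ])
    def test_published_conversions(self, z, df, expected):
        assert round(quantile_substitute(z, df), 3) == expected

    def test_converges_to_z_with_df(self):
        z = 1.7
        prev = quantile_substitute(z, 5)
        for df in (10, 100, 1000, 10 ** 6):
            cur = quantile_substitute(z, df)
            assert z <= cur <= prev  # decreases monotonically toward z
            prev = cur
        assert abs(prev - z) < 1e-3


class TestFixedSampleTheta:
    def test_pilot_design_value(self):
        es = fixed_sample_theta(62, 0.05, 0.2)
        assert round(es.theta, 4) == 0.3558
        assert round(es.hedges_g, 2) == 0.71
        assert es.hedges_g == pytest.approx(2 * es.theta)

    def test_direct_evaluation_n100(self):
        es = fixed_sample_theta(100, 0.05, 0.2)
        assert es.theta == pytest.approx(2.8016 / 10, abs=5e-5)

    def test_vanishes_at_large_n(self):
        assert fixed_sample_theta(1e12).theta < 1e-5


class TestMarginOfError:
    @pytest.mark.parametrize("n,n2,expected", [
        (10, None, 0.72), (10, 10, 0.94), (8, 8, 1.07)])
    def test_published_margins(self, n, n2, expected):
        assert round(margin_of_error(n, 0.95, n2), 2) == expected

    def test_large_n_limit(self):
        n = 10 ** 6
        assert margin_of_error(n) * math.sqrt(n) == pytest.approx(1.96,
                                                                  abs=1e-3)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            margin_of_error(1)


class TestBoundarySolver:
    def test_one_stage_reduces_to_fixed_design(self):
        spec = DesignSpec(n_stages=1, info_fractions=(1.0,),
                          per_group_n=(31,), n_fix=62, n_max=62)
        b = solve_boundaries(spec)
        assert b.z_upper[0] == pytest.approx(stats.norm.isf(0.025), abs=1e-6)

    def test_pilot_interim_boundaries(self, pilot_design):
        _, b = pilot_design
        assert b.z_lower[0] == pytest.approx(0.40, abs=0.02)
        assert b.z_upper[0] == pytest.approx(2.75, abs=0.02)

    def test_t_scale_boundaries_above_z(self, pilot_design):
        _, b = pilot_design
        for z, t in zip(b.z_upper, b.t_upper):
            assert t >= z  # fat tails push positive bounds out

    def test_alpha_never_exceeded(self, pilot_design):
        spec, b = pilot_design
        # cumulative efficacy crossing under H0 with binding futility
        from gspilot.ocsim import oc_analytic_check
        probs = oc_analytic_check(b.z_lower[0], b.z_upper[0], b.z_upper[1],
                                  0.0)
        assert probs["p_reject_overall"] <= spec.alpha_total / 2 + 1e-6

    def test_power_at_alternative(self, pilot_design):
        spec, b = pilot_design
        from gspilot.ocsim import oc_analytic_check
        interim_drift = b.drift * math.sqrt(spec.info_fractions[0])
        probs = oc_analytic_check(b.z_lower[0], b.z_upper[0], b.z_upper[1],
                                  interim_drift)
        assert probs["p_reject_overall"] >= 0.79

    def test_quadrature_matches_monte_carlo(self, pilot_design):
        """Stage-2 crossing probabilities from the recursion agree with a
        plain bivariate-normal simulation within 3 MC standard errors."""
        spec, b = pilot_design
        n = 10 ** 6
        rng = np.random.default_rng(2024)
        z1 = rng.standard_normal(n)
        inc = rng.standard_normal(n)
        z2 = (z1 + inc) / math.sqrt(2)  # corr sqrt(0.5)
        cont = (z1 > b.z_lower[0]) & (z1 < b.z_upper[0])
        from gspilot.ocsim import oc_analytic_check
        probs = oc_analytic_check(b.z_lower[0], b.z_upper[0], b.z_upper[1],
                                  0.0)
        for key, mc in [
            ("p_futility_interim", np.mean(z1 <= b.z_lower[0])),
            ("p_success_interim", np.mean(z1 >= b.z_upper[0])),
            ("p_reject_final_only", np.mean(cont & (z2 > b.z_upper[1]))),
        ]:
            se = math.sqrt(mc * (1 - mc) / n)
            assert abs(probs[key] - mc) < 3 * se + 1e-9, key

    def test_solved_drift_implies_n_max_near_64(self, pilot_design):
        _, b = pilot_design
        assert 62 < b.n_max_continuous < 65


class TestExpectedSampleSize:
    def test_degenerate_continuation(self, pilot_design):
        spec, b = pilot_design
        # a drift so large the trial always stops at interim
        assert expected_sample_size(spec, b, drift=10.0) == pytest.approx(
            32, abs=0.1)

    def test_expected_n_alternative(self, pilot_design):
        spec, b = pilot_design
        theta = fixed_sample_theta(spec.n_fix).theta
        assert expected_sample_size(spec, b, theta) == pytest.approx(54.7,
                                                                     abs=0.5)

    def test_expected_n_null(self, pilot_design):
        spec, b = pilot_design
        assert expected_sample_size(spec, b, 0.0) == pytest.approx(42.8,
                                                                   abs=0.5)


class TestSpecValidation:
    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            DesignSpec(info_fractions=(1.0, 0.5))

    def test_rejects_nfix_above_nmax(self):
        with pytest.raises(ValueError):
            DesignSpec(n_fix=70, n_max=64)
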