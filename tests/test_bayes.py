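"""Bayesian mixed model: transforms, priors, sampler, contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from gspilot.bayes import (ModelSpec, PriorSpec, build_informative_priors,
                           default_priors, fit_lmm, logit_transform,
                           posterior_contrasts, sample_prior)
from tests.conftest import add_logit_columns, adherence_from_seed


class TestLogitTransform:
    def test_symmetry_and_values(self):
        assert logit_transform(50.0) == pytest.approx(0.0)
        assert logit_transform(90.0) == pytest.approx(math.log(9), abs=1e-9)

    def test_shrink_policy_at_boundary(self):
        # (1*(N-1)+0.5)/N with N=28 scheduled doses
        expected = math.log(27.5 / 28 / (1 - 27.5 / 28))
        assert logit_transform(100.0, "shrink", n_doses=28) == pytest.approx(
            expected)

    def test_boundary_errors_by_default(self):
        with pytest.raises(ValueError):
            logit_transform(0.0)

    def test_over_100_clamped_then_transformed(self):
        v = logit_transform(105.0, "shrink", n_doses=14)
        assert v == logit_transform(100.0, "shrink", n_doses=14)

    def test_eps_policy(self):
        assert logit_transform(0.0, "eps", eps=0.01) == pytest.approx(
            math.log(0.01 / 0.99))


class TestInformativePriors:
    GRID = {"placebo": {2: 90.0, 4: 79.0, 8: 66.0},
            "mph": {2: 96.0, 4: 90.0, 8: 82.0}}

    def test_reference_cell_coefficients(self):
        pr = build_informative_priors(self.GRID)
        logit = lambda p: math.log(p / (1 - p))
        assert pr.coef_means["Intercept"] == pytest.approx(logit(0.90))
        assert pr.coef_means["trt"] == pytest.approx(
            logit(0.96) - logit(0.90), abs=1e-9)
        # double difference at week 8
        expected = (logit(0.82) - logit(0.96)) - (logit(0.66) - logit(0.90))
        assert pr.coef_means["trt:visit_8"] == pytest.approx(expected)
        assert expected == pytest.approx(-0.128, abs=5e-3)
        assert pr.autoscale is False
        assert pr.coef_sds == 1.0

    def test_identical_grids_zero_treatment_means(self):
        grid = {"placebo": self.GRID["placebo"],
                "mph": self.GRID["placebo"]}
        pr = build_informative_priors(grid)
        assert pr.coef_means["trt"] == 0.0
        assert pr.coef_means["trt:visit_8"] == 0.0

    def test_degenerate_grid_rejected(self):
        grid = {"placebo": {2: 100.0, 4: 79.0, 8: 66.0},
                "mph": self.GRID["mph"]}
        with pytest.raises(ValueError):
            build_informative_priors(grid)


class TestPriorResolution:
    def test_autoscale_semantics(self):
        y = np.array([0.0, 2.0, 4.0, 6.0])       # sd = sqrt(5)
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        pr = PriorSpec()
        means, sds, rate = pr.resolve(["Intercept", "trt"], y, X)
        sy, sx = np.std(y), np.std(X[:, 1])
        assert means[0] == pytest.approx(3.0)     # sample-mean intercept
        assert sds[0] == pytest.approx(2.5 * sy)
        assert sds[1] == pytest.approx(2.5 * sy / sx)
        assert rate == pytest.approx(1.0 / sy)

    def test_autoscale_off_leaves_raw_values(self):
        y = np.array([0.0, 2.0, 4.0, 6.0])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        pr = PriorSpec(coef_means={"trt": 0.9}, coef_sds=1.0,
                       intercept_mean_rule=False, autoscale=False)
        means, sds, rate = pr.resolve(["Intercept", "trt"], y, X)
        assert list(means) == [0.0, 0.9]
        assert list(sds) == [1.0, 1.0]
        assert rate == 1.0


@pytest.fixture(scope="module")
def fitted(small_fit):
    return small_fit[0]


class TestSampler:
    def test_prior_only_moments(self):
        """Prior-only sampling reproduces the prior means/SDs within 3 MC SEs."""
        adh, _ = adherence_from_seed(3)
        pr = PriorSpec(coef_means={"trt": 0.7}, coef_sds=1.2,
                       intercept_mean_rule=False, autoscale=False,
                       error_sd_rate=2.0)
        summ = sample_prior(ModelSpec(), pr, adh, n_draws=20_000, seed=0)
        n = 20_000
        for nm in summ.coef_names:
            target = 0.7 if nm == "trt" else 0.0
            flat = summ.stacked(nm)
            assert abs(flat.mean() - target) < 3 * 1.2 / math.sqrt(n)
            assert abs(flat.std() - 1.2) < 3 * 1.2 / math.sqrt(n)
        sig = summ.stacked("sigma")
        assert abs(sig.mean() - 0.5) < 3 * 0.5 / math.sqrt(n)

    def test_zero_variance_prior_collapses_to_means(self):
        adh, _ = adherence_from_seed(4)
        pr = PriorSpec(coef_means={"trt": 0.5, "Intercept": 2.0},
                       coef_sds=1e-6, intercept_mean_rule=False,
                       autoscale=False)
        summ = fit_lmm(adh, ModelSpec(), pr, chains=2, iterations=600,
                       warmup=300, seed=8)
        assert summ.medians["trt"] == pytest.approx(0.5, abs=1e-2)
        assert summ.medians["Intercept"] == pytest.approx(2.0, abs=1e-2)

    def test_flat_data_symmetric_contrasts(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(10):
            noise = 1e-6 * rng.standard_normal(3)  # noise floor, shared
            for arm in ("placebo", "mph"):          # exactly arm-symmetric
                for w, e in zip((2, 4, 8), noise):
                    rows.append({"participant_id": f"{arm[0]}{i:03d}",
                                 "arm": arm, "visit_week": w,
                                 "pill_logit": 2.0 + e})
        df = pd.DataFrame(rows)
        summ = fit_lmm(df, ModelSpec(), default_priors(), chains=2,
                       iterations=1000, warmup=500, seed=1)
        pr8, diff = posterior_contrasts(summ, 8)
        assert abs(np.median(diff)) < 0.05
        assert 0.35 < pr8 < 0.65

    def test_reference_cell_equals_intercept(self, fitted):
        """EMM of the reference arm at the reference week is the intercept."""
        from gspilot.bayes import _cell_draws
        cell = _cell_draws(fitted.model, fitted.draws, "placebo", 2)
        assert np.array_equal(cell, fitted.stacked("Intercept"))

    def test_pr_exceed_is_one_minus_ecdf_at_zero(self, fitted):
        pr8, diff = posterior_contrasts(fitted, 8)
        assert pr8 == pytest.approx(1.0 - np.mean(diff <= 0))
        assert pr8 == fitted.pr_exceed[8]

    def test_split_rhat_agrees_with_arviz(self, fitted):
        az = pytest.importorskip("arviz")
        for nm in ("trt", "sigma"):
            ours = fitted.rhat[nm]
            theirs = float(az.rhat(np.asarray(fitted.draws[nm]),
                                   method="split"))
            assert ours == pytest.approx(theirs, abs=2e-3)

    def test_missing_visits_allowed(self):
        adh, _ = adherence_from_seed(6)
        adh = adh[~((adh["participant_id"] == "P001")
                    & (adh["visit_week"] == 8))]
        summ = fit_lmm(adh, ModelSpec(), default_priors(), chains=2,
                       iterations=400, warmup=200, seed=2)
        assert np.isfinite(summ.medians["trt:visit_8"])

    def test_unknown_week_contrast_rejected(self, fitted):
        with pytest.raises(ValueError):
            posterior_contrasts(fitted, 6)

    def test_rank_deficient_design_rejected(self):
        rows = [{"participant_id": f"P{i}", "arm": "placebo",
                 "visit_week": w, "pill_logit": 1.0}
                for i in range(6) for w in (2, 4, 8)]
        with pytest.raises(ValueError):
            fit_lmm(pd.DataFrame(rows), ModelSpec(), default_priors(),
                    chains=1, iterations=20, warmup=10, seed=0)


def test_sign_recovery_lower_mph_adherence():
    """Data generated with clearly lower MPH adherence yield
    Pr(MPH > placebo) below one half at week 8."""
    from gspilot.generate import GeneratorConfig, generate_trial
    from gspilot.endpoints import derive_adherence
    below = 0
    for seed in range(5):
        cells = {"placebo": {2: 2.2, 4: 2.2, 8: 2.2},
                 "mph": {2: 2.2, 4: 1.5, 8: 0.8}}
        cfg = GeneratorConfig(seed=seed, n_dropouts=0,
                              logit_cell_means=cells)
        ds = generate_trial(cfg)
        adh = add_logit_columns(derive_adherence(ds.visits, ds.mems_events))
        summ = fit_lmm(adh, ModelSpec(), default_priors(), chains=2,
                       iterations=800, warmup=400, seed=seed)
        below += summ.pr_exceed[8] < 0.5
    assert below >= 4
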