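import math

import numpy as np
import pytest
from scipy.stats import norm

from cdbmd.association_models import (
    LinearFit,
    LogisticFit,
    fit_linear_age_adjusted,
    fit_logistic_age_adjusted,
)
from cdbmd.bmd_engine import (
    BmdSpec,
    bmd_table,
    hybrid_bmd,
    hybrid_bmd_closed,
    hybrid_bmd_numeric,
    hybrid_bmdl,
    hybrid_cutoff,
    logistic_background,
    logistic_bmd,
    logistic_bmdl,
)
from cdbmd.synthetic_cohort import default_config, sample_cohort


def linear_fit(intercept=100.0, beta_dose=-1.0, beta_age=0.0, sigma=1.0,
               n=1_000_000_000_000, cov=None, endpoint="crcl", sex="woman",
               p_dose=0.001):
    cov = np.zeros((3, 3)) if cov is None else cov
    return LinearFit(
        endpoint=endpoint,
        sex=sex,
        params=np.array([intercept, beta_dose, beta_age]),
        cov=cov,
        residual_sd=sigma,
        n=n,
        pvalues=np.array([0.0, p_dose, 0.0]),
        conf_int=np.zeros((3, 2)),
    )


def logistic_fit(intercept=-4.0, beta_dose=0.157, beta_age=0.03, cov=None,
                 endpoint="tr_below_95", sex="man", p_dose=0.001):
    cov = np.zeros((3, 3)) if cov is None else cov
    return LogisticFit(
        endpoint=endpoint,
        sex=sex,
        params=np.array([intercept, beta_dose, beta_age]),
        cov=cov,
        n=48,
        pvalues=np.array([0.0, p_dose, 0.0]),
        conf_int=np.zeros((3, 2)),
        converged=True,
    )


class TestHybridCutoff:
    def test_low_adverse(self):
        fit = linear_fit(intercept=100.0, beta_age=0.0, sigma=20.0)
        cut = hybrid_cutoff(fit, BmdSpec(endpoint="crcl"))
        assert cut == pytest.approx(100.0 - norm.ppf(0.95) * 20.0, rel=1e-12)
        assert cut == pytest.approx(67.10, abs=5e-3)

    def test_high_adverse_ln_scale(self):
        fit = linear_fit(intercept=7.0, beta_dose=0.3, beta_age=0.0, sigma=0.8,
                         endpoint="ln_b2mg")
        cut = hybrid_cutoff(fit, BmdSpec(endpoint="ln_b2mg"))
        assert cut == pytest.approx(8.3159, abs=5e-4)
        assert math.exp(cut) == pytest.approx(4088, rel=2e-3)

    def test_median_at_half(self):
        fit = linear_fit(intercept=55.0, beta_age=0.5, sigma=12.0)
        spec = BmdSpec(endpoint="crcl", p0=0.5, bmr=0.2)
        assert hybrid_cutoff(fit, spec) == pytest.approx(55.0 + 0.5 * 70.0, rel=1e-12)

    def test_reference_age_enters(self):
        fit = linear_fit(intercept=100.0, beta_age=-1.0, sigma=10.0)
        c70 = hybrid_cutoff(fit, BmdSpec(endpoint="crcl", reference_age=70))
        c60 = hybrid_cutoff(fit, BmdSpec(endpoint="crcl", reference_age=60))
        assert c60 - c70 == pytest.approx(10.0, rel=1e-12)


class TestHybridBmd:
    def test_quantile_arithmetic(self):
        assert hybrid_bmd_closed(-1.0, 1.0, 0.05, 0.05) == pytest.approx(0.3633, abs=1e-4)
        assert hybrid_bmd_closed(-1.0, 1.0, 0.05, 0.10) == pytest.approx(0.6085, abs=1e-4)

    def test_published_pair_via_calibration(self):
        # Calibrate sigma so BMR 5% reproduces the published 5.7, then the
        # BMR 10% value must match the published 9.6 within rounding.
        k5 = norm.ppf(0.95) - norm.ppf(0.90)
        sigma = 5.7 * 1.24 / k5
        assert hybrid_bmd_closed(-1.24, sigma, 0.05, 0.05) == pytest.approx(5.7, rel=1e-12)
        assert hybrid_bmd_closed(-1.24, sigma, 0.05, 0.10) == pytest.approx(9.55, abs=0.01)

    def test_bmr_to_zero_limit(self):
        assert hybrid_bmd_closed(-1.0, 1.0, 0.05, 0.0) == 0.0

    def test_wrong_sign_refused(self):
        fit = linear_fit(beta_dose=+1.0)  # crcl is low-adverse
        with pytest.raises(ValueError, match="not signed toward adversity"):
            hybrid_bmd(fit, BmdSpec(endpoint="crcl"))

    def test_closed_form_equals_rootfind_100_draws(self, rng):
        for _ in range(100):
            beta = -float(rng.uniform(0.05, 5.0))
            sigma = float(rng.uniform(0.1, 30.0))
            p0 = float(rng.uniform(0.01, 0.4))
            bmr = float(rng.uniform(0.01, 0.4))
            if p0 + bmr >= 0.95:
                continue
            risk = "additional" if rng.uniform() < 0.5 else "extra"
            closed = hybrid_bmd_closed(beta, sigma, p0, bmr, risk)
            numeric = hybrid_bmd_numeric(beta, sigma, p0, bmr, risk)
            assert numeric == pytest.approx(closed, abs=1e-8, rel=1e-8)

    def test_homogeneity(self):
        base = hybrid_bmd_closed(-1.3, 7.0, 0.05, 0.05)
        assert hybrid_bmd_closed(-1.3, 21.0, 0.05, 0.05) == pytest.approx(3 * base, rel=1e-12)
        assert hybrid_bmd_closed(-3.9, 7.0, 0.05, 0.05) == pytest.approx(base / 3, rel=1e-12)

    def test_additional_vs_extra_ratio(self):
        # The BMR-10/BMR-5 ratio at p0 = 0.05 differs between risk types;
        # the engine must distinguish them.
        add = hybrid_bmd_closed(-1.0, 1.0, 0.05, 0.10) / hybrid_bmd_closed(-1.0, 1.0, 0.05, 0.05)
        ext = (
            hybrid_bmd_closed(-1.0, 1.0, 0.05, 0.10, "extra")
            / hybrid_bmd_closed(-1.0, 1.0, 0.05, 0.05, "extra")
        )
        assert add == pytest.approx(1.6747, abs=1e-3)
        k = lambda b: norm.ppf(0.95) - norm.ppf(1 - 0.05 - b * 0.95)
        assert ext == pytest.approx(k(0.10) / k(0.05), rel=1e-12)
        assert abs(add - ext) > 1e-3


class TestHybridBmdl:
    def test_zero_variance_limit_delta(self):
        fit = linear_fit(cov=np.zeros((3, 3)), n=10**12)
        spec = BmdSpec(endpoint="crcl", bmdl_method="delta")
        assert hybrid_bmdl(fit, spec) == pytest.approx(hybrid_bmd(fit, spec), rel=1e-5)

    def test_zero_variance_limit_slope_bound(self):
        fit = linear_fit(cov=np.zeros((3, 3)), n=100)
        spec = BmdSpec(endpoint="crcl", bmdl_method="slope_bound")
        assert hybrid_bmdl(fit, spec) == pytest.approx(hybrid_bmd(fit, spec), rel=1e-12)

    @pytest.mark.parametrize("method", ["profile", "delta", "slope_bound"])
    def test_bmdl_below_bmd_on_fits(self, markers, method):
        fit = fit_linear_age_adjusted(markers, "crcl", "woman")
        spec = BmdSpec(endpoint="crcl", bmdl_method=method)
        bmdl = hybrid_bmdl(fit, spec)
        assert 0 < bmdl <= hybrid_bmd(fit, spec)

    def test_consistency_bmdl_to_bmd(self):
        # bmdl/bmd -> 1 as n grows.
        ratios = []
        for scale in (1, 45):
            cohort, _ = sample_cohort(default_config(mode="endpoint", seed=31, scale=scale))
            fit = fit_linear_age_adjusted(cohort, "crcl", "woman")
            spec = BmdSpec(endpoint="crcl", bmdl_method="profile")
            ratios.append(hybrid_bmdl(fit, spec) / hybrid_bmd(fit, spec))
        assert ratios[1] > ratios[0]
        assert ratios[1] > 0.9

    def test_profile_close_to_delta(self, markers):
        fit = fit_linear_age_adjusted(markers, "crcl", "woman")
        prof = hybrid_bmdl(fit, BmdSpec(endpoint="crcl", bmdl_method="profile"))
        delt = hybrid_bmdl(fit, BmdSpec(endpoint="crcl", bmdl_method="delta"))
        assert prof == pytest.approx(delt, rel=0.25)

    def test_profile_falls_back_without_data(self, caplog):
        fit = linear_fit(cov=0.01 * np.eye(3), n=100)
        spec = BmdSpec(endpoint="crcl", bmdl_method="profile")
        with caplog.at_level("WARNING", logger="cdbmd.bmd_engine"):
            bmdl = hybrid_bmdl(fit, spec)
        assert any("falling back" in rec.message for rec in caplog.records)
        assert bmdl < hybrid_bmd(fit, spec)


class TestLogisticBackground:
    def test_inverse_logit_example(self):
        fit = logistic_fit(intercept=-4.0, beta_age=0.03)
        spec = BmdSpec(endpoint="tr_below_95", model_kind="logistic", p0=None)
        assert logistic_background(fit, spec) == pytest.approx(0.1301, abs=5e-5)

    def test_trivial_half(self):
        fit = logistic_fit(intercept=0.0, beta_age=0.0)
        spec = BmdSpec(endpoint="tr_below_95", model_kind="logistic", p0=None)
        assert logistic_background(fit, spec) == 0.5


class TestLogisticBmd:
    @pytest.mark.parametrize(
        "odds_ratio,p0,bmr,printed",
        [(1.17, 0.118, 0.05, 2.6), (1.21, 0.034, 0.05, 5.0), (1.12, 0.066, 0.10, 9.1)],
    )
    def test_published_values(self, odds_ratio, p0, bmr, printed):
        bmd = logistic_bmd(math.log(odds_ratio), p0, bmr)
        assert round(bmd, 1) == printed

    def test_beta_age_independence_given_p0(self):
        # With p0 held fixed, the BMD depends only on the dose slope.
        a = logistic_bmd(0.157, 0.118, 0.05)
        assert a == pytest.approx(logistic_bmd(0.157, 0.118, 0.05), rel=1e-15)
        fit_a = logistic_fit(beta_age=0.01)
        fit_b = logistic_fit(beta_age=0.08)
        bmd_a = logistic_bmd(fit_a.beta_dose, 0.118, 0.05)
        bmd_b = logistic_bmd(fit_b.beta_dose, 0.118, 0.05)
        assert bmd_a == bmd_b

    def test_extra_risk_differs(self):
        add = logistic_bmd(math.log(1.17), 0.118, 0.05, "additional")
        ext = logistic_bmd(math.log(1.17), 0.118, 0.05, "extra")
        assert round(add, 1) == 2.6
        assert round(ext, 1) == 2.3

    def test_nonpositive_slope_refused(self):
        with pytest.raises(ValueError):
            logistic_bmd(-0.1, 0.1, 0.05)


class TestLogisticBmdl:
    def test_zero_variance_limit(self):
        fit = logistic_fit(cov=np.zeros((3, 3)))
        spec = BmdSpec(endpoint="tr_below_95", model_kind="logistic", p0=None,
                       bmdl_method="delta")
        p0 = logistic_background(fit, spec)
        bmd = logistic_bmd(fit.beta_dose, p0, 0.05)
        assert logistic_bmdl(fit, spec) == pytest.approx(bmd, rel=1e-9)

    def test_slope_bound_documented_mismatch(self):
        # Evaluating at the published upper OR bound (1.35) yields ~1.37,
        # not the published BMDL of 1.8 — the reason profile/delta are the
        # defaults.
        bmdl = logistic_bmd(math.log(1.35), 0.118, 0.05)
        assert bmdl == pytest.approx(1.37, abs=0.01)
        assert abs(bmdl - 1.8) > 0.3

    @pytest.mark.parametrize("method", ["profile", "delta", "slope_bound"])
    def test_bmdl_below_bmd_on_fits(self, endpoint_cohort, method):
        cohort, _ = endpoint_cohort
        fit = fit_logistic_age_adjusted(cohort, "tr_below_95", "man")
        spec = BmdSpec(endpoint="tr_below_95", model_kind="logistic", p0=None,
                       bmdl_method=method)
        p0 = logistic_background(fit, spec)
        bmd = logistic_bmd(fit.beta_dose, p0, 0.05)
        bmdl = logistic_bmdl(fit, spec)
        assert 0 < bmdl <= bmd

    def test_profile_close_to_delta(self, endpoint_cohort):
        cohort, _ = endpoint_cohort
        fit = fit_logistic_age_adjusted(cohort, "tr_below_95", "woman")
        base = dict(endpoint="tr_below_95", model_kind="logistic", p0=None)
        prof = logistic_bmdl(fit, BmdSpec(**base, bmdl_method="profile"))
        delt = logistic_bmdl(fit, BmdSpec(**base, bmdl_method="delta"))
        assert prof == pytest.approx(delt, rel=0.25)


class TestBmdTable:
    def _fits(self):
        return [
            linear_fit(endpoint="crcl", sex="man", cov=0.01 * np.eye(3), n=48,
                       p_dose=0.118),
            linear_fit(endpoint="egfr", sex="man", cov=0.01 * np.eye(3), n=48,
                       p_dose=0.041, intercept=133.0, beta_dose=-1.02, sigma=16.0),
            linear_fit(endpoint="egfr", sex="woman", cov=0.01 * np.eye(3), n=62,
                       p_dose=0.082, beta_dose=-0.65, sigma=16.0),
            logistic_fit(endpoint="tr_below_95", sex="man",
                         cov=0.001 * np.eye(3), p_dose=0.022),
        ]

    def test_gate_failures_become_skip_rows(self):
        rows = bmd_table(self._fits(), bmdl_method="delta")
        by_key = {(r.endpoint, r.sex, r.bmr): r for r in rows}
        assert by_key[("crcl", "man", 0.05)].status == "skipped"
        assert by_key[("egfr", "woman", 0.05)].status == "skipped"
        assert by_key[("egfr", "man", 0.05)].status == "ok"
        assert "p >= 0.05" in by_key[("crcl", "man", 0.10)].reason

    def test_skipped_rows_have_no_bmd(self):
        rows = bmd_table(self._fits(), bmdl_method="delta")
        for r in rows:
            if r.status == "skipped":
                assert r.bmd is None and r.bmdl is None

    def test_every_ok_row_bmdl_le_bmd(self):
        rows = bmd_table(self._fits(), bmdl_method="delta")
        for r in rows:
            if r.status == "ok":
                assert 0 < r.bmdl <= r.bmd

    def test_hybrid_bmr_ratio_invariant(self):
        rows = bmd_table(self._fits(), bmdl_method="delta")
        by_key = {(r.endpoint, r.sex, r.bmr): r for r in rows}
        pair = (by_key[("egfr", "man", 0.10)].bmd, by_key[("egfr", "man", 0.05)].bmd)
        assert pair[0] / pair[1] == pytest.approx(1.6748, abs=1e-3)
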