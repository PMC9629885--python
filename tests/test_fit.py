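"""Binding-model estimation: recovery, nesting, equivariance, bounds."""

import numpy as np
import pytest

import ada_affinity as aa
from ada_affinity.fit import FreeAdaBindingModel

from conftest import lognormal_noise


class TestMonophasicFit:
    def test_noiseless_recovery(self, noiseless_mono_curve, mono_truth):
        res = aa.fit_monophasic(noiseless_mono_curve)
        assert res.converged
        assert res.params.kd == pytest.approx(mono_truth.kd, rel=1e-3)
        assert res.params.ab == pytest.approx(mono_truth.ab, rel=1e-3)

    def test_constant_signal_unidentifiable(self, dose_series):
        curve = aa.AffinityCurve(
            "flat", dose_series.doses_molar, np.full(8, 500.0)
        )
        res = aa.fit_monophasic(curve)
        assert not res.converged  # K_D escapes the identifiable window

    def test_scale_equivariance(self, dose_series, mono_truth):
        rng = np.random.default_rng(3)
        sig = lognormal_noise(
            aa.response_mono(dose_series.doses_molar, mono_truth), 0.05, rng
        )
        r1 = aa.fit_monophasic(aa.AffinityCurve("a", dose_series.doses_molar, sig))
        r2 = aa.fit_monophasic(
            aa.AffinityCurve("b", dose_series.doses_molar, 37.0 * sig)
        )
        assert r2.params.ab == pytest.approx(37.0 * r1.params.ab, rel=1e-6)
        assert r2.params.kd == pytest.approx(r1.params.kd, rel=1e-6)

    def test_dose_unit_equivariance(self, mono_truth):
        # fitting in ng/mL units rescales K_D by exactly the conversion factor
        ds_molar = aa.make_dose_series()
        factor = aa.to_molar(1.0, "ng/mL", 150_000.0)
        sig = aa.response_mono(ds_molar.doses_molar, mono_truth)
        r_m = aa.fit_monophasic(aa.AffinityCurve("m", ds_molar.doses_molar, sig))
        r_ng = aa.fit_monophasic(
            aa.AffinityCurve("n", ds_molar.doses_molar / factor, sig)
        )
        assert r_ng.params.kd * factor == pytest.approx(r_m.params.kd, rel=1e-6)

    def test_weight_options(self, dose_series, mono_truth):
        rng = np.random.default_rng(11)
        sig = lognormal_noise(
            aa.response_mono(dose_series.doses_molar, mono_truth), 0.1, rng
        )
        curve = aa.AffinityCurve("w", dose_series.doses_molar, sig)
        r_rel = aa.fit_monophasic(curve, weights="relative")
        r_unw = aa.fit_monophasic(curve, weights="unweighted")
        assert r_rel.weights == "relative" and r_unw.weights == "unweighted"
        # both identify K_D within the same order of magnitude
        assert 0.1 < r_unw.params.kd / r_rel.params.kd < 10


class TestBiphasicFit:
    def test_noiseless_recovery(self, noiseless_bi_curve, bi_truth):
        res = aa.fit_biphasic(noiseless_bi_curve)
        assert res.converged
        assert res.params.kd1 == pytest.approx(bi_truth.kd1, rel=1e-2)
        assert res.params.kd2 == pytest.approx(bi_truth.kd2, rel=1e-2)

    def test_nesting_rss(self, dose_series, mono_truth):
        # the biphasic model contains the monophasic one
        rng = np.random.default_rng(5)
        for _ in range(5):
            sig = lognormal_noise(
                aa.response_mono(dose_series.doses_molar, mono_truth), 0.1, rng
            )
            curve = aa.AffinityCurve("n", dose_series.doses_molar, sig)
            assert aa.fit_biphasic(curve).rss <= aa.fit_monophasic(curve).rss * (
                1 + 1e-9
            )

    def test_canonical_phase_ordering(self, noiseless_bi_curve):
        res = aa.fit_biphasic(noiseless_bi_curve)
        assert res.params.kd1 <= res.params.kd2

    def test_short_curve_rejected(self):
        doses = np.array([1e-12, 1e-11, 1e-10, 1e-9, 1e-8])
        signals = np.linspace(100, 10, 5)
        curve = aa.AffinityCurve("s", doses, signals)
        with pytest.raises(ValueError):
            FreeAdaBindingModel(curve, phases=2)  # n=5 <= k+1


class TestPredictWithBounds:
    def test_noiseless_bounds_collapse(self, noiseless_mono_curve):
        res = aa.fit_monophasic(noiseless_mono_curve)
        pred, lo, hi = res.predict_with_bounds(2e-12, level=0.99)
        assert lo[0] == pytest.approx(pred[0], abs=1e-6 * pred[0] + 1e-12)
        assert hi[0] == pytest.approx(pred[0], abs=1e-6 * pred[0] + 1e-12)

    def test_level_nesting(self, dose_series, mono_truth):
        rng = np.random.default_rng(9)
        sig = lognormal_noise(
            aa.response_mono(dose_series.doses_molar, mono_truth), 0.08, rng
        )
        res = aa.fit_monophasic(aa.AffinityCurve("l", dose_series.doses_molar, sig))
        p95, lo95, hi95 = res.predict_with_bounds(2e-12, level=0.95)
        p99, lo99, hi99 = res.predict_with_bounds(2e-12, level=0.99)
        assert lo99[0] <= lo95[0] <= p95[0] <= hi95[0] <= hi99[0]

    def test_bounds_match_parametric_bootstrap(self, dose_series, mono_truth):
        """Delta-method interval vs 2000 multivariate-t parameter draws."""
        rng = np.random.default_rng(17)
        sig = lognormal_noise(
            aa.response_mono(dose_series.doses_molar, mono_truth), 0.05, rng
        )
        res = aa.fit_monophasic(aa.AffinityCurve("b", dose_series.doses_molar, sig))
        dose = mono_truth.kd
        pred, lo, hi = res.predict_with_bounds(dose, level=0.95)
        z_hat = np.log([res.params.ab, res.params.kd])
        L = np.linalg.cholesky(res.cov_log)
        draw_rng = np.random.default_rng(2024)
        eps = draw_rng.standard_normal((2000, 2))
        chi = draw_rng.chisquare(res.dof, 2000)
        draws = z_hat + (eps @ L.T) * np.sqrt(res.dof / chi)[:, None]
        preds = np.array(
            [
                aa.response_mono(dose, aa.BindingParamsMono(np.exp(a), np.exp(k)))
                for a, k in draws
            ]
        )
        boot_lo, boot_hi = np.quantile(preds, [0.025, 0.975])
        width = boot_hi - boot_lo
        assert lo[0] == pytest.approx(boot_lo, abs=0.2 * width)
        assert hi[0] == pytest.approx(boot_hi, abs=0.2 * width)

    def test_singular_covariance_gives_infinite_bounds(self, dose_series):
        curve = aa.AffinityCurve("f", dose_series.doses_molar, np.full(8, 500.0))
        res = aa.fit_monophasic(curve)
        _, lo, hi = res.predict_with_bounds(curve.min_dose, level=0.99)
        assert not np.isfinite(lo[0]) or not np.isfinite(hi[0]) or hi[0] - lo[0] > 0


class TestResultsObject:
    def test_summary_mentions_parameters(self, noiseless_bi_curve):
        text = aa.fit_biphasic(noiseless_bi_curve).summary()
        assert "K_D1" in text and "K_D(geo)" in text

    def test_kd_ci_brackets_estimate(self, dose_series, mono_truth):
        rng = np.random.default_rng(21)
        sig = lognormal_noise(
            aa.response_mono(dose_series.doses_molar, mono_truth), 0.08, rng
        )
        res = aa.fit_monophasic(aa.AffinityCurve("c", dose_series.doses_molar, sig))
        lo, hi = res.kd_ci(0.95)["kd"]
        assert lo < res.params.kd < hi

    def test_from_dataframe_roundtrip(self, noiseless_mono_curve):
        from ada_affinity.curves import curves_to_frame

        df = curves_to_frame([noiseless_mono_curve])
        model = FreeAdaBindingModel.from_dataframe(df, "mono0", phases=1)
        res = model.fit()
        assert res.params.kd == pytest.approx(2e-12, rel=1e-6)
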