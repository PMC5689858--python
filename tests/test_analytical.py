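"""Analytical models: the r variable, fitting procedures, predictions."""

import numpy as np
import pytest

import protonmu as pm
from protonmu.analytical import (
    FitError,
    basic_term_B,
    basic_term_C,
    fit_model_B,
    fit_model_C,
    convert_B_to_C,
)


class TestComputeR:
    def test_printed_constant_arithmetic(self):
        assert pm.compute_r(15.0, 10.0) == pytest.approx((14.69 - 8.1) / 8.1)
        assert pm.compute_r(15.0, 10.0) == pytest.approx(0.813580, abs=1e-6)
        assert pm.compute_r(25.0, 10.0) == pytest.approx(2.048148, abs=1e-6)

    def test_full_modulation_limit(self):
        conv = pm.RConversion()
        m = 10.0
        r_range = conv.delta_r + conv.rho_m * m
        assert pm.compute_r(r_range, m, conv) == pytest.approx(0.0)

    def test_monotonicity(self):
        rs = [pm.compute_r(20.0, m) for m in np.arange(2.0, 18.0, 0.5)]
        assert all(a > b for a, b in zip(rs, rs[1:]))  # decreasing in M
        rr = [pm.compute_r(r, 8.0) for r in np.arange(10.0, 25.0, 0.5)]
        assert all(a < b for a, b in zip(rr, rr[1:]))  # increasing in R

    def test_rejects_nonpositive_modulation(self):
        with pytest.raises(ValueError):
            pm.compute_r(15.0, 0.0)
        with pytest.raises(ValueError):
            pm.RConversion(delta_r=-0.1)


def _synthetic_option(a0=0.05, a1=0.55, s0=0.97, s1=0.012, amp=130.0,
                      r_l=12.6, r_max=15.0):
    """Noise-free measurements from a known analytical law."""
    params = pm.AnalyticalParams(option_id=20, r_l=r_l, r_max=r_max,
                                 cf=amp / 100.0, a0=a0, a1=a1, s0=s0, s1=s1)
    ms = np.array([2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
    rr, mm, psi = [], [], []
    for R in (r_max, round((r_l + r_max) / 2, 1), r_l):
        for m in ms:
            r = pm.compute_r(R, m)
            shift = s0 + s1 * (R - r_l)
            rr.append(R)
            mm.append(m)
            psi.append(amp / (1 + a0 * r**a1) * shift)
    return params, np.array(rr), np.array(mm), np.array(psi)


class TestFitModelB:
    def test_noise_free_parameter_recovery(self):
        truth, rr, mm, psi = _synthetic_option()
        # normalize the truth convention: the fit pins s(r_max) = 1
        scale = truth.s0 + truth.s1 * (truth.r_max - truth.r_l)
        fit = fit_model_B(rr, mm, psi, r_l=truth.r_l, r_max=truth.r_max)
        assert fit.a0 == pytest.approx(truth.a0, rel=1e-6)
        assert fit.a1 == pytest.approx(truth.a1, rel=1e-6)
        assert fit.amplitude == pytest.approx(truth.amplitude * scale, rel=1e-6)
        assert fit.s0 == pytest.approx(truth.s0 / scale, rel=1e-6)
        assert fit.s1 == pytest.approx(truth.s1 / scale, rel=1e-6)

    def test_noisy_fit_predicts_held_out_points(self, rng):
        truth, rr, mm, psi = _synthetic_option()
        noisy = psi * (1 + 0.005 * rng.standard_normal(len(psi)))
        fit = fit_model_B(rr, mm, noisy, r_l=truth.r_l, r_max=truth.r_max)
        for R, m in [(14.0, 5.0), (13.0, 9.0), (15.0, 11.0)]:
            r = pm.compute_r(R, m)
            want = (truth.amplitude / (1 + truth.a0 * r**truth.a1)
                    * (truth.s0 + truth.s1 * (R - truth.r_l)))
            got = float(basic_term_B(r, fit)) * (fit.s0 + fit.s1 * (R - fit.r_l))
            assert got == pytest.approx(want, rel=0.025)

    def test_constant_outputs_degenerate_to_a0_zero(self):
        rr = np.full(6, 15.0)
        mm = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        psi = np.full(6, 1.3)
        fit = fit_model_B(rr, mm, psi, r_l=12.6, r_max=15.0)
        assert fit.a0 == 0.0
        assert fit.diagnostics_b.degenerate
        assert float(basic_term_B(2.0, fit)) == pytest.approx(1.3)

    def test_insufficient_points_raise(self):
        with pytest.raises(FitError, match="stage 1"):
            fit_model_B(np.array([15.0, 15.0, 15.0]), np.array([2.0, 6.0, 10.0]),
                        np.array([1.2, 1.1, 1.0]), r_l=12.6, r_max=15.0)


class TestFitModelC:
    def test_quartic_through_five_points_interpolates(self):
        p_true = (120.0, -8.0, 1.1, -0.07, 0.002)
        rs = np.array([0.3, 1.0, 2.5, 5.0, 9.0])
        ms = (15.0 - 0.31) / (0.81 * (1 + rs))  # invert r(M) at fixed R
        psi = np.polyval(p_true[::-1], rs)
        fit = fit_model_C(np.full(5, 15.0), ms, psi, r_l=12.6, r_max=15.0)
        assert fit.diagnostics_c.residual_norm < 1e-9
        assert np.allclose(fit.p, p_true, rtol=1e-7, atol=1e-9)

    def test_eight_point_coefficient_recovery(self):
        p_true = (110.0, -6.0, 0.9, -0.05, 0.0015)
        rs = np.linspace(0.2, 10.0, 8)
        ms = (15.0 - 0.31) / (0.81 * (1 + rs))
        psi = np.polyval(p_true[::-1], rs)
        fit = fit_model_C(np.full(8, 15.0), ms, psi, r_l=12.6, r_max=15.0)
        for got, want in zip(fit.p, p_true):
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_rank_deficient_design_rejected(self):
        ms = np.full(6, 8.0)  # all the same r
        with pytest.raises(FitError, match="rank-deficient"):
            fit_model_C(np.full(6, 15.0), ms, np.ones(6), r_l=12.6, r_max=15.0)

    def test_quartic_collapse_and_independence(self):
        params = pm.AnalyticalParams(option_id=1, r_l=22.6, r_max=25.0,
                                     p=(117.0, 0, 0, 0, 0), s2=1.0, s3=0.0)
        assert float(basic_term_C(0.0, params)) == 117.0
        assert float(basic_term_C(5.0, params)) == 117.0  # p1..p4 = 0


class TestConvertBToC:
    def test_quartic_tracks_rational_form_within_one_percent(self):
        params_b = pm.AnalyticalParams(option_id=1, r_l=22.6, r_max=25.0,
                                       cf=1.2, a0=0.05, a1=0.55, s0=0.97,
                                       s1=0.01)
        span = (pm.compute_r(25.0, 20.0), pm.compute_r(25.0, 2.0))
        params_c = convert_B_to_C(params_b, span)
        rs = np.linspace(*span, 400)
        dev = basic_term_C(rs, params_c) / basic_term_B(rs, params_b) - 1
        assert np.max(np.abs(dev)) < 0.01
        assert params_c.s2 == params_b.s0 and params_c.s3 == params_b.s1

    def test_requires_fitted_model_b(self):
        empty = pm.AnalyticalParams(option_id=1, r_l=22.6, r_max=25.0)
        with pytest.raises(FitError):
            convert_B_to_C(empty, (0.5, 10.0))


class TestPredictions:
    def test_prediction_matches_direct_formula(self, noise_free_tables):
        params = pm.AnalyticalParams(option_id=18, r_l=17.6, r_max=20.0,
                                     cf=1.18, a0=0.04, a1=0.5, s0=0.96,
                                     s1=0.015)
        beam = pm.BeamSpec(18, 18.5, 7.0, pm.FieldSize.parse("10x10"))
        geom = pm.CalibrationGeometry(esad=176.0, dz_p=1.0, dz=2.0)
        pred = pm.predict_output_B(beam, geom, params, noise_free_tables)
        r = pm.compute_r(18.5, 7.0)
        expect = (118.0 / (1 + 0.04 * r**0.5)
                  * (0.96 + 0.015 * (18.5 - 17.6))
                  * pm.isf_ocf(geom)
                  * noise_free_tables.interp_ocr(18, 0, 0)
                  * noise_free_tables.interp_fsf(18, beam.field)
                  * noise_free_tables.gacf_for_option(18, 0.0))
        assert pred.psi == pytest.approx(expect, rel=1e-12)
        assert pred.factors["basic_model"] * pred.factors["source_shift"] * (
            pred.factors["ISF_OCF"] * pred.factors["OCR"]
            * pred.factors["FSF"] * pred.factors["GACF"]
        ) == pytest.approx(pred.psi, rel=1e-12)

    def test_unfitted_option_raises(self, noise_free_tables):
        empty = pm.AnalyticalParams(option_id=18, r_l=17.6, r_max=20.0)
        beam = pm.BeamSpec(18, 18.5, 7.0, pm.FieldSize.parse("10x10"))
        geom = pm.CalibrationGeometry(esad=176.0)
        with pytest.raises(FitError):
            pm.predict_output_B(beam, geom, empty, noise_free_tables)
        with pytest.raises(FitError):
            pm.predict_output_C(beam, geom, empty, noise_free_tables)

    def test_basic_term_strictly_decreasing_in_r(self):
        params = pm.AnalyticalParams(option_id=1, r_l=5.0, r_max=25.0,
                                     cf=1.0, a0=0.3, a1=0.7, s0=1.0, s1=0.0)
        rs = np.linspace(1e-6, 10.0, 500)
        vals = basic_term_B(rs, params)
        assert np.all(np.diff(vals) < 0)

    def test_negative_r_rejected_for_fractional_exponent(self):
        params = pm.AnalyticalParams(option_id=1, r_l=5.0, r_max=25.0,
                                     a0=0.1, a1=0.6, s0=1.0, s1=0.0)
        with pytest.raises(ValueError, match="domain"):
            basic_term_B(-0.5, params)

    def test_params_round_trip(self, tmp_path):
        truth, rr, mm, psi = _synthetic_option()
        fit_b = fit_model_B(rr, mm, psi, r_l=truth.r_l, r_max=truth.r_max,
                            option_id=20)
        fit_c = convert_B_to_C(fit_b, (0.2, 8.0))
        path = tmp_path / "params.json"
        pm.write_params({20: fit_b, 21: fit_c}, path)
        back = pm.read_params(path)
        assert back[20].a0 == fit_b.a0 and back[20].s1 == fit_b.s1
        assert back[21].p == fit_c.p
        assert back[20].diagnostics_b.n_points == fit_b.diagnostics_b.n_points
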