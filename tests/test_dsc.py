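import numpy as np
import pytest

from fibrilmorph.dsc import (
    R_GAS,
    Thermogram,
    enthalpy_ratio,
    excess_cp_model,
    fit_two_state,
    integrate_enthalpy,
    reversibility,
    subtract_baseline,
)
from fibrilmorph.errors import InvalidSpecError
from fibrilmorph.synthetic import ThermogramSimSpec, gen_thermogram


class TestExcessCpModel:
    def test_midpoint_value(self):
        T_d, hc, hv = 66.57, 432.2, 448.5
        Tm = T_d + 273.15
        expect = hc * hv / (4.0 * R_GAS * Tm**2)
        assert excess_cp_model(T_d, T_d, hc, hv) == pytest.approx(expect, rel=1e-12)

    def test_integral_equals_dh_cal(self, T_grid):
        cp = excess_cp_model(T_grid, 66.57, 432.2, 448.5)
        assert np.trapezoid(cp, T_grid) == pytest.approx(432.2, rel=0.01)

    def test_width_shrinks_with_dh_vh(self, T_grid):
        def fwhm(hv):
            cp = excess_cp_model(T_grid, 66.0, 400.0, hv)
            above = T_grid[cp >= cp.max() / 2]
            return above[-1] - above[0]

        widths = [fwhm(hv) for hv in (200.0, 400.0, 800.0, 1600.0)]
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_far_from_transition_is_zero(self, T_grid):
        cp = excess_cp_model(np.array([25.0, 110.0]), 66.57, 432.2, 448.5)
        assert np.all(np.abs(cp) < 1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            excess_cp_model(50.0, 66.0, -1.0, 400.0)
        with pytest.raises(ValueError):
            excess_cp_model(50.0, 66.0, 400.0, 0.0)


class TestSubtractBaseline:
    def test_pure_model_unchanged(self, clean_thermogram):
        out = subtract_baseline(clean_thermogram)
        # the model's tails are not exactly zero on a finite bracket, so
        # "unchanged" holds to well below the 1% peak-height tolerance
        assert np.max(np.abs(out.Cp - clean_thermogram.Cp)) < 1e-3

    @pytest.mark.parametrize("method", ["linear", "progress"])
    def test_tilt_recovery(self, T_grid, method):
        spec = ThermogramSimSpec(T_d=66.57, dH_cal=432.2, dH_vH=448.5,
                                 T_grid=T_grid, baseline_coeffs=(1.2, 0.03))
        tilted = gen_thermogram(spec)
        clean = excess_cp_model(T_grid, 66.57, 432.2, 448.5)
        out = subtract_baseline(tilted, method=method)
        assert np.max(np.abs(out.Cp - clean)) < 0.01 * clean.max()

    def test_all_zero(self, T_grid):
        tg = Thermogram(T=T_grid, Cp=np.zeros_like(T_grid))
        out = subtract_baseline(tg)
        np.testing.assert_allclose(out.Cp, 0.0)


class TestIntegrateEnthalpy:
    def test_paper_value(self, clean_thermogram):
        sub = subtract_baseline(clean_thermogram)
        assert integrate_enthalpy(sub) == pytest.approx(432.2, rel=0.01)

    def test_zero_curve(self, T_grid):
        tg = Thermogram(T=T_grid, Cp=np.zeros_like(T_grid), scan_index=2)
        assert integrate_enthalpy(tg) == 0.0

    def test_linearity(self, clean_thermogram):
        doubled = Thermogram(T=clean_thermogram.T, Cp=2 * clean_thermogram.Cp)
        assert integrate_enthalpy(doubled) == pytest.approx(
            2 * integrate_enthalpy(clean_thermogram), rel=1e-12)


class TestFitTwoState:
    def test_no_ils_ratio(self, clean_thermogram):
        fit = fit_two_state(subtract_baseline(clean_thermogram))
        assert fit.ratio == pytest.approx(448.5 / 432.2, abs=0.01)
        assert round(fit.ratio, 2) == 1.04

    def test_equal_enthalpies_ratio_one(self, T_grid):
        tg = gen_thermogram(ThermogramSimSpec(
            T_d=66.0, dH_cal=400.0, dH_vH=400.0, T_grid=T_grid))
        fit = fit_two_state(subtract_baseline(tg))
        assert fit.ratio == pytest.approx(1.0, abs=0.01)

    def test_noisy_td_recovery(self, T_grid):
        peak = excess_cp_model(66.57, 66.57, 432.2, 448.5)
        tg = gen_thermogram(ThermogramSimSpec(
            T_d=66.57, dH_cal=432.2, dH_vH=448.5, T_grid=T_grid,
            noise_sd=0.01 * peak, seed=3))
        fit = fit_two_state(subtract_baseline(tg))
        assert abs(fit.T_d - 66.57) <= 0.1

    def test_noiseless_roundtrip_tight(self, T_grid):
        tg = gen_thermogram(ThermogramSimSpec(
            T_d=60.38, dH_cal=307.7, dH_vH=412.9, T_grid=T_grid))
        fit = fit_two_state(subtract_baseline(tg))
        assert fit.T_d == pytest.approx(60.38, rel=1e-3)
        assert fit.dH_cal == pytest.approx(307.7, rel=1e-3)
        assert fit.dH_vH == pytest.approx(412.9, rel=1e-3)


class TestReversibility:
    def test_identical_scans(self, clean_thermogram):
        sub = subtract_baseline(clean_thermogram)
        assert reversibility(sub, sub) == pytest.approx(100.0)

    def test_scaled_second_scan(self, T_grid):
        spec = ThermogramSimSpec(T_d=66.57, dH_cal=432.2, dH_vH=448.5, T_grid=T_grid)
        first = subtract_baseline(gen_thermogram(spec, scan_index=1))
        second = subtract_baseline(gen_thermogram(spec, scan_index=2, scale=0.98))
        assert reversibility(first, second) == pytest.approx(98.0, abs=0.2)

    def test_zero_second_scan(self, clean_thermogram, T_grid):
        sub = subtract_baseline(clean_thermogram)
        zero = Thermogram(T=T_grid, Cp=np.zeros_like(T_grid), scan_index=2,
                          baseline_subtracted=True)
        assert reversibility(sub, zero) == 0.0

    def test_zero_first_scan_rejected(self, clean_thermogram, T_grid):
        zero = Thermogram(T=T_grid, Cp=np.zeros_like(T_grid), baseline_subtracted=True)
        with pytest.raises(ValueError):
            reversibility(zero, subtract_baseline(clean_thermogram))


class TestEnthalpyRatio:
    def test_paper_rows(self):
        assert round(enthalpy_ratio(399.90, 512.60), 2) == 1.28
        assert round(enthalpy_ratio(307.70, 412.90), 2) == 1.34

    def test_identity(self):
        assert enthalpy_ratio(5.0, 5.0) == 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            enthalpy_ratio(0.0, 1.0)


class TestSimSpecValidation:
    def test_grid_must_bracket(self):
        with pytest.raises(InvalidSpecError):
            ThermogramSimSpec(T_d=66.0, dH_cal=400.0, dH_vH=400.0,
                              T_grid=np.arange(60.0, 110.0, 0.5))

    def test_positive_enthalpies(self, T_grid):
        with pytest.raises(InvalidSpecError):
            ThermogramSimSpec(T_d=66.0, dH_cal=-1.0, dH_vH=400.0, T_grid=T_grid)
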