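"""Unit and property tests for the decay models and their fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phonesmf as p
from phonesmf.constants import MU0
from phonesmf.decay_models import SLCFit
from phonesmf.fieldmap import DecayCurve

Z_STUDY = np.asarray(p.Z_LEVELS_MM)


class TestSlcField:
    @pytest.mark.parametrize(
        "r, I, T, expected_mT",
        [
            (8.0, 17.2, 8.4, 4.69),  # model 1 upper
            (8.0, 2.59, 7.7, 0.74),  # model 2 lower
        ],
    )
    def test_screen_extrapolation(self, r, I, T, expected_mT):
        fit = SLCFit(r_mm=r, I_mA=I, T_mm=T)
        assert fit.B_at_0_mT == pytest.approx(expected_mT, abs=0.005)

    def test_below_loop_plane_rejected(self, model1_upper_fit):
        with pytest.raises(ValueError):
            p.slc_field(-5.0, model1_upper_fit)

    def test_far_field_is_dipole(self, model1_upper_fit):
        # at 100 loop radii from the loop plane the field is a point dipole
        f = model1_upper_fit
        h = 100.0 * f.r_mm
        z = h - f.T_mm / 2.0
        dipole_uT = 1e6 * f.mu_r * MU0 * f.I_mA * f.r_mm**2 / (2.0 * h**3)
        assert p.slc_field(z, f) == pytest.approx(dipole_uT, rel=1e-3)

    def test_strictly_positive_and_decreasing_above_screen(self):
        z = np.linspace(0.0, 100.0, 400)
        for _, hs in p.all_hotspots():
            b = p.slc_field(z, hs.slc)
            assert np.all(b > 0)
            assert np.all(np.diff(b) < 0)

    def test_doubling_current_doubles_field(self, model1_upper_fit):
        f2 = SLCFit(
            r_mm=model1_upper_fit.r_mm,
            I_mA=2 * model1_upper_fit.I_mA,
            T_mm=model1_upper_fit.T_mm,
        )
        z = np.array([0.0, 15.0, 55.0])
        assert np.allclose(p.slc_field(z, f2), 2 * p.slc_field(z, model1_upper_fit))

    @given(T=st.floats(5.0, 12.0), T_extra=st.floats(0.5, 5.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_screen_field_decreases_with_thickness(self, T, T_extra):
        thin = SLCFit(r_mm=8.0, I_mA=17.2, T_mm=T)
        thick = SLCFit(r_mm=8.0, I_mA=17.2, T_mm=T + T_extra)
        assert thick.B_at_0_mT < thin.B_at_0_mT


class TestSlcGradient:
    def test_zero_at_loop_plane(self, model1_upper_fit):
        assert p.slc_gradient(-model1_upper_fit.T_mm / 2.0, model1_upper_fit) == 0.0

    @pytest.mark.parametrize("z", [0.0, 4.0, 15.0, 55.0])
    def test_matches_central_finite_difference(self, z):
        h = 1e-3
        for _, hs in p.all_hotspots():
            analytic = p.slc_gradient(z, hs.slc)
            numeric = (p.slc_field(z + h, hs.slc) - p.slc_field(z - h, hs.slc)) / (2 * h)
            assert analytic == pytest.approx(numeric, rel=1e-6)

    def test_screen_gradient_extremes(self):
        # model 4 upper is the steepest source (~1.1 mT/mm), model 2 lower
        # the shallowest (~0.1 mT/mm)
        steep = p.REFERENCE_PHONES[3].hotspots[0].slc
        shallow = p.REFERENCE_PHONES[1].hotspots[1].slc
        assert abs(p.slc_gradient(0.0, steep)) / 1e3 == pytest.approx(1.1, abs=0.05)
        assert abs(p.slc_gradient(0.0, shallow)) / 1e3 == pytest.approx(0.11, abs=0.01)

    def test_gradient_magnitude_decreasing_beyond_near_zone(self):
        for _, hs in p.all_hotspots():
            f = hs.slc
            z_start = max(0.0, f.r_mm / 2.0 - f.T_mm / 2.0)
            z = np.linspace(z_start, 100.0, 400)
            g = np.abs(p.slc_gradient(z, f))
            assert np.all(np.diff(g) < 0)


class TestFits:
    def test_slc_round_trip_noiseless(self, noiseless_curves):
        curve = noiseless_curves[("1", "UPPER")]
        fit = p.fit_slc(curve, T_mm=8.4)
        assert fit.r_mm == pytest.approx(8.0, rel=1e-6)
        assert fit.I_mA == pytest.approx(17.2, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_curve_rejected(self):
        curve = DecayCurve(z_mm=Z_STUDY, B_uT=np.full(5, 50.0))
        with pytest.raises(ValueError, match="constant"):
            p.fit_slc(curve, T_mm=8.4)

    def test_nonpositive_values_rejected(self):
        curve = DecayCurve(z_mm=Z_STUDY, B_uT=np.array([5.0, 4.0, 3.0, 2.0, 0.0]))
        with pytest.raises(ValueError):
            p.fit_slc(curve, T_mm=8.4)

    def test_exponential_exact_recovery(self):
        # a = 0.93 mT, b = 0.074 /mm (the model-1 upper regression)
        a_mT, b = 0.93, 0.074
        curve = DecayCurve(z_mm=Z_STUDY, B_uT=a_mT * 1e3 * np.exp(-b * Z_STUDY))
        fit = p.fit_exponential(curve)
        assert fit.a == pytest.approx(a_mT, rel=1e-9)
        assert fit.b == pytest.approx(b, rel=1e-9)
        assert fit.B_at_0_mT == pytest.approx(a_mT)

    def test_power_has_no_finite_screen_value(self):
        fit = p.RegressionFit("power", a=250029.0, b=2.369)
        assert math.isinf(fit.B_at_0_mT)

    def test_power_fit_requires_positive_z(self):
        curve = DecayCurve(z_mm=np.array([0.0, 10.0, 20.0]), B_uT=np.array([9.0, 4.0, 1.0]))
        with pytest.raises(ValueError):
            p.fit_power(curve)

    def test_ranking_on_slc_generated_curve(self, noiseless_curves):
        curve = noiseless_curves[("1", "UPPER")]
        ranked = p.compare_fits(curve, T_mm=8.4)
        assert list(ranked["family"]) == ["slc", "power", "exponential"]
        assert not ranked.attrs["low_dof"]

    def test_exponential_ranks_first_on_exponential_data(self):
        curve = DecayCurve(z_mm=Z_STUDY, B_uT=930.0 * np.exp(-0.074 * Z_STUDY))
        ranked = p.compare_fits(curve, T_mm=8.4)
        assert ranked.iloc[0]["family"] == "exponential"

    def test_minimal_curve_flagged_low_dof(self):
        f = SLCFit(r_mm=8.0, I_mA=17.2, T_mm=8.4)
        z = np.array([15.0, 25.0, 55.0])
        ranked = p.compare_fits(DecayCurve(z_mm=z, B_uT=p.slc_field(z, f)), T_mm=8.4)
        assert ranked.attrs["low_dof"]

    def test_mu_r_and_current_are_degenerate(self, noiseless_curves):
        # fitting with mu_r = 1 recovers a current exactly 5000x larger while
        # predicting identical fields: only the product mu_r * I is identified
        curve = noiseless_curves[("1", "UPPER")]
        with_core = p.fit_slc(curve, T_mm=8.4, mu_r=5000.0)
        bare = p.fit_slc(curve, T_mm=8.4, mu_r=1.0)
        assert bare.I_mA / with_core.I_mA == pytest.approx(5000.0, rel=1e-4)
        z = np.linspace(0, 55, 12)
        assert np.allclose(p.slc_field(z, bare), p.slc_field(z, with_core), rtol=1e-6)

    def test_weighted_fit_requires_uncertainties(self, noiseless_curves):
        with pytest.raises(ValueError):
            p.fit_slc(noiseless_curves[("1", "UPPER")], T_mm=8.4, weighted=True)


class TestThresholdDistance:
    def test_model3_upper_reaches_furthest(self):
        fit = p.REFERENCE_PHONES[2].hotspots[0].slc
        res = p.threshold_distance(fit, 0.02)
        assert res.above_at_screen
        assert res.z_mm == pytest.approx(27.4, abs=0.1)
        # the solution really is on the threshold contour
        assert abs(p.slc_gradient(res.z_mm, fit)) == pytest.approx(20.0, abs=0.05)

    def test_below_threshold_at_screen_flagged(self, model1_upper_fit):
        res = p.threshold_distance(model1_upper_fit, g_threshold_mT_per_mm=5.0)
        assert res.z_mm == 0.0
        assert not res.above_at_screen

    def test_invalid_threshold_rejected(self, model1_upper_fit):
        with pytest.raises(ValueError):
            p.threshold_distance(model1_upper_fit, 0.0)

    def test_vanishing_threshold_guarded(self, model1_upper_fit):
        with pytest.raises(ValueError, match="threshold"):
            p.threshold_distance(model1_upper_fit, 1e-12)


class TestInducedRate:
    @pytest.mark.parametrize(
        "B_mT, dt_s, expected", [(1.0, 1.0, 1.0), (1.0, 0.1, 10.0), (6.6, 1.0, 6.6)]
    )
    def test_rate(self, B_mT, dt_s, expected):
        assert p.induced_rate_estimate(B_mT, dt_s) == pytest.approx(expected)

    def test_largest_screen_field_rate_within_expected_band(self):
        # the strongest extrapolated screen field, moved to the head in 0.1-1 s,
        # gives a transient dB/dt of order 1-10 mT/s
        b_max = max(hs.slc.B_at_0_mT for _, hs in p.all_hotspots())
        assert 1.0 <= p.induced_rate_estimate(b_max, 1.0) <= 10.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            p.induced_rate_estimate(1.0, 0.0)
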