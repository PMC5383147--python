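"""Tests for the closed-form layer: Beer–Lambert limits, the transient dose
correction, the analytic crosslink time, the mean-intensity efficacy
approximation and its exact inverse, the Wegscheider oracle, and the
steady-state criterion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cxlsim import (
    IrradiationProtocol,
    PhotochemParams,
    RiboflavinProfile,
    S_approx,
    UnattainableEfficacyError,
    crosslink_time_analytic,
    crosslink_time_numeric,
    effective_dose_approx,
    efficacy_approx,
    exposure_time_for_efficacy,
    initial_intensity,
    rf_concentration_approx,
    steady_intensity,
    steady_state_reached,
    transient_correction,
    wegscheider_S,
)

HYP = settings(max_examples=40, deadline=None, derandomize=True)


class TestIntensityForms:
    def test_surface_values(self, params, rf01, proto_10mw):
        assert initial_intensity(0.0, rf01, params, proto_10mw) == pytest.approx(10.0)
        assert steady_intensity(0.0, rf01, params, proto_10mw) == pytest.approx(10.0)

    def test_values_at_400um(self, params, rf01, proto_10mw):
        # A1(0.04) = 69.51, A2(0.04) = 41.17
        assert initial_intensity(0.04, rf01, params, proto_10mw) == pytest.approx(0.620, abs=2e-3)
        assert steady_intensity(0.04, rf01, params, proto_10mw) == pytest.approx(1.926, abs=2e-3)

    @HYP
    @given(z=st.floats(0.0, 0.1), eps2=st.floats(0.0, 204.0))
    def test_bleached_never_darker(self, rf01, z, eps2):
        """Steady (bleached) intensity ≥ initial intensity whenever ε₂ ≤ ε₁."""
        p = PhotochemParams(epsilon2=eps2)
        proto = IrradiationProtocol(I0=10.0, t_end=1.0)
        assert steady_intensity(z, rf01, p, proto) >= initial_intensity(z, rf01, p, proto) - 1e-15


class TestTransientDose:
    def test_correction_vanishes_at_surface(self, params, rf01, proto_10mw):
        tc = transient_correction(params, rf01, proto_10mw)
        assert tc.g(0.0) == pytest.approx(0.0, abs=1e-12)
        assert tc.T == pytest.approx(12.0 / (params.a * 10.0))
        assert effective_dose_approx(0.0, 10.0, params, rf01, proto_10mw) == pytest.approx(100.0)

    def test_correction_nonnegative(self, params, rf01, proto_10mw):
        z = np.linspace(0.0, 0.05, 51)
        assert np.all(transient_correction(params, rf01, proto_10mw).g(z) >= 0)

    def test_equal_extinctions_no_correction(self, rf01, proto_10mw):
        p = PhotochemParams(epsilon1=204.0, epsilon2=204.0)
        z = 0.03
        from cxlsim import absorption_A
        A2 = absorption_A("steady", z, rf01, p)
        E = effective_dose_approx(z, 10.0, p, rf01, proto_10mw)
        assert E == pytest.approx(100.0 * math.exp(-A2 * z))

    def test_dose_tracks_solver(self, fields_10mw, params, rf01, proto_10mw):
        """The corrected dose stays within ~25 % of the solved dose down to
        400 µm (measured ≈ 6 %)."""
        iz = slice(0, 401)
        z = fields_10mw.z[iz]
        approx = effective_dose_approx(z, 10.0, params, rf01, proto_10mw)
        exact = fields_10mw.E[iz, -1]
        assert np.max(np.abs(approx - exact) / exact) < 0.25

    def test_concentration_surface_form(self, params, rf01, proto_10mw):
        """At z = 0 the approximation collapses to the exact C₀·exp(−aE₀)."""
        C = rf_concentration_approx(0.0, 10.0, params, rf01, proto_10mw)
        assert C == pytest.approx(0.1 * math.exp(-params.a * 100.0), rel=1e-9)

    def test_concentration_tracks_depletion_scale(self, fields_10mw, params, rf01, proto_10mw):
        """The approximate concentration follows the solver to within a few
        percent of the local initial concentration C₀F(z).  (Pointwise
        relative error is exponentially amplified where the riboflavin is
        nearly exhausted, so C₀F is the meaningful scale.)"""
        iz = slice(0, 401)
        z = fields_10mw.z[iz]
        approx = rf_concentration_approx(z, 10.0, params, rf01, proto_10mw)
        exact = fields_10mw.C[iz, -1]
        scale = rf01.concentration(z)
        assert np.max(np.abs(approx - exact) / scale) < 0.05


class TestCrosslinkTimeAnalytic:
    def test_surface_time_and_dose(self, params, rf01, proto_10mw):
        """T₀ = 1.285 s at M=4, I₀=10, φ=0.5; surface dose I₀T₀ ≈ 12.9 mJ/cm²."""
        T0 = crosslink_time_analytic(0.0, params, rf01, proto_10mw, M=4.0)
        assert T0 == pytest.approx(4.0 / (params.a * 10.0), rel=1e-12)
        assert T0 == pytest.approx(1.3, rel=0.02)
        assert 10.0 * T0 == pytest.approx(13.0, rel=0.02)      # mJ/cm²

    def test_coefficient_of_inverse_intensity(self, params, rf01):
        """T₀·I₀·φ is a constant ≈ 6.43 s·mW/cm² for M = 4."""
        for I0, phi in [(10.0, 0.5), (30.0, 0.3)]:
            p = PhotochemParams(phi=phi)
            proto = IrradiationProtocol(I0=I0, t_end=1.0)
            T0 = crosslink_time_analytic(0.0, p, rf01, proto, M=4.0)
            assert T0 * I0 * phi == pytest.approx(6.44, rel=0.005)

    def test_scales_linearly_with_depletion_level(self, params, rf01, proto_10mw):
        t4 = crosslink_time_analytic(0.0, params, rf01, proto_10mw, M=4.0)
        t2 = crosslink_time_analytic(0.0, params, rf01, proto_10mw, M=2.0)
        assert t4 == pytest.approx(2.0 * t2, rel=1e-12)

    def test_tracks_numeric_time(self, params, rf01):
        """Fitted approximation: within ~25 % of the solver down to 300 µm
        (measured ≈ 20 %)."""
        proto = IrradiationProtocol(I0=10.0, t_end=60.0)
        ct = crosslink_time_numeric(params, rf01, proto, M=4.0)
        iz = slice(0, 301)
        Ta = crosslink_time_analytic(ct.z[iz], params, rf01, proto, M=4.0)
        rel = np.abs(Ta - ct.T_star[iz]) / ct.T_star[iz]
        assert np.nanmax(rel) < 0.25


class TestEfficacyApproximation:
    def test_steady_surface_ceiling(self, params, rf01, proto_10mw):
        """As t → ∞ at z = 0, S saturates at √(4KC₀/(aI₀))."""
        expected = math.sqrt(4 * params.K * 0.1 / (params.a * 10.0))
        assert S_approx(0.0, 1e4, params, rf01, proto_10mw) == pytest.approx(expected, rel=1e-9)

    def test_sqrt_concentration_intensity_scaling(self, params):
        """Steady surface efficacy exponent scales as √(C₀/I₀)."""
        def S(C0, I0):
            rf = RiboflavinProfile(C0=C0, D=0.05)
            return S_approx(0.0, 1e5, params, rf, IrradiationProtocol(I0=I0, t_end=1.0))
        assert S(0.2, 10.0) / S(0.1, 10.0) == pytest.approx(math.sqrt(2.0), rel=1e-9)
        assert S(0.1, 30.0) / S(0.1, 10.0) == pytest.approx(1 / math.sqrt(3.0), rel=1e-9)

    def test_matched_dose_intensity_ordering(self, params, rf01):
        """At a fixed dose of 0.1 J/cm², lower intensity gives higher efficacy
        at every depth (5 > 10 > 20 > 30 mW/cm²)."""
        z = np.linspace(0.0, 0.05, 101)
        curves = [
            efficacy_approx(z, 100.0 / I0, params, rf01, IrradiationProtocol(I0=I0, t_end=100.0 / I0))
            for I0 in (5.0, 10.0, 20.0, 30.0)
        ]
        for lo, hi in zip(curves[1:], curves[:-1]):
            assert np.all(hi > lo)


class TestExposureTimeInversion:
    @HYP
    @given(target=st.floats(0.01, 0.3), zfrac=st.floats(0.0, 0.8))
    def test_round_trip_inverse(self, params, rf01, target, zfrac):
        """exposure_time_for_efficacy is the exact inverse of S_approx."""
        z = zfrac * 0.05
        proto = IrradiationProtocol(I0=10.0, t_end=1.0)
        try:
            t = exposure_time_for_efficacy(target, z, params, rf01, proto)
        except UnattainableEfficacyError:
            return
        S = S_approx(z, t, params, rf01, proto)
        assert S == pytest.approx(-math.log1p(-target), rel=1e-10)

    def test_unattainable_target_raises_with_ceiling(self, params, rf01, proto_10mw):
        with pytest.raises(UnattainableEfficacyError) as exc:
            exposure_time_for_efficacy(0.9, 0.0, params, rf01, proto_10mw)
        ceiling = 1 - math.exp(-math.sqrt(4 * params.K * 0.1 / (params.a * 10.0)))
        assert exc.value.ceiling == pytest.approx(ceiling, rel=1e-9)

    def test_invalid_target_rejected(self, params, rf01, proto_10mw):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                exposure_time_for_efficacy(bad, 0.0, params, rf01, proto_10mw)

    def test_small_demand_inverse_sqrt_intensity(self, params, rf01):
        """In the small-demand limit the required time scales as I₀^(−1/2):
        quadrupling the intensity halves (not quarters) the exposure."""
        t1 = exposure_time_for_efficacy(0.01, 0.0, params, rf01, IrradiationProtocol(I0=10.0, t_end=1.0))
        t4 = exposure_time_for_efficacy(0.01, 0.0, params, rf01, IrradiationProtocol(I0=40.0, t_end=1.0))
        assert t1 / t4 == pytest.approx(2.0, rel=0.02)


class TestWegscheiderOracle:
    def test_surface_limit_matches_mean_intensity_form(self, oracle_setup):
        """The z → 0 limit of the exact solution is √(4KC₀/(aI₀))·(1−Ē) —
        identically S_approx at the surface with Q = 0."""
        params, profile, protocol = oracle_setup
        for t in (0.5, 2.0, 10.0):
            exact = wegscheider_S(0.0, t, params, profile, protocol)
            approx = S_approx(0.0, t, params, profile, protocol)
            assert exact == pytest.approx(approx, rel=1e-9)

    def test_continuous_at_small_depth(self, oracle_setup):
        params, profile, protocol = oracle_setup
        vals = wegscheider_S(np.array([0.0, 1e-9, 1e-7, 1e-5]), 5.0, params, profile, protocol)
        assert np.all(np.abs(np.diff(vals)) < 1e-4 * vals[0])

    def test_long_time_limit(self, oracle_setup):
        params, profile, protocol = oracle_setup
        z = 0.02
        A = 2.3 * params.epsilon1 * profile.C0
        E2 = math.exp(A * z)
        expected = (
            math.sqrt(4 * params.K * profile.C0 / (params.a * protocol.I0))
            * math.sqrt(E2 / (E2 - 1)) * math.atan(math.sqrt(E2 - 1))
        )
        assert wegscheider_S(z, 1e5, params, profile, protocol) == pytest.approx(expected, rel=1e-9)

    def test_preconditions_enforced(self, rf01, proto_10mw):
        with pytest.raises(ValueError, match="Q = 0"):
            wegscheider_S(0.0, 1.0, PhotochemParams(Q=13.9, epsilon2=0.0), rf01, proto_10mw)
        with pytest.raises(ValueError, match="epsilon2 = 0"):
            wegscheider_S(0.0, 1.0, PhotochemParams(Q=0.0, epsilon2=50.0), rf01, proto_10mw)

    def test_solver_agrees_with_exact_solution(self, oracle_fields, oracle_setup):
        """Numerical S within 1 % of the closed form over the full domain —
        the justification of the finite-difference scheme."""
        params, profile, protocol = oracle_setup
        for t in (0.5, 1.0, 5.0, 15.0, 30.0):
            S_num = oracle_fields.at_time("S", t)
            S_ex = wegscheider_S(oracle_fields.z, t, params, profile, protocol)
            assert np.max(np.abs(S_num - S_ex) / S_ex) < 0.01


class TestSteadyStateCriterion:
    def test_zero_time_is_transient(self, params, rf01, proto_10mw):
        assert not steady_state_reached(0.0, 0.0, params, rf01, proto_10mw)

    def test_surface_threshold_time(self, params, rf01, proto_10mw):
        """Surface threshold t = 2·ln(1/0.133)/(a·I₀) ≈ 1.296 s at I₀ = 10."""
        t_thr = 2.0 * math.log(1 / 0.133) / (params.a * 10.0)
        assert t_thr == pytest.approx(1.296, abs=2e-3)
        assert not steady_state_reached(0.0, t_thr * 0.99, params, rf01, proto_10mw)
        assert steady_state_reached(0.0, t_thr * 1.01, params, rf01, proto_10mw)

    def test_threshold_deepens_with_depth(self, params, rf01, proto_10mw):
        """A time that is steady at the surface may still be transient at
        depth, never the reverse."""
        for t in (2.0, 5.0, 20.0):
            flags = steady_state_reached(np.linspace(0, 0.05, 51), t, params, rf01, proto_10mw)
            assert np.all(flags[1:] <= flags[:-1])
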