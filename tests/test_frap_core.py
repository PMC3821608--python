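"""Tests of FRAP trace normalization, half-time extraction and the
obstruction-model diffusivity rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strutdiff.errors import (
    DomainError,
    InsufficientRecoveryError,
    InvalidBleachError,
    MalformedInputError,
    UnphysicalRatioError,
)
from strutdiff.frap import (
    HALF_TIME_COEF,
    RecoveryCurve,
    analyze_curve,
    average_curves,
    decompose_kappa,
    diffusion_from_half_time,
    estimate_half_time,
    normalize_recovery,
    obstruction_parameter,
    rescale_diffusion,
)
from strutdiff.frap_synth import soumpasis_half_time

from conftest import D_DEXTRAN_WATER


class TestNormalizeRecovery:
    def test_limits_and_midpoint(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        # no recovery: F stays at F_0 -> f = 0
        c = normalize_recovery(t, np.full(4, 100.0), f_pre=200.0)
        assert np.allclose(c.f, 0.0)
        # immediate full recovery after the first sample -> f = 1
        c = normalize_recovery(t, np.array([100.0, 200.0, 200.0, 200.0]), f_pre=200.0)
        assert np.allclose(c.f[1:], 1.0)
        # midpoint intensity maps to f = 0.5 by construction
        c = normalize_recovery(t, np.array([100.0, 150.0, 180.0, 200.0]), f_pre=200.0)
        assert c.f[1] == pytest.approx(0.5)

    def test_time_shift_to_bleach_end(self):
        t = np.array([12.0, 13.0, 14.0])
        c = normalize_recovery(t, np.array([50.0, 80.0, 90.0]), f_pre=100.0)
        assert c.times[0] == 0.0
        assert np.allclose(np.diff(c.times), 1.0)

    def test_invalid_bleach_rejected(self):
        t = np.array([0.0, 1.0, 2.0])
        with pytest.raises(InvalidBleachError):
            normalize_recovery(t, np.array([100.0, 110.0, 120.0]), f_pre=90.0)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(MalformedInputError):
            normalize_recovery(
                np.array([0.0, 2.0, 1.0]), np.array([1.0, 2.0, 3.0]), f_pre=10.0
            )

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_intensity_rescaling(self, scale):
        """Multiplying all raw intensities by a positive constant leaves
        the normalized curve unchanged (pipeline linearity)."""
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        raw = np.array([100.0, 130.0, 155.0, 180.0, 196.0])
        base = normalize_recovery(t, raw, f_pre=200.0)
        scaled = normalize_recovery(t, raw * scale, f_pre=200.0 * scale)
        assert np.allclose(base.f, scaled.f, rtol=1e-12, atol=1e-12)


class TestHalfTime:
    def test_exact_crossing_of_hyperbolic_curve(self):
        # f(t) = t/(1+t) passes through 0.5 exactly at t = 1
        t = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        c = RecoveryCurve(times=t, f=t / (1 + t), omega=50.0)
        assert estimate_half_time(c) == pytest.approx(1.0)

    def test_interpolated_crossing_between_samples(self):
        t = np.array([0.0, 1.0, 2.0])
        c = RecoveryCurve(times=t, f=np.array([0.0, 0.4, 0.8]), omega=50.0)
        # linear interpolation between (1, 0.4) and (2, 0.8)
        assert estimate_half_time(c) == pytest.approx(1.25)

    def test_soumpasis_curve_half_time_matches_coefficient(self, soumpasis_curve):
        """Half-time read from the sampled closed form agrees with the
        uniform-disk coefficient within 2%."""
        t_half = estimate_half_time(soumpasis_curve)
        expected = HALF_TIME_COEF * 50.0**2 / (D_DEXTRAN_WATER * 1e8)
        assert t_half == pytest.approx(expected, rel=0.02)
        # and against the root-finding oracle on the closed form itself
        assert t_half == pytest.approx(
            soumpasis_half_time(50.0, D_DEXTRAN_WATER), rel=0.02
        )

    def test_flat_curve_raises_with_diagnostics(self):
        t = np.arange(5.0)
        c = RecoveryCurve(times=t, f=np.full(5, 0.3), omega=50.0)
        with pytest.raises(InsufficientRecoveryError) as exc:
            estimate_half_time(c)
        assert exc.value.max_f == pytest.approx(0.3)

    def test_soumpasis_fit_method(self, soumpasis_curve):
        res = analyze_curve(soumpasis_curve, method="soumpasis_fit")
        assert res.D == pytest.approx(D_DEXTRAN_WATER, rel=0.01)
        assert res.fit_residual < 1e-6


class TestDiffusionFromHalfTime:
    def test_water_reference_value(self):
        # 0.224 * (50e-4 cm)^2 / 4.375 s = 1.28e-6 cm^2/s
        assert diffusion_from_half_time(4.375, 50.0) == pytest.approx(1.28e-6)

    def test_scaling_laws(self):
        d = diffusion_from_half_time(4.0, 50.0)
        assert diffusion_from_half_time(8.0, 50.0) == pytest.approx(d / 2)
        assert diffusion_from_half_time(4.0, 100.0) == pytest.approx(4 * d)

    @pytest.mark.parametrize("t_half,omega", [(0.0, 50.0), (-1.0, 50.0), (4.0, 0.0)])
    def test_domain_errors(self, t_half, omega):
        with pytest.raises(DomainError):
            diffusion_from_half_time(t_half, omega)


class TestObstructionModel:
    def test_free_diffusion_gives_zero_kappa(self):
        assert obstruction_parameter(1.0, 1.2).kappa == 0.0

    def test_log_cancellation(self):
        p = obstruction_parameter(math.exp(-1.0), 1.2)
        assert p.kappa == pytest.approx(1 / 1.2)

    def test_dextran_reference_kappa(self):
        # -ln(0.59)/1.2 by independent arithmetic
        p = obstruction_parameter(0.59, 1.2)
        assert p.kappa == pytest.approx(0.43969, rel=1e-4)

    def test_unphysical_and_domain_errors(self):
        with pytest.raises(UnphysicalRatioError):
            obstruction_parameter(1.1, 1.2)
        with pytest.raises(DomainError):
            obstruction_parameter(0.0, 1.2)
        with pytest.raises(DomainError):
            obstruction_parameter(0.5, -1.0)

    def test_oxygen_rescaling_from_dextran(self):
        """Dextran ratio 0.59 at 1.2 nm rescaled to a 0.14 nm solute with
        free diffusivity 2.68e-5 gives ~2.52e-5 cm^2/s."""
        p = obstruction_parameter(0.59, 1.2)
        d = rescale_diffusion(p, 0.14, 2.68e-5)
        assert d == pytest.approx(2.68e-5 * 0.59 ** (0.14 / 1.2))
        assert d == pytest.approx(2.52e-5, rel=1e-3)

    def test_round_trip_reproduces_reference_ratio(self):
        p = obstruction_parameter(0.59, 1.2)
        assert rescale_diffusion(p, 1.2, 1.0) == pytest.approx(0.59, rel=1e-12)

    @given(
        d_ratio=st.floats(min_value=0.05, max_value=0.999),
        r_ref=st.floats(min_value=0.1, max_value=10.0),
        r_a=st.floats(min_value=0.1, max_value=5.0),
        dr=st.floats(min_value=0.01, max_value=5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_solute_radius(self, d_ratio, r_ref, r_a, dr):
        p = obstruction_parameter(d_ratio, r_ref)
        assert rescale_diffusion(p, r_a + dr, 1.0) < rescale_diffusion(p, r_a, 1.0)

    def test_kappa_decomposition_is_linear_in_fiber_radius(self):
        p = obstruction_parameter(0.59, 1.2)
        assert decompose_kappa(p, 1000.0) == pytest.approx(p.kappa * 1000.0)


class TestCurveContainersAndAveraging:
    def test_recovery_curve_validation(self):
        with pytest.raises(MalformedInputError):
            RecoveryCurve(times=np.array([0.0, 1.0]), f=np.array([0.0, 0.5]), omega=50)
        with pytest.raises(MalformedInputError):
            RecoveryCurve(
                times=np.array([0.0, 1.0, 1.0]), f=np.array([0.0, 0.5, 0.6]), omega=50
            )
        with pytest.raises(MalformedInputError):
            RecoveryCurve(
                times=np.array([0.0, 1.0, 2.0]), f=np.array([0.0, 1.5, 0.6]), omega=50
            )

    def test_average_of_identical_curves_is_identity(self):
        t = np.linspace(0, 10, 30)
        f = t / (1 + t)
        curves = [RecoveryCurve(times=t, f=f, omega=50.0) for _ in range(5)]
        mean, sd = average_curves(curves)
        # double linear interpolation onto the common grid and back costs
        # a little accuracy where the curve is most curved
        assert np.allclose(np.interp(t, mean.times, mean.f), f, atol=5e-3)
        assert np.allclose(sd, 0.0)

    def test_average_reports_spread(self):
        t = np.linspace(0, 10, 30)
        rng = np.random.default_rng(0)
        curves = [
            RecoveryCurve(times=t, f=np.clip(t / (1 + t) + rng.normal(0, 0.02, 30), -0.1, 1.2), omega=50.0)
            for _ in range(6)
        ]
        mean, sd = average_curves(curves)
        assert mean.meta["n_replicates"] == 6
        assert 0.0 < np.median(sd) < 0.1
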