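"""Differential model: forward exponential, inverse logarithm, observables."""

import math

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from mmtomo.calibration import AIR, QUARTER_WAVE
from mmtomo.core import (
    AnisotropyParams,
    MuellerMatrix,
    NonPhysicalMatrixError,
    build_differential,
    decompose_differential,
    depolarization_degree,
    forward_mueller,
    generalized_linear,
    params_from_optics,
    reconstruct_differential,
)
from mmtomo._linalg import g_split, logm_stack
from mmtomo.geometry import InvalidGeometryError, MeasurementGeometry, OpticalConstants

from conftest import random_params

PARAM_NAMES = ("phi_0_90", "phi_45_135", "phi_circ", "delta_0_90", "delta_45_135", "delta_circ")


class TestParamsFromOptics:
    def test_quarter_wave_index_difference_gives_half_pi(self):
        geom = MeasurementGeometry(wavelength=0.6328, thickness=40.0)
        dn = geom.wavelength / (4.0 * geom.thickness)
        oc = OpticalConstants(n={"0": 1.5 + dn, "90": 1.5})
        p = params_from_optics(oc, geom)
        assert p.phi_0_90 == pytest.approx(np.pi / 2, rel=1e-12)
        assert all(getattr(p, n) == 0 for n in PARAM_NAMES[1:])

    def test_isotropic_medium_has_no_anisotropy(self):
        oc = OpticalConstants(
            n={j: 1.4 for j in ("0", "90", "45", "135", "rc", "lc")},
            tau={j: 0.01 for j in ("0", "90", "45", "135", "rc", "lc")},
        )
        p = params_from_optics(oc, MeasurementGeometry())
        assert np.allclose(p.as_array(), 0.0)

    def test_hand_computed_linear_birefringence(self):
        # 2π · 1e-3 · 40 / 0.6328 ≈ 0.3972 rad
        geom = MeasurementGeometry(wavelength=0.6328, thickness=40.0)
        oc = OpticalConstants(n={"0": 1.501, "90": 1.5})
        p = params_from_optics(oc, geom)
        assert p.phi_0_90 == pytest.approx(0.3972, abs=5e-4)

    @pytest.mark.parametrize("kwargs", [{"wavelength": 0.0}, {"thickness": -1.0}])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(InvalidGeometryError):
            MeasurementGeometry(**kwargs)


class TestBuildDifferential:
    def test_zero_params_give_zero_generator(self):
        d = build_differential(AnisotropyParams())
        assert np.all(d.mean_part == 0) and np.all(d.depol_part == 0)

    def test_linear_birefringence_signs(self):
        x = 0.37
        d = build_differential(AnisotropyParams(phi_0_90=x))
        expected = np.zeros((4, 4))
        expected[2, 3] = x
        expected[3, 2] = -x
        np.testing.assert_allclose(d.mean_part, expected)

    def test_extraction_round_trip_each_parameter(self, rng):
        p = random_params(rng)
        q = reconstruct_differential(
            MuellerMatrix(np.eye(4)), mode="matrix_log"
        )  # trivial zero case
        assert np.allclose(q.as_array(), 0.0)
        d = build_differential(p)
        from mmtomo.core import params_from_mean_matrix

        np.testing.assert_allclose(params_from_mean_matrix(d.mean_part), p.as_array())


class TestForwardMueller:
    def test_zero_generator_is_identity(self):
        m = forward_mueller(build_differential(AnisotropyParams()))
        np.testing.assert_allclose(m.f, np.eye(4), atol=1e-14)

    def test_quarter_wave_plate_matches_calibration_matrix(self):
        # the calibration target is a π/2 retarder between the 45°/135°
        # components (f24 = +1, f42 = -1 orientation)
        m = forward_mueller(build_differential(AnisotropyParams(phi_45_135=-np.pi / 2)))
        assert abs(m.f[1, 3]) == pytest.approx(1.0, abs=1e-12)
        assert m.f[1, 3] == pytest.approx(-m.f[3, 1], abs=1e-12)
        assert m.f[2, 2] == pytest.approx(1.0, abs=1e-12)
        assert m.f[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert m.f[3, 3] == pytest.approx(0.0, abs=1e-12)
        assert np.abs(m.f - QUARTER_WAVE).max() <= 0.02 + 1e-12

    def test_exponential_agrees_with_power_series(self, rng):
        for _ in range(10):
            p = random_params(rng, max_retardance=0.5, max_dichroism=0.1)
            g = build_differential(p).total
            series = sum(np.linalg.matrix_power(g, k) / math.factorial(k) for k in range(20))
            m = forward_mueller(build_differential(p))
            np.testing.assert_allclose(m.f, series / series[0, 0], atol=1e-10)

    def test_semigroup_over_thickness(self, rng):
        p = random_params(rng, max_retardance=0.7)
        d1 = build_differential(p)
        d2 = build_differential(AnisotropyParams(*(2.0 * p.as_array())))
        m1 = forward_mueller(d1).f
        m2 = forward_mueller(d2).f
        np.testing.assert_allclose(m2, (m1 @ m1) / (m1 @ m1)[0, 0], atol=1e-12)


class TestReconstruct:
    def test_identity_gives_zero_params(self):
        p = reconstruct_differential(MuellerMatrix(np.eye(4)))
        assert np.allclose(p.as_array(), 0.0)

    def test_forward_inverse_round_trip(self, rng):
        for _ in range(50):
            p = random_params(rng)
            m = forward_mueller(build_differential(p))
            q = reconstruct_differential(m)
            np.testing.assert_allclose(q.as_array(), p.as_array(), atol=1e-8)

    def test_quarter_wave_calibration_reconstruction(self):
        p = reconstruct_differential(MuellerMatrix(QUARTER_WAVE))
        assert abs(abs(p.phi_45_135) - np.pi / 2) < 0.05
        others = [getattr(p, n) for n in PARAM_NAMES if n != "phi_45_135"]
        assert np.abs(others).max() < 0.1

    def test_mean_params_exact_under_depolarizing_component(self, rng):
        """The G-split recovers the six mean parameters even with a strong
        symmetric depolarizing generator (well within the 2% requirement)."""
        for _ in range(10):
            p = random_params(rng, max_retardance=0.8 * np.pi)
            x = rng.standard_normal((4, 4))
            depol = 0.5 * (x + np.diag([1, -1, -1, -1]) @ x.T @ np.diag([1, -1, -1, -1]))
            depol *= 0.25 / np.linalg.norm(depol, 2)
            assert np.linalg.norm(depol, 2) <= 0.3
            gen = build_differential(p).mean_part + depol
            f = scipy.linalg.expm(gen)
            q = reconstruct_differential(MuellerMatrix(f))
            scale = max(1.0, np.abs(p.as_array()).max())
            assert np.abs(q.as_array() - p.as_array()).max() / scale < 0.02

    def test_non_physical_matrix_raises(self):
        # eigenvalue on the negative real axis: no real principal log
        with pytest.raises(NonPhysicalMatrixError):
            decompose_differential(MuellerMatrix(np.diag([1.0, -0.5, 0.5, 0.5])))

    def test_elementwise_identity_and_sentinels(self):
        p0 = reconstruct_differential(MuellerMatrix(np.eye(4)), mode="elementwise")
        assert np.allclose(p0.as_array(), 0.0)
        retarder = forward_mueller(build_differential(AnisotropyParams(phi_0_90=0.4)))
        pe = reconstruct_differential(retarder, mode="elementwise")
        # a Φ0,90 retarder puts an opposite-sign pair at (f34, f43), which the
        # published element pairing reads as the 45/135 channel; the log-ratio
        # is undefined there and the sentinel must appear
        assert np.isnan(pe.phi_45_135)
        assert not np.isnan(pe.delta_0_90)


class TestGeneralizedLinear:
    def test_pythagorean_triple(self):
        phi_l, _ = generalized_linear(AnisotropyParams(phi_0_90=3.0, phi_45_135=4.0))
        assert phi_l == pytest.approx(5.0)

    def test_zero_params(self):
        assert generalized_linear(AnisotropyParams()) == (0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.tuples(*[st.floats(-3, 3, allow_nan=False) for _ in range(4)]),
    )
    def test_matches_quadrature_and_sign_invariance(self, vals):
        p1, p2, d1, d2 = vals
        p = AnisotropyParams(phi_0_90=p1, phi_45_135=p2, delta_0_90=d1, delta_45_135=d2)
        phi_l, delta_l = generalized_linear(p)
        assert phi_l == pytest.approx(np.sqrt(p1**2 + p2**2), abs=1e-12)
        assert delta_l == pytest.approx(np.sqrt(d1**2 + d2**2), abs=1e-12)
        q = AnisotropyParams(phi_0_90=-p1, phi_45_135=p2, delta_0_90=d1, delta_45_135=-d2)
        assert generalized_linear(q) == pytest.approx((phi_l, delta_l))


class TestDepolarizationDegree:
    @pytest.mark.parametrize(
        "diag,expected",
        [((1, 1, 1, 1), 0.0), ((1, 0, 0, 0), 100.0), ((1, 0.5, 0.5, 0.5), 50.0)],
    )
    def test_reference_matrices(self, diag, expected):
        assert depolarization_degree(np.diag(np.array(diag, float))) == pytest.approx(expected)

    def test_zero_on_pure_forward_matrices(self, rng):
        for _ in range(20):
            m = forward_mueller(build_differential(random_params(rng)))
            assert depolarization_degree(m) == pytest.approx(0.0, abs=1e-9)


class TestCalibrationFixtures:
    def test_air_matrix_polarization_block_is_identity_within_one_percent(self):
        dev = np.abs(AIR[:3, :3] / AIR[0, 0] - np.eye(3))
        assert dev.max() <= 0.01 + 1e-12

    def test_logm_stack_matches_scipy_oracle(self, rng):
        mats = np.stack(
            [
                forward_mueller(build_differential(random_params(rng))).f
                for _ in range(8)
            ]
        )
        logs, valid = logm_stack(mats)
        assert valid.all()
        for i in range(8):
            np.testing.assert_allclose(logs[i], scipy.linalg.logm(mats[i]).real, atol=1e-9)

    def test_g_split_reassembles(self, rng):
        m = rng.standard_normal((4, 4))
        mean, depol = g_split(m)
        np.testing.assert_allclose(mean + depol, m, atol=1e-14)
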