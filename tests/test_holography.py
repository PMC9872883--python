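"""Off-axis interferometry: simulation, demodulation, Stokes and assembly."""

import numpy as np
import pytest

from mmtomo.core import AnisotropyParams, build_differential, forward_mueller
from mmtomo.holography import (
    PROBE_JONES,
    PROBE_STOKES,
    ComplexField,
    Interferogram,
    ProbeState,
    coherent_probe_fields,
    demodulate,
    fields_from_stokes,
    jones_from_params,
    jones_map_from_mueller,
    mueller_from_probes,
    phase_slice,
    probe_stokes_through,
    simulate_interferogram,
    stokes_from_fields,
    StokesMap,
)
from mmtomo.phantom import adenoma_spec, generate_phantom


def _const_field(shape=(32, 32), value=1.0, probe=ProbeState.P0):
    return ComplexField(np.full(shape, value, dtype=complex), probe=probe)


class TestSimulate:
    def test_zero_object_gives_uniform_reference_intensity(self):
        ig = simulate_interferogram(_const_field(value=0.0), ref_amplitude=0.7)
        np.testing.assert_allclose(ig.intensity, 0.49, atol=1e-12)

    def test_equal_amplitude_waves_have_unit_visibility(self):
        ig = simulate_interferogram(_const_field(value=1.0), carrier=(0.25, 0.0))
        assert ig.intensity.max() == pytest.approx(4.0, abs=1e-9)
        assert ig.intensity.min() == pytest.approx(0.0, abs=1e-9)

    def test_carrier_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_interferogram(_const_field(), carrier=(0.6, 0.0))

    def test_shot_noise_is_seeded(self):
        f = _const_field()
        a = simulate_interferogram(f, shot_noise=0.05, rng=11).intensity
        b = simulate_interferogram(f, shot_noise=0.05, rng=11).intensity
        np.testing.assert_array_equal(a, b)


class TestDemodulate:
    def test_constant_object_recovered_interior(self):
        f = _const_field((64, 64), value=0.8)
        rec = demodulate(simulate_interferogram(f, carrier=(0.25, 0.25)))
        interior = rec.data[6:-6, 6:-6]
        assert np.abs(interior - 0.8).max() / 0.8 < 0.01

    def test_linear_phase_ramp_slope_recovered(self):
        shape = (64, 64)
        slope = 2.0 * np.pi * 2.0 / shape[1]  # two fringes across the field
        b = np.arange(shape[1])[None, :]
        f = ComplexField(np.exp(1j * slope * b) * np.ones(shape))
        rec = demodulate(simulate_interferogram(f, carrier=(0.25, 0.25)))
        phase = np.unwrap(np.angle(rec.data[32]), axis=-1)
        fitted = np.polyfit(np.arange(shape[1])[4:-4], phase[4:-4], 1)[0]
        assert abs(fitted - slope) < 1e-3

    def test_no_reference_yields_near_zero_field(self):
        f = _const_field((64, 64), value=0.5)
        ig = simulate_interferogram(f, carrier=(0.25, 0.25), ref_amplitude=0.0)
        rec = demodulate(ig)
        assert np.abs(rec.data).max() < 1e-10

    def test_small_carrier_flags_degraded(self):
        f = _const_field((64, 64))
        ig = simulate_interferogram(f, carrier=(0.05, 0.0))
        with pytest.warns(UserWarning, match="degraded"):
            rec = demodulate(ig, object_bandwidth=0.1)
        assert rec.degraded

    def test_error_decreases_with_carrier_separation(self, rng):
        """Fixed band-limited object; recovery error is monotone decreasing
        as the carrier moves from 0.05 to 0.30 cycles/pixel."""
        from scipy.ndimage import gaussian_filter

        shape = (64, 64)
        g = gaussian_filter(rng.standard_normal(shape), 5.0, mode="wrap")
        g = (g - g.mean()) / g.std()
        f = ComplexField(np.exp(0.3j * g) * (1.0 + 0.1 * g))
        errs = []
        # bin-aligned carriers from ~0.05 to ~0.30 cycles/pixel, so the
        # comparison probes sideband separation rather than DFT leakage
        for k in (3, 6, 10, 13, 16, 19):
            rec = demodulate(simulate_interferogram(f, carrier=(k / 64, 0.0)))
            errs.append(np.median(np.abs(rec.data - f.data)[4:-4, 4:-4]))
        assert np.all(np.diff(errs) < 0)


class TestStokes:
    def test_single_projection_field(self):
        e0 = _const_field(value=0.9)
        e90 = _const_field(value=0.0)
        s = stokes_from_fields(e0, e90).s
        np.testing.assert_allclose(s[0], 0.81, atol=1e-12)
        np.testing.assert_allclose(s[1], 0.81, atol=1e-12)
        np.testing.assert_allclose(s[2:], 0.0, atol=1e-12)

    def test_equal_real_fields_give_plus45_polarization(self):
        e = _const_field(value=0.5)
        s = stokes_from_fields(e, e).s
        np.testing.assert_allclose(s[0], 0.5, atol=1e-12)
        np.testing.assert_allclose(s[1], 0.0, atol=1e-12)
        np.testing.assert_allclose(s[2], 0.5, atol=1e-12)
        np.testing.assert_allclose(s[3], 0.0, atol=1e-12)

    def test_matches_per_pixel_loop_oracle(self, rng):
        shape = (9, 7)
        a = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        b = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        s = stokes_from_fields(ComplexField(a), ComplexField(b)).s
        for i in range(shape[0]):
            for k in range(shape[1]):
                e0, e90 = a[i, k], b[i, k]
                expected = [
                    abs(e0) ** 2 + abs(e90) ** 2,
                    abs(e0) ** 2 - abs(e90) ** 2,
                    2 * (e0 * np.conj(e90)).real,
                    2 * (e0 * np.conj(e90)).imag,
                ]
                np.testing.assert_allclose(s[:, i, k], expected, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            stokes_from_fields(_const_field((8, 8)), _const_field((8, 9)))

    def test_probe_output_fully_polarized_through_pure_sample(self, pure_phantom_64):
        mm = pure_phantom_64.mueller[0.6]
        for probe in ProbeState:
            dop = probe_stokes_through(mm, probe).degree_of_polarization
            np.testing.assert_allclose(dop, 1.0, atol=1e-9)


class TestJonesRoute:
    def test_jones_and_mueller_propagation_agree(self, rng):
        """Dual-route check: Stokes of the Jones-propagated field equals the
        Mueller-matrix product for every probe."""
        from conftest import random_params

        for _ in range(5):
            p = random_params(rng, max_retardance=0.8 * np.pi, max_dichroism=0.5)
            m = forward_mueller(build_differential(p))
            j = jones_from_params(p.as_array())
            for probe in ProbeState:
                e = j @ PROBE_JONES[probe]
                e0 = ComplexField(np.full((2, 2), e[0]), probe=probe)
                e90 = ComplexField(np.full((2, 2), e[1]), probe=probe)
                s = stokes_from_fields(e0, e90).s[:, 0, 0]
                s_ref = m.f @ PROBE_STOKES[probe]
                # the Jones field keeps absolute intensity; compare normalized
                np.testing.assert_allclose(s / s[0], s_ref / s_ref[0], atol=1e-10)

    def test_jones_map_rejects_depolarizing_input(self, small_adenoma):
        with pytest.raises(ValueError, match="depolarizing"):
            jones_map_from_mueller(small_adenoma.mueller[0.6])


class TestMuellerAssembly:
    def test_no_sample_gives_identity_everywhere(self):
        shape = (6, 5)
        stokes = {
            p: StokesMap(np.broadcast_to(PROBE_STOKES[p][:, None, None], (4,) + shape).copy(), probe=p)
            for p in ProbeState
        }
        mm = mueller_from_probes(stokes)
        np.testing.assert_allclose(mm.data, np.broadcast_to(np.eye(4), shape + (4, 4)), atol=1e-12)

    def test_matches_forward_model_oracle(self, small_adenoma):
        mm = small_adenoma.mueller[0.6]
        stokes = {p: probe_stokes_through(mm, p) for p in ProbeState}
        rec = mueller_from_probes(stokes, geometry=mm.geometry)
        np.testing.assert_allclose(rec.data, mm.data, atol=1e-10)

    def test_global_intensity_scaling_cancels(self, small_adenoma):
        mm = small_adenoma.mueller[0.6]
        stokes = {p: probe_stokes_through(mm, p) for p in ProbeState}
        scaled = {p: StokesMap(3.7 * stokes[p].s, probe=p) for p in ProbeState}
        rec = mueller_from_probes(stokes)
        rec_scaled = mueller_from_probes(scaled)
        np.testing.assert_allclose(rec_scaled.data, rec.data, atol=1e-12)

    def test_missing_probe_rejected(self, small_adenoma):
        mm = small_adenoma.mueller[0.6]
        stokes = {p: probe_stokes_through(mm, p) for p in ProbeState if p != ProbeState.LC}
        with pytest.raises(ValueError, match="missing probe"):
            mueller_from_probes(stokes)


class TestPhaseSlice:
    def test_zero_and_two_pi_select_same_plane(self):
        stack = [(0.0, "a"), (0.6, "b"), (1.2, "c")]
        assert phase_slice(stack, 0.0) == "a"
        assert phase_slice(stack, 2.0 * np.pi) == "a"
        assert phase_slice(stack, 0.58) == "b"

    def test_single_plane_stack_is_invariant(self):
        for phi in (0.0, 0.3, 5.9):
            assert phase_slice({0.6: "only"}, phi) == "only"
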