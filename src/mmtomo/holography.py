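"""Off-axis polarization holography: simulation and Fourier demodulation.

The measurement scheme probes the sample with six polarization states
(0°, 90°, 45°, 135°, right- and left-circular), records off-axis
interferograms behind an analyzer at Ω = 0° and 90°, and recovers the
complex orthogonal field projections by isolating the carrier sideband in
the 2D spectrum.  Per-pixel Stokes vectors follow from the field pair, and
the full Mueller map from half-sum/half-difference combinations over the
six probes.

Stokes indexing follows S1 = intensity (S1..S4); serialization converts to
the conventional S0-based order at the file boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import MuellerMap
from .geometry import MeasurementGeometry

__all__ = [
    "ProbeState",
    "PROBE_STOKES",
    "Interferogram",
    "ComplexField",
    "StokesMap",
    "simulate_interferogram",
    "demodulate",
    "stokes_from_fields",
    "fields_from_stokes",
    "jones_from_params",
    "jones_map_from_mueller",
    "coherent_probe_fields",
    "PROBE_JONES",
    "mueller_from_probes",
    "probe_stokes_through",
    "phase_slice",
    "DEFAULT_CARRIER",
]


class ProbeState(str, Enum):
    """The six polarization probe states of the measurement scheme."""

    P0 = "0"
    P90 = "90"
    P45 = "45"
    P135 = "135"
    RC = "rc"
    LC = "lc"


#: unit-intensity input Stokes vector of each probe (S1 = intensity)
PROBE_STOKES: dict[ProbeState, np.ndarray] = {
    ProbeState.P0: np.array([1.0, 1.0, 0.0, 0.0]),
    ProbeState.P90: np.array([1.0, -1.0, 0.0, 0.0]),
    ProbeState.P45: np.array([1.0, 0.0, 1.0, 0.0]),
    ProbeState.P135: np.array([1.0, 0.0, -1.0, 0.0]),
    ProbeState.RC: np.array([1.0, 0.0, 0.0, 1.0]),
    ProbeState.LC: np.array([1.0, 0.0, 0.0, -1.0]),
}

#: default spatial carrier, cycles/pixel (diagonal, well inside Nyquist)
DEFAULT_CARRIER = (0.25, 0.25)


@dataclass(frozen=True)
class ComplexField:
    """Complex object-field projection for one probe and analyzer angle."""

    data: np.ndarray
    probe: ProbeState = ProbeState.P0
    analyzer: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=complex)
        if d.ndim != 2:
            raise ValueError("ComplexField data must be a 2D grid")
        if not np.isfinite(d).all():
            raise ValueError("ComplexField entries must be finite")
        object.__setattr__(self, "data", d)


@dataclass(frozen=True)
class Interferogram:
    """Recorded off-axis intensity pattern with its carrier frequency."""

    intensity: np.ndarray
    carrier: tuple[float, float]
    probe: ProbeState = ProbeState.P0
    analyzer: int = 0
    ref_amplitude: float = 1.0
    degraded: bool = False

    def __post_init__(self) -> None:
        i = np.asarray(self.intensity, dtype=float)
        if i.ndim != 2:
            raise ValueError("interferogram must be a 2D grid")
        if (i < 0).any():
            raise ValueError("interferogram intensities must be non-negative")
        cmag = float(np.hypot(*self.carrier))
        if not (0.0 < cmag < 0.5 * np.sqrt(2.0)) or max(map(abs, self.carrier)) >= 0.5:
            raise ValueError(
                f"carrier {self.carrier} must be non-zero and inside Nyquist "
                "(each component |c| < 0.5 cycles/pixel)"
            )
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "carrier", (float(self.carrier[0]), float(self.carrier[1])))

    @property
    def carrier_magnitude(self) -> float:
        return float(np.hypot(*self.carrier))


@dataclass(frozen=True)
class StokesMap:
    """Four S1..S4 grids for one probe; S1 is the intensity."""

    s: np.ndarray  # (4, A, B)
    probe: ProbeState = ProbeState.P0

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        if s.ndim != 3 or s.shape[0] != 4:
            raise ValueError("StokesMap needs shape (4, A, B)")
        if (s[0] < -1e-12).any():
            raise ValueError("S1 (intensity) must be non-negative")
        pol = s[1] ** 2 + s[2] ** 2 + s[3] ** 2
        if (pol > s[0] ** 2 * (1 + 1e-9) + 1e-9).any():
            raise ValueError("S1^2 >= S2^2+S3^2+S4^2 violated beyond tolerance")
        object.__setattr__(self, "s", s)

    @property
    def degree_of_polarization(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(self.s[1] ** 2 + self.s[2] ** 2 + self.s[3] ** 2) / self.s[0]


def _carrier_phase(shape: tuple[int, int], carrier: tuple[float, float]) -> np.ndarray:
    a = np.arange(shape[0])[:, None]
    b = np.arange(shape[1])[None, :]
    return 2.0 * np.pi * (carrier[0] * a + carrier[1] * b)


def simulate_interferogram(
    object_field: ComplexField,
    carrier: tuple[float, float] = DEFAULT_CARRIER,
    ref_amplitude: float = 1.0,
    shot_noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> Interferogram:
    """Off-axis interferogram of an object field against a tilted plane
    reference wave.

    intensity = |E_obj + A_ref·exp(i·2π·carrier·(a,b))|², optionally with
    Poisson-like shot noise of relative strength ``shot_noise`` (explicit
    ``rng``/seed required to be reproducible).
    """
    if max(abs(carrier[0]), abs(carrier[1])) >= 0.5:
        raise ValueError("carrier must stay below Nyquist (0.5 cycles/pixel)")
    e = object_field.data
    theta = _carrier_phase(e.shape, carrier)
    intensity = np.abs(e + ref_amplitude * np.exp(1j * theta)) ** 2
    if shot_noise > 0.0:
        gen = np.random.default_rng(rng)
        intensity = np.clip(
            intensity + gen.normal(0.0, shot_noise * np.sqrt(np.maximum(intensity, 0.0))),
            0.0,
            None,
        )
    return Interferogram(
        intensity,
        carrier,
        probe=object_field.probe,
        analyzer=object_field.analyzer,
        ref_amplitude=ref_amplitude,
    )


def _sideband_window(shape: tuple[int, int], radius: float) -> np.ndarray:
    """Low-pass window after carrier demodulation: full pass inside 0.85·r,
    raised-cosine edge from 0.85·r to r (a narrow taper: the carrier is
    assumed well separated, so pass-band fidelity matters more than extra
    stop-band attenuation)."""
    fa = np.fft.fftfreq(shape[0])[:, None]
    fb = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fa, fb)
    inner = 0.85 * radius
    w = np.zeros(shape)
    w[rho <= inner] = 1.0
    edge = (rho > inner) & (rho < radius)
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * (rho[edge] - inner) / (radius - inner)))
    return w


def demodulate(ig: Interferogram, object_bandwidth: float | None = None) -> ComplexField:
    """Recover the complex object field from an off-axis interferogram.

    Shifts the +1 carrier sideband to DC (exact for non-integer carriers),
    low-passes it with a raised-cosine circular window of radius half the
    carrier magnitude, and divides out the reference amplitude.  If the
    stated object bandwidth exceeds the window, the sideband overlaps the DC
    term; a warning is emitted and the result flagged degraded.
    """
    radius = 0.5 * ig.carrier_magnitude
    degraded = False
    if object_bandwidth is not None and object_bandwidth > radius:
        warnings.warn(
            "object bandwidth exceeds the sideband separation; "
            "demodulation is degraded",
            stacklevel=2,
        )
        degraded = True
    theta = _carrier_phase(ig.intensity.shape, ig.carrier)
    shifted = ig.intensity * np.exp(-1j * theta)
    spec = np.fft.fft2(shifted)
    spec *= _sideband_window(ig.intensity.shape, radius)
    # the sideband at +carrier carries conj(E_obj)·A_ref; with no reference
    # beam there is no sideband and the recovered field is left unscaled
    scale = ig.ref_amplitude if ig.ref_amplitude > 0 else 1.0
    field = np.conj(np.fft.ifft2(spec)) / scale
    out = ComplexField(field, probe=ig.probe, analyzer=ig.analyzer)
    if degraded:
        object.__setattr__(out, "degraded", True)
    return out


def stokes_from_fields(e0: ComplexField, e90: ComplexField) -> StokesMap:
    """Per-pixel Stokes parameters from the orthogonal field projections.

    S1 = |E0|²+|E90|², S2 = |E0|²-|E90|², S3 = 2·Re(E0·E90*),
    S4 = 2·Im(E0·E90*).
    """
    if e0.data.shape != e90.data.shape:
        raise ValueError("field grids must match")
    if e0.probe != e90.probe:
        raise ValueError("fields must come from the same probe state")
    a2 = np.abs(e0.data) ** 2
    b2 = np.abs(e90.data) ** 2
    cross = e0.data * np.conj(e90.data)
    s = np.stack([a2 + b2, a2 - b2, 2.0 * cross.real, 2.0 * cross.imag])
    # clamp round-off so that S1^2 >= S2^2+S3^2+S4^2 holds exactly at DOP=1
    return StokesMap(s, probe=e0.probe)


def fields_from_stokes(sm: StokesMap) -> tuple[ComplexField, ComplexField]:
    """Synthesize a coherent field pair carrying the polarized part of a
    Stokes map (exact when the degree of polarization is 1; the unpolarized
    residue of a depolarizing medium cannot be represented by a single
    deterministic field)."""
    s1, s2, s3, s4 = sm.s
    a = np.sqrt(np.clip((s1 + s2) / 2.0, 0.0, None))
    b = np.sqrt(np.clip((s1 - s2) / 2.0, 0.0, None))
    phi = np.arctan2(-s4, s3)  # arg(E90) - arg(E0)
    e0 = a.astype(complex)
    e90 = b * np.exp(1j * phi)
    return (
        ComplexField(e0, probe=sm.probe, analyzer=0),
        ComplexField(e90, probe=sm.probe, analyzer=90),
    )


#: unit Jones vectors of the probes, consistent with PROBE_STOKES under the
#: S1..S4 convention (S4 = 2·Im(E0·E90*), so right-circular is (1, -i)/√2)
PROBE_JONES: dict[ProbeState, np.ndarray] = {
    ProbeState.P0: np.array([1.0, 0.0], dtype=complex),
    ProbeState.P90: np.array([0.0, 1.0], dtype=complex),
    ProbeState.P45: np.array([1.0, 1.0], dtype=complex) / np.sqrt(2.0),
    ProbeState.P135: np.array([1.0, -1.0], dtype=complex) / np.sqrt(2.0),
    ProbeState.RC: np.array([1.0, -1.0j], dtype=complex) / np.sqrt(2.0),
    ProbeState.LC: np.array([1.0, 1.0j], dtype=complex) / np.sqrt(2.0),
}


def jones_from_params(params: np.ndarray) -> np.ndarray:
    """Jones matrix stack of a pure (non-depolarizing) layer.

    ``params`` is (..., 6) in the order (Φ0,90, Φ45,135, Φ⊗,⊕, Δ0,90,
    Δ45,135, Δ⊗,⊕).  The Jones generator is the traceless
    N = ½[(Δ0,90 - iΦ0,90)σ3 + (Δ45,135 - iΦ45,135)σ1 - (Δ⊗,⊕ - iΦ⊗,⊕)σ2],
    whose coherency image is exactly the six-parameter Mueller generator;
    exp(N) is evaluated in closed form (N² = k²·I)."""
    params = np.asarray(params, dtype=float)
    pl1, pl2, pc, dl1, dl2, dc = np.moveaxis(params, -1, 0)
    v1 = 0.5 * (dl2 - 1j * pl2)
    v2 = -0.5 * (dc - 1j * pc)
    v3 = 0.5 * (dl1 - 1j * pl1)
    k = np.sqrt((v1**2 + v2**2 + v3**2).astype(complex))
    small = np.abs(k) < 1e-8
    with np.errstate(all="ignore"):
        sinc = np.where(small, 1.0 + k**2 / 6.0, np.sinh(k) / np.where(small, 1.0, k))
    ch = np.cosh(k)
    j = np.empty(params.shape[:-1] + (2, 2), dtype=complex)
    j[..., 0, 0] = ch + sinc * v3
    j[..., 0, 1] = sinc * (v1 - 1j * v2)
    j[..., 1, 0] = sinc * (v1 + 1j * v2)
    j[..., 1, 1] = ch - sinc * v3
    return j


def jones_map_from_mueller(mm: MuellerMap, depol_tol: float = 1e-6) -> np.ndarray:
    """Per-pixel Jones matrices of a non-depolarizing Mueller map.

    Reconstructs the six differential parameters pixel-wise and raises if
    the depolarizing generator component exceeds ``depol_tol`` anywhere — a
    single coherent field pair cannot represent partially polarized output.
    """
    from ._linalg import g_split, logm_stack

    log, valid = logm_stack(mm.data)
    if not valid.all():
        raise ValueError("Mueller map has pixels without a real principal logarithm")
    mean, depol = g_split(log)
    off = depol.copy()
    off[..., range(4), range(4)] = 0.0
    diag = depol[..., range(4), range(4)]
    # an isotropic diagonal only rescales intensity; anisotropic diagonal or
    # off-diagonal symmetric terms depolarize
    iso = diag.mean(axis=-1)
    depol_size = np.abs(off).max() + np.abs(diag - iso[..., None]).max()
    if depol_size > depol_tol:
        raise ValueError(
            f"map is depolarizing (depol generator magnitude {depol_size:.2e}); "
            "coherent field synthesis is only defined for pure media"
        )
    from .core import params_from_mean_matrix

    j = jones_from_params(params_from_mean_matrix(mean))
    return j * np.exp(0.5 * iso)[..., None, None]


def coherent_probe_fields(
    mm: MuellerMap, probe: ProbeState, jones: np.ndarray | None = None
) -> tuple[ComplexField, ComplexField]:
    """Orthogonal field projections of one probe through a pure Mueller map.

    Pass a precomputed ``jones`` stack to amortize the reconstruction over
    probes.  The fields are analytic in the medium parameters, hence as
    band-limited as the underlying maps (no gauge kinks, unlike
    ``fields_from_stokes``)."""
    if jones is None:
        jones = jones_map_from_mueller(mm)
    e = np.einsum("abij,j->abi", jones, PROBE_JONES[probe])
    return (
        ComplexField(e[..., 0], probe=probe, analyzer=0),
        ComplexField(e[..., 1], probe=probe, analyzer=90),
    )


def probe_stokes_through(mm: MuellerMap, probe: ProbeState) -> StokesMap:
    """Output Stokes map of one probe propagated through a Mueller map."""
    s_in = PROBE_STOKES[probe]
    s_out = np.einsum("abij,j->iab", mm.data, s_in)
    s_out[0] = np.clip(s_out[0], 0.0, None)
    # tolerate round-off overpolarization
    pol = np.sqrt(s_out[1] ** 2 + s_out[2] ** 2 + s_out[3] ** 2)
    over = pol > s_out[0]
    if over.any():
        scale = np.where(over & (pol > 0), s_out[0] / np.where(pol > 0, pol, 1.0), 1.0)
        excess = np.where(over, pol / np.maximum(s_out[0], 1e-300), 1.0)
        if (excess > 1 + 1e-6).any():
            raise ValueError("Mueller map over-polarizes a probe beyond round-off")
        s_out[1:] *= scale
    return StokesMap(s_out, probe=probe)


def mueller_from_probes(
    stokes: dict[ProbeState, StokesMap],
    geometry: MeasurementGeometry | None = None,
) -> MuellerMap:
    """Assemble the per-pixel Mueller map from the six probe Stokes maps.

    Column k of the matrix is the half-sum (k=1) / half-difference response
    over the orthogonal probe pairs: 0.5(S^0 ± S^90), 0.5(S^45 - S^135),
    0.5(S^rc - S^lc).  The result is f11-normalized; pixels with f11 <= 0
    become NaN sentinels.
    """
    missing = [p for p in ProbeState if p not in stokes]
    if missing:
        raise ValueError(f"missing probe states: {[p.value for p in missing]}")
    shapes = {stokes[p].s.shape for p in ProbeState}
    if len(shapes) != 1:
        raise ValueError(f"probe Stokes maps have mismatched shapes: {shapes}")
    s = {p: stokes[p].s for p in ProbeState}
    cols = [
        0.5 * (s[ProbeState.P0] + s[ProbeState.P90]),
        0.5 * (s[ProbeState.P0] - s[ProbeState.P90]),
        0.5 * (s[ProbeState.P45] - s[ProbeState.P135]),
        0.5 * (s[ProbeState.RC] - s[ProbeState.LC]),
    ]
    # cols[k][i] = f_{i+1,k+1}; stack to (i, k, A, B) then move pixel axes front
    f = np.moveaxis(np.stack(cols, axis=1), (2, 3), (0, 1))  # (A, B, 4, 4)
    f11 = f[..., 0, 0]
    bad = f11 <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        f = f / np.where(bad, np.nan, f11)[..., None, None]
    geometry = geometry or MeasurementGeometry()
    # f is already f11-normalized (NaN sentinels where f11 <= 0); the flag
    # records the normalization state without re-dividing by the NaNs
    out = MuellerMap(f, geometry=geometry, normalized=False)
    object.__setattr__(out, "normalized", True)
    return out


def phase_slice(stack, phi_k: float):
    """Select the field set of the phase plane nearest to φk.

    ``stack`` is a sequence of (φ, payload) pairs or a {φ: payload} mapping;
    planes are compared on the circle (φ and φ+2π are the same plane).  With
    a single plane the payload is returned unchanged for every φk.
    """
    if hasattr(stack, "items"):
        items = sorted(stack.items())
    else:
        items = list(stack)
    if not items:
        raise ValueError("empty phase-plane stack")
    phis = np.array([p for p, _ in items], dtype=float)
    d = np.angle(np.exp(1j * (phis - phi_k)))
    return items[int(np.argmin(np.abs(d)))][1]
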