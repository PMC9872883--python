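"""Differential Mueller-matrix model of a linearly/circularly anisotropic layer.

The polarization transfer of a thin birefringent-dichroic layer is generated
by a first-order differential matrix with six independent off-diagonal
entries: linear birefringence between the 0°/90° and 45°/135° component
pairs (Φ0,90, Φ45,135), circular birefringence (Φ⊗,⊕), and the three
matching dichroism terms (Δ0,90, Δ45,135, Δ⊗,⊕).  The layer's Mueller matrix
is the exponential of that generator; reconstruction takes the principal
matrix logarithm of a measured matrix and splits it into its G-antisymmetric
(mean anisotropy) and G-symmetric (depolarizing) parts.

Generators are stored *per layer*, i.e. already accumulated over the section
thickness l: each phase term equals (2π/λ)·Δn·l and each amplitude term
(2π/λ)·Δτ·l.  Divide by ``geometry.thickness`` for per-unit-length rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import expm_stack, g_split, logm_stack
from .geometry import MeasurementGeometry, OpticalConstants

__all__ = [
    "AnisotropyParams",
    "DifferentialMatrix",
    "MuellerMatrix",
    "MuellerMap",
    "NonPhysicalMatrixError",
    "params_from_optics",
    "build_differential",
    "forward_mueller",
    "decompose_differential",
    "reconstruct_differential",
    "reconstruct_stack",
    "generalized_linear",
    "depolarization_degree",
]


class NonPhysicalMatrixError(ValueError):
    """Raised when a matrix admits no real principal logarithm or has f11 <= 0."""


@dataclass(frozen=True)
class AnisotropyParams:
    """The six mean anisotropy parameters of one layer.

    Phase terms in radians, amplitude terms dimensionless; all accumulated
    over the layer thickness.
    """

    phi_0_90: float = 0.0
    phi_45_135: float = 0.0
    phi_circ: float = 0.0
    delta_0_90: float = 0.0
    delta_45_135: float = 0.0
    delta_circ: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.phi_0_90,
                self.phi_45_135,
                self.phi_circ,
                self.delta_0_90,
                self.delta_45_135,
                self.delta_circ,
            ]
        )

    def __post_init__(self) -> None:
        if not np.isfinite(self.as_array()).all():
            raise ValueError("anisotropy parameters must all be finite")

    @classmethod
    def _with_sentinels(cls, vals: np.ndarray) -> "AnisotropyParams":
        """Construct bypassing the finite check (NaN = undefined-pixel
        sentinel of the elementwise reconstruction)."""
        obj = object.__new__(cls)
        for name, v in zip(
            ("phi_0_90", "phi_45_135", "phi_circ", "delta_0_90", "delta_45_135", "delta_circ"),
            vals,
        ):
            object.__setattr__(obj, name, float(v))
        return obj


@dataclass(frozen=True)
class DifferentialMatrix:
    """Per-layer generator: mean (pure anisotropy) + depolarizing part."""

    mean_part: np.ndarray
    depol_part: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_part, dtype=float)
        d = np.asarray(self.depol_part, dtype=float)
        if m.shape != (4, 4) or d.shape != (4, 4):
            raise ValueError("differential matrix parts must be 4x4")
        if np.abs(np.diag(m)).max() > 1e-12:
            raise ValueError("mean part must have an exactly zero diagonal")
        # birefringence entries antisymmetric, dichroism entries symmetric
        mean_check, rest = g_split(m)
        if np.abs(rest).max() > 1e-9 * max(1.0, np.abs(m).max()):
            raise ValueError("mean part violates the six-parameter symmetry pattern")
        object.__setattr__(self, "mean_part", m)
        object.__setattr__(self, "depol_part", d)

    @property
    def total(self) -> np.ndarray:
        return self.mean_part + self.depol_part


@dataclass(frozen=True)
class MuellerMatrix:
    """A single 4x4 real Mueller matrix, normalized so that f11 = 1."""

    f: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.shape != (4, 4):
            raise ValueError("Mueller matrix must be 4x4")
        if not np.isfinite(f).all():
            raise ValueError("Mueller matrix entries must be finite")
        if self.normalized:
            if f[0, 0] <= 0:
                raise NonPhysicalMatrixError(f"f11 must be > 0 to normalize, got {f[0, 0]}")
            f = f / f[0, 0]
            if np.abs(f).max() > 1.0 + 1e-9:
                warnings.warn(
                    "normalized Mueller matrix has |f_ik| > 1; "
                    "unexpected for a passive medium",
                    stacklevel=2,
                )
        object.__setattr__(self, "f", f)


@dataclass(frozen=True)
class MuellerMap:
    """Per-pixel Mueller matrices over an A x B grid (row-major, origin
    top-left); ``data`` has shape (A, B, 4, 4) and is f11-normalized unless
    stated otherwise."""

    data: np.ndarray
    geometry: MeasurementGeometry = field(default_factory=MeasurementGeometry)
    normalized: bool = True

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4 or d.shape[2:] != (4, 4) or d.shape[0] < 1 or d.shape[1] < 1:
            raise ValueError(f"MuellerMap data must be (A, B, 4, 4), got {d.shape}")
        if self.normalized:
            f11 = d[..., 0, 0]
            if (f11 <= 0).any():
                raise NonPhysicalMatrixError("f11 <= 0 at some pixels; cannot normalize")
            d = d / f11[..., None, None]
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def __getitem__(self, idx) -> MuellerMatrix:
        a, b = idx
        return MuellerMatrix(self.data[a, b], normalized=self.normalized)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def params_from_optics(oc: OpticalConstants, geom: MeasurementGeometry) -> AnisotropyParams:
    """Anisotropy parameters from refractive-index / absorption differences.

    Each phase term is (2π/λ)·Δn·l over its orthogonal component pair and
    each amplitude term (2π/λ)·Δτ·l, with λ and l in the same length units
    as 1/τ.
    """
    k = 2.0 * np.pi * geom.thickness / geom.wavelength
    return AnisotropyParams(
        phi_0_90=k * oc.index_difference("0", "90"),
        phi_45_135=k * oc.index_difference("45", "135"),
        phi_circ=k * oc.index_difference("rc", "lc"),
        delta_0_90=k * oc.absorption_difference("0", "90"),
        delta_45_135=k * oc.absorption_difference("45", "135"),
        delta_circ=k * oc.absorption_difference("rc", "lc"),
    )


def build_differential(p: AnisotropyParams) -> DifferentialMatrix:
    """Populate the six-parameter generator layout.

    Dichroism terms sit in the symmetric first-row/first-column positions,
    birefringence terms in the antisymmetric lower-right block::

        |    0       Δ0,90    Δ45,135   Δ⊗,⊕   |
        |  Δ0,90       0       Φ⊗,⊕   -Φ45,135 |
        | Δ45,135   -Φ⊗,⊕       0      Φ0,90   |
        |  Δ⊗,⊕    Φ45,135   -Φ0,90      0     |
    """
    m = mean_matrix_from_params(p.as_array())
    return DifferentialMatrix(mean_part=m)


def mean_matrix_from_params(params: np.ndarray) -> np.ndarray:
    """Vectorized generator layout; ``params`` is (..., 6) ordered
    (Φ0,90, Φ45,135, Φ⊗,⊕, Δ0,90, Δ45,135, Δ⊗,⊕)."""
    params = np.asarray(params, dtype=float)
    pl1, pl2, pc, dl1, dl2, dc = np.moveaxis(params, -1, 0)
    m = np.zeros(params.shape[:-1] + (4, 4))
    m[..., 0, 1] = dl1
    m[..., 1, 0] = dl1
    m[..., 0, 2] = dl2
    m[..., 2, 0] = dl2
    m[..., 0, 3] = dc
    m[..., 3, 0] = dc
    m[..., 1, 2] = pc
    m[..., 2, 1] = -pc
    m[..., 1, 3] = -pl2
    m[..., 3, 1] = pl2
    m[..., 2, 3] = pl1
    m[..., 3, 2] = -pl1
    return m


def params_from_mean_matrix(m: np.ndarray) -> np.ndarray:
    """Read the six parameters back from a (stack of) mean generator(s)."""
    m = np.asarray(m, dtype=float)
    return np.stack(
        [
            m[..., 2, 3],
            -m[..., 1, 3],
            m[..., 1, 2],
            m[..., 0, 1],
            m[..., 0, 2],
            m[..., 0, 3],
        ],
        axis=-1,
    )


def forward_mueller(
    d: DifferentialMatrix, geom: MeasurementGeometry | None = None
) -> MuellerMatrix:
    """Exponentiate the per-layer generator to the layer's Mueller matrix.

    The generator is already accumulated over the thickness (per-layer
    convention), so the geometry does not rescale it; it is accepted to keep
    the measurement context attached in pipelines.  The result is
    f11-normalized.
    """
    total = d.total
    if not np.isfinite(total).all():
        raise ValueError("generator contains non-finite entries")
    f = expm_stack(total)
    return MuellerMatrix(f, normalized=True)


# ---------------------------------------------------------------------------
# inverse model
# ---------------------------------------------------------------------------

def decompose_differential(M: MuellerMatrix) -> DifferentialMatrix:
    """Principal matrix logarithm split into mean and depolarizing parts."""
    log, valid = logm_stack(M.f)
    if not valid:
        raise NonPhysicalMatrixError(
            "matrix has no real principal logarithm (eigenvalue on the "
            "negative real axis)"
        )
    mean, depol = g_split(log)
    np.fill_diagonal(mean, 0.0)
    return DifferentialMatrix(mean_part=mean, depol_part=depol)


# element pairs of the literal log-ratio reconstruction, one per parameter,
# ordered like AnisotropyParams.as_array(); 0-based (row, col)
_ELEMENTWISE_PAIRS = (
    ((1, 3), (3, 1)),  # Φ0,90
    ((2, 3), (3, 2)),  # Φ45,135
    ((2, 1), (1, 2)),  # Φ⊗,⊕
    ((0, 1), (1, 0)),  # Δ0,90
    ((0, 2), (2, 0)),  # Δ45,135
    ((0, 3), (3, 0)),  # Δ⊗,⊕
)


def elementwise_params(f: np.ndarray) -> np.ndarray:
    """Literal per-element log-ratio reconstruction, 0.5·ln(f_ik/f_ki).

    Retained for comparison with the matrix-logarithm route.  The log-ratio
    is undefined wherever the element ratio is non-positive (always the case
    for a pure retarder, whose paired elements have opposite signs); such
    entries are NaN sentinels.  Pairs where both elements are numerically
    zero give 0, so the identity matrix maps to vanishing anisotropy.
    """
    f = np.asarray(f, dtype=float)
    out = np.full(f.shape[:-2] + (6,), np.nan)
    with np.errstate(all="ignore"):
        for j, ((i1, k1), (i2, k2)) in enumerate(_ELEMENTWISE_PAIRS):
            num = f[..., i1, k1]
            den = f[..., i2, k2]
            ratio = num / den
            val = 0.5 * np.log(ratio)
            both_zero = (np.abs(num) < 1e-12) & (np.abs(den) < 1e-12)
            val = np.where(both_zero, 0.0, val)
            val = np.where(ratio > 0, val, np.where(both_zero, 0.0, np.nan))
            out[..., j] = val
    return out


def reconstruct_differential(
    M: MuellerMatrix,
    geom: MeasurementGeometry | None = None,
    mode: str = "matrix_log",
) -> AnisotropyParams:
    """Recover the six anisotropy parameters from a normalized Mueller matrix.

    ``matrix_log`` (default): principal logarithm + G-symmetry split; exact
    for any matrix generated by a per-layer differential model, phases
    recovered in (-π, π].  ``elementwise``: literal per-element log-ratios,
    NaN where undefined.
    """
    if mode == "matrix_log":
        d = decompose_differential(M)
        vals = params_from_mean_matrix(d.mean_part)
    elif mode == "elementwise":
        vals = elementwise_params(M.f)
        if np.isnan(vals).any():
            return AnisotropyParams._with_sentinels(vals)
    else:
        raise ValueError(f"unknown reconstruction mode: {mode!r}")
    return AnisotropyParams(*(float(v) for v in vals))


def reconstruct_stack(
    data: np.ndarray, mode: str = "matrix_log"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel reconstruction over a stack (..., 4, 4) of normalized
    matrices.  Returns (params (..., 6), valid mask); invalid pixels are NaN.
    """
    data = np.asarray(data, dtype=float)
    if mode == "matrix_log":
        log, valid = logm_stack(data)
        mean, _ = g_split(log)
        vals = params_from_mean_matrix(mean)
        vals[~valid] = np.nan
    elif mode == "elementwise":
        vals = elementwise_params(data)
        valid = np.isfinite(vals).all(axis=-1)
    else:
        raise ValueError(f"unknown reconstruction mode: {mode!r}")
    return vals, valid


# ---------------------------------------------------------------------------
# derived scalar observables
# ---------------------------------------------------------------------------

def generalized_linear(p: AnisotropyParams) -> tuple[float, float]:
    """Generalized linear birefringence and dichroism.

    Quadrature magnitude of the two linear component pairs:
    ΦL = sqrt(Φ0,90² + Φ45,135²), ΔL = sqrt(Δ0,90² + Δ45,135²); invariant to
    the sign of either component.
    """
    phi_l = float(np.hypot(p.phi_0_90, p.phi_45_135))
    delta_l = float(np.hypot(p.delta_0_90, p.delta_45_135))
    return phi_l, delta_l


def depolarization_degree(M: MuellerMatrix | np.ndarray) -> float | np.ndarray:
    """Depolarization degree Λ in percent.

    Defined through the single-matrix depolarization index,
    Λ = (1 - sqrt((Σ f_ik² - f11²) / (3 f11²))) · 100, clipped to [0, 100]:
    0 for any pure (non-depolarizing) matrix, 100 for the ideal depolarizer
    diag(1, 0, 0, 0).
    """
    f = M.f if isinstance(M, MuellerMatrix) else np.asarray(M, dtype=float)
    f11 = f[..., 0, 0]
    q = (np.sum(f * f, axis=(-2, -1)) - f11**2) / (3.0 * f11**2)
    lam = (1.0 - np.sqrt(np.clip(q, 0.0, None))) * 100.0
    lam = np.clip(lam, 0.0, 100.0)
    return float(lam) if lam.ndim == 0 else lam
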