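"""Layered per-pixel maps of the four anisotropy observables.

For each phase plane, the per-pixel Mueller matrices are decomposed into the
six anisotropy parameters and collapsed to the four scalar observables used
for diagnosis: generalized linear birefringence ΦL, circular birefringence,
generalized linear dichroism ΔL, and circular dichroism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MuellerMap, reconstruct_stack
from .geometry import MeasurementGeometry

__all__ = ["AnisotropyMapSet", "OBSERVABLES", "layered_anisotropy", "plane_profile"]

#: canonical observable labels, in map-set page order
OBSERVABLES = ("phi_l", "phi_circ", "delta_l", "delta_circ")


@dataclass(frozen=True)
class AnisotropyMapSet:
    """Four observable grids at one phase plane, with a validity mask.

    ``phi_l``/``delta_l`` are quadrature magnitudes (non-negative); the
    circular maps are signed.  Sentinel (invalid) pixels are NaN and False
    in ``valid``.
    """

    phi_l: np.ndarray
    phi_circ: np.ndarray
    delta_l: np.ndarray
    delta_circ: np.ndarray
    valid: np.ndarray
    phase_plane: float = 0.6
    geometry: MeasurementGeometry = field(default_factory=MeasurementGeometry)

    def __post_init__(self) -> None:
        shp = np.asarray(self.phi_l).shape
        for name in OBSERVABLES + ("valid",):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shp:
                raise ValueError(f"grid {name} has shape {arr.shape}, expected {shp}")
        v = np.asarray(self.valid, dtype=bool)
        for name in ("phi_l", "delta_l"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if (arr[v] < 0).any():
                raise ValueError(f"{name} must be non-negative on valid pixels")
        object.__setattr__(self, "valid", v)

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.phi_l).shape

    def observable(self, name: str) -> np.ndarray:
        if name not in OBSERVABLES:
            raise KeyError(f"unknown observable {name!r}; expected one of {OBSERVABLES}")
        return np.asarray(getattr(self, name), dtype=float)

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid))


def layered_anisotropy(
    mm: MuellerMap, phi_k: float = 0.6, mode: str = "matrix_log"
) -> AnisotropyMapSet:
    """Reconstruct the four anisotropy observable maps of one phase plane.

    Runs the per-pixel differential reconstruction (principal matrix
    logarithm by default) and combines the linear component pairs in
    quadrature.  Pixels where the decomposition is undefined become NaN
    sentinels; if they exceed half the map a degraded-quality warning is
    emitted.
    """
    vals, valid = reconstruct_stack(mm.data, mode=mode)
    phi_l = np.hypot(vals[..., 0], vals[..., 1])
    delta_l = np.hypot(vals[..., 3], vals[..., 4])
    out = AnisotropyMapSet(
        phi_l=phi_l,
        phi_circ=vals[..., 2],
        delta_l=delta_l,
        delta_circ=vals[..., 5],
        valid=valid,
        phase_plane=float(phi_k),
        geometry=mm.geometry,
    )
    if out.valid_fraction < 0.5:
        warnings.warn(
            f"only {out.valid_fraction:.0%} of pixels reconstructed; "
            "map quality degraded",
            stacklevel=2,
        )
    return out


def plane_profile(stack, statistic=None) -> dict[str, np.ndarray]:
    """Per-plane curve of a scalar statistic of each observable.

    ``stack`` is a sequence of AnisotropyMapSet at increasing phase planes
    (at least two).  ``statistic`` maps a 1D array of valid pixel values to
    a scalar; default is the mean (the first-order moment).  Returns a dict
    with key "phase_plane" plus one curve per observable.
    """
    stack = list(stack)
    if len(stack) < 2:
        raise ValueError("plane_profile needs at least two phase planes")
    if statistic is None:
        statistic = np.mean
    phis = np.array([ms.phase_plane for ms in stack], dtype=float)
    out: dict[str, np.ndarray] = {"phase_plane": phis}
    for name in OBSERVABLES:
        out[name] = np.array(
            [float(statistic(ms.observable(name)[ms.valid])) for ms in stack]
        )
    return out
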