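"""Measurement geometry and bulk optical constants.

The layered-medium model is parametrized by the probing wavelength and the
section thickness; the six anisotropy parameters are accumulated phase /
amplitude differences over that thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class InvalidGeometryError(ValueError):
    """Raised for non-physical measurement geometry (λ ≤ 0 or l ≤ 0)."""


@dataclass(frozen=True)
class MeasurementGeometry:
    """Probing geometry of a single histological section.

    Parameters
    ----------
    wavelength:
        Laser wavelength λ in micrometres (He-Ne default, 0.6328 µm).
    thickness:
        Section thickness l in micrometres (microtome sections, 40 µm default).
    """

    wavelength: float = 0.6328
    thickness: float = 40.0

    def __post_init__(self) -> None:
        if not (self.wavelength > 0):
            raise InvalidGeometryError(f"wavelength must be > 0, got {self.wavelength}")
        if not (self.thickness > 0):
            raise InvalidGeometryError(f"thickness must be > 0, got {self.thickness}")


#: order of the six polarization components used throughout the package
COMPONENT_LABELS = ("0", "90", "45", "135", "rc", "lc")


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices n_j and absorption coefficients τ_j per component.

    ``j`` runs over the linear 0°/90°/45°/135° and the right-/left-circular
    components.  Units: n dimensionless, τ per micrometre.
    """

    n: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for j in COMPONENT_LABELS:
            nj = self.n.get(j, 1.0)
            tj = self.tau.get(j, 0.0)
            if not nj > 0:
                raise ValueError(f"refractive index n[{j!r}] must be > 0, got {nj}")
            if tj < 0:
                raise ValueError(f"absorption tau[{j!r}] must be >= 0, got {tj}")

    def index_difference(self, a: str, b: str) -> float:
        return self.n.get(a, 1.0) - self.n.get(b, 1.0)

    def absorption_difference(self, a: str, b: str) -> float:
        return self.tau.get(a, 0.0) - self.tau.get(b, 0.0)
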