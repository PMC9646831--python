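"""Porous-medium representation of endovascular coil packing.

The coiled part of the sac is treated as an isotropic porous medium acting
on the (superficial) velocity through a Darcy-Forchheimer momentum sink

    S = -(mu/k) u - (C2/2) rho |u| u        [N/m^3]

with the permeability from the Kozeny-Carman closure

    k = eps^3 d_w^2 / (180 (1-eps)^2)

and the inertial coefficient from the Ergun closure

    C2 = 3.5 (1-eps) / (d_w eps^3),

``eps`` being the void fraction (porosity) and ``d_w`` the coil wire
diameter.  Both coefficients can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_WIRE_DIAMETER = 2.5e-4  # m, typical platinum coil wire


class CoilModelError(ValueError):
    """Invalid coil parameters."""


def permeability_from_porosity(eps: float, d_w: float = DEFAULT_WIRE_DIAMETER) -> float:
    """Kozeny-Carman permeability (m^2) of a coil mass of porosity ``eps``."""
    if not 0.0 < eps < 1.0:
        raise CoilModelError(f"porosity must lie in (0, 1), got {eps!r}")
    if d_w <= 0.0:
        raise CoilModelError("wire diameter must be positive")
    return eps**3 * d_w**2 / (180.0 * (1.0 - eps) ** 2)


def ergun_inertial_coefficient(eps: float, d_w: float = DEFAULT_WIRE_DIAMETER) -> float:
    """Ergun inertial-loss coefficient C2 (1/m)."""
    if not 0.0 < eps < 1.0:
        raise CoilModelError(f"porosity must lie in (0, 1), got {eps!r}")
    if d_w <= 0.0:
        raise CoilModelError("wire diameter must be positive")
    return 3.5 * (1.0 - eps) / (d_w * eps**3)


@dataclass(frozen=True)
class CoilProperties:
    """Porosity, wire diameter and derived Darcy-Forchheimer coefficients."""

    porosity: float
    wire_diameter: float = DEFAULT_WIRE_DIAMETER
    permeability_override: float | None = None
    inertial_override: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise CoilModelError(f"porosity must lie in (0, 1), got {self.porosity!r}")
        if self.wire_diameter <= 0.0:
            raise CoilModelError("wire diameter must be positive")
        if self.permeability_override is not None and self.permeability_override <= 0.0:
            raise CoilModelError("permeability must be positive")
        if self.inertial_override is not None and self.inertial_override < 0.0:
            raise CoilModelError("inertial coefficient must be >= 0")

    @property
    def permeability(self) -> float:
        if self.permeability_override is not None:
            return self.permeability_override
        return permeability_from_porosity(self.porosity, self.wire_diameter)

    @property
    def inertial_coefficient(self) -> float:
        if self.inertial_override is not None:
            return self.inertial_override
        return ergun_inertial_coefficient(self.porosity, self.wire_diameter)


def momentum_sink(
    u_vec: np.ndarray, mu: float | np.ndarray, rho: float, props: CoilProperties
) -> np.ndarray:
    """Darcy-Forchheimer body-force density (N/m^3) for velocity ``u_vec``.

    ``u_vec`` has shape (..., 2); ``mu`` may be scalar or broadcastable over
    the leading axes.  Only cells flagged by the mesh coil mask should
    receive this force; the caller applies the mask.
    """
    u = np.asarray(u_vec, dtype=float)
    speed = np.linalg.norm(u, axis=-1, keepdims=True)
    mu_arr = np.asarray(mu, dtype=float)[..., None] if np.ndim(mu) else mu
    darcy = -(mu_arr / props.permeability) * u
    forch = -0.5 * props.inertial_coefficient * rho * speed * u
    return darcy + forch


def sink_linear_coefficient(
    mu: float | np.ndarray, speed: float | np.ndarray, rho: float, props: CoilProperties
) -> float | np.ndarray:
    """Coefficient ``c`` such that S = -c u, for implicit treatment.

    c = mu/k + (C2/2) rho |u|; evaluated with the lagged speed.
    """
    return np.asarray(mu) / props.permeability + (
        0.5 * props.inertial_coefficient * rho * np.asarray(speed)
    )
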