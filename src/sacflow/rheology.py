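"""Blood rheology: regularized Casson apparent viscosity with haematocrit
closures, plus a Newtonian fallback.

The Casson law gives the apparent viscosity

    mu_app(gamma) = ( sqrt(mu_inf) + sqrt(tau_y / gamma) )^2

with the shear rate clamped below at ``gamma_min`` so the zero-shear
singularity is bounded.  Neither the asymptotic viscosity ``mu_inf(H)``
nor the yield stress ``tau_y(H)`` is standardized, so both are explicit,
overridable closures:

    mu_inf(H) = mu_p * (1 - H)^(-2.5)          (Einstein-type suspension law)
    tau_y(H)  = A * (H - H_c)^3,  H > H_c      (cubic yield-stress law)

Defaults give tau_y(0.40) ~ 5 mPa and mu_inf(0.40) ~ 5.2 mPa.s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_DENSITY = 1060.0  # kg/m^3
DEFAULT_PLASMA_VISCOSITY = 1.45e-3  # Pa.s
DEFAULT_YIELD_COEFFICIENT = 0.185  # Pa, cubic-law prefactor
DEFAULT_CRITICAL_HCT = 0.1
DEFAULT_GAMMA_MIN = 1.0e-3  # 1/s


class RheologyError(ValueError):
    """Invalid rheological parameters or inputs."""


@dataclass(frozen=True)
class BloodProperties:
    """Density, haematocrit and Casson coefficients for whole blood.

    ``mu_inf_override``/``tau_y_override`` bypass the haematocrit closures;
    ``model='newtonian'`` uses ``mu_inf`` as a constant viscosity.
    """

    density: float = DEFAULT_DENSITY
    hct: float = 0.40
    plasma_viscosity: float = DEFAULT_PLASMA_VISCOSITY
    yield_coefficient: float = DEFAULT_YIELD_COEFFICIENT
    critical_hct: float = DEFAULT_CRITICAL_HCT
    viscosity_exponent: float = -2.5
    gamma_min: float = DEFAULT_GAMMA_MIN
    model: str = "casson"
    mu_inf_override: float | None = None
    tau_y_override: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0.0:
            raise RheologyError("density must be positive")
        if not 0.0 < self.hct < 1.0:
            raise RheologyError("haematocrit must lie in (0, 1)")
        if self.plasma_viscosity <= 0.0:
            raise RheologyError("plasma_viscosity must be positive")
        if self.gamma_min <= 0.0:
            raise RheologyError("gamma_min must be positive")
        if self.model not in ("casson", "newtonian"):
            raise RheologyError(f"unknown rheology model {self.model!r}")
        if self.mu_inf < self.plasma_viscosity:
            raise RheologyError("asymptotic viscosity below plasma viscosity")
        if self.tau_y < 0.0:
            raise RheologyError("yield stress must be >= 0")

    @property
    def mu_inf(self) -> float:
        """Asymptotic (high-shear) viscosity, Pa.s."""
        if self.mu_inf_override is not None:
            return self.mu_inf_override
        return self.plasma_viscosity * (1.0 - self.hct) ** self.viscosity_exponent

    @property
    def tau_y(self) -> float:
        """Casson yield stress, Pa."""
        if self.tau_y_override is not None:
            return self.tau_y_override
        if self.model == "newtonian":
            return 0.0
        excess = self.hct - self.critical_hct
        return self.yield_coefficient * excess**3 if excess > 0.0 else 0.0

    @property
    def max_viscosity(self) -> float:
        """Apparent viscosity at the clamped (minimum) shear rate."""
        return casson_viscosity(0.0, self)


def casson_viscosity(
    gamma_dot: float | np.ndarray, props: BloodProperties
) -> float | np.ndarray:
    """Apparent viscosity (Pa.s) at shear rate ``gamma_dot`` (1/s).

    Vectorized over ``gamma_dot``; the shear rate is clamped at
    ``props.gamma_min`` so the result is finite for all inputs.
    """
    gamma = np.asarray(gamma_dot, dtype=float)
    if np.any(gamma < 0.0):
        raise RheologyError("shear rate must be non-negative")
    if props.model == "newtonian":
        out = np.full_like(gamma, props.mu_inf)
        return float(out) if np.isscalar(gamma_dot) else out
    g = np.maximum(gamma, props.gamma_min)
    mu = (np.sqrt(props.mu_inf) + np.sqrt(props.tau_y / g)) ** 2
    return float(mu) if np.isscalar(gamma_dot) else mu
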