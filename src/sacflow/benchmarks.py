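"""Closed-form reference solutions used to validate the solver.

These are independent of the discretization: plane Poiseuille flow, the
oscillatory (Womersley-type) pressure-driven channel, and the 1-D Darcy
pressure drop.  All assume a straight channel of width ``h`` with walls at
y = +-h/2.
"""

from __future__ import annotations

import numpy as np


def poiseuille_profile(y: np.ndarray, u_mean: float, width: float) -> np.ndarray:
    """Steady plane-Poiseuille velocity; y measured from the centerline."""
    return 1.5 * u_mean * (1.0 - (2.0 * np.asarray(y) / width) ** 2)


def poiseuille_wall_shear(mu: float, u_mean: float, width: float) -> float:
    """|WSS| on either wall: 6 mu U / h."""
    return 6.0 * mu * u_mean / width


def poiseuille_pressure_gradient(mu: float, u_mean: float, width: float) -> float:
    """-dp/dx sustaining the flow: 12 mu U / h^2."""
    return 12.0 * mu * u_mean / width**2


def womersley_number(half_width: float, omega: float, rho: float, mu: float) -> float:
    return half_width * np.sqrt(omega * rho / mu)


def oscillatory_channel_velocity(
    y: np.ndarray, t: float | np.ndarray, grad_amp: float, omega: float,
    rho: float, mu: float, width: float,
) -> np.ndarray:
    """Velocity of the channel flow driven by -dp/dx = grad_amp*cos(omega t).

    Exact solution of rho u_t = grad_amp cos(omega t) + mu u_yy with
    no-slip walls at y = +-width/2.
    """
    nu = mu / rho
    R = width / 2.0
    beta = np.sqrt(1j * omega / nu)
    prof = (grad_amp / (1j * rho * omega)) * (
        1.0 - np.cosh(beta * np.asarray(y)) / np.cosh(beta * R)
    )
    return np.real(prof * np.exp(1j * omega * np.asarray(t)))


def darcy_pressure_drop(mu: float, k: float, u_superficial: float, length: float) -> float:
    """1-D Darcy law: dp = (mu/k) U L for a fully porous channel."""
    return mu / k * u_superficial * length
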