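"""Analytic pulsatile inlet waveform and cardiac-phase landmark detection.

The inlet mean velocity over one cycle is a truncated Fourier series

    u(t) = U_mean + sum_k a_k * cos(2*pi*k*t/T + phi_k)

chosen to mimic an arterial flow pulse: a steep systolic upstroke, a
single dominant peak and a quiet diastole, strictly positive throughout.
Four landmark instants are extracted from it: maximum acceleration (A),
peak systole (B), maximum deceleration (C) and early diastole (D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_DENSE_GRID = 100_001


class WaveformError(ValueError):
    """Invalid or degenerate waveform."""


@dataclass(frozen=True)
class Waveform:
    """Periodic positive inlet mean-velocity signal.

    ``harmonics`` is a sequence of ``(amplitude, phase)`` pairs for
    k = 1, 2, ... in the cosine series above.
    """

    period: float = 0.8
    mean_velocity: float = 0.3
    harmonics: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: (
            (0.45 * 0.3, -1.9),
            (0.22 * 0.3, -2.8),
            (0.10 * 0.3, -3.7),
        )
    )
    min_velocity: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0.0:
            raise WaveformError("period must be positive")
        if self.mean_velocity <= 0.0:
            raise WaveformError("mean_velocity must be positive")
        u = self(np.linspace(0.0, self.period, 4096, endpoint=False))
        if np.any(u <= self.min_velocity):
            raise WaveformError(
                f"waveform dips to {u.min():.4g} m/s; inlet flow reversal "
                f"(u <= {self.min_velocity:g}) is not allowed"
            )

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        """Mean inlet speed (m/s) at time ``t`` (reduced modulo the period)."""
        tt = np.asarray(t, dtype=float)
        omega = 2.0 * np.pi / self.period
        u = np.full_like(tt, self.mean_velocity)
        for k, (a, phi) in enumerate(self.harmonics, start=1):
            u = u + a * np.cos(k * omega * tt + phi)
        return float(u) if np.isscalar(t) else u

    def derivative(self, t: float | np.ndarray) -> float | np.ndarray:
        """du/dt (m/s^2), analytic."""
        tt = np.asarray(t, dtype=float)
        omega = 2.0 * np.pi / self.period
        du = np.zeros_like(tt)
        for k, (a, phi) in enumerate(self.harmonics, start=1):
            du = du - a * k * omega * np.sin(k * omega * tt + phi)
        return float(du) if np.isscalar(t) else du

    @property
    def peak_velocity(self) -> float:
        t = np.linspace(0.0, self.period, _DENSE_GRID)
        return float(np.max(self(t)))

    def is_constant(self, rtol: float = 1e-12) -> bool:
        return all(abs(a) <= rtol * self.mean_velocity for a, _ in self.harmonics)

    def sample_csv(self, path, dt: float) -> None:
        """Write ``t, u`` samples of one cycle at step ``dt`` as CSV."""
        n = int(round(self.period / dt))
        t = np.arange(n + 1) * dt
        arr = np.column_stack([t, self(t)])
        np.savetxt(path, arr, delimiter=",", header="time_s,mean_velocity_m_per_s",
                   comments="", fmt="%.10g")


def inlet_velocity(t: float | np.ndarray, w: Waveform) -> float | np.ndarray:
    """Functional alias for ``w(t)``."""
    return w(t)


def parabolic_profile(xi: float | np.ndarray, u_mean: float) -> float | np.ndarray:
    """Plane-Poiseuille inlet shape: 6*u_mean*xi*(1-xi), xi in [0, 1]."""
    return 6.0 * u_mean * np.asarray(xi) * (1.0 - np.asarray(xi))


@dataclass(frozen=True)
class PhaseLandmarks:
    """Times (s, within [0, T)) of the four reporting instants."""

    t_A: float  # maximum acceleration
    t_B: float  # peak systole
    t_C: float  # maximum deceleration
    t_D: float  # early diastole

    def as_dict(self) -> dict[str, float]:
        return {"A": self.t_A, "B": self.t_B, "C": self.t_C, "D": self.t_D}

    def ordered(self) -> list[tuple[str, float]]:
        return sorted(self.as_dict().items(), key=lambda kv: kv[1])


def _refine_extremum(f, t0: float, dt: float, sign: float) -> float:
    """Parabolic refinement of a grid extremum of ``sign*f``."""
    ts = np.array([t0 - dt, t0, t0 + dt])
    ys = sign * np.asarray(f(ts))
    denom = ys[0] - 2.0 * ys[1] + ys[2]
    if denom >= 0.0 or abs(denom) < 1e-300:
        return t0
    return t0 + 0.5 * dt * (ys[0] - ys[2]) / denom


def phase_landmarks(w: Waveform, n_grid: int = _DENSE_GRID) -> PhaseLandmarks:
    """Locate the four phase landmarks of a pulsatile waveform.

    A = argmax du/dt, B = argmax u, C = argmin du/dt, and D = argmin u
    restricted to the half-cycle following C (early-diastole convention).
    Times are reported relative to a cycle rotated so that A comes first;
    near-ties resolve to the earliest time (with a warning).
    """
    if w.is_constant():
        raise WaveformError("constant waveform has no phase landmarks")
    T = w.period
    t = np.linspace(0.0, T, n_grid, endpoint=False)
    dt = t[1] - t[0]
    u = np.asarray(w(t))
    du = np.asarray(w.derivative(t))

    def grid_argopt(y: np.ndarray, maximize: bool) -> int:
        opt = y.max() if maximize else y.min()
        close = np.flatnonzero(np.isclose(y, opt, rtol=0.0, atol=1e-9 * max(abs(opt), 1.0)))
        runs = np.flatnonzero(np.diff(close) > 1)
        if len(runs) > 0:
            warnings.warn(
                "non-unique waveform extremum within tolerance; earliest time chosen",
                stacklevel=2,
            )
        return int(close[0])

    iA = grid_argopt(du, maximize=True)
    tA = _refine_extremum(w.derivative, t[iA], dt, +1.0) % T
    # rotate the cycle so A is the origin, then find B, C, D downstream
    off = np.linspace(0.0, T, n_grid, endpoint=False)
    tr = tA + off
    ur = np.asarray(w(tr))
    dur = np.asarray(w.derivative(tr))
    iB = grid_argopt(ur, maximize=True)
    tB = _refine_extremum(w, tr[iB], dt, +1.0)
    iC_rel = grid_argopt(np.where(off > off[iB], dur, np.inf), maximize=False)
    tC = _refine_extremum(w.derivative, tr[iC_rel], dt, -1.0)
    # early diastole: minimum of u within the half cycle after C
    half = (tr > tC) & (tr <= tC + T / 2.0)
    uD = np.where(half, ur, np.inf)
    iD = grid_argopt(uD, maximize=False)
    tD = _refine_extremum(w, tr[iD], dt, -1.0)

    tB_r, tC_r, tD_r = ((x - tA) % T for x in (tB, tC, tD))
    if not (0.0 < tB_r < tC_r <= tD_r):
        raise WaveformError(
            f"landmark ordering A < B < C <= D violated after rotation: "
            f"B={tB_r:.4g}, C={tC_r:.4g}, D={tD_r:.4g} (T={T:g})"
        )
    return PhaseLandmarks(t_A=tA % T, t_B=tB % T, t_C=tC % T, t_D=tD % T)
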