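"""Transient incompressible flow solver with Casson viscosity and a porous
coil sink.

Discretization: P1 (linear) finite elements on triangles (quadrilateral
meshes are split internally), lumped mass, and an incremental
pressure-projection scheme per time step:

1. tentative velocity -- implicit variable-viscosity diffusion, implicit
   linearized convection and implicit Darcy-Forchheimer sink (lagged
   coefficients), old pressure gradient on the right-hand side;
2. pressure-increment Poisson solve with Dirichlet pressure at the outlet
   (and at the inlet when pressure-driven);
3. velocity correction with the lumped-mass inverse.

The viscous term uses the component-wise form div(mu grad u); for constant
viscosity and solenoidal fields this coincides with the full stress
divergence.  Convection and the Casson viscosity are evaluated from the
previous iterate (one Picard pass by default; more via
``max_inner_iterations``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .coil_model import CoilProperties, sink_linear_coefficient
from .geometry_mesh import BoundaryTag, Mesh
from .rheology import BloodProperties, casson_viscosity
from .waveform import Waveform, PhaseLandmarks, parabolic_profile, phase_landmarks


class SolverError(RuntimeError):
    """Solver failure (divergence, NaN field, non-converged inner loop)."""


@dataclass(frozen=True)
class SolverConfig:
    """Time stepping and tolerance settings."""

    dt: float = 0.8 / 1000.0
    cycles_to_run: int = 3
    cycles_to_discard: int = 2
    pressure_velocity_scheme: str = "projection"
    divergence_tolerance: float = 1.0e-2  # 1/s, on |net boundary flux| / area
    nonlinear_tolerance: float = 1.0e-3
    max_inner_iterations: int = 1
    steady_tolerance: float = 1.0e-7
    max_steady_steps: int = 50_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.cycles_to_run < self.cycles_to_discard + 1:
            raise ValueError("cycles_to_run must exceed cycles_to_discard")
        if self.divergence_tolerance <= 0.0 or self.nonlinear_tolerance <= 0.0:
            raise ValueError("tolerances must be positive")
        if self.max_inner_iterations < 1:
            raise ValueError("max_inner_iterations must be >= 1")
        if self.pressure_velocity_scheme not in ("projection", "simple"):
            raise ValueError(
                f"unknown pressure_velocity_scheme {self.pressure_velocity_scheme!r}"
            )
        if self.pressure_velocity_scheme == "simple":
            raise NotImplementedError(
                "only the projection pressure-velocity scheme is implemented"
            )


@dataclass
class BoundaryConditions:
    """Inlet/outlet driving for the channel or aneurysm domain.

    ``inlet='velocity'`` imposes a profile scaled to the instantaneous mean
    speed ``inlet_velocity(t)``; ``inlet='pressure'`` leaves the inlet
    velocity natural and fixes the pressure there instead.
    """

    inlet: str = "velocity"
    inlet_profile: str = "parabolic"  # or "uniform"
    inlet_velocity: Callable[[float], float] | None = None
    inlet_pressure: Callable[[float], float] | None = None
    outlet_pressure: float = 0.0
    body_force: Callable[[float], tuple[float, float]] | None = None
    ramp_time: float = 0.0  # smooth start from rest over [0, ramp_time]

    def __post_init__(self) -> None:
        if self.inlet not in ("velocity", "pressure"):
            raise ValueError(f"unknown inlet mode {self.inlet!r}")
        if self.inlet_profile not in ("parabolic", "uniform"):
            raise ValueError(f"unknown inlet profile {self.inlet_profile!r}")
        if self.inlet == "velocity" and self.inlet_velocity is None:
            raise ValueError("velocity inlet requires inlet_velocity(t)")
        if self.inlet == "pressure" and self.inlet_pressure is None:
            raise ValueError("pressure inlet requires inlet_pressure(t)")


@dataclass
class FlowState:
    """Velocity/pressure fields at one instant plus the cycle clock."""

    u: np.ndarray  # (n_nodes, 2)
    p: np.ndarray  # (n_nodes,)
    t: float
    mu_cell: np.ndarray  # (n_tris,) apparent viscosity

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)

    def copy(self) -> "FlowState":
        return FlowState(self.u.copy(), self.p.copy(), self.t, self.mu_cell.copy())


@dataclass
class StepDiagnostics:
    divergence_residual: float
    inner_iterations: int
    inner_residuals: list[float] = field(default_factory=list)


class ProjectionSolver:
    """Incremental pressure-projection solver bound to one mesh."""

    def __init__(
        self,
        mesh: Mesh,
        props: BloodProperties,
        coil: CoilProperties | None = None,
        bc: BoundaryConditions | None = None,
        cfg: SolverConfig | None = None,
    ) -> None:
        mesh.validate()
        self.mesh = mesh
        self.props = props
        self.coil = coil
        self.bc = bc if bc is not None else BoundaryConditions(
            inlet_velocity=lambda t: 0.0
        )
        self.cfg = cfg if cfg is not None else SolverConfig()
        self._setup_fem()
        self._setup_boundaries()
        self._setup_pressure_solver()

    # ----- precomputation -------------------------------------------------

    def _setup_fem(self) -> None:
        tris, parent = self.mesh.triangulated()
        pts = self.mesh.points
        self.tris = tris
        self.n = len(pts)
        self.nt = len(tris)
        x = pts[tris, 0]
        y = pts[tris, 1]
        area = 0.5 * (
            (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
            - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
        )
        if np.any(area <= 0.0):
            raise SolverError("triangulation contains non-positive areas")
        self.area = area
        b = np.stack(
            [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
        ) / (2.0 * area[:, None])
        c = np.stack(
            [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
        ) / (2.0 * area[:, None])
        self.gradx, self.grady = b, c

        self.mL = np.zeros(self.n)
        np.add.at(self.mL, tris.ravel(), np.repeat(area / 3.0, 3))

        # sparsity pattern for 3x3 element blocks
        self.rows = np.repeat(tris, 3, axis=1).ravel()
        self.cols = np.tile(tris, (1, 3)).ravel()
        # geometric stiffness factors: S[e,i,j] = area * (b_i b_j + c_i c_j)
        self.S_geom = area[:, None, None] * (
            b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]
        )

        # weak gradient operators: (Gx p)_i = int phi_i dp/dx
        gx_data = (np.repeat(area / 3.0, 9) * np.tile(b, (1, 3)).ravel())
        gy_data = (np.repeat(area / 3.0, 9) * np.tile(c, (1, 3)).ravel())
        shape = (self.n, self.n)
        self.Gx = sp.coo_matrix((gx_data, (self.rows, self.cols)), shape=shape).tocsr()
        self.Gy = sp.coo_matrix((gy_data, (self.rows, self.cols)), shape=shape).tocsr()

        self.tri_coil = self.mesh.tri_coil_mask
        self.domain_area = float(area.sum())

    def _setup_boundaries(self) -> None:
        mesh = self.mesh
        wall_nodes = np.union1d(
            mesh.boundary_nodes(BoundaryTag.VESSEL_WALL),
            mesh.boundary_nodes(BoundaryTag.SAC_WALL),
        )
        inlet_nodes = mesh.boundary_nodes(BoundaryTag.INLET)
        outlet_nodes = mesh.boundary_nodes(BoundaryTag.OUTLET)
        self.wall_nodes = wall_nodes
        self.inlet_nodes = inlet_nodes
        self.outlet_nodes = outlet_nodes

        if self.bc.inlet == "velocity":
            vel_fixed = np.union1d(wall_nodes, inlet_nodes)
        else:
            vel_fixed = wall_nodes
        self.vel_fixed = vel_fixed
        mask = np.zeros(self.n, dtype=bool)
        mask[vel_fixed] = True
        self.vel_fixed_mask = mask
        self._keep = sp.diags((~mask).astype(float))
        self._fix = sp.diags(mask.astype(float))

        # inlet face geometry: cross-face coordinate and inward direction
        ie = mesh.boundary_edges[mesh.boundary_tags == int(BoundaryTag.INLET)]
        pts = mesh.points[inlet_nodes]
        e0 = mesh.points[ie[0, 0]]
        e1 = mesh.points[ie[0, 1]]
        tang = e1 - e0
        tang = tang / np.linalg.norm(tang)
        proj = (pts - pts.mean(axis=0)) @ tang
        span = proj.max() - proj.min()
        self.inlet_xi = (proj - proj.min()) / span
        self.inlet_width = float(span)
        inward = np.array([-tang[1], tang[0]])  # CCW boundary: outward=(t_y,-t_x)
        self.inlet_direction = inward

        # pressure Dirichlet set
        if self.bc.inlet == "pressure":
            self.p_fixed = np.union1d(outlet_nodes, inlet_nodes)
        else:
            self.p_fixed = outlet_nodes

        # boundary-flux quadrature (trapezoid per edge, outward normal)
        be = mesh.boundary_edges
        d = mesh.points[be[:, 1]] - mesh.points[be[:, 0]]
        lengths = np.linalg.norm(d, axis=1)
        self.b_edges = be
        self.b_normals = np.stack([d[:, 1], -d[:, 0]], axis=1) / lengths[:, None]
        self.b_lengths = lengths

    def _setup_pressure_solver(self) -> None:
        data = self.S_geom.ravel()
        A = sp.coo_matrix((data, (self.rows, self.cols)), shape=(self.n, self.n)).tocsr()
        self._Ap_raw = A
        mask = np.zeros(self.n, dtype=bool)
        mask[self.p_fixed] = True
        self.p_fixed_mask = mask
        keep = sp.diags((~mask).astype(float))
        fix = sp.diags(mask.astype(float))
        Ap = (keep @ A + fix).tocsc()
        self._Ap_lu = splu(Ap)
        self._Ap_cols = A[:, self.p_fixed]

    # ----- state ----------------------------------------------------------

    def initial_state(self, t: float = 0.0) -> FlowState:
        u = np.zeros((self.n, 2))
        if self.cfg.seed is not None:
            rng = np.random.default_rng(self.cfg.seed)
            scale = 1e-6
            u += scale * rng.standard_normal(u.shape)
            u[self.vel_fixed_mask] = 0.0
        p = np.zeros(self.n)
        mu = self._viscosity_field(u)
        return FlowState(u=u, p=p, t=t, mu_cell=mu)

    def _viscosity_field(self, u: np.ndarray) -> np.ndarray:
        dudx = np.einsum("ti,ti->t", self.gradx, u[self.tris, 0])
        dudy = np.einsum("ti,ti->t", self.grady, u[self.tris, 0])
        dvdx = np.einsum("ti,ti->t", self.gradx, u[self.tris, 1])
        dvdy = np.einsum("ti,ti->t", self.grady, u[self.tris, 1])
        gamma = np.sqrt(
            2.0 * dudx**2 + 2.0 * dvdy**2 + (dudy + dvdx) ** 2
        )
        return np.asarray(casson_viscosity(gamma, self.props))

    def shear_rate_field(self, u: np.ndarray) -> np.ndarray:
        dudx = np.einsum("ti,ti->t", self.gradx, u[self.tris, 0])
        dudy = np.einsum("ti,ti->t", self.grady, u[self.tris, 0])
        dvdx = np.einsum("ti,ti->t", self.gradx, u[self.tris, 1])
        dvdy = np.einsum("ti,ti->t", self.grady, u[self.tris, 1])
        return np.sqrt(2.0 * dudx**2 + 2.0 * dvdy**2 + (dudy + dvdx) ** 2)

    # ----- assembly per step ---------------------------------------------

    def _sink_coefficients(
        self, u_lag: np.ndarray, mu_cell: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray] | tuple[None, None]:
        """Per-cell and lumped nodal Darcy-Forchheimer coefficients."""
        if self.coil is None or not np.any(self.tri_coil):
            return None, None
        rho = self.props.density
        ubar = u_lag[self.tris].mean(axis=1)
        speed = np.linalg.norm(ubar, axis=1)
        cc = np.where(
            self.tri_coil,
            sink_linear_coefficient(mu_cell, speed, rho, self.coil),
            0.0,
        )
        sink_diag = np.zeros(self.n)
        np.add.at(sink_diag, self.tris.ravel(), np.repeat(cc * self.area / 3.0, 3))
        return cc, sink_diag

    def _velocity_matrix(
        self,
        u_lag: np.ndarray,
        mu_cell: np.ndarray,
        dt: float,
        sink_diag: np.ndarray | None,
    ):
        rho = self.props.density
        k_data = (mu_cell[:, None, None] * self.S_geom).ravel()
        ubar = u_lag[self.tris].mean(axis=1)  # (nt, 2)
        adv = rho * (self.area / 3.0)[:, None] * (
            ubar[:, 0:1] * self.gradx + ubar[:, 1:2] * self.grady
        )  # (nt, 3): row-constant convection entries
        n_data = np.repeat(adv, 3, axis=0).ravel()

        diag = rho / dt * self.mL
        if sink_diag is not None:
            diag = diag + sink_diag

        A = sp.coo_matrix(
            (k_data + n_data, (self.rows, self.cols)), shape=(self.n, self.n)
        ).tocsr()
        A = A + sp.diags(diag)
        return (self._keep @ A + self._fix).tocsc()

    def _ramp_factor(self, t: float) -> float:
        if self.bc.ramp_time <= 0.0 or t >= self.bc.ramp_time:
            return 1.0
        x = t / self.bc.ramp_time
        return x * x * (3.0 - 2.0 * x)  # C1 smoothstep

    def _inlet_values(self, t: float) -> np.ndarray | None:
        if self.bc.inlet != "velocity":
            return None
        um = self.bc.inlet_velocity(t) * self._ramp_factor(t)
        if self.bc.inlet_profile == "parabolic":
            speeds = parabolic_profile(self.inlet_xi, um)
        else:
            speeds = np.full_like(self.inlet_xi, um)
        return speeds[:, None] * self.inlet_direction

    def boundary_flux(self, u: np.ndarray, tag: BoundaryTag | None = None) -> float:
        """Outward volumetric flux (m^2/s) through a tagged boundary part."""
        sel = (
            slice(None)
            if tag is None
            else self.mesh.boundary_tags == int(tag)
        )
        e = self.b_edges[sel]
        n = self.b_normals[sel]
        ln = self.b_lengths[sel]
        un = 0.5 * ((u[e[:, 0]] + u[e[:, 1]]) * n).sum(axis=1)
        return float((un * ln).sum())

    def kinetic_energy(self, u: np.ndarray) -> float:
        return float(0.5 * self.props.density * (self.mL * (u**2).sum(axis=1)).sum())

    # ----- stepping -------------------------------------------------------

    def advance(self, state: FlowState, dt: float | None = None) -> FlowState:
        """One projection step; returns the new state.

        Diagnostics for the step are kept in ``self.last_diagnostics``.
        """
        cfg = self.cfg
        dt = cfg.dt if dt is None else dt
        rho = self.props.density
        t_new = state.t + dt
        u_n = state.u
        p_n = state.p
        if not (np.all(np.isfinite(u_n)) and np.all(np.isfinite(p_n))):
            raise SolverError(f"NaN/Inf field entering step at t={state.t:.6g}")

        inlet_vals = self._inlet_values(t_new)
        u_lag = u_n
        mu_lag = state.mu_cell
        residuals: list[float] = []
        u_star = None
        for it in range(cfg.max_inner_iterations):
            sink_cell, sink_diag = self._sink_coefficients(u_lag, mu_lag)
            A = self._velocity_matrix(u_lag, mu_lag, dt, sink_diag)
            lu = splu(A)
            rhs_x = rho / dt * self.mL * u_n[:, 0] - self.Gx @ p_n
            rhs_y = rho / dt * self.mL * u_n[:, 1] - self.Gy @ p_n
            if self.bc.body_force is not None:
                fx, fy = self.bc.body_force(t_new)
                rhs_x = rhs_x + rho * fx * self.mL
                rhs_y = rhs_y + rho * fy * self.mL
            rhs_x[self.wall_nodes] = 0.0
            rhs_y[self.wall_nodes] = 0.0
            if inlet_vals is not None:
                rhs_x[self.inlet_nodes] = inlet_vals[:, 0]
                rhs_y[self.inlet_nodes] = inlet_vals[:, 1]
                rhs_x[np.intersect1d(self.inlet_nodes, self.wall_nodes)] = 0.0
                rhs_y[np.intersect1d(self.inlet_nodes, self.wall_nodes)] = 0.0
            u_star = np.stack([lu.solve(rhs_x), lu.solve(rhs_y)], axis=1)

            if cfg.max_inner_iterations == 1:
                break
            ref = np.abs(u_star).max() + 1e-30
            res = float(np.abs(u_star - u_lag).max() / ref)
            residuals.append(res)
            u_lag = u_star
            mu_lag = self._viscosity_field(u_star)
            if res < cfg.nonlinear_tolerance:
                break
        else:
            raise SolverError(
                f"inner iterations exceeded max ({cfg.max_inner_iterations}) "
                f"without meeting nonlinear_tolerance; residual history: {residuals}"
            )

        # pressure increment: div( beta grad(phi) ) = div(u*) with
        # beta = 1/(rho/dt + c_sink); the sink weighting keeps the
        # projection consistent inside strongly resistive coil cells
        div_w = self.Gx @ u_star[:, 0] + self.Gy @ u_star[:, 1]
        phi_fix = np.zeros(len(self.p_fixed))
        if self.bc.inlet == "pressure":
            targets = np.full(self.n, np.nan)
            targets[self.inlet_nodes] = self.bc.inlet_pressure(t_new) * self._ramp_factor(
                t_new
            )
            targets[self.outlet_nodes] = self.bc.outlet_pressure
            phi_fix = targets[self.p_fixed] - p_n[self.p_fixed]
        else:
            phi_fix = self.bc.outlet_pressure - p_n[self.p_fixed]

        if sink_diag is None:
            # constant beta: solve the unit Laplacian, A phi = -(rho/dt) div
            b = -(rho / dt) * div_w - self._Ap_cols @ phi_fix
            b[self.p_fixed] = phi_fix
            phi = self._Ap_lu.solve(b)
            denom = (rho / dt) * self.mL
        else:
            beta_cell = 1.0 / (rho / dt + sink_cell)
            data = (beta_cell[:, None, None] * self.S_geom).ravel()
            Ap = sp.coo_matrix(
                (data, (self.rows, self.cols)), shape=(self.n, self.n)
            ).tocsr()
            b = -div_w - Ap[:, self.p_fixed] @ phi_fix
            b[self.p_fixed] = phi_fix
            keep = sp.diags((~self.p_fixed_mask).astype(float))
            fix = sp.diags(self.p_fixed_mask.astype(float))
            phi = splu((keep @ Ap + fix).tocsc()).solve(b)
            denom = (rho / dt) * self.mL + sink_diag

        p_new = p_n + phi
        u_new = u_star - np.stack(
            [self.Gx @ phi, self.Gy @ phi], axis=1
        ) / denom[:, None]
        u_new[self.wall_nodes] = 0.0
        if inlet_vals is not None:
            u_new[self.inlet_nodes] = inlet_vals
            u_new[np.intersect1d(self.inlet_nodes, self.wall_nodes)] = 0.0

        if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(p_new))):
            raise SolverError(f"NaN/Inf field at t={t_new:.6g}")

        div_res = abs(self.boundary_flux(u_new)) / self.domain_area
        if div_res > cfg.divergence_tolerance:
            raise SolverError(
                f"net boundary flux residual {div_res:.3e} 1/s exceeds "
                f"divergence_tolerance {cfg.divergence_tolerance:.3e} at t={t_new:.6g}"
            )

        self.last_diagnostics = StepDiagnostics(
            divergence_residual=div_res,
            inner_iterations=len(residuals) or 1,
            inner_residuals=residuals,
        )
        return FlowState(u=u_new, p=p_new, t=t_new, mu_cell=self._viscosity_field(u_new))

    # ----- drivers --------------------------------------------------------

    def run_steady(
        self,
        dt: float | None = None,
        tol: float | None = None,
        max_steps: int | None = None,
    ) -> FlowState:
        """March to steady state under time-constant boundary conditions."""
        cfg = self.cfg
        dt = cfg.dt if dt is None else dt
        tol = cfg.steady_tolerance if tol is None else tol
        max_steps = cfg.max_steady_steps if max_steps is None else max_steps
        ramp_was = self.bc.ramp_time
        if self.bc.inlet == "velocity" and ramp_was == 0.0:
            self.bc.ramp_time = 30.0 * dt  # soften the impulsive start
        try:
            state = self.initial_state()
            for _ in range(max_steps):
                new = self.advance(state, dt=dt)
                ref = np.abs(new.u).max() + 1e-30
                change = float(np.abs(new.u - state.u).max() / ref)
                state = new
                if change < tol and state.t > self.bc.ramp_time:
                    return state
            raise SolverError(
                f"steady march did not converge within {max_steps} steps "
                f"(last relative change {change:.3e})"
            )
        finally:
            self.bc.ramp_time = ramp_was


@dataclass
class PulsatileResult:
    """Time-resolved solution of one or more cardiac cycles."""

    landmark_states: dict[str, FlowState]
    landmarks: PhaseLandmarks
    wall_series: "object"  # postprocess.WallSeries
    periodicity: float
    divergence_history: np.ndarray
    dt: float
    steps_per_cycle: int
    warnings: list[str]


def run_pulsatile(
    mesh: Mesh,
    props: BloodProperties,
    coil: CoilProperties | None,
    w: Waveform,
    cfg: SolverConfig,
    periodicity_threshold: float = 0.05,
) -> PulsatileResult:
    """Run the configured number of cycles and record the final one.

    Startup cycles (``cfg.cycles_to_discard``) are run but not recorded.
    During the final cycle wall tractions and pressures are sampled every
    step, and full fields are captured at the four phase landmarks.
    """
    from .postprocess import WallProbe, WallSeries

    T = w.period
    ramp = 0.5 * T if cfg.cycles_to_discard >= 1 else 0.0
    bc = BoundaryConditions(inlet="velocity", inlet_velocity=w, ramp_time=ramp)
    solver = ProjectionSolver(mesh, props, coil=coil, bc=bc, cfg=cfg)
    spc = max(2, int(round(T / cfg.dt)))
    dt = T / spc
    lm = phase_landmarks(w)
    n_cycles = cfg.cycles_to_run
    last_start = (n_cycles - 1) * spc
    lm_steps = {
        name: last_start + min(spc, int(round(t / dt)))
        for name, t in lm.as_dict().items()
    }

    probe = WallProbe(mesh, props)
    ne = probe.n_samples
    tractions = np.zeros((spc + 1, ne, 2))
    pressures = np.zeros((spc + 1, ne))
    snapshots: dict[str, FlowState] = {}
    div_hist = np.zeros(n_cycles * spc)
    msgs: list[str] = []

    state = solver.initial_state()
    u_prev_cycle_end = None
    for step in range(1, n_cycles * spc + 1):
        state = solver.advance(state, dt=dt)
        div_hist[step - 1] = solver.last_diagnostics.divergence_residual
        if step == (n_cycles - 1) * spc:
            u_prev_cycle_end = state.u.copy()
            tractions[0] = probe.traction(state.u)
            pressures[0] = probe.pressure(state.p)
        if step > last_start:
            i = step - last_start
            tractions[i] = probe.traction(state.u)
            pressures[i] = probe.pressure(state.p)
        for name, s_idx in lm_steps.items():
            if step == s_idx:
                snapshots[name] = state.copy()
    if u_prev_cycle_end is None:  # single-cycle run: compare against start
        u_prev_cycle_end = np.zeros_like(state.u)
    ref = np.linalg.norm(state.u)
    periodicity = float(
        np.linalg.norm(state.u - u_prev_cycle_end) / (ref + 1e-30)
    )
    if n_cycles >= 2 and periodicity > periodicity_threshold:
        msg = (
            f"solution not cycle-periodic: relative L2 change {periodicity:.3e} "
            f"between the last two cycles exceeds {periodicity_threshold:.3e}"
        )
        warnings.warn(msg, stacklevel=2)
        msgs.append(msg)

    series = WallSeries(
        times=np.arange(spc + 1) * dt,
        period=T,
        positions=probe.positions,
        arclength=probe.arclength,
        chain=probe.chain,
        tags=probe.tags,
        tractions=tractions,
        pressures=pressures,
    )
    return PulsatileResult(
        landmark_states=snapshots,
        landmarks=lm,
        wall_series=series,
        periodicity=periodicity,
        divergence_history=div_hist,
        dt=dt,
        steps_per_cycle=spc,
        warnings=msgs,
    )
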