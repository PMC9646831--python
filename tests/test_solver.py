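import numpy as np
import pytest

from sacflow.coil_model import CoilProperties
from sacflow.geometry_mesh import (
    BoundaryTag,
    build_idealized_aneurysm,
    generate_mesh,
)
from sacflow.postprocess import WallProbe
from sacflow.benchmarks import poiseuille_wall_shear
from sacflow.rheology import BloodProperties
from sacflow.solver import (
    BoundaryConditions,
    ProjectionSolver,
    SolverConfig,
    SolverError,
    run_pulsatile,
)
from sacflow.waveform import Waveform


def channel(L=20e-3, D=4e-3, h=4e-4):
    geom = build_idealized_aneurysm(
        parent_width=D, parent_length=L, curvature=0.0, sac_shape="none"
    )
    return geom, generate_mesh(geom, h)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=0.0)
        with pytest.raises(ValueError):
            SolverConfig(cycles_to_run=1, cycles_to_discard=1)
        with pytest.raises(ValueError):
            SolverConfig(pressure_velocity_scheme="piso")

    def test_simple_scheme_not_implemented(self):
        with pytest.raises(NotImplementedError):
            SolverConfig(pressure_velocity_scheme="simple")

    def test_bc_validation(self):
        with pytest.raises(ValueError):
            BoundaryConditions(inlet="velocity")  # missing inlet_velocity
        with pytest.raises(ValueError):
            BoundaryConditions(inlet="pressure")
        with pytest.raises(ValueError):
            BoundaryConditions(inlet="wall")


@pytest.fixture(scope="module")
def steady(newtonian_blood):
    geom, mesh = channel()
    U = 0.1
    bc = BoundaryConditions(inlet="velocity", inlet_velocity=lambda t: U)
    cfg = SolverConfig(dt=2e-3, divergence_tolerance=1.0, steady_tolerance=1e-7)
    solver = ProjectionSolver(mesh, newtonian_blood, bc=bc, cfg=cfg)
    return geom, mesh, solver, solver.run_steady(), U


@pytest.fixture(scope="module")
def tiny_run(default_mesh):
    w = Waveform()
    cfg = SolverConfig(dt=w.period / 100, cycles_to_run=1,
                       cycles_to_discard=0, divergence_tolerance=2.0)
    props = BloodProperties(hct=0.40)
    return run_pulsatile(default_mesh, props, None, w, cfg), w


class TestSteadyPoiseuille:
    def test_centerline_velocity(self, steady):
        geom, mesh, solver, state, U = steady
        mid = np.abs(mesh.points[:, 0] - geom.parent_length / 2) < 1e-9
        center = np.abs(mesh.points[:, 1]) < 1e-9
        u_center = state.u[mid & center, 0]
        assert u_center == pytest.approx(1.5 * U, rel=0.01)

    def test_wall_shear(self, steady, newtonian_blood):
        geom, mesh, solver, state, U = steady
        probe = WallProbe(mesh, newtonian_blood)
        wss = np.linalg.norm(probe.traction(state.u), axis=1)
        interior = (probe.positions[:, 0] > 0.3 * geom.parent_length) & (
            probe.positions[:, 0] < 0.7 * geom.parent_length
        )
        expected = poiseuille_wall_shear(
            newtonian_blood.mu_inf, U, geom.parent_width
        )
        assert np.allclose(wss[interior], expected, rtol=0.01)

    def test_mass_conserved(self, steady):
        _, _, solver, state, U = steady
        net = solver.boundary_flux(state.u)
        assert abs(net) <= solver.cfg.divergence_tolerance * solver.domain_area

    def test_parabolic_profile_shape(self, steady):
        geom, mesh, solver, state, U = steady
        D = geom.parent_width
        mid = np.abs(mesh.points[:, 0] - geom.parent_length / 2) < 1e-9
        y = mesh.points[mid, 1]
        expected = 1.5 * U * (1 - (2 * y / D) ** 2)
        assert np.allclose(state.u[mid, 0], expected, atol=0.015 * 1.5 * U)


class TestNullAndEnergy:
    def test_zero_inlet_zero_field_preserved(self, newtonian_blood):
        _, mesh = channel(h=5e-4)
        bc = BoundaryConditions(inlet="velocity", inlet_velocity=lambda t: 0.0)
        solver = ProjectionSolver(mesh, newtonian_blood, bc=bc,
                                  cfg=SolverConfig(dt=1e-3))
        state = solver.initial_state()
        for _ in range(5):
            state = solver.advance(state)
        assert np.allclose(state.u, 0.0, atol=1e-14)
        assert np.allclose(state.p, 0.0, atol=1e-10)

    def test_kinetic_energy_decays_without_inflow(self, newtonian_blood):
        _, mesh = channel(h=5e-4)
        bc = BoundaryConditions(inlet="velocity", inlet_velocity=lambda t: 0.0)
        coil = CoilProperties(porosity=0.85)
        mesh.coil_mask[:] = True
        solver = ProjectionSolver(mesh, newtonian_blood, coil=coil, bc=bc,
                                  cfg=SolverConfig(dt=1e-3, divergence_tolerance=10.0))
        state = solver.initial_state()
        # seed a divergence-free-ish interior swirl
        pts = mesh.points
        state.u[:, 0] = 0.05 * np.sin(np.pi * pts[:, 1] / 4e-3)
        state.u[solver.vel_fixed_mask] = 0.0
        energies = [solver.kinetic_energy(state.u)]
        for _ in range(20):
            state = solver.advance(state)
            energies.append(solver.kinetic_energy(state.u))
        # after the first projection, energy must decrease monotonically
        assert all(e2 <= e1 * (1 + 1e-12) for e1, e2 in zip(energies[1:], energies[2:]))
        assert energies[-1] < energies[1]

    def test_nan_detection(self, newtonian_blood):
        _, mesh = channel(h=5e-4)
        bc = BoundaryConditions(inlet="velocity", inlet_velocity=lambda t: 0.1)
        solver = ProjectionSolver(mesh, newtonian_blood, bc=bc,
                                  cfg=SolverConfig(dt=1e-3, divergence_tolerance=10.0))
        state = solver.initial_state()
        state.u[mesh.n_nodes // 2] = np.nan
        with pytest.raises(SolverError):
            solver.advance(state)


class TestCoilEffects:
    def test_porosity_lowers_sac_velocity_at_peak(self, default_geometry,
                                                  default_mesh):
        from sacflow.postprocess import sac_mean_inflow_velocity

        w = Waveform()
        cfg = SolverConfig(dt=w.period / 250, cycles_to_run=2,
                           cycles_to_discard=1, divergence_tolerance=1.0)
        props = BloodProperties(hct=0.45)
        vels = {}
        for eps in (0.79, 0.89):
            res = run_pulsatile(default_mesh, props,
                                CoilProperties(porosity=eps), w, cfg)
            vels[eps] = sac_mean_inflow_velocity(
                res.landmark_states["B"], default_mesh, default_geometry
            )
        assert vels[0.79] < vels[0.89]


class TestPulsatileBookkeeping:
    def test_snapshots_and_series_shape(self, tiny_run):
        res, w = tiny_run
        assert set(res.landmark_states) == {"A", "B", "C", "D"}
        assert res.steps_per_cycle == 100
        assert res.wall_series.tractions.shape[0] == 101
        assert res.wall_series.times[-1] == pytest.approx(w.period)

    def test_snapshot_times_match_landmarks(self, tiny_run):
        res, w = tiny_run
        for name, t_lm in res.landmarks.as_dict().items():
            t_snap = res.landmark_states[name].t % w.period
            assert abs(t_snap - t_lm) <= res.dt / 2 + 1e-12

    def test_determinism_bit_identical(self, default_mesh):
        w = Waveform()
        cfg = SolverConfig(dt=w.period / 100, cycles_to_run=1,
                           cycles_to_discard=0, divergence_tolerance=2.0)
        props = BloodProperties(hct=0.40)
        r1 = run_pulsatile(default_mesh, props, None, w, cfg)
        r2 = run_pulsatile(default_mesh, props, None, w, cfg)
        assert np.array_equal(r1.wall_series.tractions, r2.wall_series.tractions)
        for k in "ABCD":
            assert np.array_equal(r1.landmark_states[k].u, r2.landmark_states[k].u)
            assert np.array_equal(r1.landmark_states[k].p, r2.landmark_states[k].p)

    def test_divergence_history_within_tolerance(self, tiny_run):
        res, _ = tiny_run
        assert np.all(res.divergence_history <= 2.0)

    def test_casson_viscosity_field_updates(self, tiny_run):
        res, _ = tiny_run
        state = res.landmark_states["B"]
        assert np.all(np.isfinite(state.mu_cell))
        assert state.mu_cell.min() >= BloodProperties(hct=0.40).mu_inf


class TestPicard:
    def test_inner_iterations_converge(self, default_mesh):
        w = Waveform()
        props = BloodProperties(hct=0.45)
        cfg = SolverConfig(dt=w.period / 100, max_inner_iterations=5,
                           nonlinear_tolerance=1e-2, divergence_tolerance=2.0)
        bc = BoundaryConditions(inlet="velocity", inlet_velocity=w)
        solver = ProjectionSolver(default_mesh, props, bc=bc, cfg=cfg)
        state = solver.initial_state()
        state = solver.advance(state)
        assert solver.last_diagnostics.inner_iterations <= 5
        assert solver.last_diagnostics.inner_residuals[-1] < 1e-2 or (
            len(solver.last_diagnostics.inner_residuals) < 5
        )

    def test_nonconvergence_aborts(self, default_mesh):
        w = Waveform()
        props = BloodProperties(hct=0.45)
        cfg = SolverConfig(dt=w.period / 100, max_inner_iterations=2,
                           nonlinear_tolerance=1e-16, divergence_tolerance=2.0)
        bc = BoundaryConditions(inlet="velocity", inlet_velocity=w)
        solver = ProjectionSolver(default_mesh, props, bc=bc, cfg=cfg)
        with pytest.raises(SolverError, match="residual history"):
            solver.advance(solver.initial_state())
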