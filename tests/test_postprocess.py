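import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacflow.geometry_mesh import BoundaryTag, build_idealized_aneurysm, generate_mesh
from sacflow.postprocess import (
    PostprocessError,
    RiskRegion,
    WallProbe,
    WallSeries,
    compare_conditions,
    high_risk_regions,
    interpolation_matrix,
    iso_velocity_area,
    osi,
    peak_pressure,
    sac_mean_inflow_velocity,
    tawss,
    windowed_osi,
)


def make_series(tractions, T=1.0, tags=None):
    """WallSeries from a (nt, ne, 2) traction array on a uniform cycle."""
    tractions = np.asarray(tractions, dtype=float)
    nt, ne, _ = tractions.shape
    times = np.linspace(0.0, T, nt)
    if tags is None:
        tags = np.full(ne, int(BoundaryTag.SAC_WALL))
    return WallSeries(
        times=times,
        period=T,
        positions=np.zeros((ne, 2)),
        arclength=np.linspace(0.0, 1.0, ne),
        chain=np.zeros(ne, dtype=int),
        tags=np.asarray(tags),
        tractions=tractions,
        pressures=np.zeros((nt, ne)),
    )


class TestOsi:
    def test_constant_traction_zero(self):
        tr = np.tile(np.array([[2.0, 0.0]]), (51, 1, 1))
        assert osi(make_series(tr)) == pytest.approx(0.0, abs=1e-14)

    def test_zero_mean_sinusoid_half(self):
        t = np.linspace(0.0, 1.0, 1001)
        tr = np.zeros((1001, 1, 2))
        tr[:, 0, 0] = np.sin(2 * np.pi * t)
        assert osi(make_series(tr))[0] == pytest.approx(0.5, abs=1e-6)

    def test_square_wave_one_third(self):
        # +2 Pa for the first half-cycle, -1 Pa for the second:
        # OSI = 1/2 (1 - 0.5/1.5) = 1/3
        nt = 20001
        t = np.linspace(0.0, 1.0, nt)
        tr = np.zeros((nt, 1, 2))
        tr[:, 0, 0] = np.where(t < 0.5, 2.0, -1.0)
        assert osi(make_series(tr))[0] == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_bounds_random_series(self, rng):
        tr = rng.standard_normal((101, 40, 2))
        vals = osi(make_series(tr))
        assert np.all(vals >= 0.0)
        assert np.all(vals <= 0.5)

    def test_zero_series_warns_and_returns_zero(self):
        tr = np.zeros((11, 3, 2))
        with pytest.warns(UserWarning, match="all-zero"):
            vals = osi(make_series(tr))
        assert np.all(vals == 0.0)

    def test_invariant_under_positive_scaling(self, rng):
        tr = rng.standard_normal((101, 10, 2))
        s = make_series(tr)
        s2 = make_series(3.7 * tr)
        assert np.allclose(osi(s), osi(s2), atol=1e-13)

    def test_trapezoid_convergence(self):
        # halving the sampling step changes OSI by < 1e-3 on a smooth series
        def series(n):
            t = np.linspace(0.0, 1.0, n)
            tr = np.zeros((n, 1, 2))
            tr[:, 0, 0] = 0.4 + np.sin(2 * np.pi * t) + 0.3 * np.cos(4 * np.pi * t)
            tr[:, 0, 1] = 0.2 * np.sin(2 * np.pi * t + 0.5)
            return make_series(tr)

        o1 = osi(series(201))[0]
        o2 = osi(series(401))[0]
        assert abs(o1 - o2) < 1e-3

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_osi_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        tr = rng.standard_normal((41, 7, 2)) * rng.uniform(0.1, 10)
        vals = osi(make_series(tr))
        assert np.all((vals >= 0.0) & (vals <= 0.5))


class TestWindowedOsi:
    def test_full_window_matches_cycle_osi(self, rng):
        tr = rng.standard_normal((200 + 1, 5, 2))
        tr[-1] = tr[0]  # periodic
        s = make_series(tr)
        assert np.allclose(windowed_osi(s, 0.5, 1.0), osi(s), atol=5e-2)

    def test_window_sees_local_reversal(self):
        # sign change at t=0.5: a window straddling it sees full oscillation,
        # a window inside the uniform part sees none
        nt = 401
        t = np.linspace(0.0, 1.0, nt)
        tr = np.zeros((nt, 1, 2))
        tr[:, 0, 0] = np.where((t > 0.5) & (t < 0.75), -1.0, 1.0)
        s = make_series(tr)
        early = windowed_osi(s, 0.15, 0.25)[0]
        straddle = windowed_osi(s, 0.5, 0.25)[0]
        assert early == pytest.approx(0.0, abs=1e-12)
        assert straddle == pytest.approx(0.5, abs=0.01)

    def test_invalid_width(self):
        s = make_series(np.ones((11, 2, 2)))
        with pytest.raises(PostprocessError):
            windowed_osi(s, 0.5, 0.0)
        with pytest.raises(PostprocessError):
            windowed_osi(s, 0.5, 2.0)


class TestTawss:
    def test_constant_magnitude(self):
        tr = np.tile(np.array([[0.0, 2.0]]), (11, 1, 1))
        assert tawss(make_series(tr))[0] == pytest.approx(2.0, rel=1e-12)

    def test_abs_sine_two_over_pi(self):
        t = np.linspace(0.0, 1.0, 20001)
        tr = np.zeros((20001, 1, 2))
        tr[:, 0, 1] = np.sin(np.pi * t)  # |sin| wave over one period
        assert tawss(make_series(tr))[0] == pytest.approx(2.0 / np.pi, abs=1e-5)

    def test_zero_series(self):
        assert tawss(make_series(np.zeros((5, 2, 2))))[0] == 0.0

    def test_linear_scaling(self, rng):
        tr = rng.standard_normal((51, 4, 2))
        assert np.allclose(tawss(make_series(2.5 * tr)), 2.5 * tawss(make_series(tr)))


class TestSeriesValidation:
    def test_nonuniform_sampling_rejected(self):
        times = np.array([0.0, 0.1, 0.3, 1.0])
        with pytest.raises(PostprocessError, match="uniform"):
            WallSeries(
                times=times, period=1.0, positions=np.zeros((1, 2)),
                arclength=np.zeros(1), chain=np.zeros(1, int),
                tags=np.zeros(1, int), tractions=np.zeros((4, 1, 2)),
                pressures=np.zeros((4, 1)),
            )

    def test_wrong_span_rejected(self):
        times = np.linspace(0.0, 0.5, 6)
        with pytest.raises(PostprocessError, match="period"):
            WallSeries(
                times=times, period=1.0, positions=np.zeros((1, 2)),
                arclength=np.zeros(1), chain=np.zeros(1, int),
                tags=np.zeros(1, int), tractions=np.zeros((6, 1, 2)),
                pressures=np.zeros((6, 1)),
            )


class TestRiskRegions:
    def test_all_zero_no_regions(self):
        s = np.linspace(0, 1, 50)
        assert high_risk_regions(s, np.zeros(50), 0.2) == []

    def test_single_arc(self):
        s = np.linspace(0, 1, 100)
        vals = np.where((s > 0.3) & (s < 0.5), 0.4, 0.0)
        regions = high_risk_regions(s, vals, 0.2)
        assert len(regions) == 1
        r = regions[0]
        assert 0.3 <= r.start_arc <= r.peak_arc <= r.end_arc <= 0.5
        assert r.peak_osi == pytest.approx(0.4)

    def test_two_disjoint_arcs(self):
        s = np.linspace(0, 1, 200)
        vals = np.zeros(200)
        vals[(s > 0.1) & (s < 0.2)] = 0.3
        vals[(s > 0.6) & (s < 0.8)] = 0.45
        regions = high_risk_regions(s, vals, 0.2)
        # brute-force scan oracle
        above = vals >= 0.2
        n_runs = int(np.sum(np.diff(above.astype(int)) == 1) + above[0])
        assert len(regions) == n_runs == 2
        assert regions[1].peak_osi == pytest.approx(0.45)

    def test_chains_not_merged(self):
        s = np.array([0.0, 0.1, 0.0, 0.1])
        chain = np.array([0, 0, 1, 1])
        vals = np.array([0.3, 0.3, 0.3, 0.3])
        regions = high_risk_regions(s, vals, 0.2, chain=chain)
        assert len(regions) == 2

    def test_invalid_threshold(self):
        with pytest.raises(PostprocessError):
            high_risk_regions(np.arange(3.0), np.zeros(3), 0.7)


class FakeState:
    def __init__(self, u):
        self.u = u


class TestSacMetrics:
    def test_uniform_field_mean(self, default_geometry, default_mesh):
        u = np.tile(np.array([0.3, 0.0]), (default_mesh.n_nodes, 1))
        v = sac_mean_inflow_velocity(FakeState(u), default_mesh, default_geometry)
        assert v == pytest.approx(0.3, rel=1e-9)

    def test_magnitude_not_signed_flux(self, default_geometry, default_mesh):
        # antisymmetric in/out field: the signed flux across the neck is ~0
        # but the mean magnitude stays close to the jet speed (the thin
        # zero-crossing strip is smoothed over ~one cell by interpolation)
        pts = default_mesh.points
        mid = default_geometry.neck_midpoint
        tang = default_geometry.neck_tangent
        xi = (pts - mid) @ tang
        m, w = 0.25, 2.5e-4
        u = np.stack([np.zeros(len(pts)), m * np.tanh(xi / w)], axis=1)
        v = sac_mean_inflow_velocity(FakeState(u), default_mesh, default_geometry)
        # analytic mean of |m tanh(xi/w)| over the chord
        N = default_geometry.sac_neck_width
        xs = np.linspace(-N / 2, N / 2, 20001)
        expected = np.trapezoid(m * np.abs(np.tanh(xs / w)), xs) / N
        assert v == pytest.approx(expected, rel=0.03)
        assert v > 0.8 * m  # far from the signed-flux value (~0)

    def test_quadrature_convergence_across_meshes(self, default_geometry):
        # same analytic field sampled on coarse and fine meshes
        def run(h):
            mesh = generate_mesh(default_geometry, h)
            pts = mesh.points
            u = np.stack(
                [0.1 + 0.5 * pts[:, 1], 0.2 - 0.3 * pts[:, 0]], axis=1
            )
            return sac_mean_inflow_velocity(FakeState(u), mesh, default_geometry)

        assert run(5e-4) == pytest.approx(run(2.5e-4), rel=0.01)

    def test_no_sac_rejected(self, straight_channel, channel_mesh):
        u = np.zeros((channel_mesh.n_nodes, 2))
        with pytest.raises(PostprocessError):
            sac_mean_inflow_velocity(FakeState(u), channel_mesh, straight_channel)

    def test_iso_velocity_area(self, channel_mesh):
        u = np.zeros((channel_mesh.n_nodes, 2))
        u[:, 0] = 1.0
        total = channel_mesh.total_area()
        assert iso_velocity_area(FakeState(u), channel_mesh, 0.5) == pytest.approx(
            total
        )
        assert iso_velocity_area(FakeState(u), channel_mesh, 1.5) == 0.0


class TestWallProbe:
    def test_linear_shear_recovered(self, channel_mesh, newtonian_blood):
        # u = g*(y+D/2) near the bottom wall: |WSS| = mu*g on both walls
        g = 50.0
        pts = channel_mesh.points
        D = 4e-3
        u = np.stack([g * (pts[:, 1] + D / 2), np.zeros(len(pts))], axis=1)
        probe = WallProbe(channel_mesh, newtonian_blood)
        tr = probe.traction(u)
        bottom = probe.positions[:, 1] < 0.0
        mu = newtonian_blood.mu_inf
        assert np.allclose(
            np.linalg.norm(tr[bottom], axis=1), mu * g, rtol=1e-6
        )

    def test_quiescent_zero(self, channel_mesh, newtonian_blood):
        probe = WallProbe(channel_mesh, newtonian_blood)
        tr = probe.traction(np.zeros((channel_mesh.n_nodes, 2)))
        assert np.allclose(tr, 0.0)

    def test_quadratic_profile_exact(self, channel_mesh, newtonian_blood):
        # parabolic profile: second-order one-sided difference is exact
        pts = channel_mesh.points
        D, U = 4e-3, 0.1
        yhat = (pts[:, 1] + D / 2) / D
        u = np.stack([6 * U * yhat * (1 - yhat), np.zeros(len(pts))], axis=1)
        probe = WallProbe(channel_mesh, newtonian_blood)
        tr = np.linalg.norm(probe.traction(u), axis=1)
        expected = 6 * newtonian_blood.mu_inf * U / D
        assert np.allclose(tr, expected, rtol=1e-9)

    def test_arclength_monotone_per_chain(self, default_mesh, newtonian_blood):
        probe = WallProbe(default_mesh, newtonian_blood)
        for cid in np.unique(probe.chain):
            s = probe.arclength[probe.chain == cid]
            assert np.all(np.diff(s) > 0)


class TestInterpolation:
    def test_linear_field_exact(self, default_mesh):
        pts = default_mesh.points
        nodal = 2.0 + 3.0 * pts[:, 0] - 1.5 * pts[:, 1]
        probe_pts = default_mesh.cell_centroids()[::7]
        W = interpolation_matrix(default_mesh, probe_pts)
        expected = 2.0 + 3.0 * probe_pts[:, 0] - 1.5 * probe_pts[:, 1]
        assert np.allclose(W @ nodal, expected, rtol=1e-9)

    def test_partition_of_unity(self, default_mesh):
        W = interpolation_matrix(default_mesh, default_mesh.points[::11])
        assert np.allclose(np.asarray(W.sum(axis=1)).ravel(), 1.0)


def _fake_indices(vals, sig="geo"):
    from sacflow.postprocess import HemodynamicIndices

    lm = {
        name: {
            "time": 0.1,
            "max_wss": vals[0],
            "max_osi": vals[1],
            "mean_osi": vals[1] / 2,
            "sac_mean_velocity": vals[2],
            "max_pressure": 100.0,
        }
        for name in "ABCD"
    }
    n = 4
    z = np.zeros(n)
    return HemodynamicIndices(
        arclength=z, chain=z.astype(int), tags=z.astype(int), tawss=z, osi=z,
        peak_pressure=z, landmark_metrics=lm, global_max={},
        geometry_signature=sig,
    )


class TestCompare:
    def test_identical_conditions_zero_change(self):
        res = {
            (0.89, 0.45): _fake_indices([2.0, 0.4, 0.1]),
            (0.79, 0.45): _fake_indices([2.0, 0.4, 0.1]),
        }
        rep = compare_conditions(res, reference=(0.89, 0.45))
        assert all(r.percent_change == pytest.approx(0.0) for r in rep.rows)

    def test_percent_change_arithmetic(self):
        # x_ref = 0.4, x = 0.1 -> 75% reduction
        res = {
            (0.89, 0.45): _fake_indices([1.0, 0.4, 1.0]),
            (0.79, 0.45): _fake_indices([1.0, 0.1, 1.0]),
        }
        rep = compare_conditions(res, reference=(0.89, 0.45))
        osi_rows = [r for r in rep.rows if r.index == "max_osi"]
        assert all(r.percent_change == pytest.approx(75.0) for r in osi_rows)

    def test_row_count_bookkeeping(self):
        res = {
            (0.89, 0.45): _fake_indices([1, 0.4, 1]),
            (0.79, 0.45): _fake_indices([1, 0.3, 1]),
            (0.79, 0.35): _fake_indices([1, 0.2, 1]),
        }
        rep = compare_conditions(res, reference=(0.89, 0.45))
        assert len(rep.rows) == (3 - 1) * 4 * 3  # (n-1) x landmarks x indices

    def test_mismatched_geometry_rejected(self):
        res = {
            (0.89, 0.45): _fake_indices([1, 0.4, 1], sig="a"),
            (0.79, 0.45): _fake_indices([1, 0.3, 1], sig="b"),
        }
        with pytest.raises(PostprocessError, match="geometries"):
            compare_conditions(res, reference=(0.89, 0.45))

    def test_single_condition_rejected(self):
        with pytest.raises(PostprocessError):
            compare_conditions({(0.89, 0.45): _fake_indices([1, 1, 1])},
                               reference=(0.89, 0.45))

    def test_table_render(self):
        res = {
            (0.89, 0.45): _fake_indices([1, 0.4, 1]),
            (0.79, 0.45): _fake_indices([1, 0.1, 1]),
        }
        rep = compare_conditions(res, reference=(0.89, 0.45))
        txt = rep.to_table()
        assert "max_osi" in txt and "75.00" in txt
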