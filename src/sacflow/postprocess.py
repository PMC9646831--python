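"""Hemodynamic wall indices: WSS, TAWSS, OSI, wall pressure, sac inflow
velocity, iso-velocity area, high-risk regions and cross-condition
comparisons.

Wall shear stress is the tangential viscous traction mu * (du_t/dn) at the
no-slip wall, recovered with a second-order one-sided difference along the
inward wall normal.  OSI follows the standard vector form

    OSI = 1/2 * (1 - |int_0^T WSS dt| / int_0^T |WSS| dt),

which is 0 for unidirectional and 0.5 for perfectly oscillatory traction.
Per-instant OSI maps use the same formula on a centered sub-window of the
cycle (default width T/4), periodically extended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.tri import Triangulation
from matplotlib.tri import TrapezoidMapTriFinder

from .geometry_mesh import BoundaryTag, Mesh, VesselGeometry
from .rheology import BloodProperties, casson_viscosity


class PostprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# interpolation helpers
# ---------------------------------------------------------------------------


def interpolation_matrix(mesh: Mesh, points: np.ndarray):
    """Sparse operator mapping nodal values to values at ``points``.

    Points marginally outside the mesh (wall-probe roundoff, concave
    corners) are assigned to the nearest triangle with clamped barycentric
    weights.
    """
    import scipy.sparse as sp

    tris, _ = mesh.triangulated()
    pts = mesh.points
    tr = Triangulation(pts[:, 0], pts[:, 1], triangles=tris)
    finder = TrapezoidMapTriFinder(tr)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    idx = finder(points[:, 0], points[:, 1])
    missing = np.flatnonzero(idx < 0)
    if len(missing) > 0:
        cent = pts[tris].mean(axis=1)
        from scipy.spatial import cKDTree

        _, near = cKDTree(cent).query(points[missing])
        idx[missing] = near
    corners = pts[tris[idx]]  # (m, 3, 2)
    v0 = corners[:, 1] - corners[:, 0]
    v1 = corners[:, 2] - corners[:, 0]
    d = points - corners[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    w1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / det
    w2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / det
    w0 = 1.0 - w1 - w2
    W = np.clip(np.stack([w0, w1, w2], axis=1), 0.0, 1.0)
    W /= W.sum(axis=1, keepdims=True)
    m = len(points)
    rows = np.repeat(np.arange(m), 3)
    cols = tris[idx].ravel()
    return sp.coo_matrix((W.ravel(), (rows, cols)), shape=(m, mesh.n_nodes)).tocsr()


# ---------------------------------------------------------------------------
# wall probe
# ---------------------------------------------------------------------------


class WallProbe:
    """Traction and pressure sampling on the wall boundary.

    Wall edges (vessel + sac) are ordered into connected chains with an
    arc-length coordinate.  For each edge midpoint two probe points are
    placed along the inward normal at the local wall-adjacent cell height
    ``d`` and ``2d``; the tangential velocity there gives the one-sided
    second-order wall gradient (4 u(d) - u(2d)) / (2 d).
    """

    WALL_TAGS = (BoundaryTag.VESSEL_WALL, BoundaryTag.SAC_WALL)

    def __init__(self, mesh: Mesh, props: BloodProperties) -> None:
        self.mesh = mesh
        self.props = props
        sel = np.isin(
            mesh.boundary_tags, [int(t) for t in self.WALL_TAGS]
        )
        edges = mesh.boundary_edges[sel]
        tags = mesh.boundary_tags[sel]
        order, chain = _order_chains(edges)
        edges = edges[order]
        tags = tags[order]
        self.edges = edges
        self.tags = tags
        self.chain = chain
        self.n_samples = len(edges)

        pts = mesh.points
        mid = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
        d = pts[edges[:, 1]] - pts[edges[:, 0]]
        lengths = np.linalg.norm(d, axis=1)
        tang = d / lengths[:, None]
        # boundary edges are CCW, so the domain lies to the left
        inward = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        self.positions = mid
        self.tangents = tang
        self.lengths = lengths

        s = np.zeros(len(edges))
        for cid in np.unique(chain):
            m = chain == cid
            cl = lengths[m]
            s[m] = np.concatenate([[0.0], np.cumsum(cl)[:-1]]) + 0.5 * cl
        self.arclength = s

        self.probe_dist = _adjacent_heights(mesh, edges)
        p1 = mid + self.probe_dist[:, None] * inward
        p2 = mid + 2.0 * self.probe_dist[:, None] * inward
        self._W1 = interpolation_matrix(mesh, p1)
        self._W2 = interpolation_matrix(mesh, p2)
        self._Wp = None  # pressure: average of edge-node values

    def wall_gradient(self, u: np.ndarray) -> np.ndarray:
        """Tangential velocity gradient du_t/dn at each wall sample."""
        u1 = self._W1 @ u
        u2 = self._W2 @ u
        ut1 = (u1 * self.tangents).sum(axis=1)
        ut2 = (u2 * self.tangents).sum(axis=1)
        return (4.0 * ut1 - ut2) / (2.0 * self.probe_dist)

    def traction(self, u: np.ndarray) -> np.ndarray:
        """Tangential viscous traction vector (Pa) at each wall sample."""
        g = self.wall_gradient(u)
        mu = np.asarray(casson_viscosity(np.abs(g), self.props))
        return (mu * g)[:, None] * self.tangents

    def pressure(self, p: np.ndarray) -> np.ndarray:
        e = self.edges
        return 0.5 * (p[e[:, 0]] + p[e[:, 1]])


def _order_chains(edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order directed boundary edges into connected chains.

    Returns (permutation, chain id per reordered edge).
    """
    start_of = {int(a): i for i, (a, b) in enumerate(edges)}
    ends = {int(b) for _, b in edges}
    heads = [i for i, (a, _) in enumerate(edges) if int(a) not in ends]
    used = np.zeros(len(edges), dtype=bool)
    order: list[int] = []
    chain: list[int] = []
    cid = 0
    seeds = heads + [i for i in range(len(edges))]  # fallback covers closed loops
    for seed in seeds:
        if used[seed]:
            continue
        i = seed
        while True:
            used[i] = True
            order.append(i)
            chain.append(cid)
            nxt = start_of.get(int(edges[i, 1]), None)
            if nxt is None or used[nxt]:
                break
            i = nxt
        cid += 1
    return np.array(order, dtype=int), np.array(chain, dtype=int)


def _adjacent_heights(mesh: Mesh, edges: np.ndarray) -> np.ndarray:
    """Height of the wall-adjacent triangle over each boundary edge."""
    tris, _ = mesh.triangulated()
    pts = mesh.points
    edge_to_tri: dict[tuple[int, int], int] = {}
    for t_idx, tri in enumerate(tris):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            edge_to_tri.setdefault(key, t_idx)
    heights = np.zeros(len(edges))
    for i, (a, b) in enumerate(edges):
        t_idx = edge_to_tri[(min(a, b), max(a, b))]
        tri = pts[tris[t_idx]]
        area = 0.5 * abs(
            (tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1])
            - (tri[2, 0] - tri[0, 0]) * (tri[1, 1] - tri[0, 1])
        )
        elen = np.linalg.norm(pts[b] - pts[a])
        heights[i] = 2.0 * area / elen
    return heights


# ---------------------------------------------------------------------------
# wall series and indices
# ---------------------------------------------------------------------------


@dataclass
class WallSeries:
    """Per-wall-sample traction/pressure time series over one cycle."""

    times: np.ndarray  # (nt,), spanning [0, T]
    period: float
    positions: np.ndarray  # (ne, 2)
    arclength: np.ndarray  # (ne,)
    chain: np.ndarray  # (ne,)
    tags: np.ndarray  # (ne,) BoundaryTag ints
    tractions: np.ndarray  # (nt, ne, 2)
    pressures: np.ndarray  # (nt, ne)

    def __post_init__(self) -> None:
        nt = len(self.times)
        if self.tractions.shape[0] != nt or self.pressures.shape[0] != nt:
            raise PostprocessError("time axis mismatch in WallSeries")
        if nt < 2:
            raise PostprocessError("WallSeries needs at least two time samples")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-8):
            raise PostprocessError("WallSeries requires uniform time sampling")
        if not np.isclose(self.times[-1] - self.times[0], self.period, rtol=1e-6):
            raise PostprocessError("WallSeries must span exactly one period")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.tractions, axis=2)

    def sac_mask(self) -> np.ndarray:
        return self.tags == int(BoundaryTag.SAC_WALL)

    def index_at_time(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - (t % self.period))))


def wall_shear_stress(
    state, mesh: Mesh, props: BloodProperties, probe: WallProbe | None = None
) -> np.ndarray:
    """Tangential viscous wall traction vectors (Pa) for one flow state."""
    if probe is None:
        probe = WallProbe(mesh, props)
    return probe.traction(state.u)


def tawss(series: WallSeries) -> np.ndarray:
    """Time-averaged WSS magnitude (Pa) per wall sample."""
    return np.trapezoid(series.magnitudes, series.times, axis=0) / series.period


def osi(series: WallSeries) -> np.ndarray:
    """Oscillatory shear index per wall sample, in [0, 0.5]."""
    mean_vec = np.trapezoid(series.tractions, series.times, axis=0)
    mean_mag = np.trapezoid(series.magnitudes, series.times, axis=0)
    return _osi_from_integrals(np.linalg.norm(mean_vec, axis=-1), mean_mag)


def _osi_from_integrals(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(den)
    ok = den > 0.0
    if not np.all(ok):
        warnings.warn("all-zero traction series: OSI defined as 0", stacklevel=2)
    out[ok] = 0.5 * (1.0 - num[ok] / den[ok])
    return np.clip(out, 0.0, 0.5)


def windowed_osi(series: WallSeries, center: float, width: float) -> np.ndarray:
    """OSI evaluated on a centered sub-window of the cycle.

    The window [center - width/2, center + width/2] is taken on the
    periodic extension of the series.  Used for per-landmark OSI maps.
    """
    if not 0.0 < width <= series.period:
        raise PostprocessError("window width must lie in (0, T]")
    t = series.times
    dt = t[1] - t[0]
    nt = len(t) - 1  # last sample repeats the first, one period later
    n_half = max(1, int(round(0.5 * width / dt)))
    i0 = int(round(((center % series.period) - 0.5 * width) / dt))
    idx = (i0 + np.arange(2 * n_half + 1)) % nt
    tr = series.tractions[idx]
    mag = series.magnitudes[idx]
    tw = np.arange(2 * n_half + 1) * dt
    num = np.linalg.norm(np.trapezoid(tr, tw, axis=0), axis=-1)
    den = np.trapezoid(mag, tw, axis=0)
    return _osi_from_integrals(num, den)


def peak_pressure(series: WallSeries) -> np.ndarray:
    """Maximum wall pressure (Pa) over the cycle, per sample."""
    return series.pressures.max(axis=0)


# ---------------------------------------------------------------------------
# sac metrics
# ---------------------------------------------------------------------------


def neck_sample_points(geom: VesselGeometry, n: int = 65) -> np.ndarray:
    p1, p2 = geom.neck_endpoints
    t = np.linspace(0.0, 1.0, n)
    pts = p1 + t[:, None] * (p2 - p1)
    # nudge off the exact chord so samples sit inside the mesh
    return pts + 1e-9 * geom.neck_outward_normal


def sac_mean_inflow_velocity(
    state, mesh: Mesh, geom: VesselGeometry, n_samples: int = 65
) -> float:
    """Length-weighted mean velocity magnitude across the neck section."""
    if not geom.has_sac:
        raise PostprocessError("geometry has no sac: neck section undefined")
    pts = neck_sample_points(geom, n_samples)
    W = interpolation_matrix(mesh, pts)
    uvec = W @ state.u
    speed = np.linalg.norm(uvec, axis=1)
    return float(np.trapezoid(speed, dx=1.0 / (n_samples - 1)))


def iso_velocity_area(state, mesh: Mesh, level: float) -> float:
    """Total area (m^2) of cells whose mean speed exceeds ``level``."""
    tris, parent = mesh.triangulated()
    speed = np.linalg.norm(state.u[tris].mean(axis=1), axis=1)
    areas = np.zeros(mesh.n_cells)
    tri_areas = _tri_area_array(mesh)
    np.add.at(areas, parent, np.where(speed >= level, tri_areas, 0.0))
    return float(areas.sum())


def _tri_area_array(mesh: Mesh) -> np.ndarray:
    tris, _ = mesh.triangulated()
    p = mesh.points
    a, b, c = p[tris[:, 0]], p[tris[:, 1]], p[tris[:, 2]]
    return 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )


# ---------------------------------------------------------------------------
# risk regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskRegion:
    """Maximal connected wall arc where OSI exceeds the threshold."""

    chain: int
    start_arc: float
    end_arc: float
    peak_osi: float
    peak_arc: float
    n_samples: int

    @property
    def extent(self) -> float:
        return self.end_arc - self.start_arc


def high_risk_regions(
    arclength: np.ndarray,
    osi_values: np.ndarray,
    threshold: float,
    chain: np.ndarray | None = None,
) -> list[RiskRegion]:
    """Contiguous wall segments with OSI >= threshold.

    Samples must be ordered by arc length within each chain (WallSeries
    order).  Returns one region per maximal super-threshold run.
    """
    if not 0.0 < threshold < 0.5:
        raise PostprocessError("osi threshold must lie in (0, 0.5)")
    arclength = np.asarray(arclength)
    osi_values = np.asarray(osi_values)
    if chain is None:
        chain = np.zeros(len(arclength), dtype=int)
    regions: list[RiskRegion] = []
    above = osi_values >= threshold
    breaks = np.flatnonzero(
        np.diff(above.astype(int)) != 0
    )
    run_edges = np.concatenate([[0], breaks + 1, [len(above)]])
    for lo, hi in zip(run_edges[:-1], run_edges[1:]):
        if not above[lo]:
            continue
        for cid in np.unique(chain[lo:hi]):
            m = np.flatnonzero((chain == cid) & above)
            m = m[(m >= lo) & (m < hi)]
            if len(m) == 0:
                continue
            vals = osi_values[m]
            pk = int(np.argmax(vals))
            regions.append(
                RiskRegion(
                    chain=int(cid),
                    start_arc=float(arclength[m[0]]),
                    end_arc=float(arclength[m[-1]]),
                    peak_osi=float(vals[pk]),
                    peak_arc=float(arclength[m[pk]]),
                    n_samples=len(m),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# per-run indices and cross-condition comparison
# ---------------------------------------------------------------------------

LANDMARK_NAMES = ("A", "B", "C", "D")
COMPARISON_INDICES = ("max_wss", "max_osi", "sac_mean_velocity")


@dataclass
class HemodynamicIndices:
    """All wall indices of one run, plus per-landmark scalar metrics."""

    arclength: np.ndarray
    chain: np.ndarray
    tags: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    peak_pressure: np.ndarray
    landmark_metrics: dict[str, dict[str, float]]
    global_max: dict[str, dict[str, float]]
    geometry_signature: str = ""

    def max_osi(self) -> float:
        return float(self.osi.max())

    def max_tawss(self) -> float:
        return float(self.tawss.max())


def compute_indices(
    result,
    mesh: Mesh,
    geom: VesselGeometry,
    osi_window: float = 0.25,
    noise_floor: float = 0.01,
) -> HemodynamicIndices:
    """Post-process a PulsatileResult into HemodynamicIndices.

    ``osi_window`` is the per-landmark OSI window width as a fraction of
    the period.  Per-landmark OSI extrema are taken over sac-wall samples
    whose cycle TAWSS exceeds ``noise_floor`` times the sac maximum, so
    near-stagnant samples (OSI saturates at 0.5 on vanishing tractions)
    do not dominate the statistic.
    """
    series: WallSeries = result.wall_series
    T = series.period
    cyc_osi = osi(series)
    cyc_tawss = tawss(series)
    pp = peak_pressure(series)
    sac = series.sac_mask()
    mags = series.magnitudes

    pool = sac if np.any(sac) else np.ones(len(cyc_tawss), dtype=bool)
    floor = noise_floor * cyc_tawss[pool].max()
    pool = pool & (cyc_tawss >= floor)

    lm_metrics: dict[str, dict[str, float]] = {}
    for name, t_lm in result.landmarks.as_dict().items():
        it = series.index_at_time(t_lm)
        wosi = windowed_osi(series, t_lm, osi_window * T)
        state = result.landmark_states[name]
        lm_metrics[name] = {
            "time": float(t_lm),
            "max_wss": float(mags[it].max()),
            "max_osi": float(wosi[pool].max()),
            "mean_osi": float(wosi[pool].mean()),
            "sac_mean_velocity": (
                sac_mean_inflow_velocity(state, mesh, geom) if geom.has_sac else 0.0
            ),
            "max_pressure": float(series.pressures[it].max()),
        }

    i_peak = np.unravel_index(np.argmax(mags), mags.shape)
    pool_idx = np.flatnonzero(pool)
    i_sac = pool_idx[int(np.argmax(cyc_osi[pool]))]
    gmax = {
        "osi_sac": {
            "value": float(cyc_osi[i_sac]),
            "arclength": float(series.arclength[i_sac]),
            "noise_floor": float(floor),
        },
        "wss": {
            "value": float(mags[i_peak]),
            "time": float(series.times[i_peak[0]]),
            "arclength": float(series.arclength[i_peak[1]]),
        },
        "osi": {
            "value": float(cyc_osi.max()),
            "arclength": float(series.arclength[int(np.argmax(cyc_osi))]),
        },
        "pressure": {
            "value": float(pp.max()),
            "arclength": float(series.arclength[int(np.argmax(pp))]),
        },
    }
    sig = _geometry_signature(geom, mesh)
    return HemodynamicIndices(
        arclength=series.arclength,
        chain=series.chain,
        tags=series.tags,
        tawss=cyc_tawss,
        osi=cyc_osi,
        peak_pressure=pp,
        landmark_metrics=lm_metrics,
        global_max=gmax,
        geometry_signature=sig,
    )


def _geometry_signature(geom: VesselGeometry, mesh: Mesh) -> str:
    g = geom
    return (
        f"D={g.parent_width:.6g};L={g.parent_length:.6g};k={g.curvature:.6g};"
        f"N={g.sac_neck_width:.6g};Hs={g.sac_depth:.6g};shape={g.sac_shape.value};"
        f"s0={g.sac_center_arc:.6g};h={mesh.h:.6g};n={mesh.n_nodes}"
    )


@dataclass
class ComparisonRow:
    condition: tuple
    landmark: str
    index: str
    reference_value: float
    value: float
    percent_change: float


@dataclass
class ComparisonReport:
    reference: tuple
    rows: list[ComparisonRow]

    def to_records(self) -> list[dict]:
        return [
            {
                "condition": list(r.condition),
                "landmark": r.landmark,
                "index": r.index,
                "reference_value": r.reference_value,
                "value": r.value,
                "percent_change": r.percent_change,
            }
            for r in self.rows
        ]

    def to_table(self) -> str:
        hdr = f"{'condition':>18} {'phase':>5} {'index':>18} {'ref':>12} {'value':>12} {'change %':>9}"
        lines = [hdr, "-" * len(hdr)]
        for r in self.rows:
            cond = ",".join(f"{v:g}" for v in r.condition)
            lines.append(
                f"{cond:>18} {r.landmark:>5} {r.index:>18} "
                f"{r.reference_value:12.5g} {r.value:12.5g} {r.percent_change:9.2f}"
            )
        return "\n".join(lines)


def compare_conditions(
    results: dict[tuple, HemodynamicIndices], reference: tuple
) -> ComparisonReport:
    """Percent change of each index vs a reference condition, per landmark.

    percent_change = 100 * (x_ref - x) / x_ref (positive = reduction).
    """
    if len(results) < 2:
        raise PostprocessError("need at least two conditions to compare")
    if reference not in results:
        raise PostprocessError(f"reference condition {reference!r} not in results")
    ref = results[reference]
    sigs = {k: v.geometry_signature for k, v in results.items()}
    if len(set(sigs.values())) > 1:
        raise PostprocessError(
            f"conditions computed on different geometries/meshes: {sigs}"
        )
    rows: list[ComparisonRow] = []
    for key, idxs in results.items():
        if key == reference:
            continue
        for lm in LANDMARK_NAMES:
            for index in COMPARISON_INDICES:
                x_ref = ref.landmark_metrics[lm][index]
                x = idxs.landmark_metrics[lm][index]
                change = 100.0 * (x_ref - x) / x_ref if x_ref != 0.0 else np.nan
                rows.append(
                    ComparisonRow(
                        condition=key,
                        landmark=lm,
                        index=index,
                        reference_value=x_ref,
                        value=x,
                        percent_change=float(change),
                    )
                )
    return ComparisonReport(reference=reference, rows=rows)
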