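"""Idealized 2-D sidewall-aneurysm geometry and mesh generation.

The domain is a planar channel of width ``D`` (a straight strip or a
circular-arc bend of centerline curvature ``kappa``) carrying, on its outer
wall, a sac shaped either as a circular segment or a half-ellipse.  A
"coil region" occupying a configurable fraction of the sac area, packed
from the dome toward the neck, is flagged on the mesh so the solver can
apply a porous momentum sink there.

Meshing is self-contained: straight/curved channels without a sac use a
mapped structured quadrilateral grid; geometries with a sac are
triangulated with a Delaunay front (boundary points at spacing ``h``,
interior points on a hexagonal lattice, Laplacian smoothing).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.optimize import brentq
from scipy.spatial import Delaunay
from shapely.geometry import Polygon


class SacShape(str, enum.Enum):
    NONE = "none"
    CIRCULAR_SEGMENT = "circular_segment"
    ELLIPTICAL = "elliptical"


class BoundaryTag(enum.IntEnum):
    INLET = 0
    OUTLET = 1
    VESSEL_WALL = 2
    SAC_WALL = 3


class GeometryError(ValueError):
    """Inconsistent geometric parameters."""


class MeshingError(RuntimeError):
    """Mesh generation failed or produced an invalid mesh."""


def circular_segment_area(radius: float, height: float) -> float:
    """Area of a circular segment of the given chordal ``height`` (sagitta).

    Valid for 0 <= height <= 2*radius; height > radius gives the major
    segment.
    """
    if height <= 0.0:
        return 0.0
    h = min(height, 2.0 * radius)
    d = radius - h
    return radius * radius * math.acos(d / radius) - d * math.sqrt(2.0 * radius * h - h * h)


def _elliptical_segment_area(a: float, b: float, cut: float) -> float:
    """Area of {x^2/a^2 + y^2/b^2 <= 1, y >= cut} for cut in [0, b]."""
    if cut >= b:
        return 0.0
    c = max(cut, 0.0)
    return (a / b) * (b * b * math.acos(c / b) - c * math.sqrt(b * b - c * c))


@dataclass(frozen=True)
class VesselGeometry:
    """Parametric parent vessel + sidewall sac, all lengths in metres.

    ``sac_center_arc`` locates the neck midpoint by arc length along the
    *outer* wall; ``coil_fill_fraction`` is the fraction of the sac area
    occupied by the coil region, measured from the dome inward.
    """

    parent_width: float
    parent_length: float
    curvature: float = 0.0
    sac_neck_width: float = 0.0
    sac_depth: float = 0.0
    sac_shape: SacShape = SacShape.NONE
    sac_center_arc: float = 0.0
    coil_fill_fraction: float = 0.0

    def __post_init__(self) -> None:
        D, L = self.parent_width, self.parent_length
        if D <= 0.0:
            raise GeometryError("parent_width must be positive")
        if L <= 0.0:
            raise GeometryError("parent_length must be positive")
        if self.curvature < 0.0:
            raise GeometryError("curvature must be >= 0 (outer wall carries the sac)")
        if self.curvature > 0.0 and 1.0 / self.curvature <= D / 2.0:
            raise GeometryError("curvature radius must exceed half the vessel width")
        if not 0.0 <= self.coil_fill_fraction <= 1.0:
            raise GeometryError("coil_fill_fraction must lie in [0, 1]")
        if self.sac_shape is SacShape.NONE:
            return
        N, Hs = self.sac_neck_width, self.sac_depth
        if N <= 0.0:
            raise GeometryError("sac_neck_width must be positive for a sac")
        if Hs <= 0.0:
            raise GeometryError("sac_depth must be positive for a sac")
        Lw = self.outer_wall_length
        if self.curvature > 0.0:
            ro = self.outer_wall_radius
            if N >= 2.0 * ro:
                raise GeometryError("sac_neck_width exceeds the admissible outer-wall chord")
        margin = N  # keep the neck a neck-width away from the ports
        if not margin <= self.sac_center_arc <= Lw - margin:
            raise GeometryError(
                f"sac_center_arc={self.sac_center_arc:g} places the neck too close to "
                f"the inlet/outlet (wall length {Lw:g}, margin {margin:g})"
            )

    # ----- parent vessel -------------------------------------------------

    @property
    def has_sac(self) -> bool:
        return self.sac_shape is not SacShape.NONE

    @property
    def is_curved(self) -> bool:
        return self.curvature > 0.0

    @property
    def centerline_radius(self) -> float:
        if not self.is_curved:
            return math.inf
        return 1.0 / self.curvature

    @property
    def bend_angle(self) -> float:
        return self.parent_length * self.curvature

    @property
    def curvature_center(self) -> np.ndarray:
        # Inlet at the origin with tangent +x; the bend turns toward -y so
        # the outer (sac-carrying) wall is the +y side.
        return np.array([0.0, -self.centerline_radius])

    @property
    def outer_wall_radius(self) -> float:
        return self.centerline_radius + self.parent_width / 2.0

    @property
    def inner_wall_radius(self) -> float:
        return self.centerline_radius - self.parent_width / 2.0

    @property
    def outer_wall_length(self) -> float:
        if not self.is_curved:
            return self.parent_length
        return self.outer_wall_radius * self.bend_angle

    @property
    def inner_wall_length(self) -> float:
        if not self.is_curved:
            return self.parent_length
        return self.inner_wall_radius * self.bend_angle

    def outer_wall_point(self, s: float | np.ndarray) -> np.ndarray:
        """Point on the outer wall at wall arc length ``s`` (vectorized)."""
        s = np.asarray(s, dtype=float)
        if not self.is_curved:
            return np.stack([s, np.full_like(s, self.parent_width / 2.0)], axis=-1)
        ro = self.outer_wall_radius
        th = s / ro
        return self.curvature_center + ro * np.stack([np.sin(th), np.cos(th)], axis=-1)

    def inner_wall_point(self, s_frac: float | np.ndarray) -> np.ndarray:
        """Point on the inner wall at fractional position along it."""
        f = np.asarray(s_frac, dtype=float)
        if not self.is_curved:
            return np.stack(
                [f * self.parent_length, np.full_like(f, -self.parent_width / 2.0)], axis=-1
            )
        ri = self.inner_wall_radius
        th = f * self.bend_angle
        return self.curvature_center + ri * np.stack([np.sin(th), np.cos(th)], axis=-1)

    @property
    def parent_area(self) -> float:
        # Annulus sector area equals centerline length x width for any kappa.
        return self.parent_length * self.parent_width

    # ----- sac -----------------------------------------------------------

    @property
    def neck_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Neck chord endpoints on the outer wall, upstream first."""
        if not self.has_sac:
            raise GeometryError("geometry has no sac")
        N = self.sac_neck_width
        if not self.is_curved:
            y = self.parent_width / 2.0
            return (
                np.array([self.sac_center_arc - N / 2.0, y]),
                np.array([self.sac_center_arc + N / 2.0, y]),
            )
        ro = self.outer_wall_radius
        th0 = self.sac_center_arc / ro
        dphi = math.asin(N / (2.0 * ro))
        c = self.curvature_center
        p1 = c + ro * np.array([math.sin(th0 - dphi), math.cos(th0 - dphi)])
        p2 = c + ro * np.array([math.sin(th0 + dphi), math.cos(th0 + dphi)])
        return p1, p2

    @property
    def neck_midpoint(self) -> np.ndarray:
        p1, p2 = self.neck_endpoints
        return 0.5 * (p1 + p2)

    @property
    def neck_outward_normal(self) -> np.ndarray:
        """Unit normal of the neck chord pointing into the sac."""
        if not self.is_curved:
            return np.array([0.0, 1.0])
        v = self.neck_midpoint - self.curvature_center
        return v / np.linalg.norm(v)

    @property
    def neck_tangent(self) -> np.ndarray:
        p1, p2 = self.neck_endpoints
        v = p2 - p1
        return v / np.linalg.norm(v)

    @property
    def sac_dome_radius(self) -> float:
        """Radius of the sac circle (circular_segment shape only)."""
        if self.sac_shape is not SacShape.CIRCULAR_SEGMENT:
            raise GeometryError("dome radius defined only for circular_segment sacs")
        N, Hs = self.sac_neck_width, self.sac_depth
        return ((N / 2.0) ** 2 + Hs**2) / (2.0 * Hs)

    @property
    def sac_circle_center(self) -> np.ndarray:
        r = self.sac_dome_radius
        return self.neck_midpoint + (self.sac_depth - r) * self.neck_outward_normal

    @property
    def dome_point(self) -> np.ndarray:
        return self.neck_midpoint + self.sac_depth * self.neck_outward_normal

    @property
    def _wall_lens_sagitta(self) -> float:
        """Height of the outer-wall arc bulge beyond the neck chord."""
        if not self.has_sac or not self.is_curved:
            return 0.0
        ro = self.outer_wall_radius
        return ro - math.sqrt(ro * ro - (self.sac_neck_width / 2.0) ** 2)

    def _sac_region_area_above(self, cut: float) -> float:
        """Sac area beyond the line parallel to the neck chord at offset ``cut``."""
        Hs = self.sac_depth
        if self.sac_shape is SacShape.CIRCULAR_SEGMENT:
            seg = circular_segment_area(self.sac_dome_radius, Hs - cut)
        elif self.sac_shape is SacShape.ELLIPTICAL:
            seg = _elliptical_segment_area(self.sac_neck_width / 2.0, Hs, cut)
        else:
            return 0.0
        zeta = self._wall_lens_sagitta
        if cut < zeta:
            seg -= circular_segment_area(self.outer_wall_radius, zeta - cut)
        return seg

    @property
    def sac_area(self) -> float:
        """Analytic area of the sac proper (beyond the outer wall)."""
        if not self.has_sac:
            return 0.0
        return self._sac_region_area_above(0.0)

    def coil_cut_offset(self) -> float:
        """Chord-parallel offset delimiting the coil region (dome side).

        The returned offset ``c`` satisfies
        area(sac beyond c) = coil_fill_fraction * sac_area.
        """
        f = self.coil_fill_fraction
        if not self.has_sac or f <= 0.0:
            return self.sac_depth
        if f >= 1.0:
            return 0.0
        target = f * self.sac_area
        return brentq(
            lambda c: self._sac_region_area_above(c) - target, 0.0, self.sac_depth, xtol=1e-14
        )

    @property
    def coil_region_area(self) -> float:
        return self.coil_fill_fraction * self.sac_area

    @property
    def total_area(self) -> float:
        return self.parent_area + self.sac_area

    # ----- point classification ------------------------------------------

    def _chord_offsets(self, pts: np.ndarray) -> np.ndarray:
        w = self.neck_outward_normal
        return (pts - self.neck_midpoint) @ w

    def _inside_sac_shape(self, pts: np.ndarray) -> np.ndarray:
        if self.sac_shape is SacShape.CIRCULAR_SEGMENT:
            d = np.linalg.norm(pts - self.sac_circle_center, axis=-1)
            return d <= self.sac_dome_radius
        t = (pts - self.neck_midpoint) @ self.neck_tangent
        n = self._chord_offsets(pts)
        a, b = self.sac_neck_width / 2.0, self.sac_depth
        return (t / a) ** 2 + (n / b) ** 2 <= 1.0

    def _outside_parent(self, pts: np.ndarray) -> np.ndarray:
        if not self.is_curved:
            return pts[..., 1] > self.parent_width / 2.0
        d = np.linalg.norm(pts - self.curvature_center, axis=-1)
        return d > self.outer_wall_radius

    def coil_region_mask(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask of points lying inside the coil region."""
        pts = np.asarray(pts, dtype=float)
        if not self.has_sac or self.coil_fill_fraction <= 0.0:
            return np.zeros(pts.shape[:-1], dtype=bool)
        cut = self.coil_cut_offset()
        return (
            self._inside_sac_shape(pts)
            & (self._chord_offsets(pts) >= cut)
            & self._outside_parent(pts)
        )

    # ----- boundary polyline ---------------------------------------------

    def _sac_arc_points(self, spacing: float) -> np.ndarray:
        """Sac wall from downstream neck point to upstream one (CCW walk)."""
        p1, p2 = self.neck_endpoints
        if self.sac_shape is SacShape.CIRCULAR_SEGMENT:
            c = self.sac_circle_center
            r = self.sac_dome_radius
            a2 = math.atan2(*(p2 - c)[::-1])
            a1 = math.atan2(*(p1 - c)[::-1])
            ad = math.atan2(*(self.dome_point - c)[::-1])
            # walk from p2 to p1 passing through the dome
            ccw = (a1 - a2) % (2.0 * math.pi)
            dome_ccw = (ad - a2) % (2.0 * math.pi)
            if dome_ccw <= ccw:
                sweep = ccw
            else:
                sweep = ccw - 2.0 * math.pi
            n = max(8, int(math.ceil(abs(sweep) * r / spacing)))
            ang = a2 + sweep * np.arange(n + 1) / n
            pts = c + r * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
            pts[0], pts[-1] = p2, p1  # snap to the exact neck endpoints
            return pts
        # elliptical: parametrize from p2 (t=+a) over the dome to p1 (t=-a)
        a, b = self.sac_neck_width / 2.0, self.sac_depth
        n = max(8, int(math.ceil(math.pi * max(a, b) / spacing)))
        phi = np.linspace(0.0, math.pi, n + 1)
        t = a * np.cos(phi)
        w = b * np.sin(phi)
        tang, norm = self.neck_tangent, self.neck_outward_normal
        pts = self.neck_midpoint + t[:, None] * tang + w[:, None] * norm
        pts[0], pts[-1] = p2, p1  # snap to the exact neck endpoints
        return pts

    def boundary_segments(self, spacing: float) -> list[tuple[BoundaryTag, np.ndarray]]:
        """Closed CCW boundary as tagged polylines.

        Each segment includes both endpoints; consecutive segments share one
        point.  Order: inner wall (inlet to outlet), outlet face, outer wall
        downstream, sac arc (if any), outer wall upstream, inlet face.
        """
        D = self.parent_width
        segs: list[tuple[BoundaryTag, np.ndarray]] = []

        def sample_line(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
            n = max(1, int(round(np.linalg.norm(p1 - p0) / spacing)))
            t = np.linspace(0.0, 1.0, n + 1)
            return p0 + t[:, None] * (p1 - p0)

        def sample_outer(s0: float, s1: float) -> np.ndarray:
            n = max(1, int(round(abs(s1 - s0) / spacing)))
            return self.outer_wall_point(np.linspace(s0, s1, n + 1))

        ni = max(2, int(round(self.inner_wall_length / spacing)))
        inner = self.inner_wall_point(np.linspace(0.0, 1.0, ni + 1))
        segs.append((BoundaryTag.VESSEL_WALL, inner))

        inlet_in = self.inner_wall_point(0.0)
        inlet_out = self.outer_wall_point(0.0)
        outlet_in = self.inner_wall_point(1.0)
        outlet_out = self.outer_wall_point(self.outer_wall_length)
        segs.append((BoundaryTag.OUTLET, sample_line(outlet_in, outlet_out)))

        Lw = self.outer_wall_length
        if self.has_sac:
            p1, p2 = self.neck_endpoints
            if self.is_curved:
                ro = self.outer_wall_radius
                th0 = self.sac_center_arc / ro
                dphi = math.asin(self.sac_neck_width / (2.0 * ro))
                s1 = (th0 - dphi) * ro
                s2 = (th0 + dphi) * ro
            else:
                s1 = self.sac_center_arc - self.sac_neck_width / 2.0
                s2 = self.sac_center_arc + self.sac_neck_width / 2.0
            segs.append((BoundaryTag.VESSEL_WALL, sample_outer(Lw, s2)[:-1]))
            # re-append shared point for exact neck endpoints
            segs[-1] = (BoundaryTag.VESSEL_WALL, np.vstack([segs[-1][1], p2]))
            segs.append((BoundaryTag.SAC_WALL, self._sac_arc_points(spacing)))
            up = sample_outer(s1, 0.0)
            up[0] = p1
            segs.append((BoundaryTag.VESSEL_WALL, up))
        else:
            segs.append((BoundaryTag.VESSEL_WALL, sample_outer(Lw, 0.0)))

        segs.append((BoundaryTag.INLET, sample_line(inlet_out, inlet_in)))
        return segs

    def boundary_polygon(self, spacing: float) -> Polygon:
        pts = np.vstack([seg[:-1] for _, seg in self.boundary_segments(spacing)])
        return Polygon(pts)


def build_idealized_aneurysm(
    parent_width: float = 4.0e-3,
    parent_length: float = 40.0e-3,
    curvature: float = 50.0,
    sac_neck_width: float = 4.0e-3,
    sac_depth: float | None = None,
    sac_dome_radius: float | None = 3.0e-3,
    sac_shape: SacShape | str = SacShape.CIRCULAR_SEGMENT,
    sac_center_arc: float | None = None,
    coil_fill_fraction: float = 1.0,
) -> VesselGeometry:
    """Construct the default curved parent vessel with a sidewall sac.

    For a ``circular_segment`` sac the depth may be given either directly
    (``sac_depth``) or via the dome radius, in which case the dome-shaped
    (major-segment) depth ``r + sqrt(r^2 - (N/2)^2)`` is used.
    """
    sac_shape = SacShape(sac_shape)
    if sac_shape is SacShape.NONE or sac_neck_width == 0.0:
        return VesselGeometry(
            parent_width=parent_width,
            parent_length=parent_length,
            curvature=curvature,
            sac_shape=SacShape.NONE,
        )
    if sac_depth is None:
        if sac_dome_radius is None:
            raise GeometryError("provide sac_depth or sac_dome_radius")
        if sac_shape is not SacShape.CIRCULAR_SEGMENT:
            raise GeometryError("sac_dome_radius applies to circular_segment sacs only")
        r = sac_dome_radius
        if sac_neck_width > 2.0 * r:
            raise GeometryError(
                f"sac_neck_width={sac_neck_width:g} exceeds the sac diameter "
                f"2*r={2 * r:g} (violated constraint: N <= 2*dome radius)"
            )
        sac_depth = r + math.sqrt(r * r - (sac_neck_width / 2.0) ** 2)
    if sac_center_arc is None:
        if curvature > 0.0:
            lw = (1.0 / curvature + parent_width / 2.0) * parent_length * curvature
        else:
            lw = parent_length
        sac_center_arc = lw / 2.0
    return VesselGeometry(
        parent_width=parent_width,
        parent_length=parent_length,
        curvature=curvature,
        sac_neck_width=sac_neck_width,
        sac_depth=sac_depth,
        sac_shape=sac_shape,
        sac_center_arc=sac_center_arc,
        coil_fill_fraction=coil_fill_fraction,
    )


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """2-D mesh: triangles or quadrilaterals with tagged boundary edges."""

    points: np.ndarray  # (n_nodes, 2)
    cells: np.ndarray  # (n_cells, 3) or (n_cells, 4)
    boundary_edges: np.ndarray  # (n_bedges, 2) node pairs, outward CCW order
    boundary_tags: np.ndarray  # (n_bedges,) BoundaryTag values
    coil_mask: np.ndarray  # (n_cells,) bool
    h: float
    geometry: VesselGeometry | None = None
    _tri_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def is_quad(self) -> bool:
        return self.cells.shape[1] == 4

    def cell_areas(self) -> np.ndarray:
        p = self.points
        c = self.cells
        if self.is_quad:
            a1 = _tri_areas(p[c[:, 0]], p[c[:, 1]], p[c[:, 2]])
            a2 = _tri_areas(p[c[:, 0]], p[c[:, 2]], p[c[:, 3]])
            return a1 + a2
        return _tri_areas(p[c[:, 0]], p[c[:, 1]], p[c[:, 2]])

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    def triangulated(self) -> tuple[np.ndarray, np.ndarray]:
        """Triangle connectivity plus parent-cell index per triangle."""
        if self._tri_cache is None:
            if self.is_quad:
                q = self.cells
                t = np.vstack([q[:, [0, 1, 2]], q[:, [0, 2, 3]]])
                parent = np.concatenate([np.arange(self.n_cells)] * 2)
            else:
                t = self.cells
                parent = np.arange(self.n_cells)
            object.__setattr__(self, "_tri_cache", (t, parent))
        return self._tri_cache

    @property
    def tri_coil_mask(self) -> np.ndarray:
        _, parent = self.triangulated()
        return self.coil_mask[parent]

    def total_area(self) -> float:
        return float(self.cell_areas().sum())

    def boundary_nodes(self, tag: BoundaryTag | None = None) -> np.ndarray:
        if tag is None:
            e = self.boundary_edges
        else:
            e = self.boundary_edges[self.boundary_tags == int(tag)]
        return np.unique(e)

    def edge_lengths(self, edges: np.ndarray) -> np.ndarray:
        d = self.points[edges[:, 1]] - self.points[edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    def validate(self) -> None:
        areas = self.cell_areas()
        if not np.all(areas > 0.0):
            raise MeshingError(f"{np.sum(areas <= 0)} cells with non-positive area")
        tris, _ = self.triangulated()
        if np.any(_tri_areas(*(self.points[tris[:, i]] for i in range(3))) <= 0.0):
            raise MeshingError("negatively oriented or degenerate triangle present")
        edge_count: dict[tuple[int, int], int] = {}
        ncorner = self.cells.shape[1]
        for k in range(ncorner):
            a = self.cells[:, k]
            b = self.cells[:, (k + 1) % ncorner]
            for e in zip(np.minimum(a, b).tolist(), np.maximum(a, b).tolist()):
                edge_count[e] = edge_count.get(e, 0) + 1
        if any(v > 2 for v in edge_count.values()):
            raise MeshingError("non-manifold edge (shared by >2 cells)")
        hull = {e for e, v in edge_count.items() if v == 1}
        tagged = {
            (min(a, b), max(a, b)) for a, b in self.boundary_edges.tolist()
        }
        if hull != tagged:
            raise MeshingError(
                f"boundary tagging not exhaustive/disjoint: {len(hull)} hull edges "
                f"vs {len(tagged)} tagged edges"
            )
        if len(self.boundary_tags) != len(self.boundary_edges):
            raise MeshingError("boundary tag array length mismatch")
        for tag in (BoundaryTag.INLET, BoundaryTag.OUTLET):
            if not np.any(self.boundary_tags == int(tag)):
                raise MeshingError(f"missing boundary group {tag.name}")


def _tri_areas(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    return 0.5 * (
        (p1[..., 0] - p0[..., 0]) * (p2[..., 1] - p0[..., 1])
        - (p2[..., 0] - p0[..., 0]) * (p1[..., 1] - p0[..., 1])
    )


def _structured_channel_mesh(geom: VesselGeometry, h: float) -> Mesh:
    D, L = geom.parent_width, geom.parent_length
    nx = max(4, int(round(L / h)))
    ny = max(4, int(round(D / h)))
    xi = np.linspace(0.0, 1.0, nx + 1)
    eta = np.linspace(-0.5, 0.5, ny + 1)
    if geom.is_curved:
        rc = geom.centerline_radius
        th = xi * geom.bend_angle
        r = rc + eta * D
        c = geom.curvature_center
        X = c[0] + np.outer(np.sin(th), r)
        Y = c[1] + np.outer(np.cos(th), r)
    else:
        X, Y = np.meshgrid(xi * L, eta * D, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(i: int | np.ndarray, j: int | np.ndarray) -> np.ndarray:
        return i * (ny + 1) + j

    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    quads = np.stack(
        [nid(ii, jj), nid(ii + 1, jj), nid(ii + 1, jj + 1), nid(ii, jj + 1)], axis=-1
    ).reshape(-1, 4)

    edges, tags = [], []
    for j in range(ny):  # inlet i=0, CCW means descending j
        edges.append((nid(0, j + 1), nid(0, j)))
        tags.append(BoundaryTag.INLET)
    for j in range(ny):  # outlet i=nx
        edges.append((nid(nx, j), nid(nx, j + 1)))
        tags.append(BoundaryTag.OUTLET)
    for i in range(nx):  # bottom wall j=0
        edges.append((nid(i, 0), nid(i + 1, 0)))
        tags.append(BoundaryTag.VESSEL_WALL)
    for i in range(nx):  # top wall j=ny
        edges.append((nid(i + 1, ny), nid(i, ny)))
        tags.append(BoundaryTag.VESSEL_WALL)
    mesh = Mesh(
        points=pts,
        cells=quads,
        boundary_edges=np.array(edges, dtype=int),
        boundary_tags=np.array([int(t) for t in tags], dtype=int),
        coil_mask=np.zeros(len(quads), dtype=bool),
        h=h,
        geometry=geom,
    )
    mesh.validate()
    return mesh


def _delaunay_mesh(geom: VesselGeometry, h: float, smooth_iters: int = 6) -> Mesh:
    segs = geom.boundary_segments(h)
    bpts = np.vstack([seg[:-1] for _, seg in segs])
    nb = len(bpts)
    poly = Polygon(bpts)
    if not poly.is_valid:
        raise MeshingError("boundary polygon is self-intersecting; refine h")

    # hexagonal interior lattice, kept clear of the boundary
    minx, miny, maxx, maxy = poly.bounds
    dx, dy = h, h * math.sqrt(3.0) / 2.0
    rows = int(math.ceil((maxy - miny) / dy)) + 1
    cols = int(math.ceil((maxx - minx) / dx)) + 2
    jj, ii = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    px = minx + (ii + 0.5 * (jj % 2)) * dx
    py = miny + jj * dy
    cand = np.stack([px.ravel(), py.ravel()], axis=1)
    clear = poly.buffer(-0.72 * h)
    if clear.is_empty:
        interior = np.empty((0, 2))
    else:
        keep = shapely.contains_xy(clear, cand[:, 0], cand[:, 1])
        interior = cand[keep]

    pts = np.vstack([bpts, interior])

    def triangulate(p: np.ndarray) -> np.ndarray:
        tri = Delaunay(p)
        cent = p[tri.simplices].mean(axis=1)
        inside = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        # collinear boundary runs yield zero-area slivers; drop them
        areas = np.abs(
            _tri_areas(
                p[tri.simplices[:, 0]], p[tri.simplices[:, 1]], p[tri.simplices[:, 2]]
            )
        )
        return tri.simplices[inside & (areas > 1e-6 * h * h)]

    cells = triangulate(pts)
    for _ in range(smooth_iters):
        # Laplacian smoothing of interior points over the current topology
        nbr_sum = np.zeros_like(pts)
        nbr_cnt = np.zeros(len(pts))
        for a, b in ((0, 1), (1, 2), (2, 0)):
            np.add.at(nbr_sum, cells[:, a], pts[cells[:, b]])
            np.add.at(nbr_cnt, cells[:, a], 1.0)
            np.add.at(nbr_sum, cells[:, b], pts[cells[:, a]])
            np.add.at(nbr_cnt, cells[:, b], 1.0)
        upd = nbr_sum[nb:] / np.maximum(nbr_cnt[nb:], 1.0)[:, None]
        ok = shapely.contains_xy(clear, upd[:, 0], upd[:, 1])
        pts[nb:][ok] = upd[ok]
        cells = triangulate(pts)

    # drop unused points (lattice points outside can't occur, but be safe)
    used = np.unique(cells)
    if len(used) < len(pts):
        remap = -np.ones(len(pts), dtype=int)
        remap[used] = np.arange(len(used))
        if np.any(remap[:nb] < 0):
            raise MeshingError("a boundary point was not meshed; refine h")
        pts = pts[used]
        cells = remap[cells]

    # enforce positive orientation
    neg = _tri_areas(pts[cells[:, 0]], pts[cells[:, 1]], pts[cells[:, 2]]) < 0.0
    cells[neg] = cells[neg][:, ::-1]

    # boundary edges must be consecutive boundary-point pairs
    edge_count: dict[tuple[int, int], int] = {}
    for a, b in ((0, 1), (1, 2), (2, 0)):
        lo = np.minimum(cells[:, a], cells[:, b])
        hi = np.maximum(cells[:, a], cells[:, b])
        for e in zip(lo.tolist(), hi.tolist()):
            edge_count[e] = edge_count.get(e, 0) + 1
    hull = [e for e, v in edge_count.items() if v == 1]
    expected = {(min(i, (i + 1) % nb), max(i, (i + 1) % nb)) for i in range(nb)}
    if set(hull) != expected:
        raise MeshingError(
            f"triangulated hull does not match the boundary chain "
            f"(h={h:g}, neck={geom.sac_neck_width:g}); refine h"
        )

    # tags by construction order of boundary points
    tag_per_bpt = np.concatenate(
        [np.full(len(seg) - 1, int(tag)) for tag, seg in segs]
    )
    bedges = np.array([(i, (i + 1) % nb) for i in range(nb)], dtype=int)
    btags = tag_per_bpt.copy()  # edge i starts at boundary point i

    cent = pts[cells].mean(axis=1)
    coil = geom.coil_region_mask(cent)
    mesh = Mesh(
        points=pts,
        cells=cells,
        boundary_edges=bedges,
        boundary_tags=btags,
        coil_mask=coil,
        h=h,
        geometry=geom,
    )
    mesh.validate()
    return mesh


def generate_mesh(geom: VesselGeometry, h: float, kind: str = "auto") -> Mesh:
    """Mesh the geometry at characteristic size ``h``.

    ``kind='auto'`` uses a mapped structured quad grid for channels without
    a sac and a smoothed Delaunay triangulation otherwise.
    """
    if h <= 0.0:
        raise MeshingError("h must be positive")
    if h >= geom.parent_width / 4.0:
        raise MeshingError(
            f"h={h:g} too coarse for parent width {geom.parent_width:g} (need h < D/4)"
        )
    if geom.has_sac and h > geom.sac_neck_width / 8.0:
        raise MeshingError(
            f"h={h:g} does not resolve the neck (width {geom.sac_neck_width:g}) "
            f"with >= 8 faces"
        )
    if kind == "auto":
        kind = "quad" if not geom.has_sac else "tri"
    if kind == "quad":
        if geom.has_sac:
            raise MeshingError("structured quad meshing supports sac-free channels only")
        mesh = _structured_channel_mesh(geom, h)
    elif kind == "tri":
        mesh = _delaunay_mesh(geom, h)
    else:
        raise ValueError(f"unknown mesh kind {kind!r}")

    target = geom.total_area
    if abs(mesh.total_area() - target) > 0.01 * target:
        raise MeshingError(
            f"meshed area {mesh.total_area():.6e} deviates >1% from analytic "
            f"area {target:.6e}"
        )
    return mesh


def with_coil_fill(geom: VesselGeometry, f_c: float) -> VesselGeometry:
    """Copy of the geometry with a different coil fill fraction."""
    return replace(geom, coil_fill_fraction=f_c)
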