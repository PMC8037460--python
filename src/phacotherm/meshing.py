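"""Triangular meshing of the anterior-chamber domain.

The chamber is meshed with a force-equilibrium smoothed-Delaunay method
(Persson & Strang's distmesh algorithm) driven by a graded size field:
fine elements at the aqueous inlets, along the trabecular-meshwork (TM)
interface and around the phaco-tip segment, coarser elements in the bulk.
Only the right half (x >= 0) is meshed; the mesh is then reflected about
the pupil axis so the discrete problem is exactly mirror symmetric.  The
two TM blocks are structured micro-grids merged node-exactly onto fixed
interface nodes of the chamber mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, Polygon

from .geometry import DomainGeometry, GeometryError

BULK, POROUS = 0, 1

#: boundary tags used on the anterior-chamber mesh
AC_TAGS = ("lens", "inlet", "pupil_wall", "iris", "cornea",
           "tm_wall", "sc_outlet", "probe")


class MeshingError(RuntimeError):
    pass


@dataclass
class Mesh:
    """P1 triangle mesh with tagged boundary edges and subdomains.

    ``points`` are in mm.  ``boundary_edges`` store (node_a, node_b)
    oriented counter-clockwise as seen from the owning triangle;
    ``boundary_tag[i]`` indexes into ``tag_names``.  ``subdomain`` is 0 for
    bulk fluid and 1 for porous (TM) elements.
    """

    points: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    boundary_tag: np.ndarray
    tag_names: tuple[str, ...]
    subdomain: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.subdomain is None:
            self.subdomain = np.zeros(len(self.triangles), dtype=np.int8)

    # ------------------------------------------------------------------
    @property
    def num_points(self) -> int:
        return len(self.points)

    @property
    def num_triangles(self) -> int:
        return len(self.triangles)

    def tri_areas(self) -> np.ndarray:
        p = self.points
        t = self.triangles
        d1 = p[t[:, 1]] - p[t[:, 0]]
        d2 = p[t[:, 2]] - p[t[:, 0]]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def boundary_area(self) -> float:
        """Domain area from the oriented boundary loop (shoelace)."""
        a = self.points[self.boundary_edges[:, 0]]
        b = self.points[self.boundary_edges[:, 1]]
        return 0.5 * float(np.sum(a[:, 0] * b[:, 1] - b[:, 0] * a[:, 1]))

    def edges_of_tag(self, tag: str) -> np.ndarray:
        code = self.tag_names.index(tag)
        return self.boundary_edges[self.boundary_tag == code]

    def nodes_of_tag(self, tag: str) -> np.ndarray:
        return np.unique(self.edges_of_tag(tag))

    def validate(self) -> None:
        areas = self.tri_areas()
        if np.any(areas <= 0):
            raise MeshingError(f"{int(np.sum(areas <= 0))} non-positive "
                               "triangle areas")
        total = float(areas.sum())
        loop = self.boundary_area()
        if abs(total - loop) > 1e-8 * total:
            raise MeshingError(
                f"element area sum {total} disagrees with boundary loop "
                f"area {loop}")
        if np.any(self.boundary_tag < 0):
            raise MeshingError("untagged boundary edge present")

    def min_quality(self) -> float:
        """Minimum triangle quality 2 r_in / r_circ (1 = equilateral)."""
        p = self.points
        t = self.triangles
        a = np.linalg.norm(p[t[:, 1]] - p[t[:, 0]], axis=1)
        b = np.linalg.norm(p[t[:, 2]] - p[t[:, 1]], axis=1)
        c = np.linalg.norm(p[t[:, 0]] - p[t[:, 2]], axis=1)
        s = (a + b + c) / 2
        with np.errstate(invalid="ignore"):
            q = 8 * (s - a) * (s - b) * (s - c) / (a * b * c + 1e-300)
        return float(np.min(q))


# ----------------------------------------------------------------------
# generic helpers
# ----------------------------------------------------------------------

def _orient_ccw(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    d1 = points[tris[:, 1]] - points[tris[:, 0]]
    d2 = points[tris[:, 2]] - points[tris[:, 0]]
    flip = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0] < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _boundary_edges(tris: np.ndarray) -> np.ndarray:
    """Oriented edges appearing in exactly one triangle (CCW triangles)."""
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(e, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return e[counts[inv] == 1]


def _merge_points(points: np.ndarray, tris: np.ndarray,
                  decimals: int = 9) -> tuple[np.ndarray, np.ndarray]:
    rounded = np.round(points, decimals)
    _, first, inv = np.unique(rounded, axis=0, return_index=True,
                              return_inverse=True)
    # keep original ordering of first occurrences for determinism
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return points[first[order]], rank[inv][tris]


def structured_rect(x_levels, y_levels):
    """Structured triangulation of a rectangle from grid levels."""
    xs = np.asarray(x_levels, float)
    ys = np.asarray(y_levels, float)
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            n00 = i * ny + j
            n10 = (i + 1) * ny + j
            n01 = i * ny + j + 1
            n11 = (i + 1) * ny + j + 1
            if (i + j) % 2 == 0:   # alternate diagonals
                tris += [(n00, n10, n11), (n00, n11, n01)]
            else:
                tris += [(n00, n10, n01), (n10, n11, n01)]
    return pts, np.asarray(tris, dtype=np.int64)


def rectangle_mesh(width: float, height: float, nx: int, ny: int) -> Mesh:
    """Tagged structured mesh of [0,width] x [0,height].

    Boundary tags: ``left``, ``right``, ``bottom``, ``top``.  Used for
    verification problems (1-D conduction strips and the like).
    """
    pts, tris = structured_rect(np.linspace(0, width, nx + 1),
                                np.linspace(0, height, ny + 1))
    tris = _orient_ccw(pts, tris)
    edges = _boundary_edges(tris)
    mids = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
    tag = np.full(len(edges), -1, dtype=np.int32)
    tol = 1e-9 * max(width, height)
    names = ("left", "right", "bottom", "top")
    tag[np.abs(mids[:, 0]) < tol] = 0
    tag[np.abs(mids[:, 0] - width) < tol] = 1
    tag[np.abs(mids[:, 1]) < tol] = 2
    tag[np.abs(mids[:, 1] - height) < tol] = 3
    mesh = Mesh(pts, tris, edges, tag, names)
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------
# distmesh core
# ----------------------------------------------------------------------

def _signed_distance(poly: Polygon, pts: np.ndarray) -> np.ndarray:
    boundary = poly.exterior
    geoms = shapely.points(pts)
    d = shapely.distance(geoms, boundary)
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return np.where(inside, -d, d)


def distmesh(poly: Polygon, h_func, h_min: float, pfix: np.ndarray,
             n_iter: int = 90, seed: int = 20210330) -> tuple[np.ndarray, np.ndarray]:
    """Graded triangulation of a polygon (Persson-Strang iteration).

    ``h_func(pts)`` returns the desired local edge length; ``pfix`` are
    pinned nodes (corners, feature polylines).  Deterministic for fixed
    inputs.  Returns (points, triangles).
    """
    dptol, ttol, fscale, deltat = 0.001, 0.1, 1.2, 0.2
    geps = 1e-3 * h_min
    deps = np.sqrt(np.finfo(float).eps) * h_min

    xmin, ymin, xmax, ymax = poly.bounds
    # hexagonal candidate lattice at the finest spacing
    x = np.arange(xmin, xmax + h_min, h_min)
    y = np.arange(ymin, ymax + h_min * np.sqrt(3) / 2, h_min * np.sqrt(3) / 2)
    X, Y = np.meshgrid(x, y)
    X[1::2] += h_min / 2
    p = np.column_stack([X.ravel(), Y.ravel()])
    p = p[_signed_distance(poly, p) < geps]
    # density-matched rejection (deterministic rng)
    r0 = 1.0 / h_func(p) ** 2
    rng = np.random.default_rng(seed)
    p = p[rng.random(len(p)) < r0 / r0.max()]

    pfix = np.unique(np.round(np.asarray(pfix, float), 12), axis=0)
    if len(pfix):
        keep = cKDTree(pfix).query(p, k=1)[0] > 0.8 * h_func(p)
        p = p[keep]
        p = np.vstack([pfix, p])
    nfix = len(pfix)

    pold = np.full_like(p, np.inf)
    tris = bars = None
    for _ in range(n_iter):
        if np.max(np.linalg.norm(p - pold, axis=1)) > ttol * h_min:
            pold = p.copy()
            tri = Delaunay(p)
            cent = p[tri.simplices].mean(axis=1)
            tris = tri.simplices[_signed_distance(poly, cent) < -geps]
            bars = np.unique(
                np.sort(np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]],
                                        tris[:, [2, 0]]]), axis=1), axis=0)
        vec = p[bars[:, 0]] - p[bars[:, 1]]
        L = np.linalg.norm(vec, axis=1)
        mid = 0.5 * (p[bars[:, 0]] + p[bars[:, 1]])
        hbars = h_func(mid)
        L0 = hbars * fscale * np.sqrt(np.sum(L**2) / np.sum(hbars**2))
        F = np.maximum(L0 - L, 0)
        Fvec = vec * (F / np.maximum(L, 1e-300))[:, None]
        Ftot = np.zeros_like(p)
        np.add.at(Ftot, bars[:, 0], Fvec)
        np.add.at(Ftot, bars[:, 1], -Fvec)
        Ftot[:nfix] = 0
        p = p + deltat * Ftot
        # project escaped points back onto the boundary
        d = _signed_distance(poly, p)
        out = d > 0
        if np.any(out):
            dx = (_signed_distance(poly, p[out] + [deps, 0]) - d[out]) / deps
            dy = (_signed_distance(poly, p[out] + [0, deps]) - d[out]) / deps
            grad = np.column_stack([dx, dy])
            norm2 = np.maximum(np.sum(grad**2, axis=1), 1e-300)
            p[out] -= grad * (d[out] / norm2)[:, None]
        interior = d < -geps
        if len(p[interior]):
            move = np.max(np.linalg.norm(deltat * Ftot[interior], axis=1)
                          / h_func(p[interior]))
            if move < dptol:
                break

    # exact projection of near-boundary nodes onto the outline polyline
    line = LineString(poly.exterior.coords)
    d = _signed_distance(poly, p)
    hloc = h_func(p)
    near = d > -0.12 * hloc
    near[:nfix] = False
    for i in np.where(near)[0]:
        q = line.interpolate(line.project(shapely.Point(p[i])))
        p[i] = (q.x, q.y)
    p[np.abs(p[:, 0]) < 1e-7, 0] = 0.0    # snap to the symmetry axis

    tri = Delaunay(p)
    cent = p[tri.simplices].mean(axis=1)
    tris = tri.simplices[_signed_distance(poly, cent) < -geps]
    used = np.unique(tris)
    remap = -np.ones(len(p), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return p[used], remap[tris]


# ----------------------------------------------------------------------
# anterior-chamber mesh
# ----------------------------------------------------------------------

def _tm_y_levels(geom: DomainGeometry) -> np.ndarray:
    """TM grid levels along the rim, conforming to the SC outlet ends."""
    y0, y1 = geom.iris_top, geom.rim_top
    s0, s1 = geom.sc_interval
    n_lo = max(2, int(round((s0 - y0) / 0.021)))
    n_mid = max(2, int(round((s1 - s0) / 0.021)))
    n_hi = max(2, int(round((y1 - s1) / 0.021)))
    return np.unique(np.concatenate([
        np.linspace(y0, s0, n_lo + 1),
        np.linspace(s0, s1, n_mid + 1),
        np.linspace(s1, y1, n_hi + 1),
    ]))


def _size_field(geom: DomainGeometry, h_bulk: float):
    """Graded size function: fine at inlets, the TM interface and the
    probe surface (including the narrow lens gap under the tip)."""
    pw = geom.pupil_half
    hx = geom.half_length
    cx, cy = geom.probe_center
    r = geom.probe_radius
    il = geom.params.inlet_length_mm

    def h(pts):
        pts = np.atleast_2d(pts)
        x, y = np.abs(pts[:, 0]), pts[:, 1]
        d_inlet = np.hypot(np.maximum(np.abs(x - (pw - il / 2)) - il / 2, 0), y)
        d_tm = np.hypot(np.abs(x - hx),
                        np.maximum(geom.iris_top - y, 0)
                        + np.maximum(y - geom.rim_top, 0))
        if geom.params.probe_obstacle:
            d_probe = np.abs(np.hypot(x - cx, y - cy) - r)
        else:  # refine around the immersed tip segment instead
            d_probe = np.hypot(np.maximum(x - r, 0),
                               np.abs(y - (cy - r)))
        val = np.minimum.reduce([
            np.full(len(pts), h_bulk),
            0.011 + 0.30 * d_inlet,
            0.020 + 0.30 * d_tm,
            0.055 + 0.30 * d_probe,
        ])
        return val

    return h


def _fixed_points(geom: DomainGeometry, h_func) -> np.ndarray:
    """Pinned nodes: corners, inlet, TM levels, probe circle, axis."""
    pw, hx = geom.pupil_half, geom.half_length
    it = geom.iris_top
    il = geom.params.inlet_length_mm
    pts = [(0.0, 0.0), (pw, 0.0), (pw, it), (hx, it), (0.0, geom.apex_y)]
    pts += [(pw - il, 0.0), (pw - il / 2, 0.0)]               # inlet
    pts += [(hx, yy) for yy in _tm_y_levels(geom)]            # TM interface
    cx, cy = geom.probe_center
    r = geom.probe_radius
    if geom.params.probe_obstacle:
        # probe half-circle, marched at the local size; axis ends exact
        h_pr = float(h_func(np.array([[cx + r, cy]]))[0])
        n_pr = max(8, int(round(np.pi * r / h_pr)))
        th = np.linspace(-np.pi / 2, np.pi / 2, n_pr + 1)
        ring = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        ring[0] = (cx, cy - r)
        ring[-1] = (cx, cy + r)
        pts += [tuple(q) for q in ring]
    else:
        # nodes along the immersed tip segment so the line source is exact
        x0, x1, ty = geom.tip_segment
        h_tip = float(h_func(np.array([[x1 / 2, ty]]))[0])
        n_tip = max(4, int(round(x1 / h_tip)))
        pts += [(xx, ty) for xx in np.linspace(0, x1, n_tip + 1)]
    # symmetry axis, marched at the local size, skipping the probe body
    yy = 0.0
    while yy < geom.apex_y - 0.05:
        yy += float(h_func(np.array([[0.0, yy]]))[0])
        if geom.params.probe_obstacle and cy - r - 0.03 < yy < cy + r + 0.03:
            continue
        if yy < geom.apex_y - 0.05:
            pts.append((0.0, yy))
    return np.asarray(pts, float)


def _tag_ac_boundary(geom: DomainGeometry, points: np.ndarray,
                     edges: np.ndarray) -> np.ndarray:
    mids = 0.5 * (points[edges[:, 0]] + points[edges[:, 1]])
    x, y = np.abs(mids[:, 0]), mids[:, 1]
    pw, hx = geom.pupil_half, geom.half_length
    it, rt = geom.iris_top, geom.rim_top
    tml = geom.params.tm_length_mm
    il = geom.params.inlet_length_mm
    s0, s1 = geom.sc_interval
    tol = 1e-6
    tag = np.full(len(edges), -1, dtype=np.int32)

    on_floor = (np.abs(y) < tol) & (x <= pw + tol)
    tag[on_floor & (x >= pw - il - tol)] = AC_TAGS.index("inlet")
    tag[on_floor & (x < pw - il - tol)] = AC_TAGS.index("lens")
    tag[(np.abs(x - pw) < tol) & (y > -tol) & (y < it + tol)] = \
        AC_TAGS.index("pupil_wall")
    tag[(np.abs(y - it) < tol) & (x > pw + tol) & (x < hx - tol)] = \
        AC_TAGS.index("iris")
    r = np.hypot(mids[:, 0], y - geom.arc_center_y)
    elen = np.linalg.norm(points[edges[:, 1]] - points[edges[:, 0]], axis=1)
    arc_tol = elen**2 / (4 * geom.arc_radius) + 1e-6  # chord sagitta bound
    tag[(np.abs(r - geom.arc_radius) < arc_tol) & (x < hx - tol)
        & (y > rt - tol)] = AC_TAGS.index("cornea")
    on_tm_face = np.abs(x - (hx + tml)) < tol
    tag[on_tm_face & (y > s0 - tol) & (y < s1 + tol)] = AC_TAGS.index("sc_outlet")
    tag[on_tm_face & ((y <= s0 - tol) | (y >= s1 + tol))] = AC_TAGS.index("tm_wall")
    horiz_tm = (x >= hx - tol) & (x <= hx + tml + tol) & \
               ((np.abs(y - it) < tol) | (np.abs(y - rt) < tol))
    tag[horiz_tm] = AC_TAGS.index("tm_wall")
    if geom.params.probe_obstacle:
        cx, cy = geom.probe_center
        rp = np.hypot(mids[:, 0] - cx, y - cy)
        probe_tol = elen**2 / (4 * geom.probe_radius) + 1e-6
        tag[np.abs(rp - geom.probe_radius) < probe_tol] = \
            AC_TAGS.index("probe")
    return tag


def generate_mesh(geom: DomainGeometry, target_elements: int = 4981) -> Mesh:
    """Mesh the anterior chamber with roughly ``target_elements`` triangles.

    The bulk size is calibrated against the target count; the porous TM
    blocks are structured micro-grids, and the whole mesh is exactly
    mirror symmetric about the pupil axis.
    """
    if target_elements < 100:
        raise MeshingError("target_elements must be at least 100")

    poly_half = geom.chamber_polygon_half()
    area_full = 2 * poly_half.area

    def count_estimate(h_bulk: float) -> float:
        h = _size_field(geom, h_bulk)
        # Monte-Carlo-free density integral on a grid
        xmin, ymin, xmax, ymax = poly_half.bounds
        gx = np.linspace(xmin, xmax, 220)
        gy = np.linspace(ymin, ymax, 160)
        X, Y = np.meshgrid(gx, gy)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        inside = shapely.contains_xy(poly_half, pts[:, 0], pts[:, 1])
        cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
        dens = 1.0 / (np.sqrt(3) / 4 * h(pts[inside]) ** 2)
        return 2 * float(np.sum(dens) * cell)

    # bisection on the bulk size to hit the target count
    lo, hi = 0.02, 1.0
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        if count_estimate(mid) > target_elements:
            lo = mid
        else:
            hi = mid
    h_bulk = np.sqrt(lo * hi)

    h = _size_field(geom, h_bulk)
    pfix = _fixed_points(geom, h)
    h_min = 0.011
    pts_h, tris_h = distmesh(poly_half, h, h_min, pfix)

    # reflect about the pupil axis
    pts_m = pts_h.copy()
    pts_m[:, 0] *= -1
    tris_m = tris_h[:, [0, 2, 1]] + len(pts_h)
    points = np.vstack([pts_h, pts_m])
    tris = np.vstack([tris_h, tris_m])

    # structured TM blocks
    y_levels = _tm_y_levels(geom)
    for (x0, x1, _, _) in geom.tm_rects:
        n_across = max(3, int(round((x1 - x0) / 0.021)))
        bp, bt = structured_rect(np.linspace(x0, x1, n_across + 1), y_levels)
        tris = np.vstack([tris, bt + len(points)])
        points = np.vstack([points, bp])

    points, tris = _merge_points(points, tris)
    tris = _orient_ccw(points, tris)
    d1 = points[tris[:, 1]] - points[tris[:, 0]]
    d2 = points[tris[:, 2]] - points[tris[:, 0]]
    areas = 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    keep = areas > 1e-12
    tris = tris[keep]

    edges = _boundary_edges(tris)
    tag = _tag_ac_boundary(geom, points, edges)
    if np.any(tag < 0):
        bad = 0.5 * (points[edges[tag < 0][:, 0]] + points[edges[tag < 0][:, 1]])
        raise MeshingError(
            f"{int(np.sum(tag < 0))} untagged boundary edges near "
            f"{bad[:5].tolist()}; geometry: {geom.params}")

    # porous subdomain from the TM rectangles
    cent = points[tris].mean(axis=1)
    sub = np.zeros(len(tris), dtype=np.int8)
    for (x0, x1, y0, y1) in geom.tm_rects:
        inside = ((cent[:, 0] > x0 - 1e-9) & (cent[:, 0] < x1 + 1e-9)
                  & (cent[:, 1] > y0 - 1e-9) & (cent[:, 1] < y1 + 1e-9))
        sub[inside] = POROUS

    mesh = Mesh(points, tris, edges, tag, AC_TAGS, sub)
    mesh.validate()

    n = mesh.num_triangles
    if not 0.70 * target_elements <= n <= 1.35 * target_elements:
        raise MeshingError(
            f"mesh has {n} elements, outside +-30% of target "
            f"{target_elements} (domain area {area_full:.3f} mm^2)")
    return mesh
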