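"""Point sampling and summary extraction from field time series.

Temperatures are in deg C; reported speeds are in mm/s (the scale of
aqueous-humor convection).  Sampling uses exact barycentric interpolation
on the P1 mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.tri import Triangulation

from .geometry import GeometryError
from .meshing import Mesh
from .solver import FieldState, FieldTimeSeries


class PointInterpolator:
    """Barycentric P1 interpolation at a fixed set of points (mm)."""

    def __init__(self, mesh: Mesh, points):
        pts = np.atleast_2d(np.asarray(points, float))
        tri = Triangulation(mesh.points[:, 0], mesh.points[:, 1],
                            mesh.triangles)
        finder = tri.get_trifinder()
        elems = finder(pts[:, 0], pts[:, 1])
        if np.any(elems < 0):
            bad = pts[elems < 0]
            raise GeometryError(f"points outside the domain: {bad.tolist()}")
        t = mesh.triangles[elems]
        a = mesh.points[t[:, 0]]
        b = mesh.points[t[:, 1]]
        c = mesh.points[t[:, 2]]
        det = ((b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0])
               + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1]))
        l1 = ((b[:, 1] - c[:, 1]) * (pts[:, 0] - c[:, 0])
              + (c[:, 0] - b[:, 0]) * (pts[:, 1] - c[:, 1])) / det
        l2 = ((c[:, 1] - a[:, 1]) * (pts[:, 0] - c[:, 0])
              + (a[:, 0] - c[:, 0]) * (pts[:, 1] - c[:, 1])) / det
        self.nodes = t
        self.weights = np.column_stack([l1, l2, 1.0 - l1 - l2])

    def __call__(self, field: np.ndarray) -> np.ndarray:
        return np.sum(field[self.nodes] * self.weights, axis=1)


@dataclass
class ProbeTrace:
    """A sampled time series at one probe point."""

    name: str
    times: np.ndarray
    values: np.ndarray
    reference: float      # initial steady value

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def sample_point(series: FieldTimeSeries, point,
                 name: str = "probe") -> ProbeTrace:
    """Temperature trace at a point, one sample per stored step."""
    interp = PointInterpolator(series.mesh, [point])
    vals = np.array([interp(T)[0] for T in series.T])
    ref = float(interp(series.reference.T)[0])
    return ProbeTrace(name, series.times, vals, ref)


def trace_extrema(trace: ProbeTrace) -> tuple[float, float, float]:
    """(time of maximum, maximum value, maximum rise above reference)."""
    if len(trace.values) == 0:
        raise ValueError("empty trace")
    i = int(np.argmax(trace.values))
    vmax = float(trace.values[i])
    return float(trace.times[i]), vmax, vmax - trace.reference


def relaxation_time(series: FieldTimeSeries, reference: FieldState,
                    tol_T: float = 0.5, tol_u: float = 0.05) -> float:
    """Time after the impulse end at which the fields have returned to,
    and stay within, the steady baseline.

    The criterion is field-wide: max nodal |T - T_ref| < ``tol_T`` (deg C)
    and max nodal velocity deviation < ``tol_u`` relative to the baseline
    peak speed.  Returns ``inf`` when the stored horizon never satisfies
    it ("not relaxed").
    """
    if reference.T.shape != series.T.shape[1:]:
        raise ValueError("reference state is on a different mesh")
    t_imp = series.source.duration if series.source is not None else 0.0
    dT = np.max(np.abs(series.T - reference.T[None, :]), axis=1)
    du = np.max(np.linalg.norm(series.u - reference.u[None], axis=2), axis=1)
    u_scale = max(float(np.max(np.hypot(reference.u[:, 0],
                                        reference.u[:, 1]))), 1e-12)
    ok = (dT < tol_T) & (du / u_scale < tol_u) & (series.times >= t_imp)
    # first index from which the criterion holds for the rest of the run
    holds = np.flip(np.logical_and.accumulate(np.flip(ok)))
    idx = np.where(holds)[0]
    if not len(idx):
        return float("inf")
    return float(series.times[idx[0]] - t_imp)


def _interior_mask(mesh: Mesh, exclude_tags=("inlet", "sc_outlet"),
                   rings: int = 2) -> np.ndarray:
    """Interior nodes, minus a ``rings``-element band around in/outlets."""
    mask = np.ones(mesh.num_points, bool)
    mask[np.unique(mesh.boundary_edges)] = False
    seed = np.concatenate([mesh.nodes_of_tag(t) for t in exclude_tags
                           if t in mesh.tag_names] or [np.empty(0, int)])
    banned = np.zeros(mesh.num_points, bool)
    banned[seed.astype(int)] = True
    tris = mesh.triangles
    for _ in range(rings):
        hit = banned[tris].any(axis=1)
        banned[np.unique(tris[hit])] = True
    mask &= ~banned
    return mask


def velocity_range(series: FieldTimeSeries, window: tuple[float, float],
                   rings: int = 2) -> tuple[float, float]:
    """(min, max) interior speed [mm/s] over nodes and the time window.

    Nodes within ``rings`` elements of the inlets/outlet are excluded:
    speeds there reflect the mesh resolution of near-singular corners,
    not the chamber flow.
    """
    t0, t1 = window
    sel = (series.times >= t0 - 1e-12) & (series.times <= t1 + 1e-12)
    if not np.any(sel):
        raise ValueError(f"empty time window {window}")
    mask = _interior_mask(series.mesh, rings=rings)
    speeds = np.linalg.norm(series.u[sel][:, mask, :], axis=2) * 1e3
    return float(speeds.min()), float(speeds.max())
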