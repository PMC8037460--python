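"""Planar anterior-chamber geometry.

The computational domain is a 2-D cross-section of the anterior chamber (AC):
a circular corneal arc roofing a flat floor made of the lens plane (spanning
the pupil) and the iris annulus, with a porous trabecular-meshwork (TM) block
and a Schlemm's-canal (SC) outlet at each lateral rim.  Aqueous humor enters
through two short inlet segments at the pupil margin and leaves through the
SC after crossing the TM.

Coordinates are millimetres throughout, ``x`` across the chamber (the pupil
axis is ``x = 0``), ``y`` from the lens plane toward the cornea.  The outline
is mirror symmetric about the pupil axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Raised for invalid geometric parameters or out-of-domain points."""


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the anterior-chamber cross-section.

    Lengths are in mm except the fine outflow-pathway features
    (``tm_length``, ``tm_width``, ``sc_length``, ``inlet_length``), which are
    in µm.  Defaults are the dimensions of the modelled adult eye.
    """

    ac_length: float = 10.0          # corneal chord [mm]
    ac_depth: float = 3.2            # sagittal depth of the corneal arc [mm]
    pupil_length: float = 2.98       # pupil gap in the iris [mm]
    iris_thickness: float = 0.45     # iris slab thickness [mm]
    tm_length: float = 85.0          # TM flow-path length [µm]
    tm_width: float = 300.0          # TM extent along the rim [µm]
    sc_length: float = 163.0         # Schlemm's-canal outlet length [µm]
    inlet_length: float = 20.0       # each pupil inlet segment [µm]
    probe_tip_diameter: float = 2.2  # phaco tip footprint [mm]
    probe_offset_above_lens: float = 0.25   # tip height over the lens [mm]
    point_probe_depth_below_cornea: float = 0.6  # probe depth from apex [mm]
    #: model the phaco tip as a solid disk obstacle with the impulse flux
    #: on its lens-facing underside; False leaves the chamber unobstructed
    #: and deposits the impulse on an immersed line segment at the tip
    #: position
    probe_obstacle: bool = True
    arc_resolution: int = 256        # outline points per corneal half-arc

    def __post_init__(self) -> None:
        for name in (
            "ac_length", "ac_depth", "pupil_length", "iris_thickness",
            "tm_length", "tm_width", "sc_length", "inlet_length",
            "probe_tip_diameter", "probe_offset_above_lens",
            "point_probe_depth_below_cornea",
        ):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be strictly positive")
        if not self.pupil_length < self.ac_length:
            raise GeometryError("pupil_length must be smaller than ac_length")
        if not self.probe_offset_above_lens < self.ac_depth:
            raise GeometryError(
                "probe_offset_above_lens must be smaller than ac_depth")
        if not self.probe_tip_diameter < self.pupil_length:
            raise GeometryError(
                "probe_tip_diameter must fit inside pupil_length")
        if not self.sc_length < self.tm_width:
            raise GeometryError("sc_length must be smaller than tm_width")
        if not self.inlet_length * 1e-3 < self.pupil_length / 2:
            raise GeometryError("inlet_length must fit inside the pupil gap")

    # µm fields in mm
    @property
    def tm_length_mm(self) -> float:
        return self.tm_length * 1e-3

    @property
    def tm_width_mm(self) -> float:
        return self.tm_width * 1e-3

    @property
    def sc_length_mm(self) -> float:
        return self.sc_length * 1e-3

    @property
    def inlet_length_mm(self) -> float:
        return self.inlet_length * 1e-3


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed polygon area by the shoelace formula (positive if CCW)."""
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class DomainGeometry:
    """Closed anterior-chamber outline with tagged features.

    ``outline`` is the CCW boundary polyline of the full fluid domain
    (chamber plus the two TM blocks).  Feature segments (inlets, SC outlet,
    probe tip line) and named probe points are stored for meshing, boundary
    tagging and post-processing.
    """

    params: GeometryParams
    outline: np.ndarray = field(repr=False)
    # derived landmarks (all mm)
    half_length: float = 0.0
    pupil_half: float = 0.0
    iris_top: float = 0.0
    rim_top: float = 0.0
    apex_y: float = 0.0
    arc_radius: float = 0.0
    arc_center_y: float = 0.0

    # ------------------------------------------------------------------
    @property
    def probe_center(self) -> tuple[float, float]:
        """Centre of the phaco-tip cross-section (a disk resting
        ``probe_offset_above_lens`` above the lens plane)."""
        p = self.params
        return (0.0, p.probe_offset_above_lens + p.probe_tip_diameter / 2)

    @property
    def probe_radius(self) -> float:
        return self.params.probe_tip_diameter / 2

    def probe_ring(self, n: int | None = None) -> np.ndarray:
        """CCW polyline of the probe-tip circle."""
        n = n or self.params.arc_resolution
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        cx, cy = self.probe_center
        return np.column_stack([cx + self.probe_radius * np.cos(th),
                                cy + self.probe_radius * np.sin(th)])

    @property
    def tm_rects(self) -> list[tuple[float, float, float, float]]:
        """(xmin, xmax, ymin, ymax) of the two porous TM blocks."""
        p = self.params
        x0, x1 = self.half_length, self.half_length + p.tm_length_mm
        y0, y1 = self.iris_top, self.rim_top
        return [(x0, x1, y0, y1), (-x1, -x0, y0, y1)]

    @property
    def sc_interval(self) -> tuple[float, float]:
        """y-interval of the SC outlet on the TM outer face."""
        p = self.params
        mid = 0.5 * (self.iris_top + self.rim_top)
        return (mid - p.sc_length_mm / 2, mid + p.sc_length_mm / 2)

    @property
    def inlet_intervals(self) -> list[tuple[float, float]]:
        """x-intervals of the two inlet segments on the lens plane."""
        p = self.params
        return [(self.pupil_half - p.inlet_length_mm, self.pupil_half),
                (-self.pupil_half, -self.pupil_half + p.inlet_length_mm)]

    @property
    def tip_segment(self) -> tuple[float, float, float]:
        """(x0, x1, y) of the immersed phaco-tip heating segment."""
        p = self.params
        half = p.probe_tip_diameter / 2
        return (-half, half, p.probe_offset_above_lens)

    def arc_y(self, x):
        """Height of the corneal arc above the lens plane at abscissa x."""
        return self.arc_center_y + np.sqrt(self.arc_radius**2
                                           - np.asarray(x, float) ** 2)

    # ------------------------------------------------------------------
    @property
    def area(self) -> float:
        """Fluid area: shoelace outline minus the probe disk [mm^2]."""
        if not self.params.probe_obstacle:
            return shoelace_area(self.outline)
        return shoelace_area(self.outline) - shoelace_area(self.probe_ring())

    def polygon(self) -> Polygon:
        """The fluid domain (probe hole excluded) as a shapely polygon."""
        if not self.params.probe_obstacle:
            return Polygon(self.outline)
        return Polygon(self.outline, holes=[self.probe_ring()[::-1]])

    def chamber_polygon_half(self) -> Polygon:
        """Right half (x >= 0) of the chamber without the TM block.

        The probe-tip disk is subtracted, so its half-circle becomes part
        of the (exterior) boundary of the half domain.
        """
        half = self._chamber_half_shell()
        if not self.params.probe_obstacle:
            return half
        cx, cy = self.probe_center
        r = self.probe_radius
        th = np.linspace(-np.pi / 2, np.pi / 2, self.params.arc_resolution)
        arc = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        arc[0] = (cx, cy - r)     # pin the axis endpoints exactly
        arc[-1] = (cx, cy + r)
        half_disk = Polygon([(cx - 1e-6, cy - r)] + arc.tolist()
                            + [(cx - 1e-6, cy + r)])
        return half.difference(half_disk)

    def _chamber_half_shell(self) -> Polygon:
        """Right half of the chamber outline, ignoring the probe."""
        p = self.params
        n = p.arc_resolution
        xs = np.cos(np.linspace(0, np.pi / 2, n + 1)) * self.half_length
        arc = np.column_stack([xs, self.arc_y(xs)])
        verts = [
            (0.0, 0.0),
            (self.pupil_half, 0.0),
            (self.pupil_half, self.iris_top),
            (self.half_length, self.iris_top),
        ]
        verts.extend(arc.tolist())  # (half_length, rim_top) ... (0, apex)
        return Polygon(verts)

    def contains(self, x: float, y: float) -> bool:
        return bool(shapely.contains_xy(self.polygon(), x, y))

    def mirrored(self) -> "DomainGeometry":
        """Geometry reflected about the pupil axis (x -> -x)."""
        out = self.outline.copy()[::-1]
        out[:, 0] *= -1
        return replace(self, outline=out)


def build_ac_geometry(params: GeometryParams | None = None) -> DomainGeometry:
    """Assemble the anterior-chamber outline from its dimensions.

    The corneal arc is the circular arc through the two rim points with
    sagittal height ``ac_depth``.  The floor is a flat lens plane at y = 0
    across the pupil, a vertical pupil-margin wall of height
    ``iris_thickness``, and a flat iris top; the lateral rim wall of height
    ``tm_width`` is the chamber/TM interface, with the TM block outboard of
    it and the SC outlet centred on the block's outer face.
    """
    p = params or GeometryParams()
    hx = p.ac_length / 2
    pw = p.pupil_length / 2
    it = p.iris_thickness
    rim_top = it + p.tm_width_mm
    sag = p.ac_depth
    radius = (hx**2 + sag**2) / (2 * sag)
    arc_cy = rim_top + sag - radius
    apex_y = rim_top + sag

    n = p.arc_resolution
    # full corneal arc, right rim -> apex -> left rim
    theta_rim = np.arctan2(rim_top - arc_cy, hx)
    theta = np.linspace(theta_rim, np.pi - theta_rim, 2 * n + 1)
    arc = np.column_stack([radius * np.cos(theta), arc_cy + radius * np.sin(theta)])
    arc[0] = (hx, rim_top)      # pin endpoints exactly
    arc[-1] = (-hx, rim_top)
    arc[n] = (0.0, apex_y)

    tml = p.tm_length_mm
    verts: list[tuple[float, float]] = [
        (-pw, 0.0), (pw, 0.0),              # lens plane (inlets at its ends)
        (pw, it),                           # right pupil wall
        (hx, it),                           # right iris top
        (hx + tml, it), (hx + tml, rim_top), (hx, rim_top),  # right TM block
    ]
    verts.extend(map(tuple, arc[1:-1]))     # corneal arc (skip shared rims)
    verts.extend([
        (-hx, rim_top), (-hx - tml, rim_top), (-hx - tml, it), (-hx, it),
        (-pw, it),                          # left iris top + pupil wall
    ])
    outline = np.asarray(verts, float)

    geom = DomainGeometry(
        params=p, outline=outline,
        half_length=hx, pupil_half=pw, iris_top=it, rim_top=rim_top,
        apex_y=apex_y, arc_radius=radius, arc_center_y=arc_cy,
    )
    poly = geom.polygon()
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError("outline is self-intersecting")
    return geom


def locate_probes(geom: DomainGeometry,
                  corneal_offset: float = 0.1) -> dict[str, tuple[float, float]]:
    """Named sampling points for post-processing.

    * ``endothelium_center`` — ``point_probe_depth_below_cornea`` below the
      corneal apex on the symmetry axis (the headline point probe).
    * ``probe_tip_center`` — midpoint of the heated gap between the
      phaco-tip underside and the lens.
    * ``corneal_wall_interior`` — interior point ``corneal_offset`` mm below
      the apex, just off the fixed-temperature corneal wall.
    """
    p = geom.params
    if p.point_probe_depth_below_cornea > p.ac_depth:
        raise GeometryError(
            "point_probe_depth_below_cornea exceeds ac_depth: probe would "
            "leave the chamber")
    probes = {
        "endothelium_center": (0.0, geom.apex_y - p.point_probe_depth_below_cornea),
        "probe_tip_center": (0.0, p.probe_offset_above_lens / 2
                             if p.probe_obstacle
                             else p.probe_offset_above_lens),
        "corneal_wall_interior": (0.0, geom.apex_y - corneal_offset),
    }
    for name, (x, y) in probes.items():
        if not geom.contains(x, y):
            raise GeometryError(f"probe {name!r} at ({x}, {y}) is outside "
                                "the domain")
    return probes
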