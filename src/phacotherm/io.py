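"""Plain-text exporters: legacy VTK, Gmsh v2.2 ASCII, trace CSV, YAML config."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .geometry import GeometryParams
from .meshing import Mesh
from .solver import BoundaryConditions, SolverConfig


def write_vtk(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid (triangles)."""
    path = Path(path)
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\nphacotherm mesh\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.num_points} double\n")
        for x, y in mesh.points:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        m = mesh.num_triangles
        f.write(f"CELLS {m} {4 * m}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("5\n" * m)
        if point_data:
            f.write(f"POINT_DATA {mesh.num_points}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    f.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
                else:
                    f.write(f"VECTORS {name} double\n")
                    for row in arr:
                        f.write(f"{row[0]:.9g} {row[1]:.9g} 0\n")
        cd = dict(cell_data or {})
        cd.setdefault("subdomain", mesh.subdomain)
        f.write(f"CELL_DATA {m}\n")
        for name, arr in cd.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(f"{float(v):.9g}" for v in np.asarray(arr))
                    + "\n")


def write_msh(mesh: Mesh, path) -> None:
    """Gmsh MSH 2.2 ASCII with boundary tags as physical line groups."""
    path = Path(path)
    with path.open("w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n")
        names = list(mesh.tag_names) + ["bulk", "porous"]
        f.write(f"{len(names)}\n")
        for i, nm in enumerate(mesh.tag_names):
            f.write(f'1 {i + 1} "{nm}"\n')
        f.write(f'2 {len(mesh.tag_names) + 1} "bulk"\n')
        f.write(f'2 {len(mesh.tag_names) + 2} "porous"\n')
        f.write("$EndPhysicalNames\n$Nodes\n")
        f.write(f"{mesh.num_points}\n")
        for i, (x, y) in enumerate(mesh.points, 1):
            f.write(f"{i} {x:.9g} {y:.9g} 0\n")
        f.write("$EndNodes\n$Elements\n")
        ne = len(mesh.boundary_edges) + mesh.num_triangles
        f.write(f"{ne}\n")
        eid = 1
        for (a, b), tag in zip(mesh.boundary_edges, mesh.boundary_tag):
            f.write(f"{eid} 1 2 {tag + 1} {tag + 1} {a + 1} {b + 1}\n")
            eid += 1
        off = len(mesh.tag_names)
        for t, sd in zip(mesh.triangles, mesh.subdomain):
            phys = off + 1 + int(sd)
            f.write(f"{eid} 2 2 {phys} {phys} "
                    f"{t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
            eid += 1
        f.write("$EndElements\n")


def write_trace_csv(trace, path) -> None:
    with Path(path).open("w") as f:
        f.write("time_s,value,reference\n")
        for t, v in zip(trace.times, trace.values):
            f.write(f"{t:.6g},{v:.9g},{trace.reference:.9g}\n")


def write_summary_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=float) + "\n")


def load_config(path) -> dict:
    """Parse a YAML run file into typed config objects.

    Recognized blocks: ``geometry`` (GeometryParams fields), ``bc``
    (BoundaryConditions fields), ``solver`` (SolverConfig fields),
    ``fluid`` (preset name), ``power`` (W).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {
        "geometry": GeometryParams(**raw.get("geometry", {})),
        "bc": BoundaryConditions(**raw.get("bc", {})),
        "solver": SolverConfig(**raw.get("solver", {})),
    }
    for key in ("fluid", "power", "target_elements"):
        if key in raw:
            out[key] = raw[key]
    return out
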