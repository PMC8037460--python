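"""Shared fixtures: one coarse anterior-chamber mesh and steady baseline
per session, so solver tests don't re-mesh and re-converge repeatedly."""

import numpy as np
import pytest

import phacotherm as pt


@pytest.fixture(scope="session")
def geom():
    return pt.build_ac_geometry()


@pytest.fixture(scope="session")
def coarse_mesh(geom):
    """~1200-element mesh: resolves the TM, inlets and probe surface."""
    return pt.generate_mesh(geom, 1200)


@pytest.fixture(scope="session")
def probe_points(geom):
    return pt.locate_probes(geom)


@pytest.fixture(scope="session")
def ah_solver(coarse_mesh):
    return pt.ThermoFlowSolver(coarse_mesh, pt.get_fluid("AH"))


@pytest.fixture(scope="session")
def ah_steady(ah_solver):
    return ah_solver.solve_steady_state()


def mirror_index(mesh):
    """node index permutation mapping (x, y) -> (-x, y)."""
    pts = np.round(mesh.points, 9)
    lookup = {(x, y): i for i, (x, y) in enumerate(map(tuple, pts))}
    return np.array([lookup[(-x, y)] for x, y in map(tuple, pts)])
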