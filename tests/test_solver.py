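"""Thermo-fluid solver: closed-form checks, conservation, invariants."""

import numpy as np
import pytest

import phacotherm as pt
from phacotherm.meshing import rectangle_mesh
from phacotherm.solver import (ProblemSetup, ThermoFlowSolver,
                               apply_heat_flux_bc, boussinesq_body_force,
                               energy_balance, mass_balance)

from conftest import mirror_index


# ----------------------------------------------------------------------
# pointwise operations
# ----------------------------------------------------------------------

def test_boussinesq_force_arithmetic():
    fl = pt.get_fluid("AH")
    T = np.array([35.5])          # 1 K below reference
    F = boussinesq_body_force(T, fl, t_ref=36.5, g=9.81, g_dir=(0, -1))
    assert np.linalg.norm(F[0]) == pytest.approx(998 * 3e-4 * 9.81, rel=1e-12)
    assert np.linalg.norm(F[0]) == pytest.approx(2.937, abs=2e-3)


def test_boussinesq_zero_and_antisymmetry():
    fl = pt.get_fluid("AH")
    assert np.allclose(boussinesq_body_force(np.full(5, 36.5), fl, 36.5), 0.0)
    up = boussinesq_body_force(np.array([40.0]), fl, 36.5)
    dn = boussinesq_body_force(np.array([33.0]), fl, 36.5)
    assert np.allclose(up, -dn)


def test_heat_flux_bc_values():
    src = pt.HeatSourceSpec(1.2)
    assert apply_heat_flux_bc(src, 2.0) == pytest.approx(
        1.2 / (2.2e-3 * 2.2e-3), rel=1e-12)   # ~2.479e5 W/m^2
    assert apply_heat_flux_bc(src, 6.0) == 0.0
    assert apply_heat_flux_bc(pt.HeatSourceSpec(0.0), 1.0) == 0.0
    with pytest.raises(ValueError):
        pt.HeatSourceSpec(-1.0)
    with pytest.raises(ValueError):
        apply_heat_flux_bc(src, -0.5)


def test_config_validation():
    with pytest.raises(ValueError):
        pt.SolverConfig(dt=0.0)
    with pytest.raises(ValueError):
        pt.SolverConfig(steady_tol=2.0)
    with pytest.raises(ValueError):
        pt.BoundaryConditions(inflow_ul_min=0.0)
    with pytest.raises(ValueError):
        pt.BoundaryConditions(outlet_pressure_mmhg=-1.0)


# ----------------------------------------------------------------------
# conduction oracle on a strip
# ----------------------------------------------------------------------

def strip_setup(hot=36.5, cold=27.0):
    return ProblemSetup(temp_dirichlet={"bottom": hot, "top": cold},
                        noslip_tags=("bottom", "top", "left", "right"))


def test_strip_conduction_matches_linear_profile():
    """Pure conduction between two plates: T is linear in depth.
    Compared against the closed form T = T_hot + (T_cold - T_hot) y/H."""
    mesh = rectangle_mesh(0.5, 3.2, 4, 40)
    cfg = pt.SolverConfig(buoyancy=False, inflow=False)
    solver = ThermoFlowSolver(mesh, pt.get_fluid("AH"), config=cfg,
                              setup=strip_setup())
    state = solver.solve_steady_state()
    y = mesh.points[:, 1]
    exact = 36.5 + (27.0 - 36.5) * y / 3.2
    assert np.max(np.abs(state.T - exact)) < 0.02 * 9.5


def test_strip_transient_approaches_steady():
    mesh = rectangle_mesh(0.5, 3.2, 4, 24)
    cfg = pt.SolverConfig(buoyancy=False, inflow=False, dt=0.05)
    solver = ThermoFlowSolver(mesh, pt.get_fluid("AH"), config=cfg,
                              setup=strip_setup())
    steady = solver.solve_steady_state()
    # start from a perturbed field and march: must relax to the conduction
    # profile on the diffusive time scale
    T = np.full(mesh.num_points, 30.0)
    T[solver.T_nodes] = solver.T_vals
    u = np.zeros((mesh.num_points, 2))
    p = np.zeros(mesh.num_points)
    for _ in range(2000):
        u, p, T = solver.step(u, p, T, 0.05)
    assert np.max(np.abs(T - steady.T)) < 0.05


# ----------------------------------------------------------------------
# anterior-chamber invariants
# ----------------------------------------------------------------------

def test_zero_temperature_gradient_gives_zero_flow(coarse_mesh):
    """Uniform boundary temperatures with buoyancy on (and no forced
    inflow): no driving gradient, so the fluid stays at rest."""
    bc = pt.BoundaryConditions(corneal_temp=36.5, core_temp=36.5)
    cfg = pt.SolverConfig(inflow=False)
    solver = ThermoFlowSolver(coarse_mesh, pt.get_fluid("AH"), bc=bc,
                              config=cfg)
    state = solver.solve_steady_state()
    assert np.max(np.hypot(state.u[:, 0], state.u[:, 1])) < 1e-9
    assert np.max(np.abs(state.T - 36.5)) < 1e-9


def test_steady_maximum_principle(ah_steady):
    """No internal sources: T is bounded by the wall temperatures (up to
    the advection scheme's overshoot tolerance)."""
    assert ah_steady.T.min() > 27.0 - 0.15
    assert ah_steady.T.max() < 36.5 + 0.15


def test_steady_baseline_velocity_scale(ah_steady):
    """Natural convection of aqueous humor: peak speeds of order 1 mm/s."""
    speed = np.hypot(ah_steady.u[:, 0], ah_steady.u[:, 1]) * 1e3
    assert 0.05 < speed.max() < 5.0


def test_steady_mirror_symmetry(ah_steady, coarse_mesh):
    perm = mirror_index(coarse_mesh)
    assert np.max(np.abs(ah_steady.T - ah_steady.T[perm])) < 1e-6
    assert np.max(np.abs(ah_steady.u[:, 0] + ah_steady.u[perm, 0])) < 1e-9
    assert np.max(np.abs(ah_steady.u[:, 1] - ah_steady.u[perm, 1])) < 1e-9


def test_steady_mass_balance(ah_steady):
    mb = mass_balance(ah_steady)
    assert mb["inlet"] < 0                      # inflow
    assert mb["sc_outlet"] > 0                  # outflow
    assert abs(mb["net"]) < 1e-3 * abs(mb["inlet"])


def test_steady_energy_balance(ah_steady):
    eb = energy_balance(ah_steady)
    assert eb["imbalance"] < 0.01
    assert eb["cornea"] < 0                     # heat leaves at 27 degC
    assert eb["iris"] > 0                       # enters from the warm iris


def test_divergence_small_relative_to_shear(ah_steady):
    sp = ah_steady.solver.space
    assert sp.div_l2(ah_steady.u) < 0.25 * sp.grad_l2(ah_steady.u)


def test_healon_runs_in_conduction_mode(coarse_mesh):
    solver = ThermoFlowSolver(coarse_mesh, pt.get_fluid("Healon"))
    assert not solver.flow_enabled
    state = solver.solve_steady_state()
    assert np.all(state.u == 0.0)
    assert 27.0 - 1e-9 <= state.T.min() and state.T.max() <= 36.5 + 1e-9


def test_brinkman_limit_recovers_bulk_flow(coarse_mesh):
    """As porosity -> 1 and permeability -> infinity the TM elements
    behave like bulk fluid."""
    free = pt.PorousProperties(eps_p=1.0, kappa=1e6)
    mesh_nop = pt.Mesh(coarse_mesh.points, coarse_mesh.triangles,
                       coarse_mesh.boundary_edges, coarse_mesh.boundary_tag,
                       coarse_mesh.tag_names,
                       np.zeros_like(coarse_mesh.subdomain))
    a = ThermoFlowSolver(coarse_mesh, pt.get_fluid("AH"),
                         porous=free).solve_steady_state()
    b = ThermoFlowSolver(mesh_nop, pt.get_fluid("AH")).solve_steady_state()
    scale = np.max(np.hypot(b.u[:, 0], b.u[:, 1]))
    assert np.max(np.abs(a.u - b.u)) < 0.01 * scale


# ----------------------------------------------------------------------
# transient behaviour
# ----------------------------------------------------------------------

def test_zero_power_transient_preserves_steady(ah_solver, ah_steady):
    series = ah_solver.run(ah_steady, pt.HeatSourceSpec(0.0), t_end=5.0)
    assert np.max(np.abs(series.T[-1] - ah_steady.T)) < 0.05


def test_impulse_rise_and_decay(ah_solver, ah_steady, geom, probe_points):
    """The endothelium-centre temperature climbs during the 5-s impulse
    and falls back after the source switches off."""
    src = pt.HeatSourceSpec.from_geometry(geom, 1.2)
    series = ah_solver.run(ah_steady, src, probe_points=probe_points,
                           t_end=15.0)
    tr = series.traces["endothelium_center"]
    tt = series.trace_times
    i1, i5 = int(1 / 0.02), int(5 / 0.02)
    during = tr[i1:i5 + 1]
    assert np.all(np.diff(during) > -0.01)      # monotone climb
    assert tr[i5] > tr[0]
    assert tr[-1] < tr.max()                    # decays after the peak
    # hottest spot sits at the lens gap under the tip, not at the cornea
    tip = series.traces["probe_tip_center"]
    assert tip.max() > tr.max()


def test_transient_requires_impulse_coverage(ah_solver, ah_steady):
    with pytest.raises(ValueError):
        ah_solver.run(ah_steady, pt.HeatSourceSpec(1.0, duration=5.0),
                      t_end=2.0)


def test_run_transient_module_entry(ah_steady, geom, probe_points):
    series = pt.run_transient(ah_steady,
                              pt.HeatSourceSpec.from_geometry(geom, 0.66),
                              probe_points=probe_points, t_end=6.0)
    assert series.T.shape[1] == ah_steady.T.shape[0]
    assert series.trace_times[-1] == pytest.approx(6.0)
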