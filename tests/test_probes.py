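"""Probe sampling, extrema, relaxation and velocity-range extraction,
checked on synthetic fields with closed-form answers."""

import numpy as np
import pytest

import phacotherm as pt
from phacotherm.meshing import rectangle_mesh
from phacotherm.probes import PointInterpolator, _interior_mask
from phacotherm.solver import FieldState, FieldTimeSeries, HeatSourceSpec


@pytest.fixture(scope="module")
def rect():
    return rectangle_mesh(2.0, 1.0, 10, 5)


def make_series(mesh, times, T_of_t, u_of_t=None, duration=5.0):
    """Assemble a synthetic FieldTimeSeries from field callables."""
    n = mesh.num_points
    times = np.asarray(times, float)
    T = np.array([T_of_t(t) for t in times])
    u = np.array([u_of_t(t) if u_of_t else np.zeros((n, 2)) for t in times])
    ref = FieldState(mesh, pt.get_fluid("AH"), pt.get_porous(),
                     pt.BoundaryConditions(), pt.SolverConfig(),
                     u[0].copy(), np.zeros(n), T[0].copy())
    return FieldTimeSeries(ref, times, T, u, times,
                           {}, {}, HeatSourceSpec(1.0, duration))


def test_sample_constant_series(rect):
    ser = make_series(rect, [0, 1, 2],
                      lambda t: np.full(rect.num_points, 30.0))
    tr = pt.sample_point(ser, (0.77, 0.31))
    assert np.allclose(tr.values, 30.0)
    assert tr.reference == pytest.approx(30.0)


def test_sample_node_coincident_is_exact(rect):
    rng = np.random.default_rng(0)
    field = rng.uniform(20, 40, rect.num_points)
    ser = make_series(rect, [0.0], lambda t: field)
    node = 17
    tr = pt.sample_point(ser, rect.points[node])
    assert tr.values[0] == pytest.approx(field[node], rel=1e-14)


def test_sample_linear_field_mid_edge(rect):
    """P1 interpolation reproduces any linear field exactly, so the value
    at an edge midpoint is the mean of the endpoint values."""
    lin = 3.0 * rect.points[:, 0] - 2.0 * rect.points[:, 1] + 1.0
    ser = make_series(rect, [0.0], lambda t: lin)
    a, b = rect.triangles[0][:2]
    mid = 0.5 * (rect.points[a] + rect.points[b])
    tr = pt.sample_point(ser, mid)
    assert tr.values[0] == pytest.approx(0.5 * (lin[a] + lin[b]), rel=1e-12)


def test_sample_outside_domain_raises(rect):
    ser = make_series(rect, [0.0], lambda t: np.zeros(rect.num_points))
    with pytest.raises(pt.GeometryError):
        pt.sample_point(ser, (5.0, 5.0))


def test_trace_extrema_hand_cases():
    tr = pt.ProbeTrace("p", [0, 1, 2], [36.5, 40.0, 38.0], 36.5)
    t_max, v_max, rise = pt.trace_extrema(tr)
    assert (t_max, v_max) == (1.0, 40.0)
    assert rise == pytest.approx(3.5)
    mono = pt.ProbeTrace("p", [0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0], 1.0)
    assert pt.trace_extrema(mono)[0] == 3.0


def test_relaxation_identical_series_is_zero(rect):
    ser = make_series(rect, np.arange(0, 10, 0.5),
                      lambda t: np.full(rect.num_points, 30.0), duration=5.0)
    assert pt.relaxation_time(ser, ser.reference) == 0.0


def test_relaxation_exponential_decay_matches_closed_form(rect):
    """Uniform T(t) = T_ref + A exp(-t/tau) crosses tol_T at
    tau ln(A/tol) after the (zero-length) impulse."""
    A, tau, tol = 5.0, 3.0, 0.5
    times = np.arange(0, 30, 0.05)
    ser = make_series(rect, times,
                      lambda t: np.full(rect.num_points,
                                        30.0 + A * np.exp(-t / tau)))
    # reference is the decayed baseline, impulse "ends" at t=0
    n = rect.num_points
    ref = FieldState(rect, pt.get_fluid("AH"), pt.get_porous(),
                     pt.BoundaryConditions(), pt.SolverConfig(),
                     np.zeros((n, 2)), np.zeros(n), np.full(n, 30.0))
    ser.source = HeatSourceSpec(1.0, duration=1e-9)
    got = pt.relaxation_time(ser, ref, tol_T=tol)
    assert got == pytest.approx(tau * np.log(A / tol), abs=0.051)


def test_relaxation_monotone_in_tolerance(rect):
    times = np.arange(0, 30, 0.05)
    ser = make_series(rect, times,
                      lambda t: np.full(rect.num_points,
                                        30.0 + 5 * np.exp(-t / 3)))
    ser.source = HeatSourceSpec(1.0, duration=1e-9)
    n = rect.num_points
    ref = FieldState(rect, pt.get_fluid("AH"), pt.get_porous(),
                     pt.BoundaryConditions(), pt.SolverConfig(),
                     np.zeros((n, 2)), np.zeros(n), np.full(n, 30.0))
    loose = pt.relaxation_time(ser, ref, tol_T=1.0)
    tight = pt.relaxation_time(ser, ref, tol_T=0.25)
    assert loose <= tight


def test_relaxation_never_returns_inf(rect):
    ser = make_series(rect, np.arange(0, 8, 0.5),
                      lambda t: np.full(rect.num_points, 50.0))
    n = rect.num_points
    cold = FieldState(rect, pt.get_fluid("AH"), pt.get_porous(),
                      pt.BoundaryConditions(), pt.SolverConfig(),
                      np.zeros((n, 2)), np.zeros(n), np.full(n, 30.0))
    assert pt.relaxation_time(ser, cold) == np.inf


def test_velocity_range_zero_and_rigid_rotation(rect):
    zero = make_series(rect, [0.0], lambda t: np.zeros(rect.num_points))
    assert pt.velocity_range(zero, (0, 0)) == (0.0, 0.0)

    omega = 2.0  # rad/s about the rectangle centre; speeds in m/s
    c = np.array([1.0, 0.5])
    r = (rect.points - c) * 1e-3
    u = omega * np.column_stack([-r[:, 1], r[:, 0]])
    ser = make_series(rect, [0.0], lambda t: np.zeros(rect.num_points),
                      u_of_t=lambda t: u)
    mask = _interior_mask(rect, exclude_tags=(), rings=0)
    expect = omega * np.max(np.linalg.norm(r[mask], axis=1)) * 1e3
    assert pt.velocity_range(ser, (0, 0))[1] == pytest.approx(expect)


def test_velocity_range_empty_window_raises(rect):
    ser = make_series(rect, [0.0, 1.0], lambda t: np.zeros(rect.num_points))
    with pytest.raises(ValueError):
        pt.velocity_range(ser, (5.0, 6.0))
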