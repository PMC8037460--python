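"""Coupled incompressible-flow / heat-transport solver.

Physics: laminar Boussinesq natural convection of the chamber filling,
with a Brinkman drag term in the porous trabecular-meshwork elements, and
advective-diffusive heat transport.  The phaco-tip ultrasound impulse is a
line heat source on an immersed segment, active for the first
``duration`` seconds of the transient.

Discretization: P1 triangles with lumped mass.  Each time step performs
(1) explicit Lax-Wendroff (Taylor-Galerkin) advection, sub-cycled to the
local CFL limit, (2) an implicit viscous/drag solve for a tentative
velocity, (3) an incremental pressure-correction projection, and (4) an
implicit conduction solve for temperature.  All implicit matrices are
constant in time and factorized once per time-step size, so a step costs
a few triangular back-substitutions.  The steady baseline is obtained by
marching this scheme (with the impulse off) until the fields stop
changing; for high-viscosity fillings (Healon) the momentum equation is
bypassed and the baseline is pure conduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.linalg as spla

from .fem import P1Space, apply_dirichlet, edge_outward_normals
from .materials import FluidProperties, PorousProperties, get_porous
from .meshing import AC_TAGS, POROUS, Mesh

MMHG = 133.322
UL_PER_MIN = 1e-9 / 60.0


class SolverError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history


# ----------------------------------------------------------------------
# configuration objects
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryConditions:
    """Physical boundary data of the anterior-chamber problem."""

    corneal_temp: float = 27.0        # outer corneal wall [deg C]
    core_temp: float = 36.5           # all other walls / inflow [deg C]
    outlet_pressure_mmhg: float = 10.5   # episcleral venous pressure
    inflow_ul_min: float = 2.4        # total aqueous production [uL/min]
    d_eff_mm: float = 2.2             # out-of-plane depth for 2-D conversion
    t_ref: float = 36.5               # Boussinesq reference temperature

    def __post_init__(self):
        if not np.isfinite(self.corneal_temp + self.core_temp):
            raise ValueError("boundary temperatures must be finite")
        if self.outlet_pressure_mmhg < 0:
            raise ValueError("outlet pressure must be non-negative")
        if not self.inflow_ul_min > 0:
            raise ValueError("inflow must be positive")

    @property
    def outlet_pressure(self) -> float:
        return self.outlet_pressure_mmhg * MMHG

    @property
    def d_eff(self) -> float:
        return self.d_eff_mm * 1e-3


@dataclass(frozen=True)
class HeatSourceSpec:
    """Phaco-tip boundary heat impulse.

    ``flux`` spreads the total power over the tip footprint
    (tip length x effective depth), the 2-D reading of the probe's
    radiant-plus-friction heating.
    """

    total_power: float                 # [W]
    duration: float = 5.0              # [s]
    tip_x0: float = -1.1               # segment ends [mm]
    tip_x1: float = 1.1
    tip_y: float = 0.25                # height above the lens plane [mm]
    d_eff_mm: float = 2.2

    def __post_init__(self):
        if self.total_power < 0:
            raise ValueError("total_power must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @classmethod
    def from_geometry(cls, geom, total_power: float, duration: float = 5.0):
        x0, x1, y = geom.tip_segment
        return cls(total_power, duration, x0, x1, y,
                   geom.params.probe_tip_diameter)

    @property
    def tip_length(self) -> float:
        return (self.tip_x1 - self.tip_x0) * 1e-3

    @property
    def flux(self) -> float:
        """Impulse heat flux on the tip segment [W m^-2]."""
        return self.total_power / (self.tip_length * self.d_eff_mm * 1e-3)


def apply_heat_flux_bc(source: HeatSourceSpec, t: float) -> float:
    """Neumann flux -k dT/dn = q'' on the tip at time t (0 after the impulse)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if source.total_power == 0 or t >= source.duration:
        return 0.0
    return source.flux


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 0.02                  # transient step [s]
    t_end: float = 15.0               # transient horizon [s]
    steady_tol: float = 1e-3          # steady relative tolerance
    steady_dt: float = 0.1            # pseudo-time step for the baseline
    steady_max_time: float = 400.0    # pseudo-time cap [s]
    store_stride: int = 5             # field snapshots every N steps
    buoyancy: bool = True
    inflow: bool = True
    gravity: float = 9.81
    gravity_dir: tuple[float, float] = (0.0, -1.0)  # cornea -> lens (supine)
    qp_on: bool = False               # pressure-work heat term
    qvd_on: bool = False              # viscous-dissipation heat term
    conduction_mu_threshold: float = 1.0  # [Pa s]; above: skip the flow solve
    n_proj: int = 2                   # projection sweeps per step
    cfl: float = 0.4                  # advection sub-cycle target

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not 0 < self.steady_tol < 1:
            raise ValueError("steady_tol must lie in (0, 1)")


@dataclass
class ProblemSetup:
    """Tag-level boundary conditions (mesh-format agnostic)."""

    temp_dirichlet: dict[str, float]
    noslip_tags: tuple[str, ...] = ()
    #: tag -> prescribed 2-D flux [m^2/s]; positive into the domain,
    #: negative out (velocity along the local boundary normal)
    inflow_tags: dict[str, float] = field(default_factory=dict)
    inflow_temp: float | None = None
    #: tag -> pressure datum [Pa] (fixes the pressure level there)
    outlet_tags: dict[str, float] = field(default_factory=dict)


def ac_problem_setup(bc: BoundaryConditions,
                     config: SolverConfig) -> ProblemSetup:
    """Boundary conditions on the anterior-chamber mesh tags."""
    q2d = bc.inflow_ul_min * UL_PER_MIN / bc.d_eff  # total, per depth [m^2/s]
    return ProblemSetup(
        temp_dirichlet={
            "cornea": bc.corneal_temp,
            "lens": bc.core_temp, "iris": bc.core_temp,
            "pupil_wall": bc.core_temp, "tm_wall": bc.core_temp,
            "inlet": bc.core_temp,
        },
        noslip_tags=("lens", "iris", "pupil_wall", "tm_wall", "cornea",
                     "probe"),
        inflow_tags={"inlet": q2d if config.inflow else 0.0,
                     "sc_outlet": -q2d if config.inflow else 0.0},
        inflow_temp=bc.core_temp,
        outlet_tags={"sc_outlet": bc.outlet_pressure},
    )


# ----------------------------------------------------------------------
# states
# ----------------------------------------------------------------------

@dataclass
class FieldState:
    """(u, p, T) on the mesh nodes plus the problem context."""

    mesh: Mesh
    fluid: FluidProperties
    porous: PorousProperties
    bc: BoundaryConditions
    config: SolverConfig
    u: np.ndarray          # (N, 2) [m/s]
    p: np.ndarray          # (N,)   [Pa]
    T: np.ndarray          # (N,)   [deg C]
    solver: "ThermoFlowSolver" = field(default=None, repr=False)


@dataclass
class FieldTimeSeries:
    """Strided field snapshots plus per-step probe traces."""

    reference: FieldState
    times: np.ndarray      # snapshot times [s]
    T: np.ndarray          # (S, N)
    u: np.ndarray          # (S, N, 2)
    trace_times: np.ndarray            # every step
    traces: dict[str, np.ndarray]      # probe name -> temperature [deg C]
    speed_traces: dict[str, np.ndarray]
    source: HeatSourceSpec = None

    @property
    def mesh(self) -> Mesh:
        return self.reference.mesh


def boussinesq_body_force(T: np.ndarray, fluid: FluidProperties,
                          t_ref: float, g: float = 9.81,
                          g_dir=(0.0, -1.0)) -> np.ndarray:
    """Volumetric buoyancy force F = rho alpha g (T_ref - T) [N/m^3]."""
    T = np.asarray(T, float)
    g_vec = g * np.asarray(g_dir, float)
    return fluid.rho * fluid.alpha * (t_ref - T)[:, None] * g_vec[None, :]


# ----------------------------------------------------------------------
# the solver
# ----------------------------------------------------------------------

class ThermoFlowSolver:
    def __init__(self, mesh: Mesh, fluid: FluidProperties,
                 porous: PorousProperties | None = None,
                 bc: BoundaryConditions | None = None,
                 config: SolverConfig | None = None,
                 setup: ProblemSetup | None = None):
        self.mesh = mesh
        self.fluid = fluid
        self.porous = porous or get_porous()
        self.bc = bc or BoundaryConditions()
        self.config = config or SolverConfig()
        self.setup = setup or ac_problem_setup(self.bc, self.config)
        self.space = P1Space(mesh)
        sp_ = self.space
        cfg = self.config

        por = mesh.subdomain == POROUS
        eps = self.porous.eps_p
        mu, rho = fluid.mu, fluid.rho
        self.flow_enabled = mu < cfg.conduction_mu_threshold

        # element coefficients
        self.c_visc = np.where(por, mu / eps, mu)
        self.c_rho = np.where(por, rho / eps, rho)       # momentum time term
        self.c_adv_m = np.where(por, rho / eps**2, rho)  # momentum advection
        drag = np.where(por, mu / self.porous.kappa + self.porous.beta_f, 0.0)
        cpr = rho * fluid.cp
        self.c_heat = np.full(len(mesh.triangles), cpr)

        self.m_unit = sp_.lumped_mass(1.0)
        self.m_mom = sp_.lumped_mass(self.c_rho)
        self.m_drag = sp_.lumped_mass(drag)
        self.m_heat = sp_.lumped_mass(self.c_heat)
        self.K_visc = sp_.stiffness(self.c_visc)
        self.K_T = sp_.stiffness(fluid.k)
        self.K_p = sp_.stiffness(1.0)

        self._setup_bc_nodes()
        self._lu_cache: dict[float, tuple] = {}
        self._lu_p = None

    # ------------------------------------------------------------------
    def _setup_bc_nodes(self):
        mesh, sp_, setup = self.mesh, self.space, self.setup
        # temperature Dirichlet
        nodes, vals = [], []
        for tag, val in setup.temp_dirichlet.items():
            n = mesh.nodes_of_tag(tag)
            nodes.append(n)
            vals.append(np.full(len(n), float(val)))
        self.T_nodes = np.concatenate(nodes) if nodes else np.empty(0, int)
        self.T_vals = np.concatenate(vals) if vals else np.empty(0)
        # later tags overwrite earlier at shared corners (dict order)
        self.T_nodes, idx = np.unique(self.T_nodes[::-1], return_index=True)
        self.T_vals = self.T_vals[::-1][idx]

        # velocity Dirichlet: walls no-slip, inlets prescribed
        wall = [mesh.nodes_of_tag(t) for t in setup.noslip_tags]
        wall_nodes = (np.unique(np.concatenate(wall)) if wall
                      else np.empty(0, int))
        in_nodes, in_vel = [], []
        for tag, q2d in setup.inflow_tags.items():
            edges = mesh.edges_of_tag(tag)
            if not len(edges):
                continue
            normals = edge_outward_normals(sp_, edges)
            # length-weighted outward normal per node
            L = np.linalg.norm(sp_.points[edges[:, 1]]
                               - sp_.points[edges[:, 0]], axis=1)
            n_node = np.zeros((sp_.n_nodes, 2))
            np.add.at(n_node, edges[:, 0], normals * (L / 2)[:, None])
            np.add.at(n_node, edges[:, 1], normals * (L / 2)[:, None])
            cand = np.setdiff1d(np.unique(edges), wall_nodes)
            if q2d != 0 and not len(cand):
                raise SolverError(f"inflow tag {tag!r} has no free nodes")
            w_eff = np.linalg.norm(n_node[cand], axis=1)
            dirs = -n_node[cand] / w_eff[:, None]
            # trapezoid integral of u.n over the tag is then exactly -q2d
            speed = q2d / w_eff.sum() if w_eff.sum() > 0 else 0.0
            in_nodes.append(cand)
            in_vel.append(dirs * speed)
        if in_nodes:
            in_nodes = np.concatenate(in_nodes)
            in_vel = np.concatenate(in_vel)
        else:
            in_nodes = np.empty(0, int)
            in_vel = np.empty((0, 2))
        self.u_nodes = np.concatenate([wall_nodes, in_nodes])
        self.u_vals = np.vstack([np.zeros((len(wall_nodes), 2)), in_vel])

        # pressure outlet
        out_nodes, out_vals = [], []
        for tag, pval in self.setup.outlet_tags.items():
            n = mesh.nodes_of_tag(tag)
            out_nodes.append(n)
            out_vals.append(np.full(len(n), float(pval)))
        if out_nodes:
            self.p_nodes = np.concatenate(out_nodes)
            self.p_vals = np.concatenate(out_vals)
        else:  # pin one node to fix the pressure nullspace
            self.p_nodes = np.array([0])
            self.p_vals = np.array([0.0])

    # ------------------------------------------------------------------
    def _factors(self, dt: float):
        if dt not in self._lu_cache:
            A_u = self.K_visc.copy()
            A_u = A_u + _diag(self.m_mom / dt + self.m_drag)
            A_u = apply_dirichlet(A_u.tocsr(), self.u_nodes)
            A_T = self.K_T + _diag(self.m_heat / dt)
            A_T = apply_dirichlet(A_T.tocsr(), self.T_nodes)
            self._lu_cache[dt] = (spla.splu(A_u) if self.flow_enabled else None,
                                  spla.splu(A_T))
        if self._lu_p is None and self.flow_enabled:
            A_p = apply_dirichlet(self.K_p.copy().tocsr(), self.p_nodes)
            self._lu_p = spla.splu(A_p)
        return self._lu_cache[dt]

    # ------------------------------------------------------------------
    def _advect(self, vel, f, c_m_elem, c_a_elem, dt):
        """Sub-cycled Lax-Wendroff advection of nodal field f."""
        sp_ = self.space
        ux = sp_.elem_mean(vel[:, 0])
        uy = sp_.elem_mean(vel[:, 1])
        rate = np.hypot(ux, uy) * (c_a_elem / c_m_elem) / sp_.h_elem
        m = max(1, int(np.ceil(dt * rate.max() / self.config.cfl)))
        dt_s = dt / m
        m_nodes = 1.0 / np.maximum(self._m_of(c_m_elem), 1e-300)
        c_sd = c_a_elem**2 / c_m_elem
        f = f.copy()
        for _ in range(m):
            r = sp_.advection_rhs(vel, f, c_a_elem)
            r -= sp_.streamline_diffusion_rhs(vel, f, dt_s / 2, c_sd)
            f -= dt_s * r * m_nodes
        return f

    def _m_of(self, c_elem):
        key = id(c_elem)
        cache = getattr(self, "_m_cache", None)
        if cache is None:
            cache = self._m_cache = {}
        if key not in cache:
            cache[key] = self.space.lumped_mass(c_elem)
        return cache[key]

    # ------------------------------------------------------------------
    def step(self, u, p, T, dt, heat_rhs=None):
        """Advance one time step; returns (u, p, T)."""
        lu_u, lu_T = self._factors(dt)
        sp_ = self.space
        cfg = self.config
        rho = self.fluid.rho

        if self.flow_enabled:
            ux = self._advect(u, u[:, 0], self.c_rho, self.c_adv_m, dt)
            uy = self._advect(u, u[:, 1], self.c_rho, self.c_adv_m, dt)
            gp = sp_.gradient_rhs(p)
            rhs = np.column_stack([self.m_mom / dt * ux,
                                   self.m_mom / dt * uy]) - gp
            if cfg.buoyancy:
                F = boussinesq_body_force(T, self.fluid, self.bc.t_ref,
                                          cfg.gravity, cfg.gravity_dir)
                rhs += self.m_unit[:, None] * F
            rhs[self.u_nodes] = self.u_vals
            u_star = np.column_stack([lu_u.solve(rhs[:, 0]),
                                      lu_u.solve(rhs[:, 1])])
            p = p.copy()
            for _ in range(cfg.n_proj):
                d = sp_.divergence_rhs(u_star)
                rhs_p = -(rho / dt) * d
                rhs_p[self.p_nodes] = 0.0
                phi = self._lu_p.solve(rhs_p)
                u_star -= (dt / rho) * sp_.gradient_rhs(phi) / \
                    self.m_unit[:, None]
                u_star[self.u_nodes] = self.u_vals
                p += phi
            u = u_star
        # energy transport
        T_a = self._advect(u, T, self.c_heat, self.c_heat, dt) \
            if self.flow_enabled else T
        rhs_T = self.m_heat / dt * T_a
        if heat_rhs is not None:
            rhs_T = rhs_T + heat_rhs
        if cfg.qvd_on:
            rhs_T = rhs_T + sp_.viscous_dissipation_rhs(u, self.c_visc)
        if cfg.qp_on:
            # pressure work alpha T (u . grad p), explicit
            px, py = sp_.elem_grad(p)
            ux_e = sp_.elem_mean(u[:, 0])
            uy_e = sp_.elem_mean(u[:, 1])
            T_e = sp_.elem_mean(T) + 273.15
            w = self.fluid.alpha * T_e * (ux_e * px + uy_e * py) \
                * sp_.area / 3.0
            qp = np.zeros(sp_.n_nodes)
            for k in range(3):
                np.add.at(qp, sp_.tris[:, k], w)
            rhs_T = rhs_T + qp
        rhs_T[self.T_nodes] = self.T_vals
        T = lu_T.solve(rhs_T)
        return u, p, T

    # ------------------------------------------------------------------
    def conduction_state(self) -> FieldState:
        """Pure-conduction temperature field (flow at rest)."""
        A = apply_dirichlet(self.K_T.copy().tocsr(), self.T_nodes)
        rhs = np.zeros(self.space.n_nodes)
        rhs[self.T_nodes] = self.T_vals
        T = spla.splu(A).solve(rhs)
        p = np.full(self.space.n_nodes, float(self.p_vals.mean())
                    if len(self.p_vals) else 0.0)
        return FieldState(self.mesh, self.fluid, self.porous, self.bc,
                          self.config, np.zeros((self.space.n_nodes, 2)),
                          p, T, solver=self)

    def solve_steady_state(self) -> FieldState:
        """March to the stationary baseline (impulse off)."""
        state = self.conduction_state()
        if not self.flow_enabled:
            return state
        cfg = self.config
        dt = cfg.steady_dt
        u, p, T = state.u, state.p, state.T
        t = 0.0
        history = []
        # rate tolerances scaled by the boundary-data ranges
        T_range = max(np.ptp(self.T_vals), 1.0) if len(self.T_vals) else 1.0
        tol_T = cfg.steady_tol * T_range * 0.1      # [deg C / s]
        tol_u = cfg.steady_tol * 1e-2               # [m/s / s] vs mm/s flows
        while t < cfg.steady_max_time:
            u1, p1, T1 = self.step(u, p, T, dt)
            rate_T = float(np.max(np.abs(T1 - T)) / dt)
            rate_u = float(np.max(np.abs(u1 - u)) / dt)
            history.append((t, rate_T, rate_u))
            u, p, T = u1, p1, T1
            t += dt
            if t > 20 * dt and rate_T < tol_T and rate_u < tol_u:
                break
        else:
            raise SolverError(
                f"steady baseline did not converge within "
                f"{cfg.steady_max_time} s of pseudo-time "
                f"(last rates dT/dt={history[-1][1]:.3g} deg C/s, "
                f"du/dt={history[-1][2]:.3g} m/s^2)", history=history)
        return FieldState(self.mesh, self.fluid, self.porous, self.bc,
                          self.config, u, p, T, solver=self)

    # ------------------------------------------------------------------
    def tip_source_rhs(self, source: HeatSourceSpec) -> np.ndarray:
        """Nodal weight vector of the tip heat source.

        The impulse power is spread over the probe-tip boundary (the
        meshed obstacle surface when present, otherwise an immersed line
        segment at the tip position).  Weights are normalized to sum to
        ``tip_length`` m, so ``flux * weights`` deposits exactly
        ``total_power / d_eff`` watts per metre of out-of-plane depth.
        """
        if "probe" in self.mesh.tag_names:
            edges = self.mesh.edges_of_tag("probe")
            if len(edges):
                # the active tip face is the underside of the probe: keep
                # edges below the tip centre (the face looking at the lens)
                cy = 0.5 * (self.mesh.points[np.unique(edges), 1].min()
                            + self.mesh.points[np.unique(edges), 1].max())
                mids = 0.5 * (self.mesh.points[edges[:, 0], 1]
                              + self.mesh.points[edges[:, 1], 1])
                lower = edges[mids < cy]
                from .fem import boundary_node_weights
                w = boundary_node_weights(self.space, lower)
                return w * (source.tip_length / w.sum())
        pts = self.mesh.points
        tol = 1e-6
        on = (np.abs(pts[:, 1] - source.tip_y) < tol) \
            & (pts[:, 0] > source.tip_x0 - tol) \
            & (pts[:, 0] < source.tip_x1 + tol)
        idx = np.where(on)[0]
        if len(idx) < 2:
            raise SolverError(
                "no mesh nodes on the phaco-tip boundary or segment; the "
                "mesh was not generated for this source position")
        order = np.argsort(pts[idx, 0])
        idx = idx[order]
        x = pts[idx, 0] * 1e-3
        w = np.zeros(len(idx))
        dx = np.diff(x)
        w[:-1] += dx / 2
        w[1:] += dx / 2
        rhs = np.zeros(self.space.n_nodes)
        rhs[idx] = w * (source.tip_length / w.sum())
        return rhs

    def run(self, initial: FieldState, source: HeatSourceSpec,
            probe_points: dict[str, tuple[float, float]] | None = None,
            t_end: float | None = None) -> FieldTimeSeries:
        from .probes import PointInterpolator

        cfg = self.config
        dt = cfg.dt
        t_end = cfg.t_end if t_end is None else t_end
        if t_end < source.duration:
            raise ValueError("t_end must cover the impulse duration")
        n_steps = int(round(t_end / dt))
        tip_w = self.tip_source_rhs(source) if source.total_power > 0 else None

        interp = None
        if probe_points:
            interp = PointInterpolator(self.mesh,
                                       list(probe_points.values()))
        u, p, T = initial.u.copy(), initial.p.copy(), initial.T.copy()
        snap_T = [T.copy()]
        snap_u = [u.copy()]
        snap_t = [0.0]
        tr_t = [0.0]
        tr_T = [interp(T) if interp else None]
        tr_s = [interp(np.hypot(u[:, 0], u[:, 1])) if interp else None]
        for n in range(n_steps):
            t = n * dt
            q = apply_heat_flux_bc(source, t)
            heat = tip_w * q if (tip_w is not None and q > 0) else None
            u, p, T = self.step(u, p, T, dt, heat_rhs=heat)
            if not np.all(np.isfinite(T)):
                raise SolverError(f"solution diverged at step {n} "
                                  f"(t={t + dt:.3f} s)")
            tnow = (n + 1) * dt
            tr_t.append(tnow)
            if interp:
                tr_T.append(interp(T))
                tr_s.append(interp(np.hypot(u[:, 0], u[:, 1])))
            if (n + 1) % cfg.store_stride == 0 or n + 1 == n_steps:
                snap_T.append(T.copy())
                snap_u.append(u.copy())
                snap_t.append(tnow)

        names = list(probe_points) if probe_points else []
        traces = {nm: np.array([v[i] for v in tr_T])
                  for i, nm in enumerate(names)}
        speeds = {nm: np.array([v[i] for v in tr_s])
                  for i, nm in enumerate(names)}
        return FieldTimeSeries(
            reference=initial, times=np.array(snap_t),
            T=np.array(snap_T), u=np.array(snap_u),
            trace_times=np.array(tr_t), traces=traces,
            speed_traces=speeds, source=source)


def _diag(v):
    return sparse.diags(v)


# ----------------------------------------------------------------------
# module-level operations
# ----------------------------------------------------------------------

def solve_steady(mesh: Mesh, fluid: FluidProperties,
                 porous: PorousProperties | None = None,
                 bc: BoundaryConditions | None = None,
                 config: SolverConfig | None = None,
                 setup: ProblemSetup | None = None) -> FieldState:
    """Stationary baseline for the given mesh and filling fluid.

    For anterior-chamber meshes the tag-level boundary conditions are
    derived from ``bc``; pass an explicit ``setup`` for other meshes.
    """
    if setup is None and tuple(mesh.tag_names) != AC_TAGS:
        raise SolverError("non-AC mesh: an explicit ProblemSetup is required")
    solver = ThermoFlowSolver(mesh, fluid, porous, bc, config, setup)
    return solver.solve_steady_state()


def run_transient(initial: FieldState, source: HeatSourceSpec,
                  config: SolverConfig | None = None,
                  probe_points=None, t_end=None) -> FieldTimeSeries:
    """Transient impulse-and-relaxation run from a steady baseline."""
    solver = initial.solver
    if solver is None or (config is not None
                          and config is not initial.config):
        cfg = config or initial.config
        solver = ThermoFlowSolver(initial.mesh, initial.fluid,
                                  initial.porous, initial.bc, cfg)
    return solver.run(initial, source, probe_points=probe_points,
                      t_end=t_end)


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------

def mass_balance(state: FieldState) -> dict[str, float]:
    """Boundary flux integrals of u.n per tag [m^2/s] and the net."""
    sp_ = state.solver.space if state.solver else P1Space(state.mesh)
    out = {}
    for tag in state.mesh.tag_names:
        edges = state.mesh.edges_of_tag(tag)
        if not len(edges):
            out[tag] = 0.0
            continue
        n = edge_outward_normals(sp_, edges)
        a, b = edges[:, 0], edges[:, 1]
        L = np.linalg.norm(sp_.points[b] - sp_.points[a], axis=1)
        un = 0.5 * ((state.u[a] * n).sum(1) + (state.u[b] * n).sum(1))
        out[tag] = float(np.sum(un * L))
    out["net"] = sum(v for k, v in out.items())
    return out


def energy_balance(state: FieldState) -> dict[str, float]:
    """Steady-state energy budget, in W per metre of depth.

    Wall fluxes come from the scheme-consistent nodal residual of the
    converged heat step (the discrete heat entering at each Dirichlet
    node, positive into the fluid), attributed uniquely per tag;
    ``advective_net`` is the trapezoid enthalpy transport through the
    in/outflow edges.  At a converged steady state the wall fluxes and
    the advective transport cancel: ``imbalance`` is the residual of
    that cancellation relative to the largest flux.
    """
    slv = state.solver
    if slv is None:
        raise SolverError("energy_balance needs the solver context "
                          "attached to the state")
    sp_ = slv.space
    mesh = state.mesh
    dt = slv.config.steady_dt
    if slv.flow_enabled:
        T_a = slv._advect(state.u, state.T, slv.c_heat, slv.c_heat, dt)
    else:
        T_a = state.T
    resid = slv.m_heat / dt * (state.T - T_a) + slv.K_T @ state.T

    node_tag: dict[int, str] = {}
    for tag in mesh.tag_names:
        for n in mesh.nodes_of_tag(tag):
            node_tag.setdefault(int(n), tag)
    out = {tag: 0.0 for tag in mesh.tag_names}
    for n, tag in node_tag.items():
        out[tag] += float(resid[n])

    rcp = state.fluid.rho * state.fluid.cp
    adv = 0.0
    for tag in ("inlet", "sc_outlet"):
        if tag not in mesh.tag_names:
            continue
        for a, b in mesh.edges_of_tag(tag):
            d = sp_.points[b] - sp_.points[a]
            L = float(np.hypot(d[0], d[1]))
            nv = np.array([d[1], -d[0]]) / L
            Tm = 0.5 * (state.T[a] + state.T[b])
            um = 0.5 * (state.u[a] + state.u[b])
            adv += rcp * Tm * float(um @ nv) * L
    out["advective_net"] = adv
    scale = max(max(abs(v) for v in out.values()), 1e-300)
    out["imbalance"] = abs(sum(v for t, v in out.items()
                               if t not in ("imbalance", "advective_net"))
                           - adv) / scale
    return out
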