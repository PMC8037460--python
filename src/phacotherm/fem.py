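"""Linear (P1) finite-element operators on a triangle mesh.

All operators work in SI units: the mm mesh coordinates are converted to
metres on construction.  Scalar fields live on nodes; coefficients are
per-element.  Mass matrices are lumped (row-summed), which keeps the
transient schemes positivity-friendly and makes nodal updates cheap.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .meshing import Mesh

MM = 1e-3  # mesh coordinates are mm; operators are SI


class P1Space:
    """Precomputed P1 element data for a mesh (SI coordinates)."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.points = mesh.points * MM
        self.tris = np.asarray(mesh.triangles, dtype=np.int64)
        p = self.points
        t = self.tris
        x = p[:, 0][t]  # (M,3)
        y = p[:, 1][t]
        # grad phi_i = (b_i, c_i) / (2A)
        self.b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0],
                           y[:, 0] - y[:, 1]], axis=1)
        self.c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2],
                           x[:, 1] - x[:, 0]], axis=1)
        self.area = 0.5 * (self.b[:, 0] * self.c[:, 1]
                           - self.b[:, 1] * self.c[:, 0])
        # normalized gradients
        self.gx = self.b / (2 * self.area[:, None])
        self.gy = self.c / (2 * self.area[:, None])
        self.n_nodes = len(p)
        # element length scale: shortest height (for CFL estimates)
        el = np.stack([np.hypot(self.b[:, i], self.c[:, i]) for i in range(3)],
                      axis=1)
        self.h_elem = 2 * self.area / el.max(axis=1)

    # ------------------------------------------------------------------
    def stiffness(self, coeff) -> sp.csr_matrix:
        """Assemble int coeff grad(phi_i) . grad(phi_j)."""
        coeff = np.broadcast_to(np.asarray(coeff, float), len(self.tris))
        M = len(self.tris)
        rows = np.repeat(self.tris, 3, axis=1).ravel()          # i index
        cols = np.tile(self.tris, (1, 3)).ravel()               # j index
        gxi = self.gx[:, :, None] * self.gx[:, None, :]
        gyi = self.gy[:, :, None] * self.gy[:, None, :]
        vals = ((gxi + gyi) * (coeff * self.area)[:, None, None]).reshape(M, 9)
        A = sp.coo_matrix((vals.ravel(), (rows, cols)),
                          shape=(self.n_nodes, self.n_nodes))
        return A.tocsr()

    def lumped_mass(self, coeff=1.0) -> np.ndarray:
        """Row-sum (lumped) mass vector: int coeff phi_i."""
        coeff = np.broadcast_to(np.asarray(coeff, float), len(self.tris))
        m = np.zeros(self.n_nodes)
        w = coeff * self.area / 3.0
        for k in range(3):
            np.add.at(m, self.tris[:, k], w)
        return m

    # ------------------------------------------------------------------
    def elem_mean(self, f: np.ndarray) -> np.ndarray:
        return f[self.tris].mean(axis=1)

    def elem_grad(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fx = np.sum(self.gx * f[self.tris], axis=1)
        fy = np.sum(self.gy * f[self.tris], axis=1)
        return fx, fy

    def advection_rhs(self, vel: np.ndarray, f: np.ndarray,
                      coeff=1.0, vel_scale=1.0) -> np.ndarray:
        """Galerkin advection term r_i = int coeff phi_i (v . grad f).

        ``vel_scale`` rescales the element velocity (seepage velocity in
        porous elements).
        """
        coeff = np.broadcast_to(np.asarray(coeff, float), len(self.tris))
        vel_scale = np.broadcast_to(np.asarray(vel_scale, float),
                                    len(self.tris))
        ux = self.elem_mean(vel[:, 0]) * vel_scale
        uy = self.elem_mean(vel[:, 1]) * vel_scale
        fx, fy = self.elem_grad(f)
        conv = (ux * fx + uy * fy) * coeff * self.area / 3.0
        r = np.zeros(self.n_nodes)
        for k in range(3):
            np.add.at(r, self.tris[:, k], conv)
        return r

    def streamline_diffusion_rhs(self, vel: np.ndarray, f: np.ndarray,
                                 tau, coeff=1.0, vel_scale=1.0) -> np.ndarray:
        """r_i = int coeff tau (v.grad phi_i)(v.grad f) (Lax-Wendroff term)."""
        coeff = np.broadcast_to(np.asarray(coeff, float), len(self.tris))
        vel_scale = np.broadcast_to(np.asarray(vel_scale, float),
                                    len(self.tris))
        tau = np.broadcast_to(np.asarray(tau, float), len(self.tris))
        ux = self.elem_mean(vel[:, 0]) * vel_scale
        uy = self.elem_mean(vel[:, 1]) * vel_scale
        fx, fy = self.elem_grad(f)
        udf = ux * fx + uy * fy
        w = tau * coeff * self.area * udf
        r = np.zeros(self.n_nodes)
        for k in range(3):
            np.add.at(r, self.tris[:, k],
                      w * (ux * self.gx[:, k] + uy * self.gy[:, k]))
        return r

    def divergence_rhs(self, vel: np.ndarray) -> np.ndarray:
        """d_i = int phi_i div(v)."""
        ux, _ = self.elem_grad(vel[:, 0])
        _, vy = self.elem_grad(vel[:, 1])
        div = (ux + vy) * self.area / 3.0
        d = np.zeros(self.n_nodes)
        for k in range(3):
            np.add.at(d, self.tris[:, k], div)
        return d

    def gradient_rhs(self, f: np.ndarray) -> np.ndarray:
        """g_i = int phi_i grad(f), shape (N, 2)."""
        fx, fy = self.elem_grad(f)
        g = np.zeros((self.n_nodes, 2))
        wx = fx * self.area / 3.0
        wy = fy * self.area / 3.0
        for k in range(3):
            np.add.at(g[:, 0], self.tris[:, k], wx)
            np.add.at(g[:, 1], self.tris[:, k], wy)
        return g

    def div_l2(self, vel: np.ndarray) -> float:
        ux, _ = self.elem_grad(vel[:, 0])
        _, vy = self.elem_grad(vel[:, 1])
        return float(np.sqrt(np.sum(self.area * (ux + vy) ** 2)))

    def grad_l2(self, vel: np.ndarray) -> float:
        gxx, gxy = self.elem_grad(vel[:, 0])
        gyx, gyy = self.elem_grad(vel[:, 1])
        return float(np.sqrt(np.sum(
            self.area * (gxx**2 + gxy**2 + gyx**2 + gyy**2))))

    def viscous_dissipation_rhs(self, vel: np.ndarray, mu) -> np.ndarray:
        """Q_vd: r_i = int phi_i mu (2 ux^2 + 2 vy^2 + (uy + vx)^2)."""
        mu = np.broadcast_to(np.asarray(mu, float), len(self.tris))
        ux, uy = self.elem_grad(vel[:, 0])
        vx, vy = self.elem_grad(vel[:, 1])
        phi = mu * (2 * ux**2 + 2 * vy**2 + (uy + vx) ** 2)
        w = phi * self.area / 3.0
        r = np.zeros(self.n_nodes)
        for k in range(3):
            np.add.at(r, self.tris[:, k], w)
        return r


def boundary_edge_lengths(space: P1Space, edges: np.ndarray) -> np.ndarray:
    a = space.points[edges[:, 0]]
    b = space.points[edges[:, 1]]
    return np.linalg.norm(b - a, axis=1)


def boundary_node_weights(space: P1Space, edges: np.ndarray) -> np.ndarray:
    """Per-node trapezoid weights (m) of a set of boundary edges."""
    L = boundary_edge_lengths(space, edges)
    w = np.zeros(space.n_nodes)
    np.add.at(w, edges[:, 0], L / 2)
    np.add.at(w, edges[:, 1], L / 2)
    return w


def edge_outward_normals(space: P1Space, edges: np.ndarray) -> np.ndarray:
    """Unit outward normals of CCW-oriented boundary edges."""
    a = space.points[edges[:, 0]]
    b = space.points[edges[:, 1]]
    t = b - a
    n = np.column_stack([t[:, 1], -t[:, 0]])
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def apply_dirichlet(A: sp.csr_matrix, nodes: np.ndarray) -> sp.csr_matrix:
    """Replace the given rows of A by identity rows (in place copy)."""
    A = A.tolil()
    A[nodes, :] = 0.0
    A[nodes, nodes] = 1.0
    return A.tocsc()
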