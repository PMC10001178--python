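"""Axisymmetric P1 finite-element kernels on triangle meshes.

All operators are assembled in cylindrical (r, z) coordinates with the
revolution weight 2*pi*r.  For linear basis functions the stiffness
integrand (constant gradients times the linear weight r) is integrated
exactly by the centroid rule.  Mass and Robin-boundary operators are
row-sum lumped: together with backward-Euler time stepping and a
non-obtuse mesh this yields a discrete maximum principle, and because
the stiffness matrix has exactly zero row sums the discrete water/heat
inventory balances the boundary fluxes to round-off.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["P1Operators"]


class P1Operators:
    """Precomputed geometry for fast reassembly of axisymmetric operators."""

    def __init__(self, points: np.ndarray, triangles: np.ndarray):
        self.points = points
        self.triangles = triangles
        self.n = len(points)
        p = points[triangles]  # (M, 3, 2)
        # shape-function gradients: phi_i = (a_i + b_i r + c_i z)/(2A)
        r = p[:, :, 0]
        z = p[:, :, 1]
        self.area = 0.5 * np.abs(
            (r[:, 1] - r[:, 0]) * (z[:, 2] - z[:, 0])
            - (r[:, 2] - r[:, 0]) * (z[:, 1] - z[:, 0])
        )
        b = np.stack([z[:, 1] - z[:, 2], z[:, 2] - z[:, 0], z[:, 0] - z[:, 1]], axis=1)
        c = np.stack([r[:, 2] - r[:, 1], r[:, 0] - r[:, 2], r[:, 1] - r[:, 0]], axis=1)
        inv2A = 1.0 / (2.0 * self.area)
        self.grad_r = b * inv2A[:, None]  # (M, 3)
        self.grad_z = c * inv2A[:, None]
        self.r_centroid = r.mean(axis=1)
        self.r_nodes = r  # (M, 3)
        # local stiffness shape (M, 3, 3): grad_i . grad_j
        gg = (
            self.grad_r[:, :, None] * self.grad_r[:, None, :]
            + self.grad_z[:, :, None] * self.grad_z[:, None, :]
        )
        self._local_stiff = gg * (self.area * 2 * np.pi)[:, None, None]
        rows = np.repeat(triangles, 3, axis=1).reshape(-1)
        cols = np.tile(triangles, (1, 3)).reshape(-1)
        self._rows = rows
        self._cols = cols

    def stiffness(self, kappa_elem: np.ndarray) -> sp.csr_matrix:
        """K_ij = int kappa grad(phi_i).grad(phi_j) 2 pi r dA (exact in r)."""
        vals = (self._local_stiff * (kappa_elem * self.r_centroid)[:, None, None]).reshape(-1)
        K = sp.coo_matrix((vals, (self._rows, self._cols)), shape=(self.n, self.n))
        return K.tocsr()

    def lumped_mass(self, coef_elem: np.ndarray | float = 1.0) -> np.ndarray:
        """Row-sum lumped mass vector m_i = int coef phi_i 2 pi r dA."""
        coef_elem = np.broadcast_to(np.asarray(coef_elem, float), self.area.shape)
        # int phi_i r dA = A (2 r_i + r_j + r_k) / 12 on a P1 triangle
        rsum = self.r_nodes.sum(axis=1)
        local = (self.r_nodes + rsum[:, None]) / 12.0
        vals = 2 * np.pi * (coef_elem * self.area)[:, None] * local
        m = np.zeros(self.n)
        np.add.at(m, self.triangles, vals)
        return m

    def boundary_lumped(self, edges: np.ndarray, coef: float = 1.0) -> np.ndarray:
        """Lumped Robin weight w_i = int coef phi_i 2 pi r ds over the edges."""
        w = np.zeros(self.n)
        if len(edges) == 0:
            return w
        p0 = self.points[edges[:, 0]]
        p1 = self.points[edges[:, 1]]
        length = np.linalg.norm(p1 - p0, axis=1)
        r0, r1 = p0[:, 0], p1[:, 0]
        w0 = 2 * np.pi * coef * length * (2 * r0 + r1) / 6.0
        w1 = 2 * np.pi * coef * length * (r0 + 2 * r1) / 6.0
        np.add.at(w, edges[:, 0], w0)
        np.add.at(w, edges[:, 1], w1)
        return w
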