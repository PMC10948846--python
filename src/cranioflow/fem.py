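"""Minimal P1/P2 simplex finite-element kernel on triangle meshes.

Supports planar and axisymmetric (r-z, revolved about x=0) weak forms for the
Stokes/Navier-Stokes, linear-elastic/Biot and Laplace problems used by the
fluid, solid and mesh-motion solvers. Coordinates are in meters; the
axisymmetric weight 2*pi*x is applied through the quadrature weights.

Vector fields use a block dof layout: [all x-components, all y-components].
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# ---------------------------------------------------------------- quadrature

# Dunavant 6-point rule, degree 4, on the reference triangle (area 1/2)
_QP = np.array(
    [
        [0.445948490915965, 0.445948490915965],
        [0.108103018168070, 0.445948490915965],
        [0.445948490915965, 0.108103018168070],
        [0.091576213509771, 0.091576213509771],
        [0.816847572980459, 0.091576213509771],
        [0.091576213509771, 0.816847572980459],
    ]
)
_QW = 0.5 * np.array(
    [
        0.223381589678011,
        0.223381589678011,
        0.223381589678011,
        0.109951743655322,
        0.109951743655322,
        0.109951743655322,
    ]
)

# 3-point Gauss on [0,1]
_EDGE_QP = np.array([0.5 * (1 - np.sqrt(0.6)), 0.5, 0.5 * (1 + np.sqrt(0.6))])
_EDGE_QW = np.array([5.0, 8.0, 5.0]) / 18.0


def _p1_phi(xi, eta):
    return np.stack([1.0 - xi - eta, xi, eta], axis=-1)


def _p1_dphi():
    return np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])


def _p2_phi(xi, eta):
    l0 = 1.0 - xi - eta
    l1, l2 = xi, eta
    return np.stack(
        [
            l0 * (2 * l0 - 1),
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            4 * l1 * l2,  # edge opposite vertex 0
            4 * l2 * l0,  # edge opposite vertex 1
            4 * l0 * l1,  # edge opposite vertex 2
        ],
        axis=-1,
    )


def _p2_dphi(xi, eta):
    """Reference gradients, shape (..., 6, 2)."""
    l0 = 1.0 - xi - eta
    l1, l2 = xi, eta
    z = np.zeros_like(xi)
    d = np.empty(np.shape(xi) + (6, 2))
    d[..., 0, 0] = 1 - 4 * l0
    d[..., 0, 1] = 1 - 4 * l0
    d[..., 1, 0] = 4 * l1 - 1
    d[..., 1, 1] = z
    d[..., 2, 0] = z
    d[..., 2, 1] = 4 * l2 - 1
    d[..., 3, 0] = 4 * l2
    d[..., 3, 1] = 4 * l1
    d[..., 4, 0] = -4 * l2
    d[..., 4, 1] = 4 * (l0 - l2)
    d[..., 5, 0] = 4 * (l0 - l1)
    d[..., 5, 1] = -4 * l1
    return d


_LOCAL_EDGES = np.array([[1, 2], [2, 0], [0, 1]])  # edge i opposite vertex i


def build_edges(cells: np.ndarray):
    """Unique mesh edges and the cell->edge incidence map."""
    e = np.sort(cells[:, _LOCAL_EDGES].reshape(-1, 2), axis=1)
    edges, inv = np.unique(e, axis=0, return_inverse=True)
    return edges, inv.reshape(-1, 3)


class Basis:
    """Precomputed shape-function data for a P1 or P2 space on a triangle mesh."""

    def __init__(self, vertices: np.ndarray, cells: np.ndarray, degree: int):
        self.x = np.asarray(vertices, dtype=float)
        self.cells = np.asarray(cells, dtype=np.int64)
        self.degree = degree
        nv = self.x.shape[0]
        self.edges, self.cell_edges = build_edges(self.cells)
        if degree == 1:
            self.cell_dofs = self.cells.copy()
            self.ndof = nv
            self.dof_x = self.x.copy()
            self.phi = _p1_phi(_QP[:, 0], _QP[:, 1])  # (nq, 3)
            dref = np.broadcast_to(_p1_dphi(), (_QP.shape[0], 3, 2))
        elif degree == 2:
            self.cell_dofs = np.hstack([self.cells, nv + self.cell_edges])
            self.ndof = nv + self.edges.shape[0]
            mid = 0.5 * (self.x[self.edges[:, 0]] + self.x[self.edges[:, 1]])
            self.dof_x = np.vstack([self.x, mid])
            self.phi = _p2_phi(_QP[:, 0], _QP[:, 1])  # (nq, 6)
            dref = _p2_dphi(_QP[:, 0], _QP[:, 1])  # (nq, 6, 2)
        else:
            raise ValueError("degree must be 1 or 2")
        self.nloc = self.cell_dofs.shape[1]
        # geometry: affine map x = x0 + J xi
        x0 = self.x[self.cells[:, 0]]
        J = np.stack(
            [self.x[self.cells[:, 1]] - x0, self.x[self.cells[:, 2]] - x0], axis=-1
        )  # (m, 2, 2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("mesh contains inverted or degenerate cells")
        Jinv = np.empty_like(J)
        Jinv[:, 0, 0] = J[:, 1, 1]
        Jinv[:, 0, 1] = -J[:, 0, 1]
        Jinv[:, 1, 0] = -J[:, 1, 0]
        Jinv[:, 1, 1] = J[:, 0, 0]
        Jinv /= detJ[:, None, None]
        self.detJ = detJ
        self._Jinv = Jinv
        # physical quad points and weights
        ref = np.concatenate([_QP, np.zeros((_QP.shape[0], 0))], axis=1)
        self.qx = x0[:, None, :] + np.einsum("mij,qj->mqi", J, ref)  # (m, nq, 2)
        self.qw = detJ[:, None] * _QW[None, :]  # (m, nq)
        # physical gradients (m, nq, nloc, 2)
        self.dphi = np.einsum("qld,mdi->mqli", dref, Jinv)
        self.nq = _QP.shape[0]

    # -- helpers ---------------------------------------------------------
    def weights(self, axisym: bool) -> np.ndarray:
        """Quadrature weights, including the 2*pi*x factor if axisymmetric."""
        if axisym:
            return self.qw * (2.0 * np.pi * self.qx[:, :, 0])
        return self.qw

    def interpolate(self, u: np.ndarray) -> np.ndarray:
        """Scalar dof vector -> values at quadrature points (m, nq)."""
        return np.einsum("ql,ml->mq", self.phi, u[self.cell_dofs])

    def interpolate_vec(self, u: np.ndarray) -> np.ndarray:
        """Vector dof vector (2*ndof) -> (m, nq, 2)."""
        ux = self.interpolate(u[: self.ndof])
        uy = self.interpolate(u[self.ndof :])
        return np.stack([ux, uy], axis=-1)

    def interpolate_grad(self, u: np.ndarray) -> np.ndarray:
        """Scalar dofs -> gradient at quad points (m, nq, 2)."""
        return np.einsum("mqld,ml->mqd", self.dphi, u[self.cell_dofs])

    def dofs_on(self, vertex_ids: np.ndarray, facet_list: np.ndarray | None = None):
        """Dof indices touching the given vertices (plus midpoints of facets)."""
        dofs = list(np.asarray(vertex_ids, dtype=np.int64))
        if self.degree == 2 and facet_list is not None and len(facet_list):
            key = {tuple(e): i for i, e in enumerate(map(tuple, self.edges))}
            nv = self.x.shape[0]
            for f in facet_list:
                dofs.append(nv + key[tuple(sorted(f))])
        return np.unique(np.asarray(dofs, dtype=np.int64))


def _scatter(cell_mat: np.ndarray, rows_dofs: np.ndarray, cols_dofs: np.ndarray, shape):
    """Accumulate per-cell dense blocks (m, a, b) into a CSR matrix."""
    m, a, b = cell_mat.shape
    r = np.repeat(rows_dofs, b, axis=1).ravel()
    c = np.tile(cols_dofs, (1, a)).ravel()
    return sp.coo_matrix((cell_mat.ravel(), (r, c)), shape=shape).tocsr()


def mass_matrix(basis: Basis, w: np.ndarray, coef=1.0) -> sp.csr_matrix:
    cw = w * coef if np.ndim(coef) else w * float(coef)
    cell = np.einsum("mq,qi,qj->mij", cw, basis.phi, basis.phi)
    return _scatter(cell, basis.cell_dofs, basis.cell_dofs, (basis.ndof, basis.ndof))


def stiffness_matrix(basis: Basis, w: np.ndarray, coef=1.0) -> sp.csr_matrix:
    cw = w * coef if np.ndim(coef) else w * float(coef)
    cell = np.einsum("mq,mqid,mqjd->mij", cw, basis.dphi, basis.dphi)
    return _scatter(cell, basis.cell_dofs, basis.cell_dofs, (basis.ndof, basis.ndof))


def load_vector(basis: Basis, w: np.ndarray, f_qp: np.ndarray) -> np.ndarray:
    """f_qp shape (m, nq) -> scalar load vector."""
    cell = np.einsum("mq,qi->mi", w * f_qp, basis.phi)
    out = np.zeros(basis.ndof)
    np.add.at(out, basis.cell_dofs, cell)
    return out


# --------------------------------------------------- vector / mixed operators


def _bmat(basis: Basis, q: int, axisym: bool):
    """Strain-displacement matrix at quad point q: (m, 4, 2*nloc) for strain
    components (e_xx, e_yy, gamma_xy, e_theta)."""
    m, nloc = basis.cells.shape[0], basis.nloc
    B = np.zeros((m, 4, 2 * nloc))
    d = basis.dphi[:, q]  # (m, nloc, 2)
    B[:, 0, :nloc] = d[:, :, 0]
    B[:, 1, nloc:] = d[:, :, 1]
    B[:, 2, :nloc] = d[:, :, 1]
    B[:, 2, nloc:] = d[:, :, 0]
    if axisym:
        x = basis.qx[:, q, 0]
        B[:, 3, :nloc] = basis.phi[q][None, :] / x[:, None]
    return B


def elasticity_D(mu, lam):
    """4x4 constitutive matrix for (e_xx, e_yy, gamma_xy, e_theta)."""
    D = np.array(
        [
            [2 * mu + lam, lam, 0.0, lam],
            [lam, 2 * mu + lam, 0.0, lam],
            [0.0, 0.0, mu, 0.0],
            [lam, lam, 0.0, 2 * mu + lam],
        ]
    )
    return D


def elastic_stiffness(basis: Basis, w: np.ndarray, D: np.ndarray, axisym: bool) -> sp.csr_matrix:
    """K = int B^T D B w over vector dofs (block layout)."""
    m, nloc = basis.cells.shape[0], basis.nloc
    K = np.zeros((m, 2 * nloc, 2 * nloc))
    for q in range(basis.nq):
        B = _bmat(basis, q, axisym)
        K += np.einsum("maf,ab,mbg->mfg", B, D, B) * w[:, q, None, None]
    vd = vector_dofs(basis)
    return _scatter(K, vd, vd, (2 * basis.ndof, 2 * basis.ndof))


def vector_dofs(basis: Basis) -> np.ndarray:
    """Per-cell vector dof indices (m, 2*nloc): x-dofs then y-dofs."""
    return np.hstack([basis.cell_dofs, basis.cell_dofs + basis.ndof])


def vector_mass(basis: Basis, w: np.ndarray, coef=1.0) -> sp.csr_matrix:
    M = mass_matrix(basis, w, coef)
    return sp.block_diag([M, M], format="csr")


def strain_at_qp(basis: Basis, u: np.ndarray, axisym: bool) -> np.ndarray:
    """Strains (e_xx, e_yy, gamma_xy, e_theta) at quad points: (m, nq, 4)."""
    ux, uy = u[: basis.ndof], u[basis.ndof :]
    gx = basis.interpolate_grad(ux)
    gy = basis.interpolate_grad(uy)
    out = np.empty((basis.cells.shape[0], basis.nq, 4))
    out[..., 0] = gx[..., 0]
    out[..., 1] = gy[..., 1]
    out[..., 2] = gx[..., 1] + gy[..., 0]
    if axisym:
        out[..., 3] = basis.interpolate(ux) / basis.qx[:, :, 0]
    else:
        out[..., 3] = 0.0
    return out


def internal_force(basis: Basis, w: np.ndarray, stress: np.ndarray, axisym: bool) -> np.ndarray:
    """f_i = int B_i^T sigma w for a per-qp stress (m, nq, 4)."""
    m, nloc = basis.cells.shape[0], basis.nloc
    f = np.zeros((m, 2 * nloc))
    for q in range(basis.nq):
        B = _bmat(basis, q, axisym)
        f += np.einsum("maf,ma->mf", B, stress[:, q] * w[:, q, None])
    out = np.zeros(2 * basis.ndof)
    np.add.at(out, vector_dofs(basis), f)
    return out


def divergence_matrix(
    vec_basis: Basis, p_basis: Basis, w: np.ndarray, axisym: bool
) -> sp.csr_matrix:
    """B[p, u] = int psi_p div(u) w  (axisym div includes u_x/x)."""
    m = vec_basis.cells.shape[0]
    nl_u, nl_p = vec_basis.nloc, p_basis.nloc
    cell = np.zeros((m, nl_p, 2 * nl_u))
    for q in range(vec_basis.nq):
        du = vec_basis.dphi[:, q]  # (m, nl_u, 2)
        pp = p_basis.phi[q]  # (nl_p,)
        wq = w[:, q]
        divx = du[:, :, 0]
        if axisym:
            divx = divx + vec_basis.phi[q][None, :] / vec_basis.qx[:, q, 0][:, None]
        cell[:, :, :nl_u] += wq[:, None, None] * pp[None, :, None] * divx[:, None, :]
        cell[:, :, nl_u:] += wq[:, None, None] * pp[None, :, None] * du[:, None, :, 1]
    return _scatter(
        cell, p_basis.cell_dofs, vector_dofs(vec_basis), (p_basis.ndof, 2 * vec_basis.ndof)
    )


def convection_matrix(basis: Basis, w: np.ndarray, a_qp: np.ndarray, rho: float) -> sp.csr_matrix:
    """C_ij = int rho (a . grad phi_j) phi_i w, applied per component."""
    adv = np.einsum("mqjd,mqd->mqj", basis.dphi, a_qp)  # (m, nq, nloc)
    cell = rho * np.einsum("mq,qi,mqj->mij", w, basis.phi, adv)
    C = _scatter(cell, basis.cell_dofs, basis.cell_dofs, (basis.ndof, basis.ndof))
    return sp.block_diag([C, C], format="csr")


# ------------------------------------------------------------------ facets


class FacetBasis:
    """Quadrature and traces on a set of mesh facets (vertex-pair edges).

    Normals are outward with respect to the supplied adjacent cells.
    """

    def __init__(self, basis: Basis, facets: np.ndarray, adj_cells: np.ndarray):
        self.basis = basis
        self.facets = np.asarray(facets, dtype=np.int64).reshape(-1, 2)
        self.adj = np.asarray(adj_cells, dtype=np.int64)
        x0 = basis.x[self.facets[:, 0]]
        x1 = basis.x[self.facets[:, 1]]
        tang = x1 - x0
        self.length = np.linalg.norm(tang, axis=1)
        n = np.stack([tang[:, 1], -tang[:, 0]], axis=-1) / self.length[:, None]
        # orient outward: away from adjacent cell centroid
        cent = basis.x[basis.cells[self.adj]].mean(axis=1)
        mid = 0.5 * (x0 + x1)
        flip = np.einsum("fd,fd->f", n, mid - cent) < 0
        n[flip] *= -1.0
        self.normal = n  # (F, 2)
        s = _EDGE_QP
        self.qx = x0[:, None, :] + s[None, :, None] * tang[:, None, :]  # (F, nq, 2)
        self.qw = self.length[:, None] * _EDGE_QW[None, :]
        # facet dof traces
        if basis.degree == 1:
            self.facet_dofs = self.facets.copy()
            self.phi = np.stack([1 - s, s], axis=-1)  # (nq, 2)
        else:
            key = {tuple(e): i for i, e in enumerate(map(tuple, basis.edges))}
            nv = basis.x.shape[0]
            mids = np.array([nv + key[tuple(sorted(f))] for f in self.facets])
            self.facet_dofs = np.column_stack([self.facets, mids])
            self.phi = np.stack(
                [(1 - s) * (1 - 2 * s), s * (2 * s - 1), 4 * s * (1 - s)], axis=-1
            )  # (nq, 3)
        self.nq = s.size
        # reference coordinates of facet quad points inside adjacent cells
        # (for evaluating cell gradients on the facet)
        xc = basis.x[basis.cells[self.adj, 0]]
        J = np.stack(
            [
                basis.x[basis.cells[self.adj, 1]] - xc,
                basis.x[basis.cells[self.adj, 2]] - xc,
            ],
            axis=-1,
        )
        Jinv = np.linalg.inv(J)
        self.ref_qp = np.einsum("fij,fqj->fqi", Jinv, self.qx - xc[:, None, :])

    def weights(self, axisym: bool) -> np.ndarray:
        if axisym:
            return self.qw * (2.0 * np.pi * self.qx[:, :, 0])
        return self.qw

    def trace(self, u: np.ndarray) -> np.ndarray:
        """Scalar dofs -> values at facet quad points (F, nq)."""
        return np.einsum("qi,fi->fq", self.phi, u[self.facet_dofs])

    def grad_from_cell(self, u: np.ndarray) -> np.ndarray:
        """Scalar dofs -> gradient at facet quad points evaluated from the
        adjacent cell's polynomial: (F, nq, 2)."""
        b = self.basis
        xi, eta = self.ref_qp[..., 0], self.ref_qp[..., 1]
        if b.degree == 1:
            dref = np.broadcast_to(_p1_dphi(), xi.shape + (3, 2))
        else:
            dref = _p2_dphi(xi, eta)
        dphi = np.einsum("fqld,fdi->fqli", dref, b._Jinv[self.adj])
        return np.einsum("fqli,fl->fqi", dphi, u[b.cell_dofs[self.adj]])

    def load(self, g_qp: np.ndarray, axisym: bool) -> np.ndarray:
        """Vector surface load: g_qp (F, nq, 2) -> vector load (2*ndof)."""
        w = self.weights(axisym)
        cell = np.einsum("fq,qi,fqd->fid", w, self.phi, g_qp)
        out = np.zeros(2 * self.basis.ndof)
        np.add.at(out, self.facet_dofs, cell[..., 0])
        np.add.at(out, self.facet_dofs + self.basis.ndof, cell[..., 1])
        return out

    def flux(self, u: np.ndarray, axisym: bool) -> float:
        """int u . n over the facet set (u a vector dof array)."""
        uq = np.stack(
            [self.trace(u[: self.basis.ndof]), self.trace(u[self.basis.ndof :])], axis=-1
        )
        w = self.weights(axisym)
        return float(np.einsum("fq,fqd,fd->", w, uq, self.normal))

    def measure(self, axisym: bool) -> float:
        return float(self.weights(axisym).sum())


# ------------------------------------------------------------ linear algebra


def condense(A: sp.csr_matrix, b: np.ndarray, fixed: np.ndarray, values: np.ndarray):
    """Eliminate Dirichlet dofs; returns (A_ff, b_f, free_idx, full_template)."""
    n = A.shape[0]
    mask = np.ones(n, dtype=bool)
    mask[fixed] = False
    free = np.nonzero(mask)[0]
    x = np.zeros(n)
    x[fixed] = values
    b_f = (b - A @ x)[free]
    A_ff = A[free][:, free]
    return A_ff, b_f, free, x


def solve_condensed(A, b, fixed, values):
    A_ff, b_f, free, x = condense(A, b, fixed, values)
    x[free] = spla.spsolve(A_ff.tocsc(), b_f)
    return x
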