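"""Poro-viscoelastic brain tissue solver.

Small-strain Biot poroelasticity (Biot coefficient 1, incompressible
constituents) with a Prony-series relaxation of the deviatoric (shear)
response:

    G_r(t) = G0 (1 - sum_k g_k (1 - exp(-t / tau_k))),   G0 = E / (2 (1 + nu))

The volumetric response is elastic (bulk modulus from E, nu). Displacement is
P2, pore pressure P1, backward-Euler in time; the Prony convolution uses the
standard per-term exponential-integrator recurrence for the internal deviatoric
stress variables, which is unconditionally stable and reproduces G_r exactly
for step-strain histories sampled at the stress level.

The momentum balance div(sigma) + f = rho * a is solved quasi-statically by
default (tissue inertia is negligible at cardiac frequencies and its omission
keeps partitioned FSI coupling free of added-mass instability); a
backward-difference inertia term can be enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .errors import SolverDivergenceError
from .geometry import Mesh
from .subdomain import Subdomain, dof_keys

#: unit vector of the volumetric part in (e_xx, e_yy, g_xy, e_theta) notation
_VOL = np.array([1.0, 1.0, 0.0, 1.0])


@dataclass(frozen=True)
class PoroViscoelasticMaterial:
    """Constitutive constants of the brain parenchyma.

    Defaults are the validated hydrocephalic-brain values: E = 584.4 Pa,
    nu = 0.35, permeability 4.08e-12 m^4/(N s), void ratio 0.2, Prony
    relaxation times (3.1, 27, 410) s with relaxation modulus 0.285.
    ``prony_mode`` resolves how the single printed modulus maps onto three
    terms: "per_term" applies 0.285 to each (sum 0.855), "total" divides it
    evenly (sum 0.285).
    """

    youngs_modulus: float = 584.4  # Pa
    poisson_ratio: float = 0.35
    permeability: float = 4.08e-12  # m^4/(N s) == m^2/(Pa s) Darcy coefficient
    void_ratio: float = 0.2
    density: float = 1000.0  # kg/m^3
    prony_relaxation_times: tuple = (3.1, 27.0, 410.0)  # s
    prony_modulus: float = 0.285
    prony_mode: str = "per_term"
    biot_alpha: float = 1.0

    def __post_init__(self):
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not (0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must be in (0, 0.5)")
        if self.permeability <= 0:
            raise ValueError("permeability must be positive")
        if any(t <= 0 for t in self.prony_relaxation_times):
            raise ValueError("relaxation times must be positive")
        if self.prony_mode not in ("per_term", "total"):
            raise ValueError("prony_mode must be 'per_term' or 'total'")
        if sum(self.prony_moduli) >= 1.0:
            raise ValueError("sum of Prony moduli must be < 1")

    @property
    def prony_moduli(self) -> tuple:
        n = len(self.prony_relaxation_times)
        if self.prony_mode == "per_term":
            return tuple(self.prony_modulus for _ in range(n))
        return tuple(self.prony_modulus / n for _ in range(n))

    @property
    def shear_modulus(self) -> float:
        """Instantaneous (input) shear modulus G0 = E / (2 (1 + nu))."""
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def bulk_modulus(self) -> float:
        return self.youngs_modulus / (3.0 * (1.0 - 2.0 * self.poisson_ratio))

    @property
    def long_term_shear_modulus(self) -> float:
        return self.shear_modulus * (1.0 - sum(self.prony_moduli))

    def elastic(self) -> "PoroViscoelasticMaterial":
        """Copy with the viscous (Prony) part switched off."""
        from dataclasses import replace

        return replace(self, prony_modulus=0.0)


def relaxation_modulus(t, material: PoroViscoelasticMaterial):
    """Shear relaxation modulus G_r(t) in Pa; accepts scalars or arrays."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    g = np.asarray(material.prony_moduli)
    tau = np.asarray(material.prony_relaxation_times)
    out = material.shear_modulus * (
        1.0 - np.sum(g[:, None] * (1.0 - np.exp(-t.ravel()[None, :] / tau[:, None])), axis=0)
    )
    return float(out[0]) if np.isscalar(t) or t.ndim == 0 else out.reshape(t.shape)


@dataclass
class SolidState:
    """Displacement, pore pressure and viscoelastic internal variables."""

    displacement: np.ndarray  # (2*nd,) m
    velocity: np.ndarray  # (2*nd,) m/s
    pore_pressure: np.ndarray  # (npp,) Pa
    cauchy_stress: np.ndarray  # (m, nq, 4) total stress, Pa
    prony_internal: list  # one (m, nq, 4) deviatoric stress per Prony term
    time: float
    converged: bool = True


class SolidSolver:
    """Quasi-static (optionally inertial) Biot + Prony solver on the brain
    region of a labeled mesh.

    Boundary-condition specs per facet label:
      ("fixed",) / ("fixed_x",) / ("fixed_y",)  displacement Dirichlet
      ("symmetry",)                             u_x = 0 (rotation axis)
      ("traction", g)                           surface traction, g=(tx, ty)
                                                constant or callable(t)
      ("normal_traction", s)                    traction s * n (s<0 pushes in)
      ("drained", p)                            pore-pressure Dirichlet
    FSI interface facets receive nodal forces via ``set_interface_forces``.
    """

    def __init__(
        self,
        mesh: Mesh,
        material: PoroViscoelasticMaterial | None = None,
        bc: dict | None = None,
        regions: tuple = ("brain",),
        inertia: bool = False,
        pin_dofs: tuple | None = None,
        interface_mode: str = "force",
    ):
        if interface_mode not in ("force", "displacement"):
            raise ValueError("interface_mode must be 'force' or 'displacement'")
        self.interface_mode = interface_mode
        self.mesh = mesh
        self.mat = material or PoroViscoelasticMaterial()
        self.bc = dict(bc or {})
        self.inertia = inertia
        self.axisym = mesh.axisymmetric
        self.sub = Subdomain(mesh, list(regions))
        self.Db = fem.Basis(self.sub.vertices, self.sub.cells, 2)  # displacement
        self.Pb = fem.Basis(self.sub.vertices, self.sub.cells, 1)  # pore pressure
        self.nd = self.Db.ndof
        self.npp = self.Pb.ndof
        self.disp_keys = dof_keys(self.Db, self.sub.vertex_gids)
        self.pin_dofs = pin_dofs  # (vector dof indices, values)

        ifac, _ = self.sub.facets("fsi_inner", "fsi_outer")
        self.interface_dofs = (
            self.Db.dofs_on(np.unique(ifac), ifac) if ifac.size else np.zeros(0, np.int64)
        )
        self._interface_forces: np.ndarray | None = None
        self._extra_load: np.ndarray | None = None

        nq, m = self.Db.nq, self.sub.cells.shape[0]
        self.d = np.zeros(2 * self.nd)
        self.d_prev = np.zeros(2 * self.nd)
        self.v = np.zeros(2 * self.nd)
        self.p = np.zeros(self.npp)
        self.q = [np.zeros((m, nq, 4)) for _ in self.mat.prony_moduli]
        self.eps_dev_old = np.zeros((m, nq, 4))
        self.time = 0.0
        self._dt = None
        self._lu = None

    # ----------------------------------------------------------- assembly
    def _gamma(self, dt: float) -> np.ndarray:
        """Per-term incremental shear moduli of the exponential recurrence."""
        g = np.asarray(self.mat.prony_moduli)
        tau = np.asarray(self.mat.prony_relaxation_times)
        x = dt / tau
        return self.mat.shear_modulus * g * (1.0 - np.exp(-x)) / x

    def prepare(self, dt: float):
        """Assemble and factorize the (constant-in-time) step operator."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        G_eff = self.mat.long_term_shear_modulus + float(self._gamma(dt).sum())
        lam_eff = self.mat.bulk_modulus - 2.0 * G_eff / 3.0
        w = self.Db.weights(self.axisym)
        wp = self.Pb.weights(self.axisym)
        K = fem.elastic_stiffness(self.Db, w, fem.elasticity_D(G_eff, lam_eff), self.axisym)
        B = fem.divergence_matrix(self.Db, self.Pb, w, self.axisym) * self.mat.biot_alpha
        H = fem.stiffness_matrix(self.Pb, wp, self.mat.permeability)
        A11 = K
        if self.inertia:
            self._Mv = fem.vector_mass(self.Db, w, self.mat.density)
            A11 = K + self._Mv / dt**2
        A = sp.bmat([[A11, -B.T], [B / dt, H]], format="csr")
        fixed, values = self._dirichlet()
        if self.interface_mode == "displacement" and self.interface_dofs.size:
            extra = np.concatenate([self.interface_dofs, self.interface_dofs + self.nd])
            fixed = np.concatenate([fixed, np.setdiff1d(extra, fixed)])
            values = np.concatenate([values, np.zeros(fixed.size - values.size)])
            order = np.argsort(fixed)
            fixed, values = fixed[order], values[order]
            self._ifpos_x = np.searchsorted(fixed, self.interface_dofs)
            self._ifpos_y = np.searchsorted(fixed, self.interface_dofs + self.nd)
        self._A = A
        self._K_eff = (G_eff, lam_eff)
        self._B = B
        self._fixed, self._fixvals = fixed, values
        A_ff, _, free, _ = fem.condense(A, np.zeros(A.shape[0]), fixed, values)
        self._free = free
        self._lu = spla.splu(A_ff.tocsc())
        self._dt = dt

    def _dirichlet(self):
        idx, val = [], []
        nd = self.nd

        def fix(dofs, x=False, y=False):
            if x:
                idx.append(dofs)
            if y:
                idx.append(dofs + nd)

        for name, spec in self.bc.items():
            specs = spec if isinstance(spec, list) else [spec]
            if name not in self.sub.facet_sets:
                continue
            facets, _ = self.sub.facet_sets[name]
            dofs = self.Db.dofs_on(np.unique(facets), facets)
            for s in specs:
                if s[0] == "fixed":
                    fix(dofs, x=True, y=True)
                elif s[0] == "fixed_x" or s[0] == "symmetry":
                    fix(dofs, x=True)
                elif s[0] == "fixed_y":
                    fix(dofs, y=True)
        # drained pore-pressure dofs (P1: vertex dofs only)
        pidx, pval = [], []
        for name, spec in self.bc.items():
            specs = spec if isinstance(spec, list) else [spec]
            if name not in self.sub.facet_sets:
                continue
            facets, _ = self.sub.facet_sets[name]
            for s in specs:
                if s[0] == "drained":
                    pd = np.unique(facets)
                    pidx.append(pd)
                    pval.append(np.full(pd.size, float(s[1])))
        fixed = [np.concatenate(idx)] if idx else []
        values = [np.zeros(sum(a.size for a in idx))] if idx else []
        if self.pin_dofs is not None:
            fixed.append(np.asarray(self.pin_dofs[0], dtype=np.int64))
            values.append(np.broadcast_to(self.pin_dofs[1], (len(self.pin_dofs[0]),)).astype(float))
        if pidx:
            fixed.append(2 * nd + np.concatenate(pidx))
            values.append(np.concatenate(pval))
        if fixed:
            fixed = np.concatenate(fixed)
            values = np.concatenate(values)
            fixed, first = np.unique(fixed, return_index=True)
            values = values[first]
        else:
            fixed = np.zeros(0, dtype=np.int64)
            values = np.zeros(0)
        return fixed, values

    def set_interface_forces(self, forces: np.ndarray | None):
        """(n_iface, 2) nodal forces aligned with ``interface_dofs``."""
        self._interface_forces = forces

    def set_interface_displacement(self, values: np.ndarray):
        """(n_iface, 2) Dirichlet interface displacement (displacement mode)."""
        if self.interface_mode != "displacement":
            raise RuntimeError("solver not in displacement interface mode")
        if self._lu is None:
            raise RuntimeError("call prepare(dt) before setting interface values")
        self._fixvals[self._ifpos_x] = values[:, 0]
        self._fixvals[self._ifpos_y] = values[:, 1]

    def set_extra_load(self, load: np.ndarray | None):
        """Additional assembled load vector (2*nd,) added to the momentum RHS
        (e.g. fluid pressure acting across a non-FSI patch such as the inlet)."""
        self._extra_load = load

    # ---------------------------------------------------------------- step
    def _history_stress(self, dt: float):
        """Deviatoric history contribution 2 sum_k (decay*q_k - gamma_k e_dev_old)."""
        gam = self._gamma(dt)
        tau = np.asarray(self.mat.prony_relaxation_times)
        h = np.zeros_like(self.eps_dev_old)
        for k, (qk, gk) in enumerate(zip(self.q, gam)):
            h += np.exp(-dt / tau[k]) * qk - gk * self.eps_dev_old
        h = 2.0 * h
        h[..., 2] *= 0.5  # slot 2 pairs with engineering shear: store sigma_xy
        return h

    def step(self, dt: float, t_new: float | None = None) -> SolidState:
        """Advance displacement, pore pressure and internal variables."""
        x = self.solve_step(dt, t_new)
        return self.commit_step(x, dt, t_new)

    def solve_step(self, dt: float, t_new: float | None = None) -> np.ndarray:
        """Solve one backward-Euler step from the committed history without
        committing it (used by FSI subiterations)."""
        if self._dt != dt or self._lu is None:
            self.prepare(dt)
        t_new = self.time + dt if t_new is None else t_new
        w = self.Db.weights(self.axisym)

        rhs_u = np.zeros(2 * self.nd)
        for name, spec in self.bc.items():
            specs = spec if isinstance(spec, list) else [spec]
            if name not in self.sub.facet_sets:
                continue
            facets, adj = self.sub.facet_sets[name]
            fb = fem.FacetBasis(self.Db, facets, adj)
            for s in specs:
                if s[0] == "traction":
                    g = np.asarray(s[1](t_new) if callable(s[1]) else s[1], dtype=float)
                    rhs_u += fb.load(np.broadcast_to(g, fb.qx.shape), self.axisym)
                elif s[0] == "normal_traction":
                    sval = float(s[1](t_new) if callable(s[1]) else s[1])
                    rhs_u += fb.load(sval * np.broadcast_to(fb.normal[:, None, :], fb.qx.shape), self.axisym)
        if self._interface_forces is not None and self.interface_dofs.size:
            rhs_u[self.interface_dofs] += self._interface_forces[:, 0]
            rhs_u[self.interface_dofs + self.nd] += self._interface_forces[:, 1]
        if getattr(self, "_extra_load", None) is not None:
            rhs_u += self._extra_load

        # viscoelastic history forces (subtract: internal stress on RHS)
        h = self._history_stress(dt)
        rhs_u -= fem.internal_force(self.Db, w, h, self.axisym)
        if self.inertia:
            rhs_u += self._Mv @ (2.0 * self.d - self.d_prev) / dt**2

        rhs_p = (self._B @ self.d) / dt
        rhs = np.concatenate([rhs_u, rhs_p])
        self._last_rhs = rhs

        x = np.zeros(self._A.shape[0])
        x[self._fixed] = self._fixvals
        b_f = (rhs - self._A @ x)[self._free]
        x[self._free] = self._lu.solve(b_f)
        # iterative refinement: the Biot saddle system spans ~14 orders of
        # magnitude (stiffness in Pa vs permeability in m^4/(N s)) and a single
        # LU pass leaves interface displacements with O(1e-10 m) noise
        x[self._free] += self._lu.solve((rhs - self._A @ x)[self._free])
        if not np.all(np.isfinite(x)):
            raise SolverDivergenceError("solid solve produced non-finite values")
        return x

    def commit_step(self, x: np.ndarray, dt: float, t_new: float | None = None) -> SolidState:
        """Accept a solved step: update fields and Prony internal variables."""
        t_new = self.time + dt if t_new is None else t_new
        d_new = x[: 2 * self.nd]
        p_new = x[2 * self.nd :]
        # update internal variables with the realized strain increment
        eps = fem.strain_at_qp(self.Db, d_new, self.axisym)
        tr = eps @ _VOL
        eps_dev = eps - (tr[..., None] / 3.0) * _VOL
        gam = self._gamma(dt)
        tau = np.asarray(self.mat.prony_relaxation_times)
        deps = eps_dev - self.eps_dev_old
        for k in range(len(self.q)):
            self.q[k] = np.exp(-dt / tau[k]) * self.q[k] + gam[k] * deps
        self.eps_dev_old = eps_dev

        self.d_prev = self.d
        self.v = (d_new - self.d) / dt
        self.d = d_new
        self.p = p_new
        self.time = t_new
        return self.state()

    # ------------------------------------------------------------- outputs
    def total_stress_qp(self) -> np.ndarray:
        """Total Cauchy stress (m, nq, 4): effective viscoelastic minus
        Biot pore-pressure contribution."""
        eps = fem.strain_at_qp(self.Db, self.d, self.axisym)
        tr = eps @ _VOL
        eps_dev = eps - (tr[..., None] / 3.0) * _VOL
        sig = (self.mat.bulk_modulus * tr[..., None]) * _VOL
        sig = sig + 2.0 * self.mat.long_term_shear_modulus * eps_dev
        for qk in self.q:
            sig = sig + 2.0 * qk
        # engineering-shear column stores sigma_xy directly: 2 G e_xy = G g_xy
        sig[..., 2] *= 0.5
        pq = self.Pb.interpolate(self.p)
        sig = sig - self.mat.biot_alpha * pq[..., None] * _VOL
        return sig

    def state(self) -> SolidState:
        return SolidState(
            displacement=self.d.copy(),
            velocity=self.v.copy(),
            pore_pressure=self.p.copy(),
            cauchy_stress=self.total_stress_qp(),
            prony_internal=[qk.copy() for qk in self.q],
            time=self.time,
        )

    def interface_traction(self, *facet_names: str) -> tuple[np.ndarray, np.ndarray]:
        """Total-stress traction sigma . n on the named facets (outward normal
        of the solid), evaluated from the adjacent cell's mean stress.
        Returns (tractions (F, 2), facet midpoints (F, 2))."""
        f, adj = self.sub.facets(*facet_names)
        if f.size == 0:
            raise ValueError(f"no facets named {facet_names} on the solid subdomain")
        fb = fem.FacetBasis(self.Db, f, adj)
        sig = self.total_stress_qp().mean(axis=1)[adj]  # (F, 4) cell-mean
        n = fb.normal
        tx = sig[:, 0] * n[:, 0] + sig[:, 2] * n[:, 1]
        ty = sig[:, 2] * n[:, 0] + sig[:, 1] * n[:, 1]
        mid = 0.5 * (self.Db.x[f[:, 0]] + self.Db.x[f[:, 1]])
        return np.column_stack([tx, ty]), mid

    def interface_compliance(self, dof_idx: np.ndarray) -> np.ndarray:
        """Dense interface compliance C[i, j] = displacement at vector dof i per
        unit nodal force at vector dof j (both from ``dof_idx``; x dofs as-is,
        y dofs offset by nd). Requires :meth:`prepare`; all dofs must be free.

        This is the exact linear interface response of the current step
        operator; its inverse is the interface stiffness used by the coupled
        solver's Robin condition."""
        if self._lu is None:
            raise RuntimeError("call prepare(dt) first")
        dof_idx = np.asarray(dof_idx, dtype=np.int64)
        if np.isin(dof_idx, self._fixed).any():
            raise ValueError("compliance requested at a Dirichlet-constrained dof")
        free = self._free
        pos_in_free = np.searchsorted(free, dof_idx)
        na = dof_idx.size
        C = np.empty((na, na))
        for start in range(0, na, 128):  # chunk to bound memory
            cols = np.arange(start, min(start + 128, na))
            rhs = np.zeros((free.size, cols.size))
            rhs[pos_in_free[cols], np.arange(cols.size)] = 1.0
            sol = self._lu.solve(rhs)
            sol += self._lu.solve(rhs - (self._A[free][:, free] @ sol))
            C[:, cols] = sol[pos_in_free]
        return C

    def interface_reactions(self, x: np.ndarray) -> np.ndarray:
        """Nodal reactions sum(sigma_S . n_S phi_i) at the interface dofs of a
        solved (uncommitted) step ``x``; the force the solid exerts on the
        fluid is the negative of this."""
        r = self._A @ x - self._last_rhs
        i = self.interface_dofs
        return np.column_stack([r[i], r[i + self.nd]])

    def interface_displacement(self) -> np.ndarray:
        """(n_iface, 2) displacement at the interface dofs."""
        i = self.interface_dofs
        return np.column_stack([self.d[i], self.d[i + self.nd]])

    def interface_velocity(self) -> np.ndarray:
        i = self.interface_dofs
        return np.column_stack([self.v[i], self.v[i + self.nd]])

    def viscous_dissipation_step(self) -> float:
        """Energy released by the internal variables over the last step when the
        deviatoric strain is frozen (relaxation-only loading); non-negative."""
        g0 = self.mat.shear_modulus
        out = 0.0
        w = self.Db.weights(self.axisym)
        tau = np.asarray(self.mat.prony_relaxation_times)
        dt = self._dt or 0.0
        for k, (qk, gk) in enumerate(zip(self.q, self.mat.prony_moduli)):
            if gk == 0:
                continue
            q_prev = qk / np.exp(-dt / tau[k]) if dt else qk
            e_prev = (q_prev**2).sum(-1) / (2 * g0 * gk)
            e_now = (qk**2).sum(-1) / (2 * g0 * gk)
            out += float((w * (e_prev - e_now)).sum())
        return out
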