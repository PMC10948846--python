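"""Incompressible Newtonian CSF solver on a moving (ALE) mesh.

Mixed Taylor-Hood (P2 velocity / P1 pressure) finite elements, backward-Euler
time stepping, and semi-implicit (Oseen) treatment of the ALE advection term
rho ((u - W) . grad) u with the mesh velocity W. Continuity carries the CSF
production source S in the ventricular compartment and is divergence-free in
the subarachnoid space. A sealed fluid compartment (complete aqueductal
stenosis) has no pressure-reference boundary; there the continuity equation
keeps the physical compressibility of water (bulk modulus ~2.2 GPa), which
both fixes the pressure level and keeps intermediate fluid solves well-posed
while the coupled interface converges. Compartments with a pressure outlet
stay exactly divergence-free.

Boundary condition types (per facet label):
  ("noslip",)              u = 0
  ("velocity", provider)   u prescribed (FSI interface; set per subiteration)
  ("flow", f)              plug flow normal to the patch; f(t) in ml/min,
                           positive INTO the domain; discrete flux exact
  ("pressure", p)          traction outlet -p n (p in Pa, value or callable)
  ("symmetry",)            u_x = 0 (axis of rotation)
  ("symmetry_y",)          u_y = 0 (used by channel benchmarks)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .errors import SolverDivergenceError
from .geometry import Mesh
from .subdomain import Subdomain, dof_keys
from .units import M3_S_TO_ML_MIN, ML_MIN_TO_M3_S

FLUID_REGIONS = ("ventricle_csf", "sas_csf")


@dataclass(frozen=True)
class FluidProperties:
    """CSF material constants (SI)."""

    density: float = 998.2  # kg/m^3
    viscosity: float = 1e-3  # kg/(m s)
    body_force: tuple = (0.0, 0.0)  # N/m^3, or callable(t) -> (fx, fy)
    bulk_modulus: float = 2.2e9  # Pa; storage term for sealed compartments

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass
class FluidState:
    """Velocity/pressure fields on the current mesh configuration."""

    u: np.ndarray  # (2*nu,) m/s, block layout
    p: np.ndarray  # (np,) Pa
    time: float
    coords: np.ndarray  # current vertex coordinates (m)
    mesh_velocity: np.ndarray  # (2*nu,) m/s
    converged: bool = True
    picard_residuals: list = field(default_factory=list)


def apply_production_source(mesh: Mesh, rate_ml_min: float) -> np.ndarray:
    """Uniform volumetric production S (1/s) per global-mesh cell, supported on
    the ventricular CSF region, with integral exactly the requested rate."""
    if rate_ml_min < 0:
        raise ValueError("production rate must be >= 0")
    S = np.zeros(mesh.cells.shape[0])
    if rate_ml_min == 0.0:
        return S
    vent = mesh.cells_in("ventricle_csf")
    if vent.size == 0:
        raise ValueError("mesh has no ventricle_csf region")
    vol_m3 = mesh.region_volume_ml("ventricle_csf") * 1e-6
    S[vent] = rate_ml_min * ML_MIN_TO_M3_S / vol_m3
    return S


class FluidSolver:
    """Navier-Stokes/ALE solver on the fluid regions of a labeled mesh."""

    def __init__(
        self,
        mesh: Mesh,
        props: FluidProperties | None = None,
        bc: dict | None = None,
        production_ml_min: float = 0.0,
        production_mode: str = "boundary",
        initial_pressure: float = 0.0,
        cfl_warn: float = 20.0,
        interface_mode: str = "velocity",
    ):
        if interface_mode not in ("traction", "velocity", "robin"):
            raise ValueError("interface_mode must be 'traction', 'velocity' or 'robin'")
        self.interface_mode = interface_mode
        self.mesh = mesh
        self.props = props or FluidProperties()
        self.bc = dict(bc or {})
        if production_mode not in ("boundary", "volumetric"):
            raise ValueError("production_mode must be 'boundary' or 'volumetric'")
        self.production_mode = production_mode
        self.production_ml_min = production_ml_min
        self.axisym = mesh.axisymmetric
        self.cfl_warn = cfl_warn

        regions = [r for r in FLUID_REGIONS if mesh.cells_in(r).size]
        self.sub = Subdomain(mesh, regions)
        self.ref_coords = self.sub.vertices.copy()
        self.coords = self.sub.vertices.copy()
        self._Vb = fem.Basis(self.coords, self.sub.cells, 2)
        self._Pb = fem.Basis(self.coords, self.sub.cells, 1)
        self.nu = self._Vb.ndof
        self.np_ = self._Pb.ndof
        self.u = np.zeros(2 * self.nu)
        self.p = np.full(self.np_, float(initial_pressure))
        self.W = np.zeros(2 * self.nu)
        self.time = 0.0
        self._prev_coords = self.coords.copy()
        self._prev_p = self.p.copy()
        self._last_dt = None

        self.vel_keys = dof_keys(self._Vb, self.sub.vertex_gids)
        self._interface_values: np.ndarray | None = None
        self._interface_forces: np.ndarray | None = None
        self._lu = None

        # interface dof bookkeeping (x-component indices; y = idx + nu)
        ifac, _ = self.sub.facets("fsi_inner", "fsi_outer")
        self.interface_dofs = (
            self._Vb.dofs_on(np.unique(ifac), ifac) if ifac.size else np.zeros(0, np.int64)
        )
        self._setup_compartments()

    # ------------------------------------------------------------ plumbing
    def _setup_compartments(self):
        """Connected components; sealed ones (no pressure outlet) get the
        compressible-storage continuity term, or a pressure pin if solid-walled."""
        n = self.coords.shape[0]
        e = self.sub.cells[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
        g = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        ncomp, labels = sp.csgraph.connected_components(g, directed=False)
        cell_comp = labels[self.sub.cells[:, 0]]
        pressure_vertices = set()
        for name, spec in self._bc_items():
            if spec[0] == "pressure" and name in self.sub.facet_sets:
                pressure_vertices.update(self.sub.facet_sets[name][0].ravel().tolist())
        if self.interface_mode in ("traction", "robin"):
            # a Neumann/Robin interface fixes the pressure level too
            ifac, _ = self.sub.facets("fsi_inner", "fsi_outer")
            pressure_vertices.update(np.unique(ifac).tolist())
        open_comps = {int(labels[v]) for v in pressure_vertices}
        self._compress_cells = np.nonzero(~np.isin(cell_comp, list(open_comps)))[0]
        self._pressure_pins = []
        vent_cells = set(self.sub.cells_in("ventricle_csf").tolist())
        # fully Dirichlet non-ventricular compartments: pin one pressure dof
        if len(self._compress_cells):
            comp_of_compress = set(cell_comp[self._compress_cells].tolist())
            for c in list(comp_of_compress):
                cells_c = np.nonzero(cell_comp == c)[0]
                if not any(cc in vent_cells for cc in cells_c):
                    self._pressure_pins.append(int(self.sub.cells[cells_c[0], 0]))
                    self._compress_cells = np.setdiff1d(self._compress_cells, cells_c)

    def _bc_items(self):
        """Flattened (facet name, spec) pairs; a facet may carry several specs
        (e.g. a pressure outlet combined with a symmetry constraint)."""
        for name, spec in self.bc.items():
            if isinstance(spec, list):
                for s in spec:
                    yield name, s
            else:
                yield name, spec

    def set_interface_velocity(self, values: np.ndarray | None):
        """(n_iface, 2) velocities aligned with ``interface_dofs``."""
        self._interface_values = values

    def set_interface_traction(self, forces: np.ndarray | None):
        """(n_iface, 2) nodal interface forces (traction mode)."""
        self._interface_forces = forces

    def _interface_force_vector(self) -> np.ndarray:
        out = np.zeros(2 * self.nu)
        if self._interface_forces is not None and self.interface_dofs.size:
            out[self.interface_dofs] = self._interface_forces[:, 0]
            out[self.interface_dofs + self.nu] = self._interface_forces[:, 1]
        return out

    def set_interface_compliance(
        self, compliance: np.ndarray, dof_idx: np.ndarray, rhs_c: np.ndarray
    ):
        """Compliance-constrained interface for strongly coupled FSI.

        The step system is augmented with the interface nodal forces f (acting
        on the solid; the fluid receives -f) and the solid's exact linear
        interface response as a constraint,

            C f - dt u_Gamma = d_Gamma^n - d_part,

        where ``compliance`` is the dense (na, na) solid interface compliance,
        ``dof_idx`` the global velocity dof index of each interface unknown
        (x dofs as-is, y dofs offset by ndof) and ``rhs_c`` the constraint
        right-hand side for the current subiteration."""
        self._robin = (
            np.asarray(compliance),
            np.asarray(dof_idx, dtype=np.int64),
            np.asarray(rhs_c),
        )

    def set_interface_constraint_rhs(self, rhs_c: np.ndarray):
        self._robin = (self._robin[0], self._robin[1], np.asarray(rhs_c))

    def move_mesh(self, new_coords: np.ndarray, dt: float, midpoint_disp: np.ndarray | None = None):
        """Adopt externally computed mesh coordinates; W by backward difference.

        ``midpoint_disp`` optionally carries the P2 edge-dof displacement of the
        harmonic extension (vertices + midpoints, block layout, total from the
        reference configuration)."""
        old_dof_x = self._dof_positions()
        self.coords = np.asarray(new_coords, dtype=float)
        try:
            self._Vb = fem.Basis(self.coords, self.sub.cells, 2)
            self._Pb = fem.Basis(self.coords, self.sub.cells, 1)
        except ValueError as exc:
            raise SolverDivergenceError(f"fluid mesh tangled: {exc}") from exc
        if midpoint_disp is not None:
            new_dof_x = np.column_stack(
                [self.ref_dof_x[:, 0] + midpoint_disp[: self.nu],
                 self.ref_dof_x[:, 1] + midpoint_disp[self.nu :]]
            )
        else:
            new_dof_x = self._dof_positions()
        W = (new_dof_x - old_dof_x) / dt
        self.W = np.concatenate([W[:, 0], W[:, 1]])

    @property
    def ref_dof_x(self) -> np.ndarray:
        if not hasattr(self, "_ref_dof_x"):
            self._ref_dof_x = fem.Basis(self.ref_coords, self.sub.cells, 2).dof_x
        return self._ref_dof_x

    def _dof_positions(self):
        return self._Vb.dof_x.copy()

    def _facet_basis(self, *names, space=None):
        f, adj = self.sub.facets(*names)
        return fem.FacetBasis(space or self._Vb, f, adj) if f.size else None

    # ----------------------------------------------------------- dirichlet
    def _dirichlet(self, t: float):
        """Velocity Dirichlet dofs and values; order encodes priority."""
        nu = self.nu
        idx, val = [], []

        def fix(dofs, vx=None, vy=None):
            if vx is not None:
                idx.append(dofs)
                val.append(np.broadcast_to(vx, dofs.shape).astype(float))
            if vy is not None:
                idx.append(dofs + nu)
                val.append(np.broadcast_to(vy, dofs.shape).astype(float))

        for name, spec in self._bc_items():
            if name not in self.sub.facet_sets or spec[0] != "flow":
                continue
            facets, adj = self.sub.facet_sets[name]
            fb = fem.FacetBasis(self._Vb, facets, adj)
            dofs = self._Vb.dofs_on(np.unique(facets), facets)
            # per-dof outward normal (averaged over adjacent facets)
            nrm = np.zeros((nu, 2))
            for k in range(fb.facet_dofs.shape[1]):
                np.add.at(nrm, fb.facet_dofs[:, k], fb.normal * fb.length[:, None])
            nn = np.linalg.norm(nrm[dofs], axis=1)
            nhat = nrm[dofs] / np.where(nn > 0, nn, 1.0)[:, None]
            q = float(spec[1](t) if callable(spec[1]) else spec[1]) * ML_MIN_TO_M3_S
            area = fb.measure(self.axisym)
            v = -nhat * (q / area)  # plug, into the domain for q > 0
            # rescale so the discrete facet flux equals q exactly
            trial = np.zeros(2 * nu)
            trial[dofs] = v[:, 0]
            trial[dofs + nu] = v[:, 1]
            flux = fb.flux(trial, self.axisym)
            if abs(flux) > 1e-30:
                v *= (-q) / flux
            fix(dofs, v[:, 0], v[:, 1])

        for name, spec in self._bc_items():
            if name not in self.sub.facet_sets:
                continue
            facets, _ = self.sub.facet_sets[name]
            dofs = self._Vb.dofs_on(np.unique(facets), facets)
            kind = spec[0]
            if kind == "velocity":
                if name in ("fsi_inner", "fsi_outer"):
                    continue  # handled via interface values below
                v = spec[1](t, self._Vb.dof_x[dofs])
                fix(dofs, v[:, 0], v[:, 1])

        if self._interface_values is not None and self.interface_dofs.size:
            fix(self.interface_dofs, self._interface_values[:, 0], self._interface_values[:, 1])

        for name, spec in self._bc_items():
            if name not in self.sub.facet_sets:
                continue
            facets, _ = self.sub.facet_sets[name]
            dofs = self._Vb.dofs_on(np.unique(facets), facets)
            if spec[0] == "noslip":
                fix(dofs, 0.0, 0.0)
        for name, spec in self._bc_items():
            if name not in self.sub.facet_sets:
                continue
            facets, _ = self.sub.facet_sets[name]
            dofs = self._Vb.dofs_on(np.unique(facets), facets)
            if spec[0] == "symmetry":
                fix(dofs, 0.0, None)
            elif spec[0] == "symmetry_y":
                fix(dofs, None, 0.0)

        if idx:
            idx = np.concatenate(idx)
            val = np.concatenate(val)
            # later entries override earlier ones
            order = np.arange(idx.size)
            uniq, last = {}, {}
            for i in order:
                uniq[int(idx[i])] = val[i]
            fixed = np.fromiter(uniq.keys(), dtype=np.int64)
            values = np.fromiter(uniq.values(), dtype=float)
        else:
            fixed = np.zeros(0, dtype=np.int64)
            values = np.zeros(0)
        # pressure pins appended at offset 2*nu
        if self._pressure_pins:
            fixed = np.concatenate([fixed, 2 * nu + np.asarray(self._pressure_pins)])
            values = np.concatenate([values, np.zeros(len(self._pressure_pins))])
        return fixed, values

    # ---------------------------------------------------------------- step
    def step(self, dt: float, n_picard: int = 1, reassemble: bool = True) -> FluidState:
        """Advance one backward-Euler step on the current mesh configuration."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        t_new = self.time + dt
        Vb, Pb = self._Vb, self._Pb
        w = Vb.weights(self.axisym)
        mu, rho = self.props.viscosity, self.props.density

        A = fem.elastic_stiffness(Vb, w, fem.elasticity_D(mu, 0.0), self.axisym)
        Mv = fem.vector_mass(Vb, w, rho)
        B = fem.divergence_matrix(Vb, Pb, w, self.axisym)
        # compressible storage on sealed ventricular cells
        wp = self._Pb.weights(self.axisym)
        cmask = np.zeros(self.sub.cells.shape[0])
        if len(self._compress_cells):
            cmask[self._compress_cells] = 1.0 / self.props.bulk_modulus
        Mp = fem.mass_matrix(Pb, wp * cmask[:, None], 1.0)

        a_qp = Vb.interpolate_vec(self.u - self.W)
        self._check_cfl(a_qp, dt)
        C = fem.convection_matrix(Vb, w, a_qp, rho)

        f = self.props.body_force(t_new) if callable(self.props.body_force) else self.props.body_force
        rhs_u = (Mv @ self.u) / dt
        if any(abs(c) > 0 for c in f):
            rhs_u[: self.nu] += fem.load_vector(Vb, w, np.full(w.shape, f[0]))
            rhs_u[self.nu :] += fem.load_vector(Vb, w, np.full(w.shape, f[1]))
        for name, spec in self._bc_items():
            if spec[0] == "pressure" and name in self.sub.facet_sets:
                fb = self._facet_basis(name)
                pv = float(spec[1](t_new) if callable(spec[1]) else spec[1])
                rhs_u += fb.load(-pv * np.broadcast_to(fb.normal[:, None, :], fb.qx.shape), self.axisym)

        rhs_p = (Mp @ self.p) / dt
        if self.production_mode == "volumetric" and self.production_ml_min > 0:
            vent = self.sub.cells_in("ventricle_csf")
            vol = float(wp[vent].sum())
            Sval = self.production_ml_min * ML_MIN_TO_M3_S / vol
            sfield = np.zeros(wp.shape)
            sfield[vent] = Sval
            rhs_p += fem.load_vector(Pb, wp, sfield)

        K = sp.bmat([[Mv / dt + A + C, -B.T], [B, Mp / dt]], format="csr")
        rhs_base = np.concatenate([rhs_u, rhs_p])
        rhs = rhs_base.copy()
        if self.interface_mode == "traction":
            rhs[: 2 * self.nu] += self._interface_force_vector()
        elif self.interface_mode == "robin" and getattr(self, "_robin", None) is not None:
            Cm, idx, rhs_c = self._robin
            na = idx.size
            # scale constraint rows toward the momentum-row magnitude to keep
            # the direct solve accurate at micrometre interface displacements
            self._cscale = 1.0 / max(float(np.abs(Cm).max()), 1e-30)
            N = sp.coo_matrix(
                (np.ones(na), (idx, np.arange(na))), shape=(K.shape[0], na)
            ).tocsr()
            K = sp.bmat(
                [[K, N], [-dt * self._cscale * N.T, sp.csr_matrix(self._cscale * Cm)]],
                format="csr",
            )
            rhs = np.concatenate([rhs, self._cscale * rhs_c])
            rhs_base = np.concatenate([rhs_base, np.zeros(na)])
        fixed, values = self._dirichlet(t_new)

        residuals = []
        u_iter = self.u.copy()
        for it in range(max(1, n_picard)):
            if it > 0:  # refresh advection with the new velocity
                a_qp = Vb.interpolate_vec(u_iter - self.W)
                C = fem.convection_matrix(Vb, w, a_qp, rho)
                K = sp.bmat([[Mv / dt + A + C, -B.T], [B, Mp / dt]], format="csr")
            A_ff, b_f, free, x = fem.condense(K, rhs, fixed, values)
            lu = spla.splu(A_ff.tocsc())
            x[free] = lu.solve(b_f)
            x[free] += lu.solve((rhs - K @ x)[free])  # one refinement pass
            if not np.all(np.isfinite(x)):
                raise SolverDivergenceError("fluid solve produced non-finite values", residuals)
            du = np.linalg.norm(x[: 2 * self.nu] - u_iter) / max(np.linalg.norm(x[: 2 * self.nu]), 1e-30)
            residuals.append(du)
            u_iter = x[: 2 * self.nu]
            p_iter = x[2 * self.nu : 2 * self.nu + self.np_]
            self._interface_force_solution = x[2 * self.nu + self.np_ :]
            if du < 1e-10:
                break
        # cache for cheap interface re-solves within an FSI subiteration
        self._cache = dict(K=K, rhs=rhs, rhs_base=rhs_base, lu=lu, free=free)

        self._prev_p = self.p.copy()
        self._prev_coords_step = self._prev_coords
        self._prev_coords = self.coords.copy()
        self._last_dt = dt
        self.u, self.p, self.time = u_iter, p_iter, t_new
        return self.state(residuals)

    def resolve_interface(self, values: np.ndarray) -> FluidState:
        """Re-solve the current step with updated interface velocities (same
        matrix factorization; Dirichlet set unchanged)."""
        self.set_interface_velocity(values)
        fixed, vals = self._dirichlet(self.time)
        c = self._cache
        n = c["K"].shape[0]
        x = np.zeros(n)
        x[fixed] = vals
        b_f = (c["rhs"] - c["K"] @ x)[c["free"]]
        x[c["free"]] = c["lu"].solve(b_f)
        self.u = x[: 2 * self.nu]
        self.p = x[2 * self.nu :]
        return self.state([])

    def resolve_interface_traction(self, forces: np.ndarray) -> FluidState:
        """Re-solve the current step with updated interface nodal forces
        (traction mode; same factorization)."""
        self.set_interface_traction(forces)
        c = self._cache
        rhs = c["rhs_base"].copy()
        rhs[: 2 * self.nu] += self._interface_force_vector()
        c["rhs"] = rhs
        fixed, vals = self._dirichlet(self.time)
        x = np.zeros(c["K"].shape[0])
        x[fixed] = vals
        b_f = (rhs - c["K"] @ x)[c["free"]]
        x[c["free"]] = c["lu"].solve(b_f)
        self.u = x[: 2 * self.nu]
        self.p = x[2 * self.nu :]
        return self.state([])

    def resolve_interface_constraint(self, rhs_c: np.ndarray) -> FluidState:
        """Re-solve the current step with an updated compliance-constraint
        right-hand side (same matrix factorization)."""
        self.set_interface_constraint_rhs(rhs_c)
        c = self._cache
        na = rhs_c.size
        rhs = c["rhs_base"].copy()
        rhs[-na:] = self._cscale * rhs_c
        c["rhs"] = rhs
        fixed, vals = self._dirichlet(self.time)
        x = np.zeros(c["K"].shape[0])
        x[fixed] = vals
        b_f = (rhs - c["K"] @ x)[c["free"]]
        x[c["free"]] = c["lu"].solve(b_f)
        x[c["free"]] += c["lu"].solve((rhs - c["K"] @ x)[c["free"]])
        self.u = x[: 2 * self.nu]
        self.p = x[2 * self.nu : 2 * self.nu + self.np_]
        self._interface_force_solution = x[2 * self.nu + self.np_ :]
        return self.state([])

    def interface_velocity(self) -> np.ndarray:
        """(n_iface, 2) fluid velocity at the interface dofs."""
        i = self.interface_dofs
        return np.column_stack([self.u[i], self.u[i + self.nu]])

    def state(self, residuals=None) -> FluidState:
        return FluidState(
            u=self.u.copy(),
            p=self.p.copy(),
            time=self.time,
            coords=self.coords.copy(),
            mesh_velocity=self.W.copy(),
            picard_residuals=list(residuals or []),
        )

    def _check_cfl(self, a_qp, dt):
        amax = float(np.sqrt((a_qp**2).sum(-1)).max()) if a_qp.size else 0.0
        h = np.sqrt(self._Vb.detJ).min()
        if h > 0 and amax * dt / h > self.cfl_warn:
            warnings.warn(
                f"advective Courant number {amax * dt / h:.1f} exceeds {self.cfl_warn}",
                RuntimeWarning,
                stacklevel=2,
            )

    # ------------------------------------------------------------- outputs
    def interface_reactions(self) -> tuple[np.ndarray, np.ndarray]:
        """Variationally consistent nodal forces the fluid exerts on the solid
        at interface dofs: -(K x - rhs) restricted to interface rows.
        Returns (forces (n_iface, 2), dof keys list index array)."""
        c = self._cache
        x = np.concatenate([self.u, self.p])
        r = c["K"] @ x - c["rhs"]
        i = self.interface_dofs
        return -np.column_stack([r[i], r[i + self.nu]]), i

    def mean_pressure(self, region: str | None = "ventricle_csf") -> float:
        """Volume-averaged pressure over a region (Pa)."""
        wp = self._Pb.weights(self.axisym)
        cells = self.sub.cells_in(region) if region and self.sub.cells_in(region).size else slice(None)
        pq = self._Pb.interpolate(self.p)
        return float((wp[cells] * pq[cells]).sum() / wp[cells].sum())

    def boundary_flux_ml_min(self, *names: str) -> float:
        """Net outward volume flux through the named facet sets, ml/min."""
        fb = self._facet_basis(*names)
        if fb is None:
            return 0.0
        return fb.flux(self.u, self.axisym) * M3_S_TO_ML_MIN

    def fluid_volume_m3(self, coords=None) -> float:
        b = fem.Basis(self.coords if coords is None else coords, self.sub.cells, 1)
        return float(b.weights(self.axisym).sum())

    def global_mass_balance(self) -> float:
        """|net patch outflow + dV/dt - production - storage release| in ml/min.

        Interface motion enters through the geometric dV/dt, so this measures
        the consistency of boundary data, production, storage and mesh motion
        (geometric conservation); it is not the trivially-satisfied discrete
        continuity identity."""
        patch_names = sorted({
            n for n, s in self._bc_items()
            if s[0] in ("flow", "pressure", "noslip", "velocity", "symmetry", "symmetry_y")
            and n not in ("fsi_inner", "fsi_outer")
        })
        q_out = self.boundary_flux_ml_min(*patch_names)
        dvdt = 0.0
        if self._last_dt:
            dvdt = (
                (self.fluid_volume_m3() - self.fluid_volume_m3(self._prev_coords_step))
                / self._last_dt
                * M3_S_TO_ML_MIN
            )
        prod = self.production_ml_min if self.production_mode == "volumetric" else 0.0
        storage = 0.0
        if len(self._compress_cells) and self._last_dt:
            wp = self._Pb.weights(self.axisym)
            dp = self._Pb.interpolate(self.p - self._prev_p)
            storage = -float(
                (wp[self._compress_cells] * dp[self._compress_cells]).sum()
                / self.props.bulk_modulus
                / self._last_dt
            ) * M3_S_TO_ML_MIN
        return abs(q_out + dvdt - prod - storage)


def step_fluid(solver: FluidSolver, dt: float, n_picard: int = 1) -> FluidState:
    """Functional wrapper over :meth:`FluidSolver.step`."""
    return solver.step(dt, n_picard=n_picard)
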