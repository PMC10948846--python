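"""CSF (Navier-Stokes/ALE) solver against closed-form channel flows and
conservation diagnostics."""

import numpy as np
import pytest

from cranioflow.fluid import FluidProperties, FluidSolver, apply_production_source, step_fluid
from cranioflow.geometry import HeadGeometry, generate_mesh, rectangle_mesh

RHO, MU = 998.2, 1e-3


def _channel_bc(p_in, p_out=0.0):
    return {
        "left": [("pressure", p_in), ("symmetry_y",)],
        "right": [("pressure", p_out), ("symmetry_y",)],
        "top": ("noslip",),
        "bottom": ("noslip",),
    }


def _march_to_steady(solver, dt=0.05, steps=40):
    for _ in range(steps):
        st = step_fluid(solver, dt)
    return st


class TestPoiseuille:
    def test_profile_and_flux_match_closed_form(self):
        L, H, Pin = 10e-3, 1e-3, 10.0
        mesh = rectangle_mesh(10.0, 1.0, 30, 8)
        s = FluidSolver(mesh, FluidProperties(), _channel_bc(Pin), cfl_warn=1e9)
        _march_to_steady(s)
        G = Pin / L
        ys, xs = s._Vb.dof_x[:, 1], s._Vb.dof_x[:, 0]
        mid = np.abs(xs - L / 2) < 1e-5
        u_ex = G / (2 * MU) * ys[mid] * (H - ys[mid])
        err = np.abs(s.u[: s.nu][mid] - u_ex).max() / u_ex.max()
        assert err < 0.02
        q_ex = G * H**3 / (12 * MU) * 60e6  # ml/min per metre depth
        assert s.boundary_flux_ml_min("right") == pytest.approx(q_ex, rel=0.02)

    def test_steady_rigid_mass_balance_below_1e6_ml_min(self):
        mesh = rectangle_mesh(10.0, 1.0, 20, 6)
        s = FluidSolver(mesh, FluidProperties(), _channel_bc(5.0), cfl_warn=1e9)
        _march_to_steady(s)
        assert s.global_mass_balance() < 1e-6


class TestWomersley:
    def _run(self, nx, ny, nsteps):
        H, L = 1e-3, 4e-3
        om, G = 2 * np.pi, 50.0
        mesh = rectangle_mesh(4.0, 1.0, nx, ny)
        props = FluidProperties(body_force=lambda t: (G * np.cos(om * t), 0.0))
        s = FluidSolver(mesh, props, _channel_bc(0.0), cfl_warn=1e9)
        T = 1.0
        for _ in range(4 * nsteps):
            s.step(T / nsteps)
        lam = np.sqrt(1j * om / (MU / RHO))
        h = H / 2
        ys, xs = s._Vb.dof_x[:, 1], s._Vb.dof_x[:, 0]
        mid = np.abs(xs - L / 2) < 1e-6
        yp = ys[mid] - h
        u_ex = np.real(
            G / (1j * RHO * om) * (1 - np.cosh(lam * yp) / np.cosh(lam * h)) * np.exp(1j * om * s.time)
        )
        amp = np.abs(G / (1j * RHO * om) * (1 - 1 / np.cosh(lam * h)))
        return np.abs(s.u[: s.nu][mid] - u_ex).max() / amp

    def test_profile_matches_series_solution_within_5_percent(self):
        assert self._run(12, 16, 48) < 0.05

    def test_error_decreases_under_refinement(self):
        coarse = self._run(8, 8, 32)
        fine = self._run(12, 16, 64)
        assert fine < coarse


class TestQuiescentAndInvariance:
    def test_no_forcing_decays_to_rest_at_outlet_pressure(self):
        mesh = rectangle_mesh(4.0, 1.0, 8, 4)
        p_ref = 100.0
        bc = {"left": ("noslip",), "top": ("noslip",), "bottom": ("noslip",),
              "right": ("pressure", p_ref)}
        s = FluidSolver(mesh, FluidProperties(), bc, initial_pressure=p_ref, cfl_warn=1e9)
        s.u = np.zeros(2 * s.nu)
        for _ in range(20):
            s.step(0.05)
        assert np.abs(s.u).max() < 1e-12
        assert np.allclose(s.p, p_ref, atol=1e-8)

    def test_galilean_frame_shift_with_matching_mesh_velocity(self):
        # W equal to a rigid translation velocity: the solution is the
        # uniform translation itself, with no pressure gradient
        mesh = rectangle_mesh(4.0, 1.0, 8, 4)
        U = 0.01
        bc = {name: ("velocity", lambda t, x: np.column_stack([np.full(len(x), U), np.zeros(len(x))]))
              for name in ("left", "right", "top", "bottom")}
        s = FluidSolver(mesh, FluidProperties(), bc, cfl_warn=1e9)
        s.u[: s.nu] = U
        s.W[: s.nu] = U
        s.step(0.01)
        assert np.allclose(s.u[: s.nu], U, atol=1e-10)
        assert np.ptp(s.p) < 1e-8


class TestProductionSource:
    def test_integral_equals_requested_rate(self, coarse_mesh):
        S = apply_production_source(coarse_mesh, 0.35)
        vent = coarse_mesh.cells_in("ventricle_csf")
        vol_m3 = coarse_mesh.region_volume_ml("ventricle_csf") * 1e-6
        total_ml_min = S[vent][0] * vol_m3 * 60e6
        assert total_ml_min == pytest.approx(0.35, rel=1e-10)
        assert np.all(S[np.setdiff1d(np.arange(len(S)), vent)] == 0)

    def test_zero_rate_gives_identically_zero_field(self, coarse_mesh):
        assert not apply_production_source(coarse_mesh, 0.0).any()

    def test_smaller_ventricle_has_proportionally_larger_density(self):
        m1 = generate_mesh(HeadGeometry(ventricle_radius=20.0), "coarse")
        m2 = generate_mesh(HeadGeometry(ventricle_radius=16.0), "coarse")
        s1 = apply_production_source(m1, 0.35)[m1.cells_in("ventricle_csf")][0]
        s2 = apply_production_source(m2, 0.35)[m2.cells_in("ventricle_csf")][0]
        v1 = m1.region_volume_ml("ventricle_csf")
        v2 = m2.region_volume_ml("ventricle_csf")
        assert s2 / s1 == pytest.approx(v1 / v2, rel=1e-9)

    def test_negative_rate_rejected(self, coarse_mesh):
        with pytest.raises(ValueError):
            apply_production_source(coarse_mesh, -1.0)

    def test_volumetric_mode_satisfies_sourced_continuity(self):
        # sealed ventricle, volumetric production, rigid walls: the stored
        # volume must equal production (compressible-storage bookkeeping)
        mesh = generate_mesh(HeadGeometry(shunt_half_angle_deg=0.0), "coarse")
        bc = {"inlet": ("noslip",), "dura": ("noslip",), "axis": ("symmetry",),
              "spinal_outlet": ("flow", 0.0), "sinus_outlet": ("pressure", 0.0)}
        s = FluidSolver(mesh, FluidProperties(), bc, production_ml_min=0.35,
                        production_mode="volumetric", interface_mode="velocity", cfl_warn=1e9)
        s.set_interface_velocity(np.zeros((s.interface_dofs.size, 2)))
        s.step(0.05)
        assert s.global_mass_balance() < 1e-6


class TestErrors:
    def test_nonpositive_dt_rejected(self):
        mesh = rectangle_mesh(2.0, 1.0, 4, 2)
        s = FluidSolver(mesh, bc={"left": ("pressure", 0.0)})
        with pytest.raises(ValueError):
            s.step(0.0)

    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0)
        with pytest.raises(ValueError):
            FluidProperties(viscosity=0.0)

    def test_cfl_warning_emitted(self):
        mesh = rectangle_mesh(10.0, 1.0, 30, 8)
        s = FluidSolver(mesh, FluidProperties(), _channel_bc(50.0), cfl_warn=0.01)
        s.step(0.05)
        with pytest.warns(RuntimeWarning, match="Courant"):
            s.step(0.05)
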