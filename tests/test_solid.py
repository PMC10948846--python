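"""Poro-viscoelastic solid: Prony relaxation, Terzaghi consolidation,
elastic limits and traction extraction."""

from dataclasses import replace

import numpy as np
import pytest

from cranioflow.geometry import rectangle_mesh
from cranioflow.solid import PoroViscoelasticMaterial, SolidSolver, relaxation_modulus

MAT = PoroViscoelasticMaterial()


def _homogeneous_shear_solver(gamma0, mat=MAT, n=3):
    """All dofs pinned to u_x = gamma0*y: exact homogeneous simple shear."""
    mesh = rectangle_mesh(10.0, 10.0, n, n, region="brain")
    sol = SolidSolver(mesh, mat, bc={})
    pins = np.concatenate([np.arange(sol.nd), np.arange(sol.nd) + sol.nd])
    vals = np.concatenate([gamma0 * sol.Db.dof_x[:, 1], np.zeros(sol.nd)])
    sol.pin_dofs = (pins, vals)
    return sol


class TestRelaxationModulus:
    def test_instantaneous_value_is_input_shear_modulus(self):
        # G0 = E / (2 (1 + nu)) = 584.4 / 2.7
        assert MAT.shear_modulus == pytest.approx(584.4 / 2.7)
        assert relaxation_modulus(0.0, MAT) == pytest.approx(216.4444, abs=1e-3)

    def test_long_time_limit(self):
        # three terms of 0.285 each leave a 0.145 fraction
        assert relaxation_modulus(1e9, MAT) / MAT.shear_modulus == pytest.approx(0.145)

    def test_strictly_decreasing_and_convex(self):
        t = np.linspace(0, 1500, 400)
        g = relaxation_modulus(t, MAT)
        assert np.all(np.diff(g) < 0)
        assert np.all(np.diff(g, 2) > -1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            relaxation_modulus(-1.0, MAT)

    def test_total_mode_splits_printed_modulus(self):
        tot = PoroViscoelasticMaterial(prony_mode="total")
        assert sum(tot.prony_moduli) == pytest.approx(0.285)
        assert sum(MAT.prony_moduli) == pytest.approx(0.855)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PoroViscoelasticMaterial(poisson_ratio=0.5)
        with pytest.raises(ValueError):
            PoroViscoelasticMaterial(prony_modulus=0.34)  # sum 1.02 >= 1


class TestStepShearRelaxation:
    def test_stress_tracks_relaxation_modulus_to_1000s(self):
        gamma0 = 0.01
        sol = _homogeneous_shear_solver(gamma0)
        sol.step(1e-4)  # near-instantaneous application of the step strain
        t = 1e-4
        worst = 0.0
        for _ in range(100):
            st = sol.step(10.0)
            t += 10.0
            sxy = st.cauchy_stress[..., 2].mean()
            exact = gamma0 * relaxation_modulus(t, MAT)
            worst = max(worst, abs(sxy - exact) / exact)
        assert worst < 0.005

    def test_internal_variables_decay_without_strain(self):
        sol = _homogeneous_shear_solver(0.01)
        sol.step(1e-4)
        q0 = max(np.abs(q).max() for q in sol.q)
        for _ in range(20):  # 4000 s >> tau_3 = 410 s
            sol.step(200.0)
        q1 = max(np.abs(q).max() for q in sol.q)
        assert q1 < 1e-3 * q0

    def test_dissipation_nonnegative_during_relaxation(self):
        sol = _homogeneous_shear_solver(0.01)
        sol.step(1e-4)
        for _ in range(5):
            sol.step(5.0)
            assert sol.viscous_dissipation_step() >= 0.0

    def test_linear_ramp_is_integrated_exactly(self):
        # the exponential recurrence is exact for piecewise-linear strain, so
        # a ramp sampled at any dt must match the hereditary integral
        # sigma(t) = integral G(t-s) dgamma/ds ds to quadrature accuracy
        gamma_rate, t_end, nsteps = 0.005, 2.0, 8
        s = np.linspace(0, t_end, 40001)
        exact = gamma_rate * np.trapezoid(relaxation_modulus(t_end - s, MAT), s)
        mesh = rectangle_mesh(10.0, 10.0, 2, 2, region="brain")
        sol = SolidSolver(mesh, MAT, bc={})
        pins = np.concatenate([np.arange(sol.nd), np.arange(sol.nd) + sol.nd])
        dt = t_end / nsteps
        for i in range(1, nsteps + 1):
            g = gamma_rate * i * dt
            sol.pin_dofs = (pins, np.concatenate([g * sol.Db.dof_x[:, 1], np.zeros(sol.nd)]))
            sol.prepare(dt)  # pin values changed
            st = sol.step(dt)
        assert abs(st.cauchy_stress[..., 2].mean() - exact) / exact < 1e-6

    def test_smooth_history_error_vanishes_with_dt(self):
        # for a curved (sinusoidal) strain history the sampling error of the
        # recurrence must shrink under time refinement
        t_end = 2.0
        gam = lambda t: 0.01 * np.sin(np.pi * t / (2 * t_end))
        s = np.linspace(0, t_end, 40001)
        dgam = np.gradient(gam(s), s)
        exact = np.trapezoid(relaxation_modulus(t_end - s, MAT) * dgam, s)
        errs = []
        for nsteps in (4, 16):
            mesh = rectangle_mesh(10.0, 10.0, 2, 2, region="brain")
            sol = SolidSolver(mesh, MAT, bc={})
            pins = np.concatenate([np.arange(sol.nd), np.arange(sol.nd) + sol.nd])
            dt = t_end / nsteps
            for i in range(1, nsteps + 1):
                g = gam(i * dt)
                sol.pin_dofs = (pins, np.concatenate([g * sol.Db.dof_x[:, 1], np.zeros(sol.nd)]))
                sol.prepare(dt)
                st = sol.step(dt)
            errs.append(abs(st.cauchy_stress[..., 2].mean() - exact))
        assert errs[1] < errs[0] / 2


class TestTerzaghiConsolidation:
    def test_pore_pressure_profile_matches_series_solution(self):
        mat = replace(MAT, prony_modulus=0.0, permeability=1e-7)
        H, sigma0 = 0.01, 100.0
        mesh = rectangle_mesh(2.0, 10.0, 2, 40, region="brain")
        bc = {
            "bottom": ("fixed_y",),
            "left": ("fixed_x",),
            "right": ("fixed_x",),
            "top": [("normal_traction", -sigma0), ("drained", 0.0)],
        }
        sol = SolidSolver(mesh, mat, bc=bc)
        E, nu = mat.youngs_modulus, mat.poisson_ratio
        cv = mat.permeability * E * (1 - nu) / ((1 + nu) * (1 - 2 * nu))

        def series(z, t, terms=200):
            Tv = cv * t / H**2
            out = np.zeros_like(z)
            for m in range(1, 2 * terms, 2):
                out += 4 / (m * np.pi) * np.sin(m * np.pi * z / (2 * H)) * np.exp(-((m * np.pi / 2) ** 2) * Tv)
            return out

        t, dt = 0.0, 0.02
        for i in range(60):
            sol.step(dt)
            t += dt
            if i in (9, 29, 59):
                z = H - sol.Pb.dof_x[:, 1]
                err = np.abs(sol.p - sigma0 * series(z, t)).max() / sigma0
                assert err < 0.02


class TestElasticLimits:
    def test_zero_load_zero_state(self):
        mesh = rectangle_mesh(5.0, 5.0, 3, 3, region="brain")
        sol = SolidSolver(mesh, MAT, bc={"bottom": ("fixed",)})
        for _ in range(3):
            st = sol.step(0.1)
        assert np.abs(st.displacement).max() == 0.0
        assert np.abs(st.pore_pressure).max() == 0.0

    def test_cantilever_tip_deflection_matches_beam_theory(self):
        # prony off, high permeability (drained): pure linear elasticity
        mat = replace(MAT, prony_modulus=0.0, permeability=1.0)
        L, h = 0.02, 0.002  # m
        P = 1e-4  # N per metre depth, downward tip load
        mesh = rectangle_mesh(20.0, 2.0, 60, 6, region="brain")
        bc = {"left": ("fixed",), "right": ("traction", (0.0, -P / h))}
        sol = SolidSolver(mesh, mat, bc=bc)
        for _ in range(30):  # allow drainage to complete
            st = sol.step(5.0)
        E_eff = mat.youngs_modulus / (1 - mat.poisson_ratio**2)  # plane strain
        I = h**3 / 12.0
        w_exact = P * L**3 / (3 * E_eff * I)
        tip = sol.Db.dof_x[:, 0] > L - 1e-9
        w_num = -st.displacement[sol.nd :][tip].mean()
        assert w_num == pytest.approx(w_exact, rel=0.05)


class TestTractions:
    def test_hydrostatic_pore_pressure_gives_minus_p_n(self):
        mesh = rectangle_mesh(5.0, 5.0, 4, 4, region="brain")
        sol = SolidSolver(mesh, MAT, bc={})
        p0 = 123.0
        sol.p = np.full(sol.npp, p0)
        trac, _ = sol.interface_traction("top")
        np.testing.assert_allclose(trac[:, 1], -p0, rtol=1e-12)  # n = +y on top
        np.testing.assert_allclose(trac[:, 0], 0.0, atol=1e-12)

    def test_uniaxial_homogeneous_stress_traction_magnitude(self):
        mat = replace(MAT, prony_modulus=0.0, permeability=1.0)
        mesh = rectangle_mesh(5.0, 5.0, 4, 4, region="brain")
        sigma = -50.0
        bc = {
            "bottom": ("fixed_y",),
            "left": ("fixed_x",),
            "top": ("normal_traction", sigma),
        }
        sol = SolidSolver(mesh, mat, bc=bc)
        for _ in range(40):
            sol.step(10.0)
        trac, _ = sol.interface_traction("top")
        assert trac[:, 1].mean() == pytest.approx(sigma, rel=0.02)

    def test_unlabeled_facets_rejected(self):
        mesh = rectangle_mesh(5.0, 5.0, 3, 3, region="brain")
        sol = SolidSolver(mesh, MAT, bc={})
        with pytest.raises(ValueError):
            sol.interface_traction("fsi_inner")
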