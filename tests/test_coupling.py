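"""Two-way coupled runs: interface conditions, limits, and reducers."""

import numpy as np
import pytest

from cranioflow.coupling import (
    CouplingConfig,
    SimulationResult,
    extract_deformation,
    extract_icp,
    run_fsi,
    run_rigid_cavity,
)
from cranioflow.errors import NotConvergedError
from cranioflow.solid import PoroViscoelasticMaterial
from cranioflow.synthetic import generate_pulsatile_waveform, StageWaveforms

CFG = CouplingConfig(n_cycles=3, steps_per_cycle=16)


@pytest.fixture(scope="module")
def default_run(coarse_mesh_module, waveforms_module):
    return run_fsi(coarse_mesh_module, None, None, waveforms_module, CFG)


# session fixtures re-exported at module scope so the run is shared
@pytest.fixture(scope="module")
def coarse_mesh_module():
    from cranioflow.geometry import HeadGeometry, generate_mesh

    return generate_mesh(HeadGeometry(), "coarse")


@pytest.fixture(scope="module")
def waveforms_module():
    from cranioflow.synthetic import generate_waveform_triplet

    return generate_waveform_triplet(heart_rate=70.0, seed=1)


def _steady_waveforms():
    """Constant components only: 0.35 in, 0.17 spinal out (sinus via pressure)."""
    mk = lambda c, site: generate_pulsatile_waveform(70.0, c, [0.0], [0.0], site=site)
    return StageWaveforms(
        patient_id=0, stage=0,
        inlet=mk(0.35, "ventricular_inlet"),
        spinal_outlet=mk(0.17, "spinal_outlet"),
        sinus_outlet=mk(0.18, "sinus_outlet"),
    )


class TestCoupledRun:
    def test_all_steps_converged_within_tolerance(self, default_run):
        res = default_run
        assert res.all_converged
        for ok, hist in zip(res.converged_flags, res.residual_history):
            if ok:
                assert hist[-1] < CFG.interface_tolerance

    def test_velocity_matching_at_interface(self, default_run):
        # kinematic condition u_S = u_F at the shared interface dofs
        assert np.max(default_run.velocity_residuals) < 1e-3

    def test_last_two_cycles_periodic_below_1_percent(self, default_run):
        assert default_run.periodicity_rms() < 0.01

    def test_series_lengths_consistent(self, default_run):
        n = CFG.n_cycles * CFG.steps_per_cycle
        assert default_run.times.shape == (n,)
        assert default_run.icp_series.shape == (n,)
        assert default_run.deformation_series.shape == (n,)

    def test_icp_sits_at_shunt_valve_pressure(self, default_run):
        # a zero-resistance ventricular shunt outlet clamps the mean ICP to
        # the valve pressure
        assert extract_icp(default_run) == pytest.approx(CFG.outlet_pressure_cmH2O, abs=0.05)

    def test_mass_balance_diagnostic_stays_small(self, default_run):
        # bookkeeping consistency of boundary fluxes, production and mesh
        # volume change; the residual is dominated by flux through the
        # stationary inlet/shunt patches (a few % of the pulsatile amplitude)
        assert np.max(default_run.mass_balance_series) < 0.05  # ml/min

    def test_temporal_refinement_changes_mean_icp_little(
        self, coarse_mesh_module, waveforms_module, default_run
    ):
        fine_dt = run_fsi(
            coarse_mesh_module, None, None, waveforms_module,
            CouplingConfig(n_cycles=3, steps_per_cycle=32),
        )
        a, b = extract_icp(default_run), extract_icp(fine_dt)
        assert abs(a - b) / abs(b) < 0.01


class TestLimits:
    def test_rigid_limit_reproduces_rigid_cavity_solution(
        self, coarse_mesh_module, waveforms_module
    ):
        stiff = PoroViscoelasticMaterial(youngs_modulus=584.4e6)
        fsi = run_fsi(coarse_mesh_module, None, stiff, waveforms_module, CFG)
        rigid = run_rigid_cavity(coarse_mesh_module, None, waveforms_module, CFG)
        err = np.abs(fsi.icp_series - rigid.icp_series).max() / np.abs(rigid.icp_series).max()
        assert err < 0.01
        assert fsi.interface_displacement_series.max() < 1e-3  # < 1 um (mm units)

    def test_steady_forcing_gives_steady_icp(self, coarse_mesh_module):
        res = run_fsi(coarse_mesh_module, None, None, _steady_waveforms(), CFG)
        final = res.final_cycle(res.icp_series)
        assert np.ptp(final) / np.mean(final) < 1e-3

    def test_softer_brain_deforms_more(self, coarse_mesh_module, waveforms_module, default_run):
        soft = PoroViscoelasticMaterial(youngs_modulus=584.4 / 2)
        res = run_fsi(coarse_mesh_module, None, soft, waveforms_module, CFG)
        assert extract_deformation(res) > extract_deformation(default_run)


def _result_with_series(icp, steps_per_cycle, deformation=None):
    n = len(icp)
    z = np.zeros(n)
    return SimulationResult(
        times=np.arange(1, n + 1, dtype=float),
        icp_series=np.asarray(icp, dtype=float),
        icp_max_series=np.asarray(icp, dtype=float),
        deformation_series=np.asarray(deformation if deformation is not None else z),
        interface_displacement_series=z,
        ventricle_volume_series=z,
        intracranial_volume_series=z,
        brain_surface_area=650.0,
        velocity_residuals=z,
        subiterations=np.ones(n, dtype=int),
        converged_flags=np.ones(n, dtype=bool),
        mass_balance_series=z,
        dt=1.0,
        steps_per_cycle=steps_per_cycle,
        period=float(steps_per_cycle),
    )


class TestReducers:
    def test_constant_series_both_reducers_return_it(self):
        res = _result_with_series(np.full(16, 12.5), 8)
        assert extract_icp(res, "cycle_mean") == 12.5
        assert extract_icp(res, "cycle_peak") == 12.5

    def test_sinusoid_mean_and_peak(self):
        t = np.arange(32)
        icp = 10.0 + 2.0 * np.sin(2 * np.pi * t / 16)
        res = _result_with_series(icp, 16)
        assert extract_icp(res, "cycle_mean") == pytest.approx(10.0)
        assert extract_icp(res, "cycle_peak") == pytest.approx(12.0, abs=0.1)

    def test_peak_never_below_mean(self, default_run):
        assert extract_icp(default_run, "cycle_peak") >= extract_icp(default_run, "cycle_mean")
        assert extract_deformation(default_run, "cycle_peak") >= extract_deformation(
            default_run, "cycle_mean"
        )

    def test_nonconverged_result_refused(self):
        res = _result_with_series(np.full(16, 10.0), 8)
        res.converged_flags[3] = False
        with pytest.raises(NotConvergedError):
            extract_icp(res)
        with pytest.raises(NotConvergedError):
            extract_deformation(res)

    def test_uniform_normal_displacement_is_returned_exactly(self, coarse_mesh_module):
        # push every fsi_inner dof by delta along its own normal: the
        # deformation reducer must report exactly delta
        from cranioflow.coupling import _dof_normals
        from cranioflow.solid import SolidSolver

        solid = SolidSolver(coarse_mesh_module)
        dofs, normals = _dof_normals(solid, "fsi_inner")
        delta = 0.25e-3  # m
        solid.d[dofs] = delta * normals[:, 0]
        solid.d[dofs + solid.nd] = delta * normals[:, 1]
        dn = np.abs(
            solid.d[dofs] * normals[:, 0] + solid.d[dofs + solid.nd] * normals[:, 1]
        )
        assert dn.mean() * 1e3 == pytest.approx(0.25)
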