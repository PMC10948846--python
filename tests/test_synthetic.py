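"""Synthetic cohort generators: waveforms, longitudinal records, monitor noise."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cranioflow.synthetic import (
    CohortSpec,
    FlowWaveform,
    generate_cohort,
    generate_monitored_icp,
    generate_pulsatile_waveform,
    generate_stage_records,
    sample_independent_metric_table,
)


class TestPulsatileWaveform:
    def test_zero_harmonics_is_the_constant_production_rate(self):
        wf = generate_pulsatile_waveform(72.0, 0.35, [0, 0, 0], [0, 0, 0], n_samples=32)
        assert np.allclose(wf.rates, 0.35)
        assert wf.period == pytest.approx(60.0 / 72.0)

    def test_single_harmonic_cycle_mean_equals_constant(self):
        wf = generate_pulsatile_waveform(60.0, 0.35, [0.8], [0.0], n_samples=16)
        assert wf.rates.mean() == pytest.approx(0.35, abs=1e-12)

    def test_matches_direct_fourier_sum_oracle(self):
        rng = np.random.default_rng(42)
        amps = rng.uniform(0.1, 1.0, 3)
        phases = rng.uniform(0, 2 * np.pi, 3)
        hr, n = 65.0, 48
        wf = generate_pulsatile_waveform(hr, 0.35, amps, phases, n_samples=n)
        # independent term-by-term reference evaluation
        period = 60.0 / hr
        t = np.arange(n) * period / n
        expected = np.full(n, 0.35)
        for k in range(3):
            expected += amps[k] * np.sin(2 * np.pi * (k + 1) / period * t + phases[k])
        expected -= expected.mean() - 0.35
        assert np.abs(wf.rates - expected).max() < 1e-12

    @settings(max_examples=25, deadline=None)
    @given(
        hr=st.floats(40.0, 120.0),
        const=st.floats(-1.0, 1.0),
        seed=st.integers(0, 2**16),
    )
    def test_cycle_mean_invariant_for_any_harmonic_content(self, hr, const, seed):
        rng = np.random.default_rng(seed)
        amps = rng.uniform(0, 2, 3)
        phases = rng.uniform(0, 2 * np.pi, 3)
        wf = generate_pulsatile_waveform(hr, const, amps, phases, n_samples=32)
        assert abs(wf.rates.mean() - const) < 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(heart_rate=0.0, constant_component=0.3, harmonic_amplitudes=[1], harmonic_phases=[0]),
            dict(heart_rate=-5.0, constant_component=0.3, harmonic_amplitudes=[1], harmonic_phases=[0]),
            dict(heart_rate=60.0, constant_component=0.3, harmonic_amplitudes=[1], harmonic_phases=[0], n_samples=4),
            dict(heart_rate=60.0, constant_component=0.3, harmonic_amplitudes=[1, 2], harmonic_phases=[0]),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_pulsatile_waveform(**kwargs)

    def test_csv_roundtrip(self, tmp_path):
        wf = generate_pulsatile_waveform(70.0, 0.17, [0.4, 0.1], [0.3, 1.1], site="spinal_outlet")
        wf.to_csv(tmp_path / "w.csv")
        back = FlowWaveform.from_csv(tmp_path / "w.csv")
        assert back.site == "spinal_outlet"
        assert back.heart_rate == wf.heart_rate
        np.testing.assert_allclose(back.rates, wf.rates)

    def test_periodic_evaluation_wraps(self):
        wf = generate_pulsatile_waveform(60.0, 0.35, [0.5], [0.2])
        assert wf.rate_at(0.25 + 3 * wf.period) == pytest.approx(wf.rate_at(0.25))


class TestCohort:
    def test_default_design_yields_112_waveform_triplets(self):
        trips = generate_cohort(CohortSpec(seed=3))
        assert len(trips) == 14 * 8

    def test_constant_components_balance_exactly_every_stage(self):
        for tr in generate_cohort(CohortSpec(n_patients=3, n_stages=4, seed=5)):
            assert tr.inlet.constant_component == pytest.approx(
                tr.spinal_outlet.constant_component + tr.sinus_outlet.constant_component,
                abs=0,
            )

    def test_same_seed_bit_identical(self):
        a = generate_cohort(CohortSpec(n_patients=2, n_stages=3, seed=11))
        b = generate_cohort(CohortSpec(n_patients=2, n_stages=3, seed=11))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.inlet.rates, tb.inlet.rates)
            assert np.array_equal(ta.sinus_outlet.rates, tb.sinus_outlet.rates)

    def test_zero_oscillation_gives_strictly_monotone_trajectories(self):
        rec = generate_stage_records(CohortSpec(oscillation_amplitude=0.0, seed=7))
        for _, grp in rec.groupby("patient_id"):
            icp = grp.sort_values("stage")["icp_cmH2O"].to_numpy()
            assert np.all(np.diff(icp) < 0)

    def test_stage_records_schema_and_determinism(self):
        spec = CohortSpec(seed=9)
        a = generate_stage_records(spec)
        b = generate_stage_records(spec)
        assert len(a) == 112
        pd.testing.assert_frame_equal(a, b)
        assert (a["intracranial_volume_ml"] > 0).all()
        assert (a["brain_surface_area_cm2"] > 0).all()

    def test_independent_metric_table_is_uncorrelated_by_construction(self):
        assert len(sample_independent_metric_table(seed=0)) == 98
        rs = []
        for s in range(20):
            df = sample_independent_metric_table(seed=s)
            rs.append(np.corrcoef(df["icc_ml_per_cmH2O"], df["stiffness_N_per_m"])[0, 1])
        # independent draws: E[r] = 0, sd(r) ~ 1/sqrt(97)
        assert abs(np.mean(rs)) < 0.1


class TestMonitoredICP:
    def test_zero_noise_returns_true_values_in_order(self):
        true = np.linspace(10, 25, 10)
        m = generate_monitored_icp(true, noise_fraction=0.0, seed=1)
        np.testing.assert_array_equal(m.readings, true)
        np.testing.assert_array_equal(m.patient_ids, np.arange(10))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            generate_monitored_icp([10.0], noise_fraction=-0.1)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            generate_monitored_icp([10.0, -2.0])

    def test_mean_absolute_relative_error_matches_folded_normal(self):
        # for eps ~ N(0, s), E|eps| = s * sqrt(2/pi)
        s = 0.02
        true = np.full(10, 15.0)
        devs = [
            np.abs(generate_monitored_icp(true, s, seed=k).readings / true - 1.0).mean()
            for k in range(1000)
        ]
        expected = s * np.sqrt(2 / np.pi)
        assert np.mean(devs) == pytest.approx(expected, rel=0.03)
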