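"""Synthetic study inputs: pulsatile CSF waveforms, a longitudinal shunt
cohort, and noisy "monitored" ICP readings.

The real study quantities these emulate come from cardiac-gated phase-contrast
MRI and intraoperative pressure monitoring, neither of which is public. The
generators reproduce their statistical structure: cardiac-cycle flow-rate
graphs that superpose a constant production/absorption component (0.35 ml/min
ventricular inflow, 0.17 spinal + 0.18 sinus outflow) with a pulsatile
component; a 14-patient x 8-stage longitudinal cohort whose ICP and
ventricular volume decline after shunting toward a plateau with oscillatory
month-to-month variation; and multiplicative-Gaussian-noise pressure readings
for a validation subset.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_SITES = ("ventricular_inlet", "spinal_outlet", "sinus_outlet")

#: constant flow-rate components, ml/min (ventricular production, spinal
#: absorption, sagittal-sinus absorption)
CONSTANT_INFLOW_ML_MIN = 0.35
CONSTANT_SPINAL_OUTFLOW_ML_MIN = 0.17
CONSTANT_SINUS_OUTFLOW_ML_MIN = 0.18


@dataclass(frozen=True)
class FlowWaveform:
    """One cardiac cycle of CSF flow rate at an inlet or outlet.

    ``times`` are seconds, uniformly sampled on [0, period); ``rates`` are
    ml/min. The cycle mean of ``rates`` equals ``constant_component``.
    """

    times: np.ndarray
    rates: np.ndarray
    constant_component: float
    site: str
    heart_rate: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rates", r)
        if self.site not in VALID_SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {VALID_SITES}")
        if t.ndim != 1 or t.shape != r.shape or t.size < 2:
            raise ValueError("times and rates must be matching 1-D arrays (>= 2 samples)")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite")
        if abs(float(r.mean()) - self.constant_component) > 1e-9:
            raise ValueError("cycle mean of rates does not equal constant_component")

    @property
    def period(self) -> float:
        """Cardiac period in seconds (60 / heart rate)."""
        return 60.0 / self.heart_rate

    def rate_at(self, t: float | np.ndarray) -> np.ndarray:
        """Periodic evaluation in ml/min by Fourier-free linear interpolation."""
        tm = np.mod(t, self.period)
        tt = np.append(self.times, self.period)
        rr = np.append(self.rates, self.rates[0])
        return np.interp(tm, tt, rr)

    def to_csv(self, path: str | Path) -> None:
        """Write `time_s,rate_ml_min` CSV plus a JSON sidecar with metadata."""
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "rate_ml_min": self.rates}).to_csv(
            path, index=False
        )
        sidecar = {
            "site": self.site,
            "constant_component_ml_min": self.constant_component,
            "heart_rate_bpm": self.heart_rate,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FlowWaveform":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            times=df["time_s"].to_numpy(),
            rates=df["rate_ml_min"].to_numpy(),
            constant_component=meta["constant_component_ml_min"],
            site=meta["site"],
            heart_rate=meta["heart_rate_bpm"],
        )


def generate_pulsatile_waveform(
    heart_rate: float,
    constant_component: float,
    harmonic_amplitudes,
    harmonic_phases,
    n_samples: int = 64,
    site: str = "ventricular_inlet",
) -> FlowWaveform:
    """Truncated-Fourier cardiac-gated flow waveform.

    rate(t) = constant + sum_k a_k sin(2 pi k f t + phi_k), sampled uniformly
    on [0, period). Because the harmonics are integer multiples of the cardiac
    frequency and sampling is uniform over one period, the discrete cycle mean
    equals ``constant_component`` exactly (to rounding).
    """
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    amps = np.asarray(harmonic_amplitudes, dtype=float)
    phases = np.asarray(harmonic_phases, dtype=float)
    if amps.shape != phases.shape:
        raise ValueError("harmonic_amplitudes and harmonic_phases must have equal length")
    if amps.size >= n_samples:
        raise ValueError("need n_samples > number of harmonics for an alias-free cycle mean")
    period = 60.0 / heart_rate
    t = np.arange(n_samples) * (period / n_samples)
    rates = np.full(n_samples, float(constant_component))
    f = 1.0 / period
    for k, (a, phi) in enumerate(zip(amps, phases), start=1):
        rates = rates + a * np.sin(2.0 * np.pi * k * f * t + phi)
    # re-centre to kill accumulated rounding so the declared mean is exact
    rates = rates - (rates.mean() - constant_component)
    return FlowWaveform(
        times=t,
        rates=rates,
        constant_component=float(constant_component),
        site=site,
        heart_rate=float(heart_rate),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of the synthetic longitudinal cohort.

    One pre-surgery stage plus monthly follow-ups. ``post_shunt_decline`` is
    the exponential rate (per stage) at which ICP and ventricular volume
    approach their post-shunt plateau; ``oscillation_amplitude`` is the
    relative scale of seeded month-to-month oscillation around that trend.
    """

    n_patients: int = 14
    n_stages: int = 8
    seed: int = 0
    baseline_icp_range: tuple[float, float] = (12.0, 25.0)  # cmH2O, pre-surgery
    post_shunt_decline: float = 0.5
    oscillation_amplitude: float = 0.05
    heart_rate_range: tuple[float, float] = (55.0, 90.0)
    plateau_fraction: float = 0.6  # stabilized level as a fraction of baseline
    n_harmonics: int = 3
    pulsatility_range: tuple[float, float] = (2.0, 5.0)  # peak-to-peak / constant

    def __post_init__(self):
        if self.n_patients <= 0 or self.n_stages <= 0:
            raise ValueError("counts must be positive")
        if self.post_shunt_decline < 0 or self.oscillation_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if not (0 < self.plateau_fraction <= 1):
            raise ValueError("plateau_fraction must be in (0, 1]")


@dataclass(frozen=True)
class StageWaveforms:
    """Waveform triplet plus metadata for one patient-stage."""

    patient_id: int
    stage: int
    inlet: FlowWaveform
    spinal_outlet: FlowWaveform
    sinus_outlet: FlowWaveform


def _pulsatile_waveform_from_rng(
    rng: np.random.Generator,
    heart_rate: float,
    constant: float,
    site: str,
    spec: CohortSpec,
) -> FlowWaveform:
    """Seeded harmonic content with peak-to-peak pulsatility 2-5x the constant."""
    k = np.arange(1, spec.n_harmonics + 1)
    rel = rng.uniform(0.5, 1.0, size=spec.n_harmonics) / k  # decaying spectrum
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_harmonics)
    target_p2p = rng.uniform(*spec.pulsatility_range) * abs(constant)
    trial = generate_pulsatile_waveform(heart_rate, 0.0, rel, phases, n_samples=64, site=site)
    p2p = trial.rates.max() - trial.rates.min()
    scale = target_p2p / p2p if p2p > 0 else 0.0
    return generate_pulsatile_waveform(
        heart_rate, constant, rel * scale, phases, n_samples=64, site=site
    )


def generate_cohort(spec: CohortSpec) -> list[StageWaveforms]:
    """Per-patient, per-stage waveform triplets (inlet, spinal, sinus).

    The constant components are the physiological production/absorption
    values, so inlet = spinal + sinus holds exactly for every stage.
    """
    ss = np.random.SeedSequence(spec.seed)
    out: list[StageWaveforms] = []
    for pid, pss in enumerate(ss.spawn(spec.n_patients)):
        rng = np.random.default_rng(pss)
        hr = rng.uniform(*spec.heart_rate_range)
        for stage in range(spec.n_stages):
            out.append(
                StageWaveforms(
                    patient_id=pid,
                    stage=stage,
                    inlet=_pulsatile_waveform_from_rng(
                        rng, hr, CONSTANT_INFLOW_ML_MIN, "ventricular_inlet", spec
                    ),
                    spinal_outlet=_pulsatile_waveform_from_rng(
                        rng, hr, CONSTANT_SPINAL_OUTFLOW_ML_MIN, "spinal_outlet", spec
                    ),
                    sinus_outlet=_pulsatile_waveform_from_rng(
                        rng, hr, CONSTANT_SINUS_OUTFLOW_ML_MIN, "sinus_outlet", spec
                    ),
                )
            )
    return out


def generate_waveform_triplet(
    heart_rate: float = 70.0, seed: int = 0, n_harmonics: int = 3,
    pulsatility_range: tuple[float, float] = (2.0, 5.0),
) -> StageWaveforms:
    """One seeded waveform triplet (inlet, spinal, sinus) for single runs."""
    spec = CohortSpec(
        n_patients=1, n_stages=1, seed=seed,
        heart_rate_range=(heart_rate, heart_rate),
        n_harmonics=n_harmonics, pulsatility_range=pulsatility_range,
    )
    return generate_cohort(spec)[0]


def _trend(baseline: float, plateau: float, stage: int, rate: float) -> float:
    """Exponential approach from pre-surgery baseline toward the plateau."""
    if stage == 0:
        return baseline
    return plateau + (baseline - plateau) * float(np.exp(-rate * stage))


def generate_stage_records(spec: CohortSpec) -> pd.DataFrame:
    """Longitudinal scalar trajectories for the cohort.

    Columns: patient_id, stage, icp_cmH2O, intracranial_volume_ml,
    brain_surface_area_cm2, deformation_mm. ICP and ventricular volume
    decline exponentially toward a post-shunt plateau (stabilization by the
    last stages) with seeded oscillatory stage-to-stage variation; surface
    area and cyclic brain deformation co-vary mildly with ventricular size.
    """
    ss = np.random.SeedSequence((spec.seed, 1))
    rows = []
    for pid, pss in enumerate(ss.spawn(spec.n_patients)):
        rng = np.random.default_rng(pss)
        icp0 = rng.uniform(*spec.baseline_icp_range)
        vent0 = rng.uniform(80.0, 180.0)  # ml, enlarged ventricles pre-shunt
        brain_vol = rng.uniform(1150.0, 1350.0)  # ml, parenchyma + SAS
        area0 = rng.uniform(1500.0, 1900.0)  # cm2
        defo0 = rng.uniform(0.3, 0.8)  # mm, cyclic interface excursion
        for stage in range(spec.n_stages):
            osc = 1.0 + spec.oscillation_amplitude * rng.uniform(-1.0, 1.0) * (stage > 0)
            icp = _trend(icp0, spec.plateau_fraction * icp0, stage, spec.post_shunt_decline)
            vent = _trend(vent0, 0.5 * vent0, stage, spec.post_shunt_decline)
            osc_v = 1.0 + spec.oscillation_amplitude * rng.uniform(-1.0, 1.0) * (stage > 0)
            osc_d = 1.0 + 2 * spec.oscillation_amplitude * rng.uniform(-1.0, 1.0) * (stage > 0)
            vent_s = vent * osc_v
            rows.append(
                {
                    "patient_id": pid,
                    "stage": stage,
                    "icp_cmH2O": icp * osc,
                    "intracranial_volume_ml": brain_vol + vent_s,
                    "brain_surface_area_cm2": area0 * (1.0 + 0.05 * (vent_s / vent0 - 1.0)),
                    "deformation_mm": defo0 * (0.7 + 0.3 * icp / icp0) * osc_d,
                }
            )
    return pd.DataFrame(rows)


def sample_independent_metric_table(
    n_patients: int = 14, n_intervals: int = 7, seed: int = 0
) -> pd.DataFrame:
    """Patient-interval table with ICC and stiffness drawn independently.

    Used for type-I-error control checks of the correlation analysis: under
    this generator any detected ICC-stiffness association is spurious.
    Scales are clinically plausible (ICC a few ml/cmH2O, stiffness tens to
    hundreds of N/m, both signed).
    """
    rng = np.random.default_rng(seed)
    n = n_patients * n_intervals
    return pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(n_patients), n_intervals),
            "interval": np.tile(np.arange(n_intervals), n_patients),
            "icc_ml_per_cmH2O": rng.normal(2.0, 4.0, size=n),
            "stiffness_N_per_m": rng.normal(50.0, 250.0, size=n),
        }
    )


@dataclass(frozen=True)
class MonitoredICPSet:
    """Noisy invasive-monitor ICP readings for a validation subset."""

    patient_ids: np.ndarray
    readings: np.ndarray  # cmH2O
    noise_fraction: float
    true_values: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "patient_ids", np.asarray(self.patient_ids))
        object.__setattr__(self, "readings", np.asarray(self.readings, dtype=float))
        if np.any(self.readings <= 0):
            raise ValueError("readings must be positive")


def generate_monitored_icp(
    true_icp_values, noise_fraction: float = 0.02, seed: int = 0, patient_ids=None
) -> MonitoredICPSet:
    """Simulated micro-sensor readings: reading = true * (1 + eps),
    eps ~ Normal(0, noise_fraction), order-preserving and seed-reproducible."""
    true = np.asarray(true_icp_values, dtype=float)
    if np.any(true <= 0):
        raise ValueError("true ICP values must be positive")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    if patient_ids is None:
        patient_ids = np.arange(true.size)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_fraction, size=true.size) if noise_fraction > 0 else 0.0
    return MonitoredICPSet(
        patient_ids=np.asarray(patient_ids),
        readings=true * (1.0 + eps),
        noise_fraction=float(noise_fraction),
        true_values=true,
    )
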