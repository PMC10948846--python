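"""Run configuration: schema-validated YAML with physiological defaults.

A single config file fully specifies a run: geometry, material, fluid,
waveforms, coupling, cohort and analysis blocks plus a seed and output
directory. Unknown keys are rejected with a spelling suggestion; an empty
file yields the pure defaults (E = 584.4 Pa, nu = 0.35, mu = 0.001 kg/(m s),
rho_F = 998.2 kg/m^3, constant flows 0.35 / 0.17 / 0.18 ml/min). The constant
flow components must balance exactly (inflow = spinal + sinus outflow).
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .coupling import CouplingConfig
from .fluid import FluidProperties
from .geometry import REFINEMENT_LEVELS, HeadGeometry
from .solid import PoroViscoelasticMaterial
from .synthetic import CohortSpec


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Block):
    ventricle_radius: float = 20.0
    aqueduct_radius: float = 0.0
    brain_outer_radius: float = 70.0
    sas_thickness: float = 3.0
    inlet_half_angle_deg: float = 25.0
    outlet_half_angle_deg: float = 20.0
    shunt_half_angle_deg: float = 15.0
    refinement_level: str = "coarse"

    @model_validator(mode="after")
    def _check(self):
        if self.refinement_level not in REFINEMENT_LEVELS:
            raise ValueError(f"refinement_level must be one of {REFINEMENT_LEVELS}")
        return self

    def to_geometry(self) -> HeadGeometry:
        d = self.model_dump()
        d.pop("refinement_level")
        return HeadGeometry(**d)


class MaterialBlock(_Block):
    youngs_modulus: float = 584.4  # Pa
    poisson_ratio: float = 0.35
    permeability: float = 4.08e-12  # m^4/(N s)
    void_ratio: float = 0.2
    density: float = 1000.0  # kg/m^3
    prony_relaxation_times: tuple[float, ...] = (3.1, 27.0, 410.0)  # s
    prony_modulus: float = 0.285
    prony_mode: str = "per_term"

    def to_material(self) -> PoroViscoelasticMaterial:
        return PoroViscoelasticMaterial(**self.model_dump())


class FluidBlock(_Block):
    density: float = 998.2  # kg/m^3
    viscosity: float = 1e-3  # kg/(m s)
    inflow_ml_min: float = 0.35
    spinal_outflow_ml_min: float = 0.17
    sinus_outflow_ml_min: float = 0.18

    @model_validator(mode="after")
    def _mass_balance(self):
        if abs(self.inflow_ml_min - self.spinal_outflow_ml_min - self.sinus_outflow_ml_min) > 1e-12:
            raise ValueError(
                "constant flow components must balance exactly: "
                f"inflow {self.inflow_ml_min} != spinal {self.spinal_outflow_ml_min} "
                f"+ sinus {self.sinus_outflow_ml_min}"
            )
        return self

    def to_properties(self) -> FluidProperties:
        return FluidProperties(density=self.density, viscosity=self.viscosity)


class WaveformBlock(_Block):
    source: str = "synthetic"  # or "files"
    heart_rate: float = 70.0  # beats/min (synthetic source)
    n_harmonics: int = 3
    inlet_path: str | None = None
    spinal_path: str | None = None
    sinus_path: str | None = None

    @model_validator(mode="after")
    def _check(self):
        if self.source not in ("synthetic", "files"):
            raise ValueError("waveforms.source must be 'synthetic' or 'files'")
        if self.source == "files" and not all(
            (self.inlet_path, self.spinal_path, self.sinus_path)
        ):
            raise ValueError("waveforms.source 'files' needs all three paths")
        return self


class CouplingBlock(_Block):
    steps_per_cycle: int = 16
    n_cycles: int = 3
    interface_tolerance: float = 1e-4
    max_subiterations: int = 40
    outlet_pressure_cmH2O: float = 5.0
    mesh_update: str = "per_step"

    def to_coupling(self) -> CouplingConfig:
        return CouplingConfig(**self.model_dump())


class CohortBlock(_Block):
    n_patients: int = 14
    n_stages: int = 8
    baseline_icp_range: tuple[float, float] = (12.0, 25.0)
    post_shunt_decline: float = 0.5
    oscillation_amplitude: float = 0.05
    heart_rate_range: tuple[float, float] = (55.0, 90.0)
    plateau_fraction: float = 0.6

    def to_spec(self, seed: int) -> CohortSpec:
        return CohortSpec(seed=seed, **self.model_dump())


class AnalysisBlock(_Block):
    alpha: float = 0.05
    interval_mode: str = "consecutive"  # or "vs_baseline"
    per_patient_mean: bool = False


class RunConfig(_Block):
    geometry: GeometryBlock = GeometryBlock()
    material: MaterialBlock = MaterialBlock()
    fluid: FluidBlock = FluidBlock()
    waveforms: WaveformBlock = WaveformBlock()
    coupling: CouplingBlock = CouplingBlock()
    cohort: CohortBlock = CohortBlock()
    analysis: AnalysisBlock = AnalysisBlock()
    seed: int = 0
    output_dir: str = "results"


def _suggest(bad: str, model: type[BaseModel]) -> str:
    names = list(model.model_fields)
    close = difflib.get_close_matches(bad, names, n=1)
    return f"; did you mean {close[0]!r}?" if close else ""


_BLOCKS = {
    "geometry": GeometryBlock,
    "material": MaterialBlock,
    "fluid": FluidBlock,
    "waveforms": WaveformBlock,
    "coupling": CouplingBlock,
    "cohort": CohortBlock,
    "analysis": AnalysisBlock,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file = defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        msgs = []
        for err in exc.errors():
            loc = err["loc"]
            if err["type"] == "extra_forbidden":
                block = _BLOCKS.get(loc[0], RunConfig) if len(loc) > 1 else RunConfig
                key = loc[-1]
                msgs.append(f"unknown key {'.'.join(map(str, loc))!r}{_suggest(str(key), block)}")
            else:
                msgs.append(f"{'.'.join(map(str, loc))}: {err['msg']}")
        raise ValueError("invalid config: " + "; ".join(msgs)) from exc


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable content hash of the full (defaults-filled) configuration."""
    return hashlib.sha256(
        json.dumps(json.loads(cfg.model_dump_json()), sort_keys=True).encode()
    ).hexdigest()[:16]
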