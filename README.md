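# cranioflow

Non-invasive computation of intracranial pressure (ICP) by two-way
fluid–structure interaction (FSI) between pulsatile cerebrospinal fluid (CSF)
and a poro-viscoelastic brain, with the downstream clinical derivations used
in hydrocephalus research: **intracranial compliance**

    ICC = ΔVolume / ΔICP            [ml/cmH₂O]

and **FSI-based brain stiffness**

    k = Δ(ICP × brain surface area) / Δ(brain deformation)   [N/m]

plus the longitudinal correlation analysis between them (Pearson and Spearman
at α = 0.05, with Shapiro–Wilk normality checks).

The package is for researchers in intracranial biomechanics who want a
desk-scale, fully reproducible counterpart to patient-specific CSF FSI
pipelines: an idealized axisymmetric head (ventricle – brain parenchyma –
subarachnoid space, rigid dura, optional aqueductal stenosis and shunt
catheter patch), an incompressible ALE Navier–Stokes CSF solver (Taylor–Hood
elements), a Biot poro-viscoelastic tissue solver with a three-term Prony
shear-relaxation series (τ = 3.1/27/410 s, E = 584.4 Pa, ν = 0.35,
permeability 4.08·10⁻¹² m⁴/(N·s)), and a strongly coupled interface exchange.
Because no patient data is public, a seeded synthetic-cohort module generates
every study input: cardiac-gated flow waveforms (constant + pulsatile,
0.35/0.17/0.18 ml/min constants), a 14-patient × 8-stage post-shunt
trajectory set, and noisy "monitored" ICP readings for validation-style
comparisons. See `docs/methods.md` for the model, assumptions and numerical
choices.

## Worked example

One coupled simulation on the default geometry (3 cardiac cycles, 16 steps
per cycle, seed 1):

```bash
cranioflow simulate --seed 1 --out simout
```

prints

```json
{
 "icp_cycle_mean_cmH2O": 5.000000331101006,
 "icp_cycle_peak_cmH2O": 5.0000053676350955,
 "deformation_cycle_mean_mm": 0.00012168266825538548,
 "brain_surface_area_cm2": 653.021535992878,
 "intracranial_volume_ml": 1601.7486712317466,
 "periodicity_rms": 1.3764230809159411e-08,
 "all_converged": true
}
```

The cycle-mean ICP sits at the shunt-valve pressure (5 cmH₂O): with the
implanted valve represented by a zero-resistance pressure outlet on the
ventricular wall, the mean pressure is clamped there and only a small
pulsatile excursion (the `icp_cycle_peak` difference) and a micrometre-scale
cyclic brain deformation remain. `simout/` also holds the full time series
(`icp_series.csv`), final fluid/solid fields (VTK), the mesh (Gmsh MSH), the
defaults-filled config and a manifest with the config hash and seed.

The longitudinal analysis pipeline:

```bash
cranioflow cohort --seed 2 --out cohortout       # synthetic 14x8 cohort
cranioflow analyze --table cohortout/cohort_table.csv --out analyzeout
```

```
n = 98
Pearson  r = -0.0168 (p = 0.87) -> not_significant
Spearman rho = +0.0989 (p = 0.3328) -> not_significant
```

98 rows are the 14 patients × 7 consecutive monthly intervals; with the
synthetic cohort the ICC–stiffness association is (correctly) not
significant at α = 0.05. `analyzeout/` contains the JSON/text report and the
scatter figure. Other subcommands: `cranioflow synth` (write all waveform
triplets to disk) and `cranioflow grid-study` (mesh-convergence study of the
coupled run).

## Library use

```python
from cranioflow import (HeadGeometry, generate_mesh, generate_waveform_triplet,
                        CouplingConfig, run_fsi, extract_icp)

mesh = generate_mesh(HeadGeometry(), "medium")
wf = generate_waveform_triplet(heart_rate=70, seed=1)
result = run_fsi(mesh, None, None, wf, CouplingConfig(n_cycles=3))
print(extract_icp(result, "cycle_mean"))   # cmH2O
```

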