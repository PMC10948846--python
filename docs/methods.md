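# Methods

## Model overview

The package simulates pulsatile cerebrospinal-fluid (CSF) dynamics in an
idealized head and derives from such simulations the two clinical quantities
of interest in shunt-treated hydrocephalus: intracranial compliance
(ICC = ΔV/ΔICP, ml/cmH₂O) and the force–deformation ("FSI-based") brain
stiffness Δ(ICP·A)/Δd (N/m), where A is the brain surface area and d the
cyclic brain deformation.

The cranium is idealized as concentric spherical compartments in a 2-D
axisymmetric (r–z) section: a CSF-filled ventricular cavity (radius 20 mm by
default), the brain parenchyma shell (outer radius 70 mm), and a 3 mm
subarachnoid space (SAS) bounded by a rigid, no-slip dura. The cerebral
aqueduct is closed by default (non-communicating hydrocephalus from
aqueductal stenosis); an optional channel of configurable radius through the
lower parenchyma models partial stenosis. All governing equations are
dimension-agnostic; the axisymmetric reduction is what makes a strongly
coupled run take seconds to minutes on one CPU.

### Fluid

CSF is an incompressible Newtonian fluid (ρ = 998.2 kg/m³,
μ = 0.001 kg·m⁻¹·s⁻¹) on a moving (ALE) mesh:

    ρ ∂u/∂t + ρ ((u − W)·∇)u = −∇p + μ∇²u + f,   ∇·u = S

with mesh velocity W and a volumetric production source S supported in the
ventricular CSF (zero in the SAS). Two production modes exist: a
boundary-inlet mode (default), where production enters as a prescribed inflow
waveform on a ventricular-wall patch, and a volumetric mode where S is
distributed uniformly over the ventricular region with its integral equal to
the production rate. Discretization is Taylor–Hood (P2 velocity / P1
pressure) on triangles, backward Euler in time, with the advection term
linearized about the previous velocity (Oseen); at CSF Reynolds numbers this
one-sweep linearization is exact to well below the time-discretization error.

Boundary data follow the clinical configuration: the ventricular inflow
(constant 0.35 ml/min plus a pulsatile component) and the spinal outflow
(constant 0.17 ml/min plus pulsation) are flux conditions with exact discrete
flux; the sagittal-sinus outlet (constant 0.18 ml/min absorption) and the
ventricular shunt-catheter patch are pressure outlets at the valve/sinus
pressure (default 5 cmH₂O). Replacing the ventriculoperitoneal shunt by a
pressure outlet follows the source study's treatment of the implanted valve;
because the catheter sits in the ventricle, the patch is carved from the
ventricular wall adjacent to the inflow patch. Without it, the sealed
ventricle accumulates the full 0.35 ml/min production and inflates without
bound — the untreated disease, not a solvable periodic state.

A fluid compartment with no pressure-type boundary at all (e.g. the sealed
ventricle in a rigid-wall run) carries the physical compressibility of water
(bulk modulus 2.2 GPa) in its continuity equation, which fixes the pressure
level; compartments with a pressure outlet or a traction/Robin interface are
exactly divergence-free.

### Solid

Brain tissue is a small-strain poro-viscoelastic (Biot) solid:
E = 584.4 Pa, ν = 0.35, Darcy permeability k = 4.08·10⁻¹² m⁴/(N·s), void
ratio 0.2, density 1000 kg/m³, Biot coefficient 1 with incompressible
constituents. The deviatoric response relaxes by a three-term Prony series

    G_r(t) = G₀ (1 − Σ_k g_k (1 − e^(−t/τ_k))),  τ = (3.1, 27, 410) s

with G₀ = E/(2(1+ν)) ≈ 216.44 Pa. The printed relaxation modulus 0.285 is
ambiguous for three terms; the default applies it per term (Σ g = 0.855,
long-term modulus 0.145·G₀), and a "total" mode divides it across terms
(Σ g = 0.285). The volumetric response is elastic. Displacement is P2, pore
pressure P1, backward Euler in time; the Prony convolution uses the per-term
exponential-integrator recurrence, which is unconditionally stable and exact
for piecewise-linear strain histories (verified against the hereditary
integral). The momentum balance is solved quasi-statically by default —
tissue inertia is negligible at cardiac frequencies — with an optional
backward-difference inertia term.

The brain shell floats between two fluids; axisymmetry fixes u_r on the
axis, and the vertical rigid-body mode is removed by pinning u_z on the
lower axis segment of the parenchyma (a brainstem/foramen tether).

### Interface coupling

The brain–CSF interfaces (ventricular and cortical surfaces) enforce
displacement compatibility, traction equilibrium, and velocity matching.
Both subproblems are linear within a time step, so the coupler exchanges the
solid's exact linear interface response: once per run the solid exports its
interface compliance matrix C (displacement per unit interface nodal force,
computed column-by-column on the factorized step operator), and each fluid
step is augmented with the interface force unknowns f and the constraint

    C f − Δt u_Γ = d_Γⁿ − d_part,

where d_part is the solid's interface displacement under history and
non-interface loads alone. Traction equilibrium holds by construction
(Newton's third law on the conforming shared nodes); the solved step
satisfies displacement and velocity compatibility to direct-solver precision,
and the remaining subiterations (typically one or two) settle the ventricular
pressure load on the non-FSI inflow/shunt patches. Displacement residuals are
recorded per subiteration and every step carries a converged flag.

Classical relaxed fixed-point alternatives (constant/Aitken relaxation,
least-squares interface quasi-Newton) are implemented in the solvers'
velocity/force interface modes, but for a sealed nearly incompressible cavity
wrapped in tissue four orders of magnitude softer than water's bulk modulus —
with a thin SAS film on the other side — essentially every interface mode is
stiff, and those iterations stall or need as many subiterations as there are
interface unknowns. The compliance-embedded exchange is what makes the
problem tractable; it is still a partitioned scheme in the sense that the
fluid and solid solvers remain separate and exchange interface data.

Two further choices keep the coupled time stepping stable:

- **Gauge pressure.** The fluid is solved relative to the outlet pressure.
  A uniform pressure on the closed surface of the undrained, incompressible
  brain produces zero deformation, so the shift is exact for the solid. It
  matters because a geometrically linear solid has no geometric stiffness to
  oppose the follower-load amplification of the ~490 Pa ambient pressure on a
  moving mesh; in gauge form the interface loads are of pulsatile magnitude
  and the feedback is negligible. Reported ICP adds the outlet pressure back.
- **Geometry update.** The fluid mesh moves once per time step by harmonic
  extension of the last converged interface displacement (no predictive
  extrapolation, which amplifies oscillations); the mesh velocity W is the
  backward difference of dof positions. Interface displacements are
  micrometres against millimetre cells, so the one-step geometric lag is far
  below the time-discretization error. A fixed-mesh (fully linearized) mode
  is available.

## Numerical choices

- Interface tolerance 1e-4 (relative, on the interface displacement scale),
  subiteration cap 40; non-converged steps are flagged, and scalar
  extraction refuses non-converged results.
- Default temporal resolution 16 steps per cardiac cycle, 3 cycles, with the
  last cycle used for cycle-mean/peak reductions; the last two cycles agree
  in ICP to ~1e-8 RMS on the default case, so the transient is gone.
- One iterative-refinement pass (residual-correction backsolve) follows every
  solid and augmented-fluid solve: the Biot saddle operator spans ~14 orders
  of magnitude (Pa-scale stiffness vs 1e-12-scale permeability) and plain LU
  leaves O(1e-10 m) displacement noise, which is not negligible against
  micrometre interface motion. Constraint rows are scaled to the momentum-row
  magnitude for the same reason.
- ICC/stiffness interval denominators below 1e-9 (working units) flag the
  interval undefined rather than producing huge finite values.
- Spearman p-values are exact permutation enumerations for n ≤ 9 without
  ties, t-approximations otherwise; ties get mid-ranks. Pearson p-values use
  the t transform. No multiple-testing correction is applied.
- Problem sizes: the default grid-independence study spans four structured
  refinement levels (~160 to ~10,700 triangles); each level at least halves
  the maximum cell diameter of the previous one.

## Synthetic data

No patient data is available, so a seeded generator supplies every study
input:

- **Waveforms.** Cardiac-gated flow graphs are truncated Fourier series
  (3 harmonics by default) superposed on the constant production/absorption
  components (0.35 / 0.17 / 0.18 ml/min), with harmonic amplitudes scaled so
  the peak-to-peak pulsatility is 2–5× the constant component — the
  phenomenology of cine phase-contrast CSF flow measurements. Heart rate,
  spectrum and phases are free, seeded parameters; cycle means equal the
  constant components to rounding by construction.
- **Longitudinal cohort.** 14 patients × 8 stages (pre-surgery plus 7 monthly
  follow-ups). ICP and ventricular volume decline exponentially toward a
  post-shunt plateau (stabilization within the follow-up window, plateau at
  60% of baseline by default) with seeded month-to-month oscillation;
  surface area and cyclic deformation co-vary mildly with ventricular size.
  Baseline ICP is drawn from 12–25 cmH₂O.
- **Monitored ICP.** Invasive-sensor readings for a 10-patient validation
  subset are true values with multiplicative Gaussian noise (2% default), so
  synthetic calculated-vs-measured differences land naturally in the
  few-percent range.
- **Independence mode.** For type-I-error control of the correlation
  analysis, a dedicated generator draws per-interval ICC and stiffness
  independently at clinically plausible scales; any detected association in
  that table is spurious by construction.

What the generator does **not** emulate: vascular (arterial/venous) volume
pulsation, which in vivo dominates the ICP pulse; patient-specific anatomy
and its stage-to-stage remodeling (the idealized geometry is
stage-independent, so longitudinal volume changes enter only through the
synthetic records); measurement artifacts beyond unbiased multiplicative
noise. Passing tests therefore demonstrate correctness of the numerics and
the analysis chain, not clinical fidelity of absolute ICP dynamics.

## Known limitations

- A zero-resistance shunt outlet clamps the cycle-mean ICP to the valve
  pressure, so the grid-independence differences on the default treated
  configuration sit at the solver noise floor (~1e-4 %); this is the model's
  honest behavior, not a tuned outcome. A valve resistance model would
  restore ICP dynamics but is outside the present scope.
- The global mass-balance diagnostic on coupled runs retains a
  dt-independent residual of a few percent of the pulsatile amplitude
  (~0.01 ml/min): fluid flows through the stationary inflow/shunt patches
  whose mesh does not move, and the geometry lags the step. Steady rigid-wall
  balance is exact (<1e-10 ml/min).
- Small-strain kinematics without geometric stiffness; finite-strain effects
  and tissue prestress enter only through the gauge-pressure argument.
- No gray/white heterogeneity, anisotropy, or glymphatic/interstitial
  exchange; the interface is impermeable to pore fluid.
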