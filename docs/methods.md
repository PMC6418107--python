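# Methods

This note documents the models, defaults, and numerical choices behind
`femstrength`, and what the synthetic data do and do not establish.

## Synthetic QCT volumes and cohorts

The proximal femur is the union of three solids: a head sphere (radius
24 mm), a neck cylinder (radius 16 mm, length 35 mm) inclined at a
125° neck–shaft angle, and a vertical shaft cylinder (radius 15 mm, length
70 mm), all scaled mildly with stature. A uniform cortical shell
(3 mm) is carved by binary erosion; the shell carries the subject's
cortical mineral-equivalent density and the interior the trabecular
density. Background soft tissue is fixed at 0 mg/cc equivalent density so
the phantom intercept stays identifiable. Three calibration rods
(0 / 75 / 150 mg/cc hydroxyapatite by default) run through the field of
view below the femur; rod ROIs are the inner cores of the rods, kept at
least one voxel half-diagonal wide so they remain non-empty at coarse
voxel sizes. A scanner forward model maps density to Hounsfield units,
`HU = s·ρ + b + N(0, σ)` with defaults `s = 0.8 HU/(mg/cc)`, `b = 10 HU`,
and per-voxel Gaussian noise.

Cohort demographics are truncated-normal draws with the published
mean ± SD (range) summaries of the reference populations: fractured
(n-scale 45, age 80.3 ± 5.7, range 71–93) and non-fractured elderly males,
age-stratified males and females spanning 27–90 years, and an
8-member astronaut-like cohort (age 46 ± 5, flight duration 154 ± 19
days). Compartment densities are cohort-level truncated normals; the
fractured specification shifts density means down 15% so its capacity
distribution sits below the non-fractured one, which is what makes a
fractured-cohort percentile a meaningful cut-point.

The spaceflight effect is multiplicative exponential decay per compartment
with subject-level lognormal noise. Defaults are 0.9 %/month trabecular
and 0.6 %/month cortical: the trabecular:cortical ratio (1.5:1) encodes the
established observation that hip trabecular bone is lost faster than
cortical bone in microgravity, and the magnitudes are sized so a ~5-month
mission produces the few-percent total-hip losses observed in crews flying
with resistive-exercise countermeasures. Doubling the duration exactly
doubles the log-scale loss at zero noise.

Projected DXA: `aBMD = Σ(ρ·voxel volume)/projected area` over the femur
mask along the anterior–posterior axis, in g/cm²; the T-score divides the
deviation from a young-adult reference by the reference SD. The clinical
reference populations are proprietary, so the default reference
(1.55 ± 0.13 g/cm²) is pinned to the synthetic young cohort's projection at
the default demo voxel size; this places astronaut-like subjects near
T ≈ +1 and fractured elderly near T ≈ −2, reproducing the band structure
the classification logic assumes. Both numbers are configuration.

## Density calibration and cross-calibration

Calibration regresses nominal rod density on observed ROI-mean HU
(ordinary least squares). The nominals are exact, so the regression runs
in this direction rather than as inverse prediction. The affine fit is
applied voxelwise and flagged; calibrating twice is an error. With a
noiseless scanner the fit inverts the forward model exactly (R² = 1).

Cross-calibration regresses region-mean calibrated densities of the same
physical regions seen on two scanners — the phantom rods plus the cortical
and trabecular compartments of a designated synthetic subject — and applies
the resulting affine map at the voxel level, rewriting the scanner
identity. Region means rather than raw voxels suppress noise. DXA
manufacturer harmonisation is a configured linear map on aBMD; the
published instrument-specific equations are user-supplied configuration.

## Voxel finite-element model

**Mesh.** Voxels above the bone threshold (default 100 mg/cc) become
8-node hexahedra sharing nodes with face-adjacent voxels; the largest
face-connected component is retained. `distal_face` is every node on the
inferior cut plane; `head_surface` is the femoral-head cap within a
configured angular window (default 50°) of the incoming load direction,
using the head centre/radius from generator metadata or an estimate from
the superior bone voxels.

**Material.** `E = 14900·ρ^1.86 MPa`, `σ_y = 102·ρ^1.8 MPa` (ρ in g/cm³
mineral-equivalent), following the widely used femoral power-law family.
The uniaxial curve is elastic to `σ_y`, perfectly plastic for 0.005 strain,
linear softening at 1000 MPa down to `0.3·σ_y`, then a residual plateau.
Poisson's ratio 0.3. All eight constants are configuration: the validated
constants used for the clinical capacity values are not public, so package
capacities are meaningful relative to the configured curve, and all tests
are stated that way.

**Solution.** Monotonic displacement-controlled loading: all three DOFs of
the head-cap nodes are prescribed along the unit load direction (NLS
default 20° from the shaft axis in the coronal plane; NLF default a
posterolateral, 68°-from-vertical direction; both recorded in result
metadata because the source protocols do not publish angles).
Nonlinearity is handled by deformation-theory secant iteration: element
Gauss-average strain → von Mises effective strain (normalised to equal the
axial strain of a uniaxial stress state at the material's ν) → uniaxial
stress → secant modulus `σ/ε_eff`, floored at 1e-4 of the element's elastic
modulus to keep fully softened elements from making the system singular.
This matches the monotone, proportional-loading regime of the capacity
test; it is not an incremental-flow plasticity and cannot represent
unloading. Iterations converge on relative change of either the moduli or
the head reaction (tolerance 1e-3), with full updates for the first three
iterations and 0.5-damped updates afterwards to quench the ping-pong the
softening branch can sustain. Factorisations (SuperLU, symmetric-mode
minimum-degree ordering) are reused as CG preconditioners while moduli
have drifted less than 25%.

"Force began to decrease" is operationalised as the current reaction
falling below `(1 − δ)` of the running maximum, δ = 0.02 by default, which
is robust to float noise; the capacity is the running maximum. The solver
is deterministic — identical inputs give bit-identical results.

**Verification.** A single displacement-loaded element reproduces the full
four-region curve with capacity `σ_y·A` to 1e-6 relative; a two-element
series bar matches it; a homogeneous elastic block passes the patch test to
machine precision; external work equals stored energy elastically; capacity
is invariant to rigid translation and node renumbering and strictly
monotone in a global density scaling.

## Cut-points, bands, and change

The POL is the q-th percentile (default 75) of the fractured-cohort
capacity sample, with linear interpolation between closest ranks (the
estimator is recorded in output metadata because several percentile
definitions exist). One POL serves both sexes. Boundary convention:
values at or above a cut-point pass, mirroring the "T ≥ −1.0" phrasing of
the certification standard; least-significant-change (LSC) exceedance is
strict. Adopted clinical constants: POL 9537 N (NLS) / 3664 N (NLF),
T-bands −1.0 / −1.5 / −2.0, LSC 3.6% (NLS) / 11.3% (NLF) — the LSCs come
from instrument precision studies and are consumed as constants, not
re-derived. Classification is a pure function of its inputs and is
monotone: raising any input never worsens the decision. Regression
statistics are simple linear regression R² with the two-sided correlation
t-test (n − 2 df, α = 0.05); the astronaut-vs-population group comparison,
whose original test is unnamed, is implemented as Welch's t-test where
needed.

## Overload risk

Applied hip loads per (mission scenario, event-energy class) are
parametric families scaled by effective gravity (ISS 0, Moon 0.165, Mars
0.379, Earth 1). The published mission load model is external and its
parameters are not public; the defaults are lognormal placeholders chosen
once so that low-energy Earth-return loads concentrate between 1 and 4 kN
(median 2.5 kN, log-σ 0.35) and high-energy events sit above them (median
4.4 kN, log-σ 0.40). Consequently the overload probabilities the package
prints at the 3664 N cut-point (≈0.14 low-energy, ≈0.68 high-energy,
≈0 for reduced-gravity scenarios) characterise these configured
distributions, not the external model. Exceedance is evaluated in closed
form via the survival function, with Monte Carlo (SE `√(p(1−p)/n)`) as the
cross-check; gravity scaling makes reduced-gravity probabilities dominated
by Earth-return for any capacity.

## Pipeline and reproducibility

`run_pipeline` executes simulate → calibrate → FE → cut-points → PRA →
report from a single YAML config with one master seed; stage seeds follow
a documented counter scheme (`master·100003 + stage index, mod 2^31`) and
subject-level generators add the subject index. The manifest records the
config snapshot, seeds, package version, and SHA-256 digests of every
output, so every number in every table is regenerable. Reruns are
byte-identical for all CSV/JSON tables. Volumes round-trip through NIfTI
with a same-grid label volume for masks and a JSON sidecar for scalar
metadata.

Default problem sizes — 6 mm voxels for the 8-subject demo cohort and its
12-subject fractured reference, 4–5 mm for single-subject examples — keep
the full chain at desk scale; they were chosen as the package's own demo
conditions. Capacities are resolution-dependent at these sizes (coarser
meshes are stiffer), so demo-scale capacities sit above the clinical
cut-points derived from ~1 mm patient scans, and the derived demo POLs are
reported alongside the adopted clinical ones rather than replacing them.

## Limitations

The parametric femur has no anatomical shape variation, no trabecular
architecture, and a resolution-limited cortical shell; the scanner model
has no beam hardening, scatter, or kernel effects; loading is prescribed
displacement on a node cap, without contact or a deformable pad; the
material is isotropic with a single curve family. Passing tests therefore
establish the correctness of the computational chain — calibration
algebra, FE mechanics against analytic oracles, estimator and
classification logic, and probabilistic machinery — not the clinical
accuracy of capacity estimates on real anatomy.
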