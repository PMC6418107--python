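# femstrength

**QCT-based finite-element hip load capacity, cut-points, and overload risk
for astronaut skeletal-health monitoring.**

Long-duration spaceflight causes rapid bone loss at the hip that DXA areal
BMD (aBMD) and its T-score only partially capture. A more direct index is
the *load capacity* of the proximal femur — the maximum force the hip can
carry before failing — estimated from quantitative CT (QCT) by nonlinear
finite-element (FE) analysis in two loading configurations:

- **NLS** — nonlinear single-limb stance (habitual loading), capacity
  `F_NLS`;
- **NLF** — nonlinear posterolateral fall onto the hip, capacity `F_NLF`.

Population capacity distributions then give clinical cut-points: the
75th percentile of the fractured elderly male reference cohort defines the
permissible outcome limit (POL), `F_NLS ≥ 9537 N` and `F_NLF ≥ 3664 N`,
used alongside the DXA bands (certify at `T ≥ −1.0`, FE screening for
`−1.5 < T < −1.0`, post-flight POL at `T = −2.0`). Finally, a Monte-Carlo
probabilistic risk assessment (PRA) turns an individual's fall capacity
into `P(applied hip load > capacity)` per mission scenario and event-energy
class.

This package implements that entire chain on synthetic data, because the
underlying human scans are restricted:

| module | role |
|---|---|
| `synth_cohort` | parametric femur QCT volumes with in-field calibration phantom; cohort demographics; spaceflight bone-loss effect; projected DXA aBMD/T-score |
| `density_cal` | phantom HU→density calibration; voxelwise scanner cross-calibration; DXA manufacturer harmonisation |
| `voxel_fe` | voxel hexahedral meshing; four-region strain-softening bone material law; displacement-controlled secant FE solve for `F_NLS` / `F_NLF` |
| `risk_bands` | percentile POL derivation; pre/post-flight operating-band classification; least-significant-change flags; regression statistics |
| `pra_overload` | mission load distributions; closed-form and Monte-Carlo overload probability; factor of risk |
| `pipeline` / `cli` | simulate → calibrate → FE → cut-points → PRA → report orchestration with a reproducibility manifest |

## The FE model in brief

Each bone voxel (calibrated mineral-equivalent density ρ, g/cm³) becomes an
8-node hexahedral element with isotropic modulus and yield stress from
density power laws `E = a·ρ^b`, `σ_y = c·ρ^d`. The uniaxial law is
elastic → perfectly plastic plateau → linear softening → residual plateau
`r·σ_y`; yield follows the distortion-energy (von Mises) criterion.
Displacement is incremented on the femoral-head surface along the
configuration's load direction with the distal shaft fixed; element secant
moduli `σ(ε_eff)/ε_eff` are iterated to equilibrium at each step, and the
capacity is the maximum head reaction force before the force–displacement
curve turns over. See `docs/methods.md` for assumptions, parameter defaults
and limitations.

## Worked example

```python
import femstrength as fs

subject = fs.generate_cohort("astronaut", 1, seed=1)[0]
scanner = fs.ScannerModel(noise_sd=2.0)
vol = fs.generate_volume(subject, scanner, voxel_mm=4.0, seed=2)

fit = fs.fit_phantom_calibration(vol)
print(f"calibration: slope {fit.slope:.4f} mg/cc per HU, "
      f"intercept {fit.intercept:.2f} mg/cc, R^2 {fit.r_squared:.6f}")
cal = fs.apply_calibration(vol, fit)

nls = fs.run_configuration(cal, "NLS")
nlf = fs.run_configuration(cal, "NLF")
print(f"{nls.label} = {nls.load_capacity:.0f} N ({nls.stopped_reason})")
print(f"{nlf.label} = {nlf.load_capacity:.0f} N ({nlf.stopped_reason})")

pre = fs.classify_preflight(fs.project_dxa(cal).t_score, nls.load_capacity)
print("pre-flight decision:", pre.preflight_decision)
```

prints

```
calibration: slope 1.2507 mg/cc per HU, intercept -12.59 mg/cc, R^2 0.999974
F_NLS = 15242 N (force_drop)
F_NLF = 10261 N (force_drop)
pre-flight decision: certified
```

The calibration inverts the simulated scanner's HU map (slope `1/0.8`
within the voxel noise), the stance capacity exceeds the fall capacity as
the weaker bending mode dictates, and the subject clears both the DXA and
FE screening bands. Capacities from the coarse demo meshes are
mesh-resolution dependent and sit above the clinical cut-points derived
from full-resolution patient models; within the package they are always
interpreted relative to the configured material curve and resolution.

The same chain is available from the shell:

```bash
femstrength run --seed 0 --out out/          # full pipeline, 8 subjects
femstrength pra --capacity 3664 --out pra.csv
```

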