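# cardioflow4d

Quantitative intracardiac analysis of 4D-flow cardiovascular MR: particle
tracing, kinetic energy, vortex-ring volumetry, through-plane stroke
volume, and the paired statistics used to compare acquisition protocols —
validated end-to-end on analytic velocity phantoms with known ground
truth.

## The problem

Whole-heart phase-contrast CMR acquires all three velocity components
over a 3D volume, time-resolved across the cardiac cycle ("4D flow").
From such data one can quantify how blood actually moves inside the left
ventricle — not just how much crosses a valve. The quantities this
package computes are the standard intracardiac ones:

- **Particle-trace (PT) inflow/outflow.** Seed one particle per voxel of
  the end-diastolic LV segmentation, each carrying one voxel volume.
  Traced *backward* in time to end-systole, particles ending on the basal
  side of the mitral plane are blood that entered during diastole; traced
  *forward* to end-systole, those basal of the aortic plane leave during
  systole. With normal valves the two volumes should be equal, so their
  difference measures data quality. Integration is 4th-order Runge–Kutta
  with a 5 ms step and linear interpolation in space and time.
- **Kinetic energy.** KE(t) = Σ ½ m v² over LV voxels, m = ρ·V_voxel with
  ρ = 1060 kg/m³, in mJ, with mean and peak summaries.
- **Vortex-ring volume.** Backward finite-time Lyapunov exponent (FTLE)
  fields, FTLE = ln λ_max(FᵀF) / (2|T|), whose ridges bound the vortex
  ring formed during rapid filling; the ring volume is delineated in
  short-axis slices 4 mm apart and summed.
- **Stroke volume.** Time integral of through-plane flux over a vessel
  ROI, on 2D flow series and on matching planes resampled from the 4D
  volume.
- **Agreement statistics.** Wilcoxon signed-rank (exact for small n),
  Pearson r / R² with linear regression, and Bland–Altman bias ± SD with
  percentage differences — the layer used to compare two protocols (e.g.
  respiratory-gated vs non-gated) on the same subjects.

Preprocessing covers velocity unwrapping at VENC and eddy-current
background correction by a linear fit to stationary tissue.

Because no real scans ship with the package, a first-class phantom module
generates periodic 4D velocity fields with analytically known truth — a
plug-flow tube, a beating-ventricle chamber with prescribed stroke
volume, and a spherical vortex — plus the corruptions the pipeline must
undo (aliasing, Gaussian velocity noise, affine background offsets). See
`docs/methods.md` for the models and every default.

## Worked example

```python
from cardioflow4d.phantoms import PhantomSpec, make_contracting_ellipsoid
from cardioflow4d.intracardiac import pt_volumes, kinetic_energy_curve

spec = PhantomSpec(kind="contracting_ellipsoid", target_sv=80.0, ed_volume=140.0)
field, truth, seg, planes = make_contracting_ellipsoid(spec)

result = pt_volumes(field, seg, planes["mitral"], planes["aortic"])
print(f"seeded ED volume : {result.seeded_volume:.1f} ml")
print(f"PT inflow        : {result.inflow_volume:.2f} ml")
print(f"PT outflow       : {result.outflow_volume:.2f} ml")

ke = kinetic_energy_curve(field, seg)
print(f"KE mean / peak   : {ke.mean_ke:.2f} / {ke.peak_ke:.2f} mJ")
```

prints

```
seeded ED volume : 140.0 ml
PT inflow        : 80.05 ml
PT outflow       : 79.06 ml
KE mean / peak   : 0.71 / 3.90 mJ
```

The phantom prescribes a 140 ml end-diastolic ventricle ejecting 80 ml
per beat; particle tracing recovers the inflow to +0.1 % and the outflow
to −1.2 %, and their 1.2 % imbalance is the healthy-valve consistency
check. The KE curve peaks during ejection, in the few-mJ range typical of
a left ventricle.

The same workflow is scriptable from the shell: `cardioflow4d phantom`
generates a dataset container, `preprocess` unwraps and removes the
background fit, `intracardiac`, `vortex` and `sv` emit the metrics, and
`compare` produces agreement tables and Bland–Altman plots. `cardioflow4d
run --config study.yaml` chains everything over multiple conditions and
subjects with deterministic seeding.

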