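# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `cardioflow4d`. It is written for a reader who wants to know
exactly what the package computes and why the defaults are what they are.

## Data model and conventions

Velocity data are a periodic, time-resolved, three-component field on a
regular grid: array axes `(timeframe, z, y, x, component)`, components
`(vx, vy, vz)` in world axes, units cm/s (the unit VENC is quoted in).
World coordinates are millimetres with a voxel-*center* convention: voxel
`(iz, iy, ix)` sits at `origin + (ix*dx, iy*dy, iz*dz)`. Frame `k`
represents time `k * timeframe_duration` ms and time wraps periodically
between the last and first frame, as retrospective ECG gating implies.
Velocities are converted to mm/ms only inside the particle tracer
(100 cm/s = 1 mm/ms). The NIfTI importer cannot infer a scanner's world
handedness reliably, so axis flips are an explicit caller decision.

## Preprocessing

**Unwrapping.** Phase-contrast velocities alias by multiples of 2·VENC.
The corrector minimizes each sample's jump to its temporal predecessor
over the periodic cycle (up to 3 passes), then removes any whole-series
2·VENC offset by re-centering the temporal mean. It is a temporal
algorithm: it assumes a voxel's velocity does not genuinely change by
more than VENC between adjacent frames, which holds at 25 ms frame
spacing for intracardiac flow. A manual-correction hook accepts explicit
`(voxel, frame, component, k)` fixes. Every change is an integer multiple
of 2·VENC by construction.

**Stationary-tissue selection.** A voxel is stationary when the temporal
standard deviation of its speed is below a threshold (default 2 cm/s) and
it lies outside all LV masks dilated by 1 voxel. The threshold trades
completeness against contamination by slow flow; 2 cm/s is comfortably
above thermal velocity noise at typical SNR yet below any pulsatile
signal.

**Background correction.** Eddy-current phase offsets appear as a static,
spatially slowly varying velocity bias. Per component, the time-averaged
velocity over stationary voxels is fitted by least squares to
`c0 + c1·x + c2·y + c3·z` (world mm) and the plane is subtracted from all
voxels and frames. Fitting the time average (rather than per-frame) is
deliberate: the physical offset is static, and averaging improves the fit
SNR by √nt. The fit requires at least 10 voxels per parameter and a
full-rank spatial design; both are enforced. The correction is idempotent.

## Particle tracing

Pathlines are integrated with classic fixed-step RK4, default 5 ms,
sampling the measured field by trilinear interpolation in space and
linear interpolation in time (periodic between the last and first frame).
The final step is shortened to land exactly on the target time. Backward
tracing integrates the same field with time running negatively and
crosses the cycle boundary when end-systole precedes end-diastole in
frame order: time is a circle. Measured convergence order on a rotation
field is 4.0; a constant field is advected exactly.

Particles that leave the voxel-center bounding box are frozen at their
last in-grid position and flagged `left_grid` instead of being dropped,
so the volume each particle carries (one source voxel, 27 mm³ at 3 mm
isotropic) is conserved and every fate is auditable. Velocity is sampled
from the measured field everywhere; segmentation masks are used only for
seeding and classification.

## Particle-trace inflow/outflow volumes

One particle is seeded at each voxel center of the end-diastolic LV mask.
Traced backward to end-systole, a particle ending on the basal side of
the mitral plane (`(y − p)·n ≥ 0`, ties basal) is inflowing blood; traced
forward to end-systole, one ending basal of the aortic plane is
outflowing. Volumes are particle counts times the voxel volume, so
`basal + residual + left_grid` accounts for the seeded ED volume exactly.
End-systole time is the ES frame center; ED/ES default to the
argmax/argmin of segmented volume. Classification uses final position
only. With normal valves, inflow and outflow should agree; their relative
difference is a data-quality measure (1.2 % on the ventricle phantom).

## Kinetic energy

`KE(t) = Σ_{voxels in mask(t)} ½ (ρ · V_voxel) |v|²`, reported in mJ,
with blood density ρ = 1060 kg/m³ (standard whole-blood value,
configurable). Mean and peak over the cycle summarize the curve. An
empty mask contributes zero with a warning.

## FTLE and vortex-ring volumetry

One particle per voxel center is traced over the integration window; the
deformation gradient F comes from central differences of end positions
over neighboring seeds, and `FTLE = ln λ_max(FᵀF) / (2|T|)` in 1/s.
Voxels whose own particle or any face neighbor left the grid are NaN.
Backward FTLE (reversed time from the window end) highlights attracting
structures — the surface bounding the filling vortex ring.

The vortex volume follows a slice-wise protocol: short-axis slices 4 mm
apart (FTLE linearly interpolated between grid planes); per slice, the
vortex region is the filled largest connected component above
0.6 × the volume-wide FTLE maximum after morphological closing (radius
1 pixel) and hole filling; slice areas × 4 mm sum to the volume. A
manual-polygon path (shoelace areas) is available as the alternative to
automatic delineation. The integration window should span at least one
core turnover time; on the 20 mm spherical-vortex phantom (peak 50 cm/s)
a 700 ms window expresses the bounding ridge on every slice and recovers
the sphere volume to −2.3 %, with halving the slice count changing the
volume by 9 %. Shorter windows leave the equatorial ridge weak and
under-segment. The ridge criterion and window are configuration
parameters, not claims about any particular prior implementation.

## Stroke volume from through-plane flux

Flux is `Σ_{pixels inside contour} v_through × pixel_area` with
center-inclusion rasterization, and SV is the rectangle-rule time
integral with `timeframe_duration` weights — matching retrospective
reconstruction, where each phase represents its temporal bin. For 4D
data the plane is resampled on a 1 mm in-plane lattice (finer than the
3 mm voxel so rasterization is not the dominant error) via the same
space-time interpolation as the tracer, and the identical ROI machinery
is applied; an in-plane rigid ROI shift mirrors manual repositioning.

## Agreement statistics

Differences are first-named condition minus second. Bland–Altman reports
bias, sample SD (n−1) of differences, and bias ± 1.96·SD limits; the
percentage difference divides by the pairwise mean (x+y)/2 by default
(the second condition is selectable) and excludes zero-denominator pairs
with a warning. The Wilcoxon signed-rank test drops zero differences
(Wilcoxon's original rule), computes the exact two-tailed p for n ≤ 25 by
convolving the signed-rank distribution over (tie-averaged, doubled)
ranks — identical to full sign enumeration — and uses the tie-corrected
normal approximation beyond, without continuity correction. Correlation
is Pearson r with OLS of y on x and a two-tailed t-test p on n−2 df. No
multiple-testing correction is applied.

## Synthetic phantoms

The generators emulate the statistical structure the pipeline assumes —
periodic cardiac flow, aliasing at VENC, Gaussian velocity noise, static
affine background offsets — with analytically known truth. They are
deterministic given their spec and seed, and all frame values are
temporal-bin averages of the underlying waveform, so rectangle-rule time
integrals of frame values reproduce continuous integrals exactly.

**Plug tube.** A straight tube with a half-sine systolic waveform
(defaults: core radius 15 mm, peak 50 cm/s, 300 ms systole, 40 frames /
1000 ms). The radial profile is 1 in the core with a smooth cosine rim of
half-width 3 mm; a hard edge at 3 mm voxels would quantize the lumen area
by ~3 %, defeating sub-percent flux checks, while the smooth rim has the
closed-form effective area `A_eff = πR² + w²(π − 8/π)` and samples
accurately. True SV is `A_eff · (2/π) v_peak · T_sys`. The segmentation
marks core voxels only, making the KE curve exactly `½ρV v(t)²`; the
ground truth also exposes the full lumen support, outside which the field
is identically zero (the exact-recovery background tests rely on this).

**Contracting ellipsoid (ventricle).** An ellipsoidal chamber bounded by
a mitral plane above (z = 10 mm, basal normal +z) and an aortic plane
below (z = −30 mm, basal normal −z) on a common axis. Both valve jets
share a radial bump profile `g(r) = (1 − (r/18 mm)²)²` (effective area
π·rj²/3) and a vertical envelope whose derivative is proportional to the
chamber's local annular capacity, with the radial component from
incompressibility — so each jet field is exactly divergence-free, inflow
deposits in a shell that fills the chamber from the inside out, and the
systolic jet drains that same shell. The Lagrangian volume crossing each
valve plane therefore equals the prescribed time-integrated flux
(`target_sv`) by construction, and it lies inside the end-diastolic mask.
Ejection ends 50 ms before end-systole and early filling starts 100 ms
after it (isovolumic phases); besides physiology, this gives marginally
slow particles slack to complete their plane crossing despite
interpolation lag, which otherwise biases traced volumes low by a few
percent. Masks rank chamber voxels by normalized ellipsoid radius and
keep exactly the count matching the volume curve (140 ml at ED, minus
80 ml at ES by default), so counted volumes track the curve within one
voxel. Measured PT recovery at the defaults: inflow +0.1 %, outflow
−1.2 %. Accuracy degrades gently toward high stroke volumes (−4 % at
SV = 102 ml) as the deposition shell approaches the chamber wall; the
multi-subject defaults stay at or below SV = 95 ml.

**Spherical vortex.** A steady, smoothly tapered spherical vortex:
Stokes streamfunction `ψ = (v_peak/2) r²(1 − s²/a²)²` inside radius
`a = 20 mm`, zero outside. Velocity vanishes continuously on the sphere
and the surround is exactly quiescent, so the recirculation region is the
sphere and the true vortex volume is `(4/3)πa³ = 33.51 ml` independent of
circulation strength. (The classical translating-sphere vortex cannot be
simultaneously steady, quiescent at infinity and boundary-continuous in
one frame; this variant keeps the volumetric ground truth while
satisfying all three.) The vortex analyses use a 2 mm grid: at 3 mm the
bounding ridge is under-resolved relative to the 20 mm radius.

**Corruption model.** Applied in acquisition order: optional periodic
through-plane displacement (a respiratory-motion stand-in, default off
and amplitude deliberately unasserted), static per-component affine
background, zero-mean Gaussian velocity noise (on velocity, not Rician on
magnitude — velocity noise is what scales with VENC), then aliasing
`v ↦ ((v + venc) mod 2·venc) − venc` with the wrap mask recorded.

**What passing phantom tests does and does not show.** The phantoms have
smooth, divergence-free (or analytically prescribed) flow, perfect
segmentations aligned with the velocity grid, white Gaussian noise and
no k-space, SENSE, or partial-volume magnitude effects. Passing them
validates the numerics and bookkeeping of the pipeline — interpolation,
integration, classification, volumetry, statistics — not its robustness
to real acquisition artifacts, mis-segmentation, or plane misplacement.

## Orchestration

The pipeline runs labelled *conditions* (e.g. clean vs noise-corrupted,
standing in for gated vs non-gated acquisitions) over a cohort of phantom
subjects that differ physiologically (stroke volumes 58–95 ml by
default), computes the selected metrics, and emits pairwise agreement
tables. All randomness derives from the config seed (condition labels are
hashed with CRC32, not Python's salted `hash`), so identical configs give
byte-identical metric CSVs; the run log records every default in use.

## Numerical choices and degenerate inputs

- RK4 stages that sample outside the grid freeze the particle; a zero
  seed set is an empty result, not an error.
- Exactly-on-plane particles classify as basal; polygon membership is by
  pixel-center inclusion; self-intersecting ROI polygons are rejected.
- FTLE guards `λ_max` with a floor before the log; zero-length windows
  are errors.
- The Wilcoxon exact distribution uses doubled ranks so tie-averaged
  half-integer ranks convolve on an integer lattice.
- All-zero differences give p = 1 with a note; zero-variance x is an
  error for correlation.
- Problem sizes in the validation suite (64³ FTLE grids, 33³ vortex grid,
  40-frame phantoms, 10⁴-shuffle null calibration) were chosen as the
  smallest at which the measured quantities are grid-converged to well
  inside their tolerances.

## Known limitations

- Temporal unwrapping cannot repair a voxel aliased in every frame by the
  same multiple (no temporal jump exists); spatial unwrapping is not
  implemented.
- The vortex delineation is a reproducible operationalization of a
  manual protocol; its threshold (0.6 of the field maximum) and window
  are defaults, not measurements of any reader.
- The tracer is fixed-step and linear-interpolating by design; adaptive
  stepping and cubic interpolation are out of scope.
- The ventricle phantom prescribes kinematics, not Navier–Stokes
  dynamics; its KE curve is a by-construction reference, not an
  independent closed form.
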