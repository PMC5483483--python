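# Methods

`aortaflow` implements a five-stage processing chain for time-resolved
phase-contrast (4D Flow) MRI of the thoracic aorta, together with a
synthetic-phantom generator that provides analytic ground truth for every
stage. This note records the models, the parameters that matter, the
numerical choices, and what the phantom does and does not emulate.

## Velocity reconstruction and corrections (step 1)

A phase-contrast acquisition encodes each Cartesian velocity component as a
phase φ ∈ (−π, π]; decoding is the linear map v = VENC·φ/π. Velocities
beyond the velocity-encoding range VENC wrap by multiples of 2·VENC
(aliasing). Three corrections are applied, in a fixed order that each field
records in provenance flags:

1. **Eddy-current (background phase) correction.** A first-order spatial
   polynomial `c0 + c1·x + c2·y + c3·z` is least-squares fitted per frame
   and component to *static* voxels and subtracted everywhere. Static
   voxels are those whose largest per-component temporal standard deviation
   falls below the 5th percentile of that statistic (default
   `static_percentile = 5`), additionally excluding voxels that are bright
   in the magnitude image (lumen). First order is the minimal standard
   background model; higher orders add free parameters the phantom cannot
   constrain.
2. **Aliasing correction.** A component differing from the median of its
   26-neighbourhood by more than VENC is shifted by the nearest multiple of
   2·VENC toward that median, iterated to a fixpoint (at most 5 sweeps).
   This is a local wrap model, not global phase unwrapping: it assumes
   aliased voxels are a minority surrounded by correctly decoded ones,
   which holds when VENC was chosen close to the true peak velocity.
3. **Noise reduction.** A componentwise 3×3×3 median filter per frame
   (reflected edges) — the smallest isotropic kernel. Note that near the
   wall the median mixes in the zero-velocity exterior and biases in-lumen
   speeds low by roughly 2% on the benchmark tube; conservation checks are
   therefore run on the decoded (unfiltered) field.

## Geometry (step 2)

The lumen region of interest is a binary voxel mask, built either from
per-slice polygon tracings (closed containment: a voxel centre on the
polygon edge is inside) or programmatically (phantoms). The wall surface is
the marching-cubes iso-surface of the mask at level 0.5, Laplacian-smoothed
(umbrella operator, 20 iterations, relaxation 0.1). This smoothing shrinks
a 10 mm tube's radius by ≈ 2%; the effect propagates to cross-section areas
(−4%) and flow (−2.7%) and sets the accuracy floor of the geometry.

The centerline is obtained by 3D thinning of the mask, ordering the
skeleton voxels by Dijkstra shortest path (26-connected graph, Euclidean
edge weights) between the skeleton voxels nearest the LVOT and DeA
landmarks, fitting an interpolating cubic spline (chord-length
parametrised), resampling at a quarter-voxel step, and smoothing with a
centred 5-point moving average whose window shrinks at the curve ends so
the endpoints are preserved. Thinning in this scikit-image release
annihilates objects of perfectly even voxel width; when that happens the
package falls back to the distance-transform ridge, which serves the same
purpose. PA and BrA landmarks are projected to the closest centerline
sample, ties broken toward smaller arc length.

**Curvature.** Pointwise curvature of a voxel-derived curve is dominated by
quantization noise (the skeleton wiggles by a fraction of a voxel at a few
millimetres' wavelength), so curvature is measured by least-squares circle
fits over 60 mm arc-length windows (or one global fit). On the torus
phantom the global fit errs by 0.25%, windowed fits by < 10%.

## Cross-sections (step 3)

Planes are placed at arc-length multiples of Δx (the mean voxel dimension)
starting at the LVOT, each normal to the local tangent x'₃. In-plane axes:
x'₁ is the configured anatomical anterior axis projected into the plane
(phantoms: +y), x'₂ = x'₃ × x'₁. Voxel centres strictly within 0.5·Δx of
the plane are projected orthogonally; their velocities are rotated into the
local frame (a pure rotation — norms are preserved to 1e-9). Coincident
projections are averaged. A plane lying exactly midway between voxel layers
gathers nothing under the strict inequality; such degenerate sections are
skipped with a log message (they arise only for measure-zero alignments).

The boundary Γ_π is the intersection of the plane with the smoothed wall
surface — not the voxel mask — for sub-voxel wall placement. It is ordered
counterclockwise viewed along +x'₃, started at the most anterior point
(the template's r = 0), and resampled to 72 equally spaced points. Wall
frames: because the boundary curve lies in both the surface and the plane,
the in-plane projection of the surface normal is exactly (anti)parallel to
the in-plane curve normal; the latter is far better conditioned on a coarse
triangulation, so the inward radial x'_r is built by rotating the boundary
tangent 90° in-plane toward the interior (this assumes star-shaped
sections, which aortic lumens are). The circumferential direction is
x'_t = x'_r × x'₃; with an inward radial and CCW boundary the ordered
triple (x'_r, x'_t, x'₃) has determinant −1 (equivalently,
(x'_t, x'_r, x'₃) is right-handed).

Scattered in-plane velocities are interpolated two ways: a Clough–Tocher
piecewise-cubic interpolant of the gathered samples (used wherever values
or derivatives near the wall are needed — it passes exactly through the
data), and a regular grid at a quarter-voxel step, masked and prolonged by
zero outside the lumen polygon with a no-slip zero ring on the boundary
(used for visualisation and any consumer wanting a dense field).

## Bulk flow (step 4)

Per section: polygon (shoelace) area A, equivalent diameter D = 2√(A/π),
and the net flow rate Q(t) = (A/N)·Σ v'₃ over the N gathered points (with
area in mm² and velocity in m/s, Q is numerically in ml/s). Peak systole
T_Ps is the first maximum of Q; end systole T_Es the last frame of the
strictly descending run that follows (a flat plateau at the maximum counts
as part of the peak); mid-deceleration T_dec the floor midpoint. Stroke
volume is the trapezoidal integral of Q from the first frame to T_Es. Speed
statistics, the jet angle α (angle between the mean of velocity vectors
with positive v'₃ and x'₃) and the normalized flow displacement d (distance
from the flow-weighted centre of velocity to the section centre, divided by
the equivalent diameter D — the normalization is a package choice) are
averaged over three frames centred on T_Ps, clipped at the sequence ends
with a logged warning. Tract summaries reduce sections over the half-open
arc-length intervals [LVOT, PA) and [PA, BrA); groups are compared with the
two-sided Mann–Whitney U test at α = 0.05 (all-tied inputs return p = 1).

## Wall shear stress (step 5)

Blood is Newtonian with viscosity μ = 3.7 cP. The shear tensor keeps only
off-diagonal terms, τ_ij = μ(∂u_i/∂x_j + ∂u_j/∂x_i) for i ≠ j with a zero
diagonal; the traction on the wall is T = τ·x'_r and the wall shear vector
its tangential part, WSS = x'_r × (T × x'_r). Two derivative estimators are
provided:

- **Global Volumetric (GV).** 3×3×3 Sobel derivative kernels, normalised so
  affine velocity fields are differentiated exactly (kernel weight 32 per
  unit spacing), give the full gradient tensor voxelwise. τ is interpolated
  trilinearly at each wall point offset one voxel inward along x'_r
  (configurable) so the zero-velocity exterior does not bias the stencil.
  GV reproduces spatial patterns (coefficient of variation < 15% along the
  uniform tube wall) but underestimates magnitude — ≈ 0.54 Pa against the
  0.74 Pa closed form on the benchmark, because the 3-voxel stencil
  averages across the steep near-wall gradient.
- **Local Planar (LP).** Works from a single cross-section. The wall-normal
  derivative of each local velocity component is extracted by sampling the
  Clough–Tocher spline along the inward radial ray at the upsampled-grid
  step over depths of 0.5–2.5 voxels and fitting v(d) ≈ c + a·d + b·d² by
  least squares; the slope a is the derivative at the wall. Fitting
  interior samples and extrapolating is the load-bearing choice: it is
  exact for locally quadratic profiles and insensitive to the sub-voxel
  wall-placement error of the smoothed surface, whereas differentiating
  across the wall mixes in the zero exterior and is biased by tens of
  percent. Because velocity vanishes identically along the wall curve
  (no slip), the full in-plane gradient of each component at a boundary
  point is its normal derivative times the inward normal; τ is assembled
  from these with out-of-plane derivatives set to zero (a single section
  carries no axial-derivative information). On the benchmark tube every
  wall point lands within 2.5% of 4μV̄/R.

Time metrics are integrated by the trapezoid rule with the actual (possibly
non-uniform) frame times over the systolic window [first frame, T_Es]:
AWSS (time-averaged |WSS|), AWSSV (|time-averaged WSS|),
OSI = 0.5·(1 − AWSSV/AWSS) ∈ [0, 0.5], RRT = [(1 − 2·OSI)·AWSS]⁻¹, and
TransWSS = time-average of |WSS·(n × ē)| with ē the unit mean-WSS direction
and n the wall normal — the literature-standard definition of the
transverse component. Component oscillation indices OSI_ax and OSI_circ
apply the scalar analogue 0.5·(1 − |∫w|/∫|w|) to the signed axial and
circumferential series. Degenerate cases are reported as missing, never
silently zero: OSI is undefined where AWSS = 0, RRT and TransWSS where the
mean vector vanishes (a perfectly reversing load has no residence-time
direction).

## Wall template and cohort comparison

Wall points between the LVOT and BrA landmarks map to normalized
coordinates: s ∈ [0, 1] (arc length from LVOT to BrA) and r ∈ [0, 1)
(counterclockwise boundary arc length from the most anterior point). The
template grid is 64 × 72 cells — the circumferential count is divisible by
8 so sector boundaries fall on cell edges. Cells average their contributing
points; empty cells are filled by nearest occupied cell within 2 cells
(wrapping circumferentially), farther cells stay missing. Eight sectors:
longitudinal split at the PA landmark line, circumferential quarters
*centred* on the orientation points (anterior at r = 0, then
counterclockwise left, posterior, right) with boundaries at r = 1/8, 3/8,
5/8, 7/8 — centring, rather than edging, the quarters on the anatomical
directions keeps the anterior sector symmetric about r = 0.

Cohort percentile maps (10th/50th/90th, linear interpolation) are computed
per cell over at least 3 subjects; a patient map is classified per cell as
above-p90 (strict), below-p10 (strict), or split at p50 (≤ p50 goes to the
lower middle class) — strict outer inequalities and a deterministic tie
rule keep the four classes a partition. Class area fractions weight cells
by local wall area (circumference × Δs). Exceedance is the maximum percent
excess over the p90 map across cells. The follow-up utility converts a
diameter change over an interval into mm/year and flags rates strictly
above the 0.5 mm/year guideline threshold.

## The phantom: what it emulates, and what it does not

The generator produces straight-tube and torus-arc lumens on voxel grids
mimicking the stated acquisition envelope (defaults: 1.6 mm isotropic
voxels, 24 frames at 40 ms, VENC 1.5 m/s). In-lumen velocity is the
axisymmetric parabolic profile v(r) = 2·V̄(t)·(1 − r²/R²) along the local
axis, with V̄(t) = V̄·w(t) and w a half-sine systole followed by zero
diastole (default systole fraction 0.6). Analytic truth ships with every
dataset: wall points, |WSS|(t) = 4μV̄(t)/R, Q(t) = πR²·V̄(t), centerline and
area. Lumen membership is by voxel centre (no partial volume) so the oracle
stays exact. Optional corruptions: additive Gaussian noise truncated so
speeds stay below VENC, per-frame first-order eddy offsets, and explicit
±2·VENC wraps of the fastest voxels (recorded for tests). Default noise is
zero: the acceptance tolerances quantify discretization, not noise.

The phantom does **not** emulate valve jets, turbulence, Womersley
(unsteady) profiles, wall motion, partial-volume or k-space/MR signal
effects. Passing tests therefore demonstrate correctness of the numerics
under idealised kinematics — parabolic-profile accuracies (e.g. LP within
2.5% of the oracle) will degrade on real jets with thinner boundary layers
than 4D Flow resolves; the method ranking (LP more accurate, GV an
underestimate) is expected to transfer.

Default phantom grids place the tube axis on voxel centres (odd transverse
dimensions, e.g. 25×25×36). Problem sizes used by the test-suite and the
acceptance script — a 25×25×36 grid with 3–10 frames, ~21 cross-sections of
72 boundary points, cohorts of 3–4 phantom subjects — were chosen as the
smallest that leave the discretization tolerances (3% flow, 10% WSS)
comfortably diagnostic.

## Known limitations

- Surface smoothing shrinkage (≈ 2% in radius at R/h ≈ 6) is the dominant
  geometric bias; areas and flow inherit it.
- The LP estimator needs ≥ ~4 interior samples along the inward ray; on
  vessels narrower than ~5 voxels it degrades (fits fall back to zero with
  a logged warning).
- The eddy-current model is first order only; concomitant-gradient
  (Maxwell) terms are out of scope.
- Sector labels assume the anterior axis is meaningful for the acquisition
  orientation; phantoms fix it to +y.
- The half-sine waveform with an even systolic frame count has a two-frame
  plateau at its maximum; timing detection treats the plateau as the peak.
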