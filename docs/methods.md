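# Methods

This note documents the models implemented in `coro3d`, the parameters that
matter, the synthetic phantom used for validation, and the design choices
made where the problem was genuinely open.

## Acquisition geometry

A single-plane C-arm view is a cone-beam projection. The world frame sits at
the isocenter with x = patient's left, y = anterior, z = cranial. For
primary angle α (LAO > 0, RAO < 0) and secondary angle β (CRA > 0, CAU < 0)
the central-ray axis is

    d(α, β) = (sin α cos β, cos α cos β, sin β),

so the AP view (α = β = 0) has the source posterior at −SOD·d and the
detector anterior at (SDD − SOD)·d. In-plane detector axes are
u = (cos α, −sin α, 0) (image columns) and v = d × u (image rows, caudal
for β = 0); detector roll about the central ray is fixed at zero, and the
phantom renderer uses the identical convention, so any roll would cancel.
Pixel coordinates are continuous (row, col) with pixel centers at integers
and the principal point defaulting to the image center.

Clinical angle and axis conventions are not standardized in the literature;
this frame was fixed once so that LAO/RAO/CRA/CAU behave as clinicians
expect and every module agrees bit-exactly.

Defaults: SOD 750 mm, SDD 1000 mm, detector pitch 0.2 mm/px, 512×512 —
typical cardiac C-arm values, all overridable per view in the case config.
The phantom's default cases use 0.35 mm/px (an ~18 cm field of view on the
512 matrix) so a ~70 mm vessel plus a 20/10 mm table shift stays inside the
image with margin.

## 2D segmentation

**Vesselness.** The Frangi response is computed per scale σ from
σ²-normalized Hessian eigenvalues |λ₁| ≤ |λ₂|:

    V_σ = exp(−R_B² / 2β²) · (1 − exp(−S² / 2c²)),   R_B = λ₁/λ₂,
    S = √(λ₁² + λ₂²),

zeroed where λ₂ ≤ 0 (wrong curvature sign for a dark vessel), maximized
over scales. Two details matter and are deliberate: the Hessian eigenvalues
are σ²-normalized, and the structureness constant c is *global* (half the
maximum Frobenius Hessian norm over all scales of the image) rather than
per scale. Per-scale normalization equalizes the peak response of every
scale, which lets small-scale *edge* responses win the across-scale maximum
and produces a double-ridge artifact along the vessel borders; the global
constant makes the response peak on the vessel axis. Derivatives come from
`skimage.feature.hessian_matrix` with reflective boundary handling.
Defaults: scales σ ∈ {1, 2, 3, 4, 6, 8} px (vessels of ~2–20 px diameter),
β = 0.5, dark polarity.

**Mask.** Threshold at 0.4 of the maximum response, keep the connected
component containing both endpoints (each snapped to the nearest
above-threshold pixel within 10 px), fill holes. The 0.4 operating point
was calibrated on the analytic straight-tube phantom, where the mask then
reproduces the true 9 px width with ≥ 97% coverage and < 1% false pixels;
lower thresholds over-segment the wall (e.g. 0.3 adds ~20% false pixels on
the tube). The threshold is relative to the image's own maximum, so a
strongly foreshortened or overlapping segment can push faint distal parts
below it — see Limitations.

**Centerline.** The eikonal equation |∇T| = 1/F with F(x) = D(x) + ε
(D = Euclidean distance to the mask boundary, ε = 0.1 px; zero speed
outside the mask) is solved with a first-order upwind fast-marching scheme
on the pixel grid from the proximal endpoint. The wall-distance speed makes
the fastest path run along the lumen axis rather than cutting corners. The
path is traced from the distal endpoint by steepest descent on the
bilinearly interpolated arrival time (step 0.25 px, with a discrete
lowest-neighbor fallback at flat spots), anchored exactly at the supplied
continuous endpoints, and resampled to 1 px arc-length steps. The supplied
endpoints are trusted landmarks (catheter tip, distal contrast end) and are
not quantized to the pixel grid; this matters for panning estimation below.

**Diameters.** At each interior point the tangent comes from central
differences; rays are cast along ± the normal, sampling the mask bilinearly
in 0.1 px steps, and the first 0.5-crossing is interpolated to sub-pixel
precision. The diameter is the *sum* d⁺ + d⁻ of the two one-sided border
distances — "averaging the two border distances" would yield a radius, and
the sum is the only reading consistent with a diameter; the choice is
isolated in one function if a different convention is ever needed.
Endpoints copy their nearest interior value; points whose rays never exit
within 40 px are flagged and interpolated from neighbors.

**Endpoint fallback.** When no endpoints are supplied, the two extremities
of the longest geodesic of the skeletonized mask are used (double
breadth-first sweep, tips extended to the mask boundary to undo
skeletonization erosion); the proximal one is the extremity nearer the
configured catheter-entry border (default: top edge). This is a heuristic
stand-in for interactive or learned endpoint detection and assumes a single
dominant vessel.

## Template correspondence

Template construction: each source 3D centerline is uniformly scaled to
unit arc length, translated so its start point is the origin, and resampled
to n = 100 points equidistant along the polyline; the template is the
coordinate-wise mean, renormalized. Equidistance is enforced exactly
(relative chord spread < 1e-7) by a shooting method: points are placed by
walking the polyline at a trial chord length and the chord is bisected
until the walk lands on the end point. Plain uniform-arc resampling leaves
chords varying with curvature and would violate the equidistance contract.
The walk requires a locally smooth polyline; centerlines whose arc length
is dominated by point-to-point noise are rejected with an explicit error
rather than silently resampled.

For a view pair, the template is projected *orthographically* along each
view axis and r_k(i) = cumulative projected length up to point i over total
projected length. A population template has no defined pose or scale in the
patient, so a perspective projection would be ill-posed; orthographic
ratios are invariant to the unknown magnification, and perspective effects
on *ratios* are second-order at coronary scales (verified on phantoms:
with the template equal to the true shape, the full
correspond-and-triangulate loop reproduces the centerline to ~0.3% of
vessel length). Correspondence pair i is then the point at arc-length
fraction r₁(i) of centerline 1 matched to the point at fraction r₂(i) of
centerline 2, linearly interpolated, with diameters interpolated the same
way. The template's start/end are assumed to coincide with the segmented
proximal/distal endpoints, which both anchor at the catheter tip and the
distal contrast front.

The per-index mean ± SD distance from the template to its source models
("template spread", unit-length scale) quantifies population shape
variability; it is zero at the start by construction and grows distally.

## Triangulation and table panning

The view-1 pixel p₁ back-projects to the ray P(s) = S₁ + s·e₁. After the
in-table-plane shift (t_x, 0, t_z), its view-2 image is a straight line
(the epipolar line), parametrized projectively in s. The reconstructed
point is P(s*) where the view-2 projection is nearest p₂ — in closed form
the foot of the perpendicular from p₂ to that line, with the perpendicular
distance (px) as the point's residual. The closed form was verified against
a dense 10⁵-sample search over s (agreement ~1e-6 mm). Depths outside
(0.1·SOD, 2·SDD) are flagged as implausible.

Panning is a single rigid translation for the whole vessel — per-point
translations would be underdetermined (3 unknowns vs 2 constraints per
point) and a table shift is physically global. It is estimated by nonlinear
least squares on signed per-pair residuals (signed, because the absolute
distance has a non-differentiable kink at zero exactly where consistent
data puts the optimum).

Which pairs constrain the fit is a deliberate choice. Translation
components that slide the epipolar lines along themselves are absorbed by
the per-point depth freedom, leaving a weakly constrained direction in
(t_x, t_z); smooth template-matching errors are enough to drag a fit using
all 100 pairs tens of millimetres along that valley. The two vessel
*endpoints*, however, are anatomically exact correspondences, free of
template error — so the default (`panning_pairs="endpoints"`) fits the
translation to the first and last pairs only (2 constraints, 2 unknowns),
which recovers injected shifts on phantoms to machine precision.
`panning_pairs="all"` retains the joint fit over every pair.

Radii: each pair's two pixel diameters are converted to mm at the
reconstructed depth (d_mm = d_px · pitch · depth / SDD) and averaged; the
radius is half that mean, using both views symmetrically. ADPS2 — the mean
± SD view-2 distance between the projected reconstruction and the
segmented centerline — is reported per run.

Surface export places circles of the local radius on planes normal to the
centerline using parallel-transported (twist-minimizing) frames,
triangulated into a watertight mesh with fan-capped ends; high curvature
relative to the radius can still self-intersect locally (a warning, not an
error).

## Synthetic phantom

The phantom emulates what the pipeline consumes: a single non-branching
contrast-filled vessel on a bright background, imaged by two calibrated
views with a rigid table shift between them.

- **Centerline**: natural cubic spline through 5 canonical control points
  per artery type (stylized LAD / LCX / RCA courses centred on the
  isocenter, fixed package constants), each control point perturbed by
  isotropic Gaussian noise (default SD 3 mm), resampled at 1 mm and scaled
  about its centroid to the target length (default 70 mm).
- **Radii**: linear taper 1.75 → 1.0 mm; optional stenoses multiply by
  1 − severity·exp(−(ℓ−center)²/2σ²) with σ = FWHM/2.355.
- **Rendering**: background 0.9, vessel floor 0.2; each densely resampled
  centerline sample darkens a disc of the magnified local radius with a
  1 px half-cosine edge, accumulated by per-pixel minimum; the true mask is
  the union of hard discs, whose boundary therefore sits exactly at the
  half-intensity level. Optional additive Gaussian noise (default study
  condition SD 0.02). This is an intensity model, not Beer–Lambert
  attenuation — sufficient to exercise vesselness segmentation, not to
  study contrast or dose effects.
- **Template libraries**: seeded perturbations of the canonical shape at
  random lengths, averaged exactly as patient-derived model libraries
  would be.

Everything is deterministic given the spec and seed; a single top-level
seed drives all stochastic components, and the numerical stages are
seed-free, so fixed inputs give byte-identical CSV outputs.

What the phantom does *not* emulate: cardiac and respiratory motion,
branching and overlapping side vessels, catheter and rib clutter,
non-simultaneous contrast filling, detector blur and scatter. Passing the
phantom suite therefore demonstrates the geometric and algorithmic
correctness of the chain under controlled conditions, not clinical-grade
robustness.

## Validation design and measured behaviour

The acceptance script (`scripts/acceptance.py`) recomputes, from scratch:
geometry round-trip error; closed-form vs grid-search triangulation
agreement; panning recovery over the 25-shift grid t_x, t_z ∈ {−20, −5, 0,
5, 20} mm; template end-point spread per artery; straight-tube centerline
and diameter accuracy; and the end-to-end quality over 10 seeded phantoms
per artery type under the default study conditions (noise SD 0.02, panning
(20, 10) mm, 10-model template libraries). Centerline RMSE is measured
point-to-curve (distance from each reconstructed point to the ground-truth
polyline), because template-ratio correspondence does not index-align the
reconstruction with the truth and along-curve reparametrization is not a
geometric error.

Two aspects of the end-to-end behaviour deserve explicit framing. First,
the dominant error source is the intrinsic mismatch between the population
template and the individual phantom: with isotropic random control-point
perturbations, the two views' foreshortening-ratio profiles differ from the
template's by a few percent, which maps to millimetre-scale depth errors
and several-pixel ADPS2 even when segmentation and panning are essentially
exact (controls with perfectly segmented centerlines move the numbers very
little, and the self-template case is an order of magnitude better). Real
coronary shape families are far more structured than isotropic
perturbations, so this phantom likely *overstates* template-matching error
relative to clinical data even though its nominal spread is milder.
Second, on rare phantoms (about 1 view in 60) a high-curvature bend
depresses the vesselness below the relative threshold and the mask
disconnects; the pipeline reports this as an explicit segmentation failure
rather than producing a silent partial result, and the acceptance script
reports the success rate.

## Limitations

- Single vessel only: no bifurcation handling, no vessel-tree matching.
- The relative vesselness threshold couples distal sensitivity to the
  image's brightest vessel segment; adaptive or hysteresis thresholding
  would be the natural extension.
- Panning is the only motion model; cardiac/respiratory deformation between
  the two acquisitions is not compensated.
- The template's start/end must correspond to the supplied endpoints; a
  wrong endpoint in either view biases every correspondence.
- Orthographic template projection ignores perspective convergence; at
  typical SOD/vessel-extent ratios (~10:1) this is second-order but not
  zero (~0.3% of length on phantoms).
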