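# Methods

## Pipeline model and assumptions

The package assumes a HU-calibrated axial CT/CBCT stack in which dental
enamel is the brightest tissue (≥ 1500 HU) and the dental arch is, on the
slice containing the tooth tips, a single curved band once small gaps are
bridged. The arch is modeled as a planar curve on that one reference slice
and reused for every slice — i.e., the arch is assumed not to tilt
appreciably across the stack, which holds for standard axial dental
acquisitions. All curve fitting and sampling happen in pixel units on the
reference slice; in-plane anisotropy above 10% triggers a warning because
the fitted curve would then be metrically distorted.

### Segmentation

- `threshold_hu = 1500` (HU, inclusive ≥). Enamel threshold; the boundary
  value itself is kept in-mask so the printed operating point is honored
  exactly.
- Reference slice = arg max of per-slice segmented-voxel counts, ties to
  the smallest index. This finds the tooth-tip slice.
- `dilation_size = 20×20` px, all-ones rectangular structuring element.
  For an even-sized element the origin must be pinned: we place it at the
  floor-center index ⌊(s−1)/2⌋, so a single pixel dilates to offsets
  −9..+10. A 20 px element bridges inter-tooth gaps up to ~19 px, which is
  what lets a single missing tooth stay connected.
- `gaussian_sigma = 4` px applied to the {0,1} cast of the binary mask,
  re-binarized at 0.5 (the symmetric level set). An isolated pixel
  vanishes (blurred peak ≈ 1/(2πσ²) ≈ 0.01 ≪ 0.5); blob boundaries are
  rounded.
- Components use 8-connectivity — the permissive choice for thin
  structures; size ties break toward the component seen first in raster
  order.

### Skeleton

Topology-preserving iterative thinning produces a 1-px-wide skeleton
contained in the mask. Thinning leaves short spurs at convexities, so the
curve is reduced to the skeleton graph's diameter restricted to endpoints:
the longest shortest path between degree-1 pixels of the 8-neighbor graph.
Side branches are discarded. The path is oriented left-to-right (smaller
image x first) so that t = 0 is always the image-left end of the arch and
panoramic column order is reproducible. If the skeleton has no endpoints
(a closed loop), a double-sweep pseudo-diameter is used. Node ordering in
the graph is sorted, so equal-length shortest paths resolve
deterministically.

### Curve fit

The cost is implemented literally as printed in its source:
`f(P) = (1/m) Σ_{i=0..m} |eᵢ − bᵢ|` — the divisor is m although the sum has
m+1 terms. The ≈0.1% offset this causes versus a true mean is irrelevant
in practice but is pinned for reproducibility. `eᵢ` is the exact nearest
skeleton point (k-d tree; ties resolve to the lowest skeleton index), and
`f` is in pixels.

The optimizer is SLSQP with no bounds or constraints; endpoints are free
(curve ends may drift off the skeleton ends — a documented behavior of the
method, not a defect of the fit). We supply the analytic subgradient of
the cost under the current nearest-neighbor assignment,
`∂f/∂Pⱼ = (1/m) Σᵢ Bⱼ(tᵢ) (bᵢ−eᵢ)/|bᵢ−eᵢ|`, which is exact wherever the
assignment is locally constant and makes fits ~50× faster than finite
differences. Defaults: `m = 1000`, `max_iter = 500`, `tol = 1e-6` (SLSQP
ftol), `n_control_points = 11`.

Initialization defaults to `skeleton_uniform` — control points taken at
uniformly spaced skeleton indices — which is deterministic and already
close to the covering optimum. `random_in_bbox` (seeded uniform draws in
the skeleton bounding box) is retained as the historically used
alternative; it mainly changes `f_initial`, which for random starts is
essentially the mean distance of random box points to the skeleton.

Bernstein binomials are built multiplicatively (stable beyond degree 20);
evaluation is validated against de Casteljau recursion, the derivative
against central finite differences.

#### Properties of the one-sided cost

`f` measures curve→skeleton distance only. Consequences worth knowing:

- **Degenerate minima exist.** A curve covering any well-fit sub-segment of
  the skeleton — or collapsing toward a single skeleton point — can have
  near-zero cost. On gently curved arches a strongly converged low-degree
  fit may retract its ends ("shrinkage") and report a cost lower than a
  higher-degree covering fit. On deep horseshoe arches, retraction forces
  the curve across the arch interior and is penalized, so covering fits are
  stable; this matches the anatomy the method targets.
- **Two-point skeletons.** For a skeleton of two points, the segment
  through both is a *local minimum* with `f ≈ 0.354·L` (L the separation):
  every sample sits at distance `min(d₀, d₁)` from the nearer endpoint, and
  any end retraction first increases the cost before the global degenerate
  collapse could be reached. The fit therefore returns the segment, not a
  collapsed point, and `f_final` is not near zero.
- `f_final ≤ f_initial` is enforced structurally: the best evaluated
  control-point vector is tracked and returned, and non-convergence yields
  a flagged result, never an exception.

### Offset curves and AIP

Normals are `rot90CCW(B′(tᵢ))/|B′(tᵢ)|` at `tᵢ = i/m`; offset curve k is
`B(tᵢ) + k·q·N(tᵢ)`, k = −K..+K. Samples with vanishing derivative (cusps)
borrow the nearest well-defined normal; a curve whose derivative vanishes
everywhere is rejected. The published description fixes neither q nor K;
defaults are `q = 2` px and `K = 5` (11 curves, ≈20 px swept thickness —
the same spatial scale as the dilation element, the only internal anchor
available). Slice sampling is bilinear (nearest-neighbor available), with
out-of-bounds samples reading −1000 HU (air) so curve overshoot darkens
rather than corrupts. The panoramic pixel (z, i) is the mean across the
2K+1 offsets for slice z; rows follow volume slice order.

Note that panoramic columns are uniform in t, not in arc length, and the
fitted curve's extent need not coincide with the anatomical arch's extent
(free endpoints; morphology shifts the skeleton ends). Mapping a panoramic
column back to an anatomical position should therefore go through the
sampled curve (project the position onto the curve samples), not through
arc-length fractions.

### Image output

16-bit grayscale PNG/TIFF with linear windowing (lo→0, hi→65535, clipped);
rounding is half-away-from-zero so mid-window values are deterministic. A
constant image under an auto window writes zeros with a warning.

## The phantom generator

`generate_phantom` emulates the features the pipeline depends on: air
background (−1000 HU), a soft-tissue head ellipse (40 HU), a bone band
(900 HU) of radius 7 px along a known Bézier arch, and tooth cylinders
(2200 HU, radius 5 px) spanning the central half of the slice stack,
centered at equally spaced arc-length fractions of the arch. Gaussian HU
noise (σ = 30) is clipped at ±10σ, so bone can never reach 1500 HU and
teeth can never fall below it — segmentation outcomes on phantoms are
deterministic by construction, not just with high probability.

Three geometries:

- **default** — 60 × 256 × 256, a U-shaped degree-3 arch of ≈191 px arc
  length with 14 teeth. At this scale tooth spacing (≈13.6 px) leaves
  ≈3.6 px gaps that dilation easily bridges, and a single missing tooth
  leaves a ≈17 px gap — still within the 20 px element's reach, which is
  exactly the behavior the dilation step exists to provide. The
  `missing-teeth` preset removes teeth 4 and 8 (two single-tooth gaps, as
  in partially edentulous patients).
- **virtual patient** (`virtual_patient_spec(seed)`) — 12 × 512 × 512 with
  a deep mandibular horseshoe arch (degree 4, ≈765 px arc), 16 teeth of
  radius 16 px, and ±10 px seeded jitter of the arch control points. This
  is the geometry for cost-trend studies: at clinical in-plane scale the
  anatomy is larger than the 20 px morphology kernel, so the skeleton
  retains the arch's shape detail, and a parabola (3 control points)
  genuinely cannot represent the recurved horseshoe — its cost stalls an
  order of magnitude above the higher-degree fits, reproducing the
  direction of the published control-point sweep. The thin slice stack
  keeps run time low without affecting the 2D fit.
- **full-scale** — 200 × 512 × 512, for manual end-to-end runs at clinical
  dimensions.

What the phantom does *not* emulate: separate maxilla/mandible anatomy,
realistic tooth shapes (crowns/roots are plain cylinders), contiguous
enamel between neighboring teeth, metal artifacts, beam hardening, or
gantry tilt. Passing phantom tests therefore validates the geometry and
numerics of the pipeline — thresholding, bridging, skeleton fidelity,
curve recovery, offset sampling, AIP — but not robustness to clinical
artifact content.

## Problem sizes and run times

The test suite and the acceptance script run the default desk-scale
phantom (60 × 256 × 256, m = 1000) for end-to-end checks and ten virtual
patients (12 × 512 × 512) for the cost sweep; a full sweep plus end-to-end
run completes in well under a minute on one CPU. These sizes are the
package's chosen study conditions; the `full-scale` preset reproduces
clinical dimensions when wanted.

## Known limitations

- The arch curve is fitted on a single reference slice; severe arch tilt
  across slices is not modeled.
- The one-sided cost admits the degenerate minima described above; on
  shallow arches, low-degree fits converged to high precision may retract
  their ends.
- Arch-end localization is intrinsically soft (free endpoints); panoramic
  columns near the image edges may sample beyond the anatomical arch.
- Only single-frame axial DICOM series are read; multi-frame files and
  non-axial acquisitions are rejected.
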