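# panorex

Automatic synthesis of 2D panoramic dental images from 3D CT/CBCT volumes.

Dental cone-beam CT is routine in clinics, but the familiar panoramic
radiograph — a single longitudinal view of the whole dental arch — normally
requires a second acquisition and a second X-ray dose. Given an axial CBCT
stack, `panorex` reconstructs that panoramic view computationally: it finds
the dental arch, models it with an optimized Bézier curve, and unrolls the
volume along the curve. It is aimed at researchers and tool builders in
dental image analysis who need a reproducible, scriptable curved-planar
reformation of the dental arch, plus a synthetic phantom generator so the
whole pipeline can be exercised and validated without patient data.

## Method

1. **Segmentation.** Global threshold at 1500 HU (dental enamel), selection
   of the axial reference slice with the most segmented voxels (the tooth
   tips), a 20×20 px morphological dilation to bridge gaps left by missing
   teeth, Gaussian smoothing (σ = 4 px) of the binary mask, and retention of
   the largest 8-connected component.
2. **Skeleton.** The arch mask is thinned to its medial axis; the longest
   endpoint-to-endpoint path through the skeleton's pixel graph becomes the
   ordered center-line.
3. **Curve fit.** A degree-n Bézier curve
   `B(t) = Σᵢ C(n,i) (1−t)^(n−i) tⁱ Pᵢ`, `t ∈ [0,1]`,
   is fitted to the skeleton by minimizing the mean distance between m+1
   curve samples `bᵢ = B(i/m)` and their nearest skeleton points `eᵢ`:
   `f(P) = (1/m) Σᵢ₌₀..m |eᵢ − bᵢ|`  (pixels, m = 1000 by default),
   using SLSQP over all 2(n+1) control-point coordinates.
4. **Panoramic synthesis.** The derivative `B′(t)` is rotated 90°
   counterclockwise to give unit normals; 2K+1 parallel offset curves spaced
   q px apart sweep the arch thickness. Every axial slice is sampled
   bilinearly along every offset curve, and the panoramic pixel (z, i) is
   the average intensity projection (AIP) across the offsets.

## Worked example

Generate a synthetic CBCT phantom with a known dental arch, then
reconstruct its panoramic image:

```bash
panorex phantom --preset default --seed 1 --out vol.npz --truth truth.json
# phantom (60, 256, 256) -> vol.npz

panorex reconstruct --input vol.npz --out pano.png --debug-dir debug/
# panoramic 60x1001 -> pano.png (f_initial=4.717 px, f_final=0.427 px)
```

The phantom is a 60-slice, 256×256 volume: air background, a soft-tissue
ellipse, a bone band (900 HU) along a ground-truth Bézier arch, and 14
tooth cylinders (2200 HU) at equally spaced arc fractions. `f_initial` is
the mean curve-to-skeleton distance of the initial control polygon;
`f_final = 0.427 px` says the optimized 11-control-point curve tracks the
extracted arch center-line to sub-pixel accuracy. `pano.png` is a 16-bit
grayscale image with one row per axial slice and m+1 = 1001 arc-sample
columns; bright columns are teeth. `pano.json` is a provenance sidecar
(resolved configuration, seed, input checksum, fit costs) and
`pano.curves.csv` holds the sampled offset-curve family. `--debug-dir`
dumps the per-stage masks (threshold, dilation, smoothing, largest
component, skeleton).

The same pipeline runs on real data: point `--input` at a directory holding
one axial DICOM series and the images are rescaled to HU via the standard
rescale tags.

`panorex fit` stops after the curve fit and writes the fit JSON only;
`panorex inspect` prints volume metadata. Exit codes: 0 success, 2 bad
input, 3 empty segmentation (no enamel-range voxels), 4 optimizer
non-convergence (outputs still written).

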