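# Methods

This document records the model implemented by `petct_register`, the
default parameters and why they are what they are, the scope of the
synthetic phantom generator, the numerical conventions, and the known
limitations. Claims here are restricted to what the code computes and what
the shipped tests verify.

## Problem model

A whole-body CT volume (the *fixed* image) and a whole-body PET volume of
the same subject (the *moving* image) cover the same anatomy at different
in-plane resolutions and with per-slice rigid-ish misalignment from
patient positioning. Registration uses the **body outline** as the only
correspondence feature: it is present and comparable in both modalities,
whereas interior intensities are not. The transform model per axial slice
is the in-plane affine

```
p' = M (p − C) + T + C
```

with a full 2×2 block in `M` (rotation, anisotropic scale, shear),
translation `T`, and rotation center `C` fixed at the centroid of the
fixed-slice contour cloud. Fixing `C` removes the translation/center
redundancy of the parameterization (any change of `C` is absorbable into
`T`); the centroid choice keeps the linear system well conditioned.

## Pipeline stages

### Intensity normalization

Each volume is mapped through its display window onto `[0, 255]`:
`I' = (I − Imin) · 255 / (Imax − Imin)`, clipped to the range. The
multiplication precedes the division so that `I = Imax` maps to exactly
255 in floating point. Window defaults fall back to modality-typical
values when the DICOM headers carry none.

### CT segmentation (GFS)

1. **External contour extraction.** Foreground (gray > 0) connected
   regions are traced with Moore boundary tracing (clockwise,
   8-neighborhood), yielding each region's outer outline as an ordered
   closed pixel chain. Only external contours are traced; interior holes
   are irrelevant to the outline feature.
2. **Area filter.** Contour area is computed by the shoelace formula plus
   the boundary correction (pixel-center polygon area underestimates pixel
   count). Candidates below `min_area = 1000` pixels — defined at 512×512
   and rescaled by `(rows·cols)/512²` for other slice sizes — are dropped;
   this removes noise blobs and small artifacts.
3. **Slice-position-aware selection.** Slices are partitioned by relative
   position `z/n` into head (`< 0.2`), trunk, and legs (`> 0.7`). In head
   and trunk, the largest candidate is kept, plus any candidate whose area
   is ≥ `β = 0.1` of the largest (arms resting beside the body pass; the
   thin bed-shadow arc fails). In the leg region, up to `max_regions = 2`
   candidates passing the same ratio test are kept. The position-based
   partition is a stand-in policy: region labels are not available from
   headers, and relative axial position separates the three zones on
   whole-body series.
4. **Feature image and segmentation.** Kept contours are rasterized and
   filled into a binary *feature image*; multiplying the input slice by it
   gives the segmented CT. GFS is idempotent on its own output.

### PET preprocessing

1. **Upsampling.** Each PET slice is interpolated to CT in-plane
   resolution with cubic B-splines (`scipy.ndimage.zoom`,
   `grid_mode=True`, so pixel *areas* align between grids rather than
   corner samples; output clipped to `[0, 255]`). Downsampling is
   rejected — the pipeline direction is PET→CT resolution.
2. **Median filtering.** 3×3 median (odd kernels only): removes isolated
   speckle while preserving step edges, which matters because the next
   stage thresholds near the background level.
3. **Dynamic threshold denoising (DTD).** The 256-bin gray histogram peak
   estimates the background mode (in PET, background pixels dominate); the
   threshold is `peak + offset` with a per-region offset (head/trunk/legs
   all default to 2 gray levels — the offset need only clear the
   background mode's width after median filtering). The thresholded mask
   then goes through the same contour extraction/selection/filling
   machinery as the CT branch, so only body-scale regions survive;
   surviving foreground keeps its pre-threshold intensities. The
   peak-plus-offset rule is a stand-in for a threshold policy otherwise
   specified only by example.

### Trunk range

The registered axial range `[m1, m2]` runs from the first to the last CT
slice whose feature image has exactly **one** connected region
(8-connectivity): head and trunk present one body region per slice, leg
slices present two. Slices outside the range pass through unregistered.

### Feature point clouds

Boundary points of each feature image are pixels of the region with a
4-neighborhood background pixel, emitted **in outline order** (Moore
trace order), not scanline order. The averaging downsampler replaces each
run of `α` consecutive points with their mean, giving `⌈N/α⌉` points per
contour. Two orderings exist:

- `contour` (default): runs are consecutive along the traced outline, so
  group means are sub-pixel samples of the underlying curve and the cloud
  remains an ordered polygon — required by point-to-contour matching.
- `axis`: lexicographic sort along x or y before grouping. Kept as an
  explicit option, but it interleaves the two branches of a closed contour
  and degrades the cloud's shape; it is not used by the pipeline.

`α = 50` is the library default for clinical-resolution contours
(thousands of boundary pixels per slice); the phantom example uses
`α = 5` because its 128×128 contours have only a few hundred points.

### Affine ICP

Per trunk slice, ICP alternates:

1. **Correspondence.** Each transformed moving point is matched to its
   nearest fixed point (KD-tree). With the default **point-to-contour**
   matching, the target is refined to the closest point on the two outline
   polyline segments adjacent to the nearest fixed sample (segments longer
   than 4× the median segment length are excluded — they bridge unrelated
   contour parts). This removes the cost-surface ruggedness caused by the
   pixel sampling of the fixed contour. **point-to-point** (the nearest
   sample itself) is available as an option.
2. **Minimization.** A Levenberg–Marquardt step over the 6 parameters
   (M row-major, then T) minimizes the summed squared correspondence
   distances. Damping starts at 1e-3, ×10 on a rejected step, ×0.1 on an
   accepted one. The residual is linear in the parameters for fixed
   correspondences, so the inner solve converges in a few steps; the
   schedule only guards conditioning. Rank-deficient systems (degenerate
   clouds) fall back to translation-only with a warning.

Convergence: with point-to-point matching, the cost is non-increasing
across iterations and this is asserted. With point-to-contour matching the
candidate segment set changes with the correspondences, so a cost
non-decrease is treated as convergence instead, and the best iterate seen
is returned.

**Multi-start:** ICP's rotation basin is narrow on near-symmetric body
outlines, so each slice is solved from the deterministic initial rotations
(0, ±4, ±8, ±12)° and the run with the lowest final cost wins (ties go to
the earlier start). The grid spans the plausible patient-positioning range
(±10–12°) at a spacing well inside the observed basin width.

Slices are split into contiguous groups over `n_threads = 4` worker
threads. Each slice's solve is independent and deterministic, so results
are bit-identical for any thread count (verified by test).

### Resampling and evaluation

The registered PET is produced by inverse-warping: for each CT-grid pixel,
the slice transform's inverse gives the source coordinate, sampled with
bilinear interpolation (nearest-neighbor for binary volumes). Metrics are
computed on the trunk sub-volume of the binary feature volumes:

- **NC** — negative normalized correlation,
  `NC(A,B) = −Σ A·B / sqrt(Σ A² · Σ B²)`, range `[−1, 0]` for nonnegative
  volumes, −1 iff the volumes are proportional. Zero-norm input is an
  error rather than a silent 0.
- **ED** — directed mean nearest-neighbor Euclidean distance from moving
  feature points to fixed feature points (optionally symmetrized).

Checkerboard composites, subtraction images (signed, before/after), and
orthogonal section exports are provided for visual inspection.

## Phantom generator

The generator renders a deterministic synthetic whole-body pair: per-slice
body cross-sections (head disk, trunk ellipse, two leg disks, partitioned
at the same 0.2/0.7 fractions the selection policy uses), a bed-shadow
strip in CT only, isolated speckle pixels in PET only, a Gaussian-edge
point-spread rendering for PET (σ = 2 px at CT scale, then area-averaged
to the PET grid), and per-slice ground-truth misalignments drawn from
declared ranges (rotation ≤ 10°, translation ≤ 8 px, scale 0.9–1.1 by
default). Ground truth (transforms, body/bed/speckle masks, expected
region counts) is serializable to JSON, and DICOM export produces two
series readable by the standard input path.

**Identifiability sizing.** Body outlines are polar-harmonic curves
`r(φ) = r₀ (1 + Σ aₖ cos(kφ + φₖ))`. A pure 2nd harmonic on a circle is
absorbable by an affine map (it is, to first order, an anisotropic
scaling), so it carries no rotation information; the lowest non-affine
harmonic is the 3rd. The generator therefore puts deliberate 3rd-harmonic
(and, on the trunk, 5th-harmonic) amplitude on every region — head:
0.10·cos2φ + 0.14·cos3φ; trunk: 0.08·cos3φ + 0.04·cos5φ plus an axial
taper — sized so that the rotation-identifying boundary excursion is
several times the ~0.5–1 px boundary-extraction noise. These amplitudes
are design constants chosen before the acceptance thresholds were
evaluated and shared with `validate_geometry`, which bounds the worst-case
radial excursion per region exactly (head factor `1 + 0.10 + 0.14`; trunk
factor `(1 + 0.08 + 0.04)(1 + taper)`) when checking that the misaligned
body stays inside the field of view.

The generator is a test instrument, not a clinical simulator: no organs,
no attenuation physics, no noise model beyond speckle and the Gaussian
edge. Its defaults are study conditions and are not tuned against test
outcomes.

## Numerical conventions

- Points are (x, y, z) with x = column, y = row; z is the slice index.
- Contour area: shoelace on pixel centers plus perimeter/2 + 1 boundary
  correction, matching filled-pixel counts on convex shapes.
- Connectivity: 8-connected for region counting and contour tracing;
  4-neighborhood background test for boundary-point extraction (yields
  closed 8-connected outlines).
- `scipy.ndimage.zoom` with `grid_mode=True` for B-spline upsampling;
  spline prefilter border distortion decays geometrically (pole ≈ 0.27
  per source pixel), relevant only within ~12 source pixels of an edge.
- All floating point is float64; metric outputs are rounded to 6 decimal
  places at the reporting boundary only.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2³¹.

## Limitations

- The transform model is per-slice 2D affine; through-plane (z)
  misalignment and nonrigid deformation are out of scope.
- The head/trunk/legs partition is by relative slice position with fixed
  fractions; atypical acquisitions (partial-body scans, arms overhead)
  may need adjusted `head_frac`/`leg_frac`/`beta`.
- DTD assumes the histogram peak is the background mode; PET slices
  dominated by foreground would mislead it.
- The trunk range rule assumes exactly one body region per head/trunk
  slice; detached regions (e.g. arms held away from the body in the trunk
  zone) would shrink the detected range.
- Multi-start covers rotations up to ±12°; larger initial rotations may
  converge to a wrong basin.
- Accuracy numbers quoted in the README are measured on the synthetic
  phantom; no claims are made about clinical data, which the package has
  not been evaluated on.
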