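# Methods

## Ratiometric model

The package analyses tissues co-expressing an O₂-labile sensor (GFP-ODD)
and a stable nuclear reference (mRFP-nls) from one promoter. For a nucleus
with pixel set *B*, the readout is

  R = mean_{p∈B} S(p) / mean_{p∈B} F(p)

with S the sensor and F the reference channel. Both means are taken on the
raw, unprocessed channels: the preprocessing steps (background
subtraction, smoothing) exist only to build the segmentation mask, so that
measured intensities remain absolute. Under the ratiometric assumption —
sensor abundance proportional to reference abundance times an
O₂-dependent survival factor — R is invariant to expression level,
illumination and detector gain applied to both channels, and scales
linearly with gain applied to the sensor channel alone. Both invariances
are verified exactly in the test suite.

Two normalization schemes are provided, matching the two experimental
designs the workflow serves:

- **per specimen**: divide by the mean ratio of all nuclei of the specimen
  (one brain hemisphere). After this the specimen's mean normalized ratio
  is exactly 1, so values are comparable across hemispheres.
- **reference condition**: one factor for a whole experiment, the mean of
  all nuclei ratios pooled over the reference-condition specimens (e.g.
  embryos kept at 21 % O₂); per-specimen summaries are then means of the
  normalized per-nucleus values. Factors are arithmetic means throughout.

Nuclei whose reference mean is zero would have an undefined ratio; such
records are flagged invalid and excluded from all ratio statistics rather
than propagated as infinities.

## Segmentation

Segmentation runs independently per optical section, on the reference
channel, in a fixed order:

1. **Rolling-ball background subtraction** (default radius 40 px). The
   background is the grayscale opening of the section with a ball
   structuring element of the given radius — the surface traced by a ball
   rolling beneath the intensity landscape — computed exactly as a
   non-flat erosion followed by dilation (replicate border handling). No
   shrink/expand approximation is used; at the problem sizes this package
   targets, exactness is cheap. A flat intensity offset is removed
   completely, which makes the whole pipeline equivariant to constant
   offsets (tested).
2. **Mean smoothing** over a 3×3 neighbourhood (replicate padding).
3. **Automatic thresholding** by the iterative intermeans rule: starting
   from the image mean, iterate t ← (mean of pixels ≤ t + mean of pixels
   > t)/2 on the intensity histogram until the induced partition is
   stable. The update map is monotone, so the iteration converges to a
   fixed point; tests verify agreement with an exhaustive fixed-point
   search over all candidate thresholds. Integer images use their native
   integer histogram, real images a 256-bin histogram. Foreground is
   *strictly above* the threshold — one convention had to be fixed, and
   this one is asserted at the boundary. A constant section has no
   threshold; such sections are skipped with a warning instead of failing
   the stack. Otsu's method is available as an alternative.
4. **Watershed separation** on the negated Euclidean distance transform,
   seeded at distance-map maxima (maxima closer than 3 px merge into one
   seed, which suppresses spurious seeds from boundary roughness at the
   4–6 px nucleus radii the generator produces). Flooding proceeds in
   decreasing distance order, so ridge pixels join the basin with the
   larger distance values; every foreground pixel ends up in exactly one
   blob.
5. **Area filter** with inclusive bounds, then relabelling 1..n in raster
   scan order. Defaults are permissive (0, ∞): no particle-size filter is
   imposed silently, the parameter exists for real data.

Blobs are 8-connected, background 4-connected. Segmentation is strictly
2D: a nucleus visible in several sections contributes several records,
which matches how per-section ratio distributions are built downstream.
Labels are offset per section so every blob id is unique within a stack.

## Regional statistics

Nuclei are assigned to regions by the region-mask label under their
centroid (cheap and deterministic; a majority vote over blob pixels was
considered and rejected as it changes assignments only for nuclei
straddling borders, which are ambiguous anyway). Histograms use half-open
bins with the last bin closed, so counts always sum to n.

The Mann–Whitney U test uses full enumeration (exact p) when
n_a + n_b ≤ 12 without ties — where enumeration is instantaneous — and the
normal approximation with midrank ties, tie correction and continuity
correction otherwise; the t test offers pooled-variance Student and Welch
variants. Because pooling nuclei across specimens inflates the effective
sample size, every comparison is reported twice: on pooled nuclei and on
per-specimen means. Readers can pick the basis appropriate to their
design; no multiple-testing machinery is included since the workflow
performs single pairwise comparisons.

Wing-disc style comparisons are served by `compartment_ratio` (posterior /
anterior mean sensor intensity over equal-size ROIs) and
`normalize_compartment_ratios` (division by the control genotype's mean).

## Surface areas

Tracheal masks are thresholded (strictly above; "auto" reuses the
intermeans rule on the pooled voxel histogram). Surface area is measured
by marching cubes at iso-level 0.5 on the zero-padded binary mask with the
anisotropic voxel spacing applied on the grid, followed by 20 iterations
of Taubin smoothing (λ = 0.5, ν = 0.53) of the extracted triangle mesh
before summing triangle areas. Raw binary marching cubes systematically
over-estimates curved surfaces (≈ +8 % for a sphere) because of voxel
staircase; smoothing the *volume* instead would fix curved surfaces but
erodes sharp edges (a cube loses ≈ 5 %). Mesh-level Taubin smoothing
flattens the staircase ripples while planar regions, having zero
Laplacian, stay put: measured errors are +0.8 % (sphere r = 20 vox),
−2.5 % (cube, side 30), +2.0 % (cylinder r = 10), with ≤ 0.7 % difference
between isotropic and 0.6 µm-section anisotropic voxelizations of the same
sphere, and the area of a scale-doubled phantom quadruples to within
0.2 %. The procedure is fully deterministic and invariant to axis
permutation.

Per-region areas clip the mask to each region before extraction. Clipping
creates artificial cut faces where tubes cross region borders; these are
included (the per-region areas then sum to at least the whole-mask area)
and the discrepancy against the unclipped surface is logged.

## Synthetic data

The generator emulates what the pipeline sees in a larval brain
hemisphere or embryo, not the optics that produced it:

- **Geometry**: disk-shaped nucleus cross-sections (radius 4–6 px) placed
  uniformly in lateral regions, without overlap (minimum center distance =
  sum of radii + 1 px), with one disk per nucleus in one section —
  consistent with strictly-2D segmentation.
- **Reference channel**: per-nucleus brightness 3000 × LogNormal(0, 0.2)
  over a background of 100 plus a linear lateral gradient of amplitude 20,
  i.e. nucleus/background contrast far above the 5:1 regime the
  segmentation guarantees are stated for.
- **Sensor channel**: the nucleus's reference signal times its region's
  true ratio times LogNormal(0, 0.05) cell-to-cell jitter — the
  multiplicative coupling is exactly the ratiometric design assumption.
  Region-dependent jitter (hypoxic cells vary more) is not modelled by
  default but per-region parameters allow it.
- **Noise**: Poisson shot noise (gain 1 intensity unit/photon) plus
  additive Gaussian read noise (σ = 5), independent per channel, clipped
  at 0.
- **Determinism**: everything derives from one `numpy` generator seeded by
  `SynthParams.seed`; identical seeds give bit-identical stacks.

The two-region preset places 200 nuclei in each of two lateral halves
("CB" with true ratio 0.83, "OL" with 1.11 — the regime where the regional
difference is biologically decisive) over 10 sections of 160×224 px.
These sections are ≈ 5× smaller than real acquisitions, so pipeline runs
stay around a second and hundred-seed power/type-I studies complete in
minutes; the rolling-ball radius used on synthetic data is scaled to
15 px accordingly, while the library default stays at the 40 px
appropriate for full-size sections. What passing tests show is that the
*measurement machinery* is unbiased and calibrated under these study
conditions; they cannot certify robustness to real-data features the
generator omits — out-of-focus light, chromatic shift between channels,
nucleus shape irregularity, spectral crosstalk or photobleaching.

Surface phantoms (sphere, cube, cylinder) are voxelized analytically and
returned together with their closed-form areas; they serve as the
independent oracle for the surfaces module.

## Numerical and design choices

- Intensities stay at native depth until measurement, where they become
  float64; no rescaling to [0, 1] ever happens on read.
- Blob tables round-trip CSV bit-exactly (`%.17g` on write, round-trip
  float parsing on read).
- The heat map uses a blue→red diverging colormap ("coolwarm") by default
  with explicit value range and clamping at the ends (clamped blobs are
  counted in the log); a legend strip is emitted alongside.
- Degenerate inputs fail loudly and specifically: constant images (no
  threshold), empty reference pools, unnamed region labels, non-ascending
  histogram edges, zero-variance t-test inputs.
- The statistical tests delegate to scipy; the exact-enumeration and
  closed-form oracles used to verify them live in the test suite.

## Known limitations

- No 3D linking of nuclei across sections; per-section records are the
  unit of analysis.
- No correction for spectral crosstalk, photobleaching or absolute O₂
  calibration — ratios are relative hypoxia indicators.
- The surface estimator's accuracy guarantees are stated for features
  ≥ 8 voxels across; thinner tubes are under-resolved by any voxel
  method.
- The manual outlining used historically for embryonic tracheal nuclei is
  not mimicked; external masks can be imported instead.
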