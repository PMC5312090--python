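# hypoximap

Quantitative mapping of cellular hypoxic state from ratiometric biosensor
imaging.

A genetically encoded oxygen sensor pairs a degradation-sensitive green
reporter (GFP fused to the oxygen-dependent degradation domain of the
*Drosophila* HIF-1α homologue Sima, "GFP-ODD") with a co-expressed,
oxygen-insensitive nuclear red reference (mRFP-nls). Under normoxia the
sensor is hydroxylated and degraded; under hypoxia it accumulates. Because
both proteins are expressed from the same promoter, the per-nucleus ratio

&nbsp;&nbsp;&nbsp;&nbsp;*R* = mean GFP-ODD intensity / mean mRFP-nls intensity

cancels expression level and illumination and reports the O₂-dependent
turnover of the sensor alone. `hypoximap` turns two-channel confocal stacks
of such tissues into per-nucleus ratio tables, specimen-normalized ratio
maps, regional statistics and tracheal surface areas.

## What it does

- **Segmentation** (`hypoximap.segmentation`) — per confocal section, on the
  nuclear reference channel: rolling-ball background subtraction
  (40 px neighbourhood by default, implemented as exact grayscale opening
  with a ball structuring element), 3×3 average smoothing, automatic
  intensity thresholding (iterative intermeans fixed point), watershed
  separation of touching nuclei and an inclusive area filter.
- **Ratiometrics** (`hypoximap.ratiometrics`) — per-nucleus mean intensities
  measured on the *raw* channels, ratio *R*, normalization either to the
  mean of all nuclei of a specimen (per-hemisphere scheme) or to the pooled
  mean of a reference condition (e.g. the 21 % O₂ samples), and heat-map
  renderings of ratio maps with a colour-scale legend.
- **Regions** (`hypoximap.regions`) — centroid-based assignment of nuclei to
  anatomical regions from a label-mask file (e.g. central brain "CB" vs
  optic lobe "OL"), ratio frequency histograms, Mann–Whitney U (exact for
  small samples, tie/continuity-corrected normal approximation otherwise)
  and Student/Welch t tests, on pooled nuclei and on per-specimen means,
  plus wing-disc posterior/anterior compartment ratios.
- **Surfaces** (`hypoximap.surfaces`) — tracheal surface area per region in
  µm² from a thresholded tube channel, via marching cubes on the anisotropic
  voxel grid with deterministic Taubin mesh smoothing.
- **Synthetic data** (`hypoximap.synth`) — fully ground-truthed two-channel
  specimens (disk nuclei, lognormal brightness, region-dependent true
  ratios, Poisson–Gaussian noise) and analytic surface phantoms, so every
  stage is testable without microscope data.

## Worked example

```python
import numpy as np
import hypoximap as hm

# synthetic brain hemisphere: central brain (true ratio 0.83, well
# oxygenated) vs optic lobe (true ratio 1.11, hypoxic), 200 nuclei each
stack, region_mask, truth = hm.generate_two_region_brain(seed=1)

params = hm.SegmentationParams(rolling_ball_radius=15)  # scaled to image size
mask = hm.segment_nuclei(stack, "reference", params)
table = hm.assign_regions(hm.measure_blobs(mask, stack), region_mask)

cb = table.region_values("CB", "ratio")
ol = table.region_values("OL", "ratio")
print(f"CB: n={cb.size}, mean ratio {cb.mean():.3f}")
print(f"OL: n={ol.size}, mean ratio {ol.mean():.3f}")
t, p = hm.t_test(cb, ol, "student")
print(f"Student's t = {t:.1f}, p = {p:.3g}")
```

prints

```
CB: n=200, mean ratio 0.839
OL: n=200, mean ratio 1.106
Student's t = -54.7, p = 3.04e-187
```

i.e. the pipeline recovers the generated region ratios (0.83 / 1.11) to
about 1 % and separates the two regions decisively — the optic-lobe-like
region, which receives the sparser tracheal supply, shows the higher
sensor/reference ratios.

The same stages are available from the shell, driven by a YAML config
(input paths, channel map, spacings, segmentation parameters,
normalization scheme, region names, output directory):

```
hypoximap synth --preset two-region --seed 1 --out-dir run/
hypoximap ratio --config my_run.yaml      # blobs.csv + heatmap.tif + legend
hypoximap regions --config my_run.yaml    # summary.csv + report.txt + histogram.png
hypoximap surface --config my_run.yaml    # surface.csv
```

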