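# fociquant

Automated quantification of immunostained confocal microscopy images,
built for the common two-channel design in oxidative-DNA-damage work: a
blue DAPI counterstain marking nuclei and a green channel carrying the
immunodetected signal (e.g. 8-OHdG).  The package turns a folder of
images grouped by condition into per-compartment intensities, nuclear
foci counts, and statistics comparing treated groups against a control.

## What it computes

**Compartmentalization.** The DAPI channel is thresholded into a nuclear
mask (holes filled, small debris removed, objects labeled); on the green
channel every remaining pixel is *cytosol* if brighter than the
background threshold and *background* otherwise.  Thresholds are set on
one reference image per staining series and propagated unchanged.

**Intensity.** Per-compartment means, nuclear area and integrated
signal, and the nuclear:cytosolic ratio N/C = mean_nuc / mean_cyt, per
image and per nucleus.  Group values are expressed relative to the
control mean, defined as 100 %.

**Foci.** Intranuclear foci are local maxima of the green channel inside
the mask under a noise-tolerance (prominence) rule: a peak only counts
if every path to higher terrain descends by at least the tolerance.
The damage load is reported as foci density = count / nuclear area (px).

**Statistics.** Every group passes a four-test normality battery
(D'Agostino-Pearson, Anderson-Darling, Shapiro-Wilk, Lilliefors-
corrected KS); the verdict selects Student's t (one-tailed) or
Mann-Whitney for two groups, one-way ANOVA with Holm-Šídák comparisons
or Kruskal-Wallis for more.  p-values are graded ns/*/**/***/****.

**Synthetic ground truth.** A scene generator renders fields of
elliptical nuclei with cytosolic halos, planted Gaussian foci and
additive noise, including a "menadione-like" treated preset (nuclear
green ×1.5, foci ×3), so the whole chain is testable against known
truth without any downloads.

## Worked example

```python
from fociquant import (DEFAULT_THRESHOLDS, DEFAULT_MAXIMA, SceneParams,
                       generate_scene, segment, compartment_intensities,
                       find_nuclear_foci)

image, truth = generate_scene(SceneParams(seed=17))
cmap = segment(image.blue, image.green, DEFAULT_THRESHOLDS)
report = compartment_intensities(image.green, cmap)
foci = find_nuclear_foci(image.green, cmap, DEFAULT_MAXIMA)
print(cmap.n_nuclei, report.nc_ratio, foci.foci_count, foci.foci_density)
```

prints

```
6 2.0798898071625344 24 0.005192319342279533
```

— six detected nuclei, a nuclear:cytosolic ratio of 2.08 (the generator
planted 2.078), and 24 foci over 4622 nuclear pixels, a density of
0.0052 foci/px.  The scripts in `examples/` extend this to foci
recall/precision against planted coordinates and to a full two-group
comparison ending in star-graded p-values; each prints the numbers it
computes and a line on how to read them.

Batch processing from a shell mirrors the same stages:

```bash
fociquant simulate --out scenes --n-images 10 --seed 1
fociquant run --manifest scenes/manifest.yaml --out results \
    --dapi-threshold 90 --background-threshold 30 --noise-tolerance 30
fociquant audit --manifest scenes/manifest.yaml --out qc \
    --image-id control_000.tif --dapi-threshold 90 \
    --background-threshold 30 --noise-tolerance 30
```

`run` writes `per_image.csv`, `per_nucleus.csv`, `foci.csv`,
`comparisons.csv` and a `summary.json`; `audit` exports the compartment
mask and foci overlay PNGs used to judge whether the propagated
thresholds suit every image of the series.

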