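# Methods

`fociquant` automates the evaluation of immunostained confocal images in
which a blue channel carries a DAPI nuclear counterstain and a green
channel carries the immunodetected signal (the motivating use case is
8-OHdG, a marker of oxidative DNA damage).  This note documents the
model behind each stage, the parameters that matter, and the limits of
what the synthetic validation can show.

## Compartmentalization

The blue channel defines the nuclear compartment: pixels strictly above
a user-set DAPI threshold form the mask; interior holes are filled
(`fill_holes`, default on) and 8-connected components below
`min_nucleus_area` pixels (default 50) are discarded as debris.  The
surviving objects are labeled 1..n in top-left-first scan order.  On the
green channel, every non-nuclear pixel is *cytosol* if strictly above
the background threshold — "not nucleus, but brighter than the
background" — and *background* otherwise.  The three classes partition
the image exactly.

Conventions fixed here because they must be fixed somewhere:

* **Strictness.** A pixel exactly at a threshold is background (and, on
  the DAPI channel, non-nucleus): the threshold truncates the signal at
  and below the limit.
* **Connectivity.** 8-connectivity everywhere, matching the common
  default of interactive image-analysis tools.
* **No splitting.** Touching nuclei are not separated by watershed.  The
  pipeline quantifies compartments, not single cells, and the foci
  metric is normalized by total nuclear area, which is insensitive to
  merged objects.
* **No correction.** No flat-field, background subtraction or
  registration: measurements are taken on the raw pixel values, and the
  background is measured but never subtracted.

Thresholds are per-series calibrations: set manually on one reference
image of a staining series (an Otsu suggestion can be printed as a
starting point) and propagated verbatim to every other image of that
series.  `propagate_threshold` issues independent copies, so a series is
immune to later edits of its reference.

## Intensity quantification

Per image: mean green intensity over each compartment, nuclear area and
integrated nuclear signal, and the nuclear:cytosolic ratio
N/C = mean_nuc / mean_cyt.  Per nucleus: mean, total and area of each
labeled object.  Group values are expressed relative to the designated
control, v -> 100 · v / mean(control), so the control group averages
exactly 100 %.  Both the per-image and the per-nucleus replication unit
are emitted; which one enters the statistics is the caller's choice
(default per nucleus).  Ratios are flagged undefined (None / empty CSV
cell) rather than invented when a compartment is empty.

## Foci detection

A focus is an accepted local maximum of the green channel inside the
nuclear mask under the noise-tolerance (prominence) rule: a candidate
plateau at intensity I is rejected iff a strictly higher pixel can be
reached along an 8-connected path whose every pixel stays above
I − tolerance.  Equal-intensity plateaus count once, represented by the
plateau pixel nearest the centroid; ties break in scan order.  Two
boundary policies follow from the strict inequality and are deliberate:
at tolerance 0 nothing is ever rejected (every plateau local maximum is
returned), and a perfectly constant region yields no maxima at all — a
flat nucleus has no foci.

Detection runs per labeled nucleus with all outside pixels at −inf, so a
merge path can never cross non-nuclear territory; two nuclei sharing a
label across a gap cannot share a focus.  The reported density is
foci_count / nuclear_area in pixels — no physical pixel size is
consumed, which is valid when all images of a comparison share one
objective and zoom.

The tolerance is the one free parameter.  Like the intensity thresholds
it is a per-series calibration; `suggest_noise_tolerance` offers
2 × robust sigma (1.4826 × MAD) of the intranuclear intensity as a
starting point.  For the synthetic defaults (focus amplitude 90, noise
sd 6) the preset tolerance is 30: five noise sigmas, one third of the
spot amplitude.

`brute_force_maxima_oracle` implements the identical acceptance rule as
a literal breadth-first path search on planes up to 32×32.  It exists so
the production implementation can be tested against an independent
executable statement of the rule; the two are required to agree exactly,
ordering included.

A known artifact, shared with the interactive operator this mirrors: a
nucleus containing no true focus still reports its brightest noise
speck as one maximum (the global maximum of a region is never rejected).
At the default simulation load of ~3 foci per nucleus this costs ~2 % in
precision; in focus-sparse material it biases counts upward by up to one
focus per empty nucleus.

## Statistics

Each group is screened with four normality tests: D'Agostino & Pearson,
Anderson-Darling, Shapiro-Wilk, and Kolmogorov-Smirnov.  The KS variant
is Lilliefors-corrected, because testing against a normal with mean and
sd estimated from the same sample invalidates the plain KS null — this
is a deliberate, documented reading of the test's name.  The combined
verdict is Gaussian iff **all four** tests have p > alpha (alpha = 0.05,
configurable); `majority` (≥3 of 4) and `any` rules are available.  The
all-four default is conservative: it errs toward the non-parametric
branch, never toward an unjustified t-test.

The verdict gates the comparison:

| groups | all Gaussian | any non-Gaussian |
|---|---|---|
| 2 | Student's t (one-tailed, no correction) | Mann-Whitney U (one-tailed) |
| ≥3 | one-way ANOVA + Holm-Šídák pairwise | Kruskal-Wallis |

The one-tailed direction is *treated above control* and requires a
designated control group; without one the pipeline warns and tests
two-sided.  After Kruskal-Wallis, Dunn's z-tests with Holm adjustment
are reported as a clearly-labeled extension (the gated rule itself names
no follow-up).  Pairwise ANOVA comparisons are control-vs-each-treatment
when a control exists, all pairs otherwise.  Significance is graded with
inclusive star thresholds: * p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001,
**** p ≤ 0.0001, ns above.

Small-sample edges: the full battery needs n ≥ 8 (below that the verdict
is non-Gaussian with a warning), n < 4 groups are routed to the rank
branch inside a comparison but are an error when tested directly, and
zero-variance samples are declared non-Gaussian outright.

## Synthetic scenes

The generator renders what the measurement model assumes: elliptical
nuclei (random semi-axes and orientation) at blue level 180 on a dark
background; a green scene of background 10, a 6-px cytosolic halo at 60
around each nucleus, nuclear interior at 120, plus isotropic Gaussian
foci (amplitude 90, sigma 1.5 px) at Poisson(3)-distributed counts per
nucleus; additive Gaussian noise (sd 6) on both channels, clipped to the
8-bit range.  The default field is 256×256 px with 6 nuclei of semi-axes
13–19 px — sizes chosen so a full two-group power study stays desk-scale
while each nucleus is large enough to host the treated foci load without
crowding.  Ground truth records the label image, the planted focus
coordinates, and the N:C ratio and foci density of the noise-free
expectation scene (foci and clipping included), i.e. exactly what an
ideal measurement would return.

Planted foci keep ~2 sigma from the nucleus boundary and ≥4 sigma from
each other.  This models biologically distinct puncta and keeps the
ground truth honest: two Gaussians closer than the resolution limit
merge into a single peak that no detector honoring the prominence rule
could count twice.  When Poisson sampling asks for more foci than a
nucleus can host at that spacing, fewer are planted and the truth is the
planted set.

The "menadione-like" treatment preset multiplies the nuclear green
level by 1.5 and the foci load by 3 — the direction of an oxidative
insult, with magnitudes chosen as a clearly detectable but not
saturating effect (no published effect sizes exist to copy; treated
levels are capped at the representable maximum).  Effect (1.0, 1.0)
gives exchangeable groups for null calibration.

What the simulation does *not* model — and hence what passing tests do
not certify on real data: optical blur at nucleus boundaries, intensity
gradients and vignetting, signal-dependent (Poisson) noise, nucleoli and
chromatin texture inside nuclei, touching/overlapping cells, and
tissue-section geometry.  The synthetic results validate the algorithmic
chain, not the biology of any particular stain.

## Validation problem sizes

The bundled validation (`fociquant.validation`, driven by the test suite
and `scripts/acceptance.py`) uses: 100 random 12×12 planes × 3
tolerances for oracle equivalence; 10 scenes for partition/monotonicity
sweeps; 20 scenes for N:C and foci recovery (2 px match radius); 2000
null repetitions at n = 1000/group for test-size calibration and 200
lognormal repetitions for the gate; and 50 repetitions of the 20-image
two-group experiment for effect detection plus 50 for the experiment-
level null.  These sizes give Monte-Carlo standard errors comfortably
inside the asserted margins while keeping a full run desk-scale on one
CPU.

## Numerical and I/O choices

Pixel data pass through unrescaled in their native dtype (8- or 16-bit);
bit depth is inferred from the dtype.  Coordinates are row-major,
0-based (row, col).  CSV column order is fixed and JSON keys are sorted,
so identical runs are byte-identical — determinism is asserted, not
assumed.  The only stochastic component is the generator, driven
entirely by explicit integer seeds.
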