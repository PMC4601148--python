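# Methods

This note documents the models, defaults, and design choices in
`fociquant`, and what the synthetic-data validation does and does not
demonstrate about real confocal data.

## Synthetic scenes

The generator emulates maximal projections of immunostained fibroblast
nuclei as they appear in DSB-repair imaging studies:

* **Nuclei** are ellipses with independently drawn semi-axes and random
  orientation, placed by rejection sampling without overlap (bounded at 500
  attempts per nucleus; failure raises a placement error rather than
  degrading silently).  Ellipses capture the variety of enlarged/flattened
  nuclei while staying convex, which keeps masking simple.
* **Foci** are isotropic 2-D Gaussians of amplitude `focus_amplitude`
  added linearly onto the background (overlapping foci sum — a linear-optics
  approximation), clipped at nucleus borders.  Focus centers are sampled
  uniformly inside the ellipse shrunk by `2σ + 1` px so every focus's
  half-maximum footprint lies inside its nucleus.  An optional minimum
  inter-focus distance keeps planted foci resolvable; the counting geometry
  sets it to 9 px (≈ 4 × the largest focus sigma) so that detector output
  can be compared against planted counts without ambiguity from merging.
* **Colocalization**: `round(coloc_fraction × |foci_A|)` channel-A foci,
  chosen globally at random, are duplicated at identical centers in channel
  B (a jitter parameter, default 0 px, is available for robustness tests);
  `independent_foci_b` unrelated foci per nucleus are added on top.
* **Pan-nuclear nuclei** (the homogeneously stained, apoptotic-type cells
  that must be excluded from focus counting) are rendered as uniform
  intensity at 1.5 × the focus amplitude across the whole nucleus in
  channel A, with no discrete planted foci.
* **Noise**: optional Poisson resampling of the signal (shot noise), then
  additive Gaussian read noise, then clipping to the declared bit depth
  (16-bit unsigned by default; clipping, never wrap-around).

Two standard geometries encode the acquisition scales of a typical study:
the counting scale (0.285 µm projection pixels, nuclei with 7–10 µm
semi-axes, focus sigma 1.2–2.2 px so half-maximum footprints span roughly
0.4–2 µm²) and the colocalization scale (30 nm pixels, one nucleus per
384×384 field, focus sigma 3.5–5 px so focal signals extend to ~25–30 px).
Default intensities — background 500, DNA level 2500, focus amplitude 3000
on the 16-bit range — put nuclei and foci well inside the linear range.
The default colocalization-scale read noise of 300 (amplitude/10) is a
plausible moderate-noise confocal setting; no noise figures are available
to calibrate against, so simulation noise levels are stated choices, not
fits.

**Timecourses** model repair as binomial thinning: geometry and the initial
focus set are sampled once, and at each later timepoint every focus is
kept independently with probability `retention(t)` (colocalized channel-B
partners follow their channel-A focus; independent B foci are thinned with
the same probability).  Retention at the first timepoint must be 1 — it is
the induction-maximum reference.

What passing tests on these scenes shows: the measurement chain is
internally correct (planted counts, areas, colocalized fractions and
retention schedules are recovered at the stated tolerances).  What it does
not show: robustness to features the generator omits — touching nuclei,
spatially varying background, chromatin texture, spectral bleed-through,
3-D point-spread functions, photobleaching, or focus-size evolution over
time.  Results on real data still require the usual visual QC.

## Nucleus segmentation

Otsu's threshold on the DNA channel smoothed with a σ = 2 px Gaussian,
hole filling, 8-connected labeling, removal of components below
`min_area` (default 200 px), optional removal of border-touching nuclei.
An automatic, deterministic rule replaces the interactive ROI drawing of
the original workflow this package mechanizes.  A contrast-free image
yields an empty mask (logged), not an error.  Watershed splitting of
touching nuclei is out of scope; the generator never places touching
nuclei, and real images with them need manual curation.

## DoG enhancement

`blur(σ_small) − blur(σ_big)` with reflect boundary handling (avoids
dark-edge artifacts that would bias border foci; configurable).  "Radius"
of a Gaussian kernel is interpreted as its standard deviation in pixels —
the convention of ImageJ's Gaussian blur.  Negative differences are clipped
to zero *before* normalization (the minimal reading of "noise and
background removed"; the alternative order is not distinguishable from the
available description), then pixels outside the nucleus mask are zeroed and
the image is scaled to an in-mask maximum of 1.  Max-normalization keeps
both coefficients scale-free; Pearson and Manders are in any case invariant
under positive gain, so the normalization scheme does not affect them —
it only standardizes the enhanced images that downstream code sees.
σ_small = 1 px treats single-pixel spikes as noise; σ_big = 30 px matches
the maximum focal-signal extent at 30 nm pixels.  `plateau_check` re-runs
the whole chain across outer radii (default 10–55 px in 5 px steps) and
reports the maximum relative coefficient deviation over a stated window;
on synthetic scenes the 30–55 px window varies well under 5 %.

## Focus detection and areas

Per nucleus: threshold at `background + threshold × (max − background)`
with the in-nucleus minimum as background and `threshold = 0.5` by default
(half of the dynamic range — the half-maximum footprint of an isolated
Gaussian focus).  The relative threshold makes counts invariant under
gain changes and transfers across simulated noise levels; an absolute
threshold mode reproduces the fixed-per-series usage of interactive
software.  Components are 8-connected (the blob-measurement default of
ImageJ-family tools); components under 3 px are discarded as noise.
Areas convert to µm² by `area_px × pixel_size²`; histograms use 0.1 µm²
bins starting at 0.2 µm² (so the 0.24 µm² floor falls in the first bin,
and bin labels carry the familiar two-decimal style) with an open
overflow bin at ≥ 5 µm²; areas below 0.2 µm² — possible at finer pixel
scales — go to a leading underflow bin rather than being dropped, keeping
fractions summing to 1.

**Pan-nuclear exclusion** is automatic where the original workflow was
visual: a nucleus is flagged when more than `coverage_cutoff` (default
0.5) of its area exceeds a threshold placed at 0.5 of the dynamic range
pooled over *all* in-mask pixels.  The pooled range is deliberate: a
uniformly stained nucleus has no internal contrast, so a per-nucleus
relative threshold can never flag it, while against the scene-wide range
its coverage is ≈ 1.  Flagged nuclei are excluded from counts, kinetics
and summaries.

## Colocalization

Coefficients are computed per nucleus on the DoG-enhanced images — the
pipeline order of enhance → mask → correlate — with a raw-intensity mode
behind a flag for comparison.  One coefficient per cell is the unit of
analysis; group values are mean ± SE over nuclei (never pooled pixels
across cells).  Undefined coefficients (constant or zero-energy channel in
a nucleus) are returned as NaN with `valid=False`, excluded from means and
counted in an `n_invalid` QC column — silent zeros would bias group means
downward.  M1/M2 split coefficients use zero intensity thresholds and are
included for completeness.  Costes-style significance testing and
object-based colocalization are out of scope.

## Kinetics and statistics

`percent_of_max = 100 × mean(t)/mean(t_ref)` with the reference taken as
the time of each group's maximum mean (the 1 h induction peak in a typical
experiment) unless an explicit reference time is given;
`percent_repaired = 100 − percent_of_max` exactly, row by row.

Group comparison: Shapiro–Wilk on each sample (n ≥ 3 required), then the
classic pooled-variance two-sample two-tailed Student's t-test (Welch
variant selectable).  A failed normality check sets a warning flag but
does not switch the test — the check is surfaced, not acted on silently.
Significance at α = 0.05; no multiple-testing correction is applied by
default, matching the single-contrast usage the package targets.

`recovery_experiment` closes the loop: it renders timecourses with a known
retention schedule at a chosen SNR (focus amplitude / read-noise sigma),
runs segmentation → counting → kinetics, and tabulates estimated vs
planted percent-repaired; optionally it renders single-nucleus fields over
a grid of planted colocalized fractions and reports mean Pearson Rr per
level with its Spearman correlation against the planted fraction.  At the
default problem sizes used in the test suite (200 nuclei per timepoint for
kinetics, 25 nuclei per colocalization level — the per-group n of a
typical coefficient table), estimated percent-repaired lands within 5
percentage points of the planted value at SNR ≥ 5, and mean Rr is strictly
monotone in the planted fraction.

## Numerical and interface choices

* Coordinates are row-major, 0-based, pixel centers at integer positions;
  one convention across all modules.
* Square pixels are required; anisotropic resolution tags are rejected
  rather than averaged, because all area conversions assume `pixel_size²`.
* TIFFs written by the package embed axes, channel names, pixel size,
  z step and bit depth and round-trip exactly; foreign TIFFs are accepted
  when the pixel size is recoverable from ImageJ-style tags or given
  explicitly — the reader fails rather than guesses.
* Maximal projection is the per-pixel maximum over z, applied before any
  counting; per-slice counting is deliberately not offered.
* All stochastic stages consume a single seeded `numpy.random.Generator`;
  identical spec + seed yields bit-identical scenes, and the CLI writes a
  config snapshot sufficient to reproduce every run.

## Known limitations

* No 3-D measurement: foci are counted and measured on projections only.
* Touching or overlapping nuclei are not split.
* The synthetic noise model (Gaussian read noise + optional Poisson shot
  noise) omits detector artifacts, bleed-through and background gradients.
* Focus-size kinetics (growth of projected areas over time) can be
  measured on real data but is not modeled by the generator, whose planted
  sigma distribution is time-invariant.
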