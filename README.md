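# fociquant

Quantification of DNA-damage repair foci in fluorescence microscopy images.

DNA double-strand breaks (DSBs) recruit phosphorylated histone H2AX (γH2AX)
and repair proteins (53BP1, phospho-DNA-PK, phospho-ATM) into discrete
nuclear foci that are visible by immunofluorescence confocal microscopy;
one γH2AX focus marks approximately one break.  Counting foci per nucleus
over time after a genotoxic insult (ionizing radiation, bleomycin) measures
repair kinetics, the distribution of projected focus areas (PAF) tracks
focus maturation, and the colocalization of γH2AX with repair-protein foci
measures recruitment efficiency.  `fociquant` implements this analysis
chain as a tested, reusable library with a synthetic ground-truth image
generator, so every stage can be validated without access to confocal data.

The package is intended for cell-biology and DNA-repair labs analysing
multichannel TIFF stacks (DNA counterstain plus one or two
immunofluorescence channels), and for method work that needs a
ground-truth-annotated simulation of such images.

## What it computes

* **Nucleus masking** — Otsu threshold on the lightly smoothed DNA channel,
  hole filling, connected-component labeling; each nucleus is the region of
  interest for everything downstream.
* **Focus counting and area measurement** — per nucleus, the focal channel
  (a maximal z-projection) is binarized at a threshold on the in-nucleus
  dynamic range; 8-connected components of ≥ 3 px are foci.  Areas convert
  to µm² as `area_px × pixel_size²` (at 0.285 µm pixels: 0.081 µm²/px, so
  the 3 px noise floor is 0.24 µm²).  Homogeneously ("pan-nuclear") stained
  apoptotic-type nuclei are flagged and excluded.  PAF histograms use
  0.1 µm² bins from 0.2 µm² with an open bin at ≥ 5 µm².
* **DoG spot enhancement** — difference of Gaussians, σ_small = 1 px,
  σ_big = 30 px by default ("radius" = kernel standard deviation), negatives
  clipped, normalized to in-mask max 1, zeroed outside the nucleus mask.
  A plateau check re-runs the pipeline across outer radii to confirm the
  coefficients do not depend on the choice.
* **Colocalization** — per nucleus, on the DoG-enhanced channels:
  Pearson `Rr = Σ(a−ā)(b−b̄)/√(Σ(a−ā)²Σ(b−b̄)²)` and Manders overlap
  `R = Σab/√(Σa²Σb²)` (plus split coefficients M1/M2); group summaries are
  mean ± SE over nuclei.
* **Repair kinetics and statistics** — mean foci/nucleus ± SE per group and
  timepoint, percent-of-maximum and percent-repaired relative to the
  induction peak, and two-group comparisons by Student's t-test gated by a
  Shapiro–Wilk normality check (α = 0.05).
* **Synthetic scenes** — elliptical nuclei, planted Gaussian foci with a
  controllable truly-colocalized fraction, pan-nuclear nuclei, background,
  read and shot noise; bit-identical under a fixed seed, with the full
  ground truth returned for validation.

## Worked example

```python
import fociquant as fq

# scene with a mix of countable and pan-nuclear nuclei
spec = fq.default_counting_spec(n_nuclei=12, seed=42, noise_sigma=300.0,
                                pan_nuclear_fraction=0.1)
stack, truth = fq.generate_scene(spec)
mask = fq.segment_nuclei(stack.channel("dna"))
records, summaries = fq.detect_foci(stack.channel("A"), mask,
                                    pixel_size=spec.pixel_size)
stats = fq.mean_foci_per_nucleus(summaries)
hist = fq.paf_histogram(records)
print(f"nuclei: {mask.n_nuclei} segmented, "
      f"{sum(s.excluded for s in summaries)} excluded as pan-nuclear")
print(f"mean foci/nucleus = {stats.mean:.2f} +/- {stats.se:.2f} SE (n={stats.n})")
print(f"mean PAF = {hist.mean_um2:.2f} um^2")

# colocalization at the 30 nm pixel scale
cspec = fq.default_coloc_spec(coloc_fraction=0.7, seed=7)
cstack, _ = fq.generate_scene(cspec)
cmask = fq.segment_nuclei(cstack.channel("dna"))
res = fq.coloc_per_nucleus(cstack, cmask)[0]
print(f"nucleus Rr = {res.Rr:.3f}, R = {res.R:.3f}")
```

prints

```
nuclei: 12 segmented, 1 excluded as pan-nuclear
mean foci/nucleus = 10.00 +/- 0.00 SE (n=11)
mean PAF = 1.09 um^2
nucleus Rr = 0.681, R = 0.699
```

All 12 planted nuclei are segmented; the one pan-nuclear (dense-staining)
nucleus is excluded, and in each remaining nucleus all 10 planted foci are
recovered despite the read noise, so the SE of the count is 0.  The
per-nucleus Pearson coefficient of ~0.68 reflects the planted 70 %
colocalized fraction diluted by noise and the independent channel-B foci.

The same stages are available from the shell:

```sh
fociquant simulate --outdir sim --seed 3 --n-nuclei 5
fociquant count-foci --image sim/scene.tif --outdir counts
fociquant coloc --image sim/scene.tif --outdir coloc
fociquant plateau-check --image sim/scene.tif --outdir plateau
```

Every command writes its artifacts plus a `config.txt` parameter snapshot
and `run.log`, and identical command line + seed reproduces identical
outputs.

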