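# scprofiler

Automated, unbiased measurement of strand-to-strand distances and
protein-distribution widths in 2D super-resolution images of synaptonemal
complexes (SCs) and similar twisted two-strand filament structures.

In spread preparations the two lateral elements of the SC (marked by
SYCP3) appear as parallel strands that twist around each other.  Measuring
their separation by hand-drawn line profiles is slow and biased: near
twists the 2D projection underestimates the true distance, and profile
placement is subjective.  `scprofiler` automates the whole chain — from a
raw TIFF to a strand distance with an uncertainty — and ships a synthetic
helix renderer so every stage can be verified against ground truth without
any microscopy data.

## Method

Given an axis-protein channel (and optionally a central-element channel
such as SYCE3 as a guide):

1. **Centerline** — Gaussian blur, Otsu binarization, skeletonization
   (Lee), line tracing with breakpoints at junctions and sharp (> 60°)
   turns, and a cubic smoothing spline per line supplying positions and
   tangents.  In 1-channel mode the midline between the strands is found
   by first blurring the axis channel with σ = d_max/2 so the strands
   merge into one ridge.
2. **Frontal-view selection** — a border floodfill of the binarized axis
   channel marks background lobes fully enclosed by the crossing strands;
   only spline points inside those lobes become profile sources.
3. **Profiling** — at each source a cross-sectional intensity profile is
   sampled perpendicular to the spline; the distance between the two
   dominant peaks on opposite sides of the midline (sub-sample refined) is
   the per-profile strand distance.  Distances outside 400–1200 nm are
   discarded (expanded-sample defaults; override for unexpanded data).
4. **Edge fit** — because projection can only *underestimate* the true
   separation, the kept distances pile up against a hard upper edge at the
   true value.  The histogram is fitted with a half-normal edge model

   y(x) = A·exp(−(x−c)²/(2σ²)) + n  for x ≤ c,  y(x) = 0 for x > c,

   and the fitted center *c* is the reported strand distance.  Monomodal
   profiles (central-element distributions) are instead summarized by a
   single-Gaussian fit reporting SD and FWHM = 2√(2 ln 2)·σ.

The synthetic module renders the validation experiment: a two-strand helix
whose maximum-intensity projection is y₁,₂(x) = ±(a/2)·cos(bx), drawn with
a Gaussian PSF at a stated pixel size, plus straight-ridge and binary
shape fixtures.

## Worked example

```sh
$ python examples/02_measure_helix.py
stage counts: {'lines_traced': 1, 'sources_selected': 662, 'profiles_extracted': 662, 'distances_kept': 523, 'distances_discarded': 139}
strand distance c = 800.17 +/- 0.38 nm (flank sigma = 17.6 nm)
ground truth a = 800.0 nm -> error +0.17 nm
```

A helix with a = 800 nm, b = 1/1612 nm⁻¹ rendered at 32.24 nm pixels is
measured by the full 1-channel pipeline: 662 profiles are placed inside
the enclosed frontal-view lobes, 523 of their peak-to-peak distances
survive the 400–1200 nm filter, and the half-normal edge fit recovers the
true separation to 0.2 nm — even though the median *measured* distance is
only ~700 nm (the projection bias the edge fit exists to remove).  The
other scripts in `examples/` demonstrate the renderer, the straight-ridge
accuracy oracle, and monomodal width fitting.

The same thing from the shell:

```sh
scprofiler simulate --out helix            # writes helix.tif + truth JSON
scprofiler run --input helix.tif --pixel-size 32.24 --out results/
scprofiler validate                        # simulate + measure + check
```

`run` writes `distances.csv` (every profile with its kept/discarded
reason), `profiles.csv` (aligned average profiles) and `summary.json`
(fit, stage counts, config echo).  Exit codes: 0 success, 1 usage/input
error, 2 analysis failure.

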