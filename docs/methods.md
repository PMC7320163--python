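# Methods

## Problem and measurement model

A synaptonemal complex spread flat on a coverslip shows its two lateral
elements as bright strands twisting around a common axis.  In a 2D image
(or maximum-intensity projection) the apparent center-to-center separation
at axial position x is well described by the projection of a helix,

    y_1,2(x) = ± (a/2) · cos(b·x),

so the apparent separation a·|cos(bx)| oscillates between 0 at strand
crossings and the true separation a in frontal view.  Any per-profile
measurement therefore *underestimates* a; the estimator must recover the
upper edge of the measured-distance distribution, not its mean.

## Pipeline

**Centerline.**  The guide channel (central element in 2-channel mode; the
axis channel itself in 1-channel mode) is blurred (Gaussian, reflective
boundaries, default σ = 1 px), binarized with Otsu's threshold over a
256-bin histogram (foreground strictly above threshold; constant images
are rejected), and skeletonized with Lee's method, which preserves
topology and yields 1-px lines.  Skeleton pixels with more than two
neighbors are junctions: they belong to no line and always break tracing,
which keeps pixel bookkeeping exact (line pixels + discarded short-line
pixels + junction pixels = skeleton pixels).  Remaining pixels form
degree-≤2 paths that are walked end to end and split wherever the angle
between successive 5-px chords exceeds 60° (both values configurable; the
angle criterion separates crossing artifacts while tolerating genuine SC
curvature).  Lines shorter than 10 px are dropped.  Each line is fitted
with a cubic smoothing spline parameterized by normalized cumulative chord
length; the smoothing parameter is expressed as a target RMS residual in
pixels (default 1 px, internally s = m·smoothing²) so its meaning does not
depend on line length.

**1-channel midline.**  With no central-element channel, the midline
between the strands is estimated by blurring the axis channel with
σ = d_max/(2·pixel size) — for the defaults 1200/2 = 600 nm — which merges
the two strands into a single ridge whose skeleton is the local transverse
center of mass.  This reuses the tested centerline machinery and is
rotation-invariant; on fixtures where the central channel is rendered
exactly on the midline, the two routes agree to within a pixel.

**Frontal-view selection.**  Where the strands cross they enclose lobes of
background.  A border floodfill of the binarized axis channel (background
4-connectivity, so diagonally touching strands still close a lobe) marks
exactly the enclosed background; spline samples (one per pixel of arc
length) whose nearest pixel lies in an enclosed lobe become profile
sources.  This automatically excludes lobes cut by the image border.

**Profiles and distances.**  At each source, intensities are sampled at
offsets ±1300 nm (step = pixel/2) along the normal (tangent rotated +90°)
by cubic-spline interpolation of the blurred axis channel.  Cubic rather
than linear interpolation matters: at 32 nm pixels, linear interpolation
quantizes peak positions to the pixel grid and leaves ~10–16 nm errors on
the per-profile distance (measured on rendered ridge fixtures), while
cubic sampling leaves ~1 nm (SD 0.9 nm, max 2.2 nm on the same fixtures).
Profiles that would leave the image are rejected, not zero-padded, because
padding biases peak detection.  The per-profile distance is the offset
difference between the two highest local maxima on opposite sides of
offset 0 (ties broken by prominence, then proximity to the axis), each
refined by a 3-point parabola; profiles without such a pair are recorded
as `no_bimodal`.  Distances outside [400, 1200] nm are flagged and
excluded from all further statistics (defaults for ~4× expanded samples;
callers measuring unexpanded data must override).  Nothing is deleted:
every attempted profile appears in the output with its reason.

**Averages.**  Kept profiles are aligned so the midpoint between their two
peaks sits at offset 0 (linear re-interpolation onto the common grid) and
averaged per line and over the whole image; the overall average equals the
per-line averages weighted by their kept counts.

## The half-normal edge fit

Kept distances are histogrammed into uniform half-open bins (default
10 nm) and fitted with the half-normal edge model

    y(x) = A·exp(−(x−c)²/(2σ²)) + n   for x ≤ c
    y(x) = 0                           for x > c

by bounded trust-region least squares (A, σ > 0, n ≥ 0, c within the data
span).  The fitted center c is the reported strand distance; both the
covariance-derived standard error of c and the flank width σ are reported,
since either may serve as the quoted uncertainty.

Three numerical choices matter here:

- **Orientation.**  The Gaussian flank sits on the *data* side (x ≤ c)
  and the model is zero above c.  Since projection only underestimates,
  essentially all histogram mass lies below the true separation; a model
  that is zero below c and decays above it has nothing to fit on the data
  side and, measured on the rendered validation helix, lands ~20 nm below
  truth.  The data-side orientation recovers truth to well under 5 nm.
  `half_norm_model` exposes both orientations (`tail="left"|"right"`).
- **Bin-integrated evaluation.**  Each bin's prediction is the model
  integrated over the bin (erf closed form) divided by the bin width,
  not the model value at the bin center.  Pointwise evaluation makes c
  unidentifiable within the edge bin (the least-squares objective is flat
  over a one-bin interval, so c quantizes to the bin grid); integration
  restores sub-bin sensitivity because the bin containing c is partially
  filled in proportion to where c cuts it.  In the smooth-bin limit the
  two evaluations coincide, so A and n keep their count units.
- **Window and starts.**  The default fit window is the whole histogram:
  a window restricted to the immediate peak leaves A, σ, n degenerate
  (only c is pinned by the edge).  The optimizer is started from a few
  edge candidates (tallest bin, one bin right, rightmost non-empty bin)
  because the piecewise model has sub-bin local minima on degenerate
  (e.g. flat) inputs.  The window remains configurable for histograms
  with multiple structures.

On histograms generated from the model itself, all four parameters are
recovered to < 1% (c to < 0.01 nm); under Poisson counting noise
(A = 100, c = 800, σ = 50, n = 5, 100 seeded replicates) the mean |ĉ − c|
is ≈ 1 nm.

Monomodal profiles (central-element proteins) are summarized instead by a
least-squares single-Gaussian fit, offset + amplitude·exp(−(x−μ)²/(2σ²)),
reporting SD and FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ; inputs with two
prominent maxima are rejected.

## Synthetic ground truth

`render_helix` draws the two strands at ±(a/2)·cos(bx) about the midline,
so the maximum center-to-center separation equals a.  (Taken literally,
±a·cos(bx) would give separation 2a; drawing at ±a/2 is what makes the
recovered distance equal a, and is the convention used throughout.)
Curves are laid down by arc-length resampling at pixel/4 steps with
bilinear splatting — constant intensity per unit curve length, no
rasterization aliasing — then convolved with a Gaussian PSF, peak-
normalized, and optionally given background and seeded Gaussian noise.
Defaults reproduce the validation condition: a = 800 nm, b = 1/1612 nm⁻¹,
pixel 32.24 nm, ~3.2 periods (32 µm), PSF σ = 40 nm (SIM-scale resolution
at this pixel size), no noise.  The canvas height (2800 nm) leaves room
for full-length profiles on both sides of the midline.  A truth record
carries a, b and the crossing positions x = (k + ½)π/b.

`render_parallel_ridges` provides the straight-line oracle (every profile
should measure the rendered separation); `render_shape` provides binary
ring / open-C / L / T / bar fixtures for the skeleton, tracing and
floodfill stages.

What the generator does *not* emulate: labeling stochastics, antibody
linkage error, expansion distortion fields, intensity variation along the
strands, or overlapping structures.  Passing tests therefore demonstrate
correctness of the measurement chain on ideal twisted-strand geometry,
not robustness to every artifact of real spreads; the 400–1200 nm filter
is the only mechanism carried over for rejecting confounding structures.

## Defaults and their rationale

| parameter | default | why |
| --- | --- | --- |
| blur_sigma_px | 1.0 | suppress shot noise without displacing peaks |
| min/max_distance_nm | 400 / 1200 | expanded-sample bounds; excludes collapsed/paired strands |
| profile_halflength_nm | 1300 | a maximal-separation pair (1200 nm) must fit in one profile |
| profile_step_nm | pixel/2 | Nyquist with respect to the raster |
| histogram_bin_nm | 10 | must resolve the ±5 nm edge target; 20 nm bins leave up to ~10 nm edge-quantization error on rendered helices |
| min_line_length_px | 10 | a cubic spline needs support; shorter fragments are noise |
| breakpoint_angle_deg | 60 | splits crossing artifacts, tolerates SC curvature |
| spline_smoothing | 1.0 px RMS | skeleton jitter is ±0.5–1 px |

Problem sizes used by the test suite and the acceptance script — a single
~990 × 90 px helix (≈ 3 periods, ~500 kept profiles) and 10 µm ridge
fixtures — are the validation condition itself; one pipeline run takes a
few seconds.

## Known limitations

- 2D only; 3D stacks must be max-projected first (`project_z`).
- One structure per enclosed-lobe system: overlapping SCs are not
  disambiguated beyond the distance filter.
- The edge fit assumes a single dominant separation; multimodal
  distributions (e.g. mixed populations) need a restricted `fit_window_nm`.
- TIFF resolution metadata is deliberately ignored; the pixel size is
  always explicit user input.
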