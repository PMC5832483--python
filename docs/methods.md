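# Methods

This note records the model behind each pipeline stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions that tests pin down.

## Signal model and reconstruction

A raster acquisition alternates laser-on line scans with laser-off gas
blanks.  The recorded quantity is a multi-isotope time series in counts per
second, one reading every `reading_interval` seconds (per-isotope dwell ×
number of monitored isotopes; 0.3–0.4 s is typical for 30–35 isotopes at
10 ms dwell).  Reconstruction assumes:

* constant stage speed within a line (`raster_rate`, μm/s), so elapsed time
  within the line maps linearly to position;
* a start-to-start line period (`line_interval`, s) that is constant unless
  the user corrects it per separation point;
* a background that is constant over each gas blank, estimated per line
  from the adjacent blanks and subtracted from the line readings.

**Separation points** are placed at the exact midpoint of each blank gap:
point k at `first_line_start + k·line_interval − gap/2` with
`gap = line_interval − line_duration`.  The midpoint is the deterministic
version of the usual "middle of the gas blank" placement heuristic; each
point can then be moved individually (`adjust_separation`), and the line
and blank windows are *derived* from the points, so moving a point moves
its windows consistently.  Line windows select readings half-open
(`start ≤ t < end`), which makes a reading at the exact boundary belong to
the blank — consistent with the simulator's labeling.

If the record is too short for the declared number of lines,
`segment_lines` raises a coverage error that states how many whole lines
fit; passing `allow_truncation=True` converts this into a warning plus
truncation.  Both behaviours are useful — hard failure for scripted
pipelines, truncation for interrupted acquisitions — so the error is the
default and truncation is explicit.

**Background.**  Per line, the blank windows immediately before and after
the line are pooled and reduced by the mean (default) or the median (for
spike robustness); a `global` scope pools every blank.  Each blank window
is trimmed by `blank_margin` on both sides, default 20% of the gap
duration per side: with a typical ~2 s washout tail and tens-of-seconds
gaps this keeps decaying signal out of the background estimate without
starving the window.  Negative post-subtraction intensities are retained;
clipping happens only at render time and (as a floor at zero, counted and
warned) before quantification, so ROI statistics stay unbiased.

**Gridding.**  Row k holds line k's readings in time order; the horizontal
pitch is `raster_rate × reading_interval`, where the reading interval is
the *median* intra-line time step — robust to occasional dropped readings.
Rows of unequal length are padded with masked cells, never truncated, so
interrupted runs still load.  Coordinates are pixel-center, in μm, x
measured from each line's start.  Scan direction defaults to
same-direction with a serpentine option (the per-line horizontal
correction workflow presumes same-direction acquisition, which is the
common protocol).  Columns are aligned by time within line rather than
globally resampled; the residual sub-pixel phase between rows (up to one
pitch when `first_line_start` is not a multiple of the reading interval)
is an inherent property of raster sampling, not corrected here.

**Shape correction** shifts row k horizontally by
`per_line_offset[k] + per_file_offset[file(k)] + shear·k` μm.  Fractional
shifts use within-row linear interpolation (the same interpolation family
as the profile machinery); cells that would sample outside the row or
through a masked cell become masked.  A declared line interval that is
wrong by δ seconds slants the image by `δ × raster_rate` μm per line, and
the matching shear undoes it without reloading.

**Running average** (±`half_width` readings along the scan direction) is a
masked moving mean; it suppresses spikes at the cost of horizontal
resolution.  ±2 points is a practical default for spiky counting data.

## Rendering

Display normalization is `v = clip((I − lo)/(hi − lo), 0, 1)` followed by
`v' = v^γ` (γ applied after normalization — the convention is pinned by
tests).  Auto-contrast uses `lo = 0` after clipping negatives and `hi` at
the 99th percentile of valid cells, robust against spikes; explicit bounds
always override.  RGB mixing normalizes the three channels independently
(each channel has its own dynamic range; joint normalization would let one
bright isotope crush the others).  Masked cells render transparent.  PNG
and BMP exports are lossless; JPEG is provided for convenience only.

## Bilinear profiles

Intensity between pixel centers is evaluated from the four surrounding
measured points: linear interpolation along the two bounding rows, then
linearly between those two results.  Queries in the half-pixel border or
touching a masked corner are rejected rather than clamped or extrapolated
— a silently clamped endpoint would bias profile statistics.  The default
sample count places one sample per finer-pitch step along the segment
(endpoints included), so profiles neither alias nor oversample.  Distances
are reported in μm.

## ROIs and correlation

Membership is per pixel center, even-odd rule, boundary inclusive (pinned
by a brute-force ray-casting oracle in the tests), intersected with the
validity mask.  Rectangles are 4-vertex polygons — one code path.
Correlation uses background-subtracted intensities; Pearson r is reported
per ROI with n, and an ROI with a constant channel is flagged degenerate
(r = NaN) instead of producing a spurious value.

## Semi-quantification

With the same isotope measured on sample and standard, atomic weight and
isotope abundance cancel in the intensity ratio, leaving one per-pixel
factor α that absorbs ablated mass and the sensitivity ratio (assumed
element-constant).  Two closures are provided:

* **internal standard**: `α = C_known / r_internal` per pixel, with the
  anchor concentration given as a scalar or a per-pixel map; pixels with
  non-positive anchor response are masked, because the method is only
  defined where the anchor is measured.
* **100% normalization**: `α = 1/Σ r_E` (element fractions) or
  `α = 1/Σ f_ox(E)·r_E` (oxide wt%), solved independently at every pixel.
  Oxide mode applies fixed-valence gravimetric factors from an embedded
  stoichiometry table (SiO₂, TiO₂, Al₂O₃, FeO, MnO, MgO, CaO, Na₂O, K₂O,
  Cr₂O₃, NiO, P₂O₅; iron always as FeO); elements without an entry get
  factor 1 with a warning.  The per-pixel sum is exactly 100 (or 1) by
  construction, and both closures are exactly invariant to scaling all
  intensities at a pixel by a positive constant.

The RSF is the mean blank-subtracted CPS over *all* line readings of one
standard raster, divided by the standard's known concentration — a single
homogeneous-glass scan is the expected calibration input, so per-line RSFs
would only add noise.  Exactly one designated quantification isotope per
element is allowed (combining isotopes of one element is out of scope).
ROI statistics are unweighted means with 1σ SD (n−1 denominator); the
deviation report is `measured/reference − 1`, rounded to three decimals
for display with full precision retained alongside.

Unmodeled effects — matrix effects, monoatomic/polyatomic interferences,
sensitivity drift over the acquisition — are the dominant real-world error
sources; the bundled garnet/wadsleyite EPMA comparison shows
major-oxide discrepancies generally below 15%, which is the realistic
accuracy scale of this class of semi-quantification.

## Simulator

The forward model emits readings every `reading_interval` second:
`ε_E·C_E(x, y)·m(x, y) + background` during ablation, background only
during blanks, where phases are polygons with compositions in μg/g or
oxide wt%, ε is a per-element sensitivity (CPS per μg/g) shared between
sample and standard runs (optionally perturbed per element to study the
constant-ratio assumption), and `m` is an optional ablated-mass modulation
— exactly the quantity the per-pixel α absorbs.  Washout is a causal
single-exponential kernel `(1−λ)λ^j`, `λ = exp(−Δt/τ)`, normalized to unit
sum (counts conserved); τ ≈ 2 s emulates a conventional cell, τ = 0
disables tailing.  Poisson noise draws counts with mean `CPS × dwell` and
is bit-reproducible per seed.  Acquisition defaults mirror a typical
silicate imaging run (10 μm/s, 11 μm spacing, 60 lines, 30 s line
interval, 0.35 s reading cycle).

Not emulated: aerosol transport physics beyond the single-exponential
tail, particle-size effects, plasma ionization, matrix effects,
interferences, detector dead time and drift.  Passing recovery tests
therefore demonstrate that the *reconstruction and normalization
arithmetic* is exact and noise-limited — not that real samples quantify to
those accuracies; the EPMA comparison table is the realistic anchor for
that.

## Problem sizes and numerical conventions

* Test and acceptance scenarios use desk-scale rasters (6–10 lines,
  70–100 μm lines) chosen so each pipeline property is exercised on
  hundreds-to-thousands of pixels while the whole suite runs in seconds;
  the parameter-recovery check draws 20 random noise-free phantoms plus 5
  Poisson-noise phantoms with sensitivities placed so major species exceed
  10⁴ counts per reading (percent-level counting noise).
* The shear-recovery scenario uses a 0.25 s reading cycle so the injected
  +0.5 s/line timing error is commensurate with the reading cadence, and
  runs without background so the deliberately wrong blank windows cannot
  corrupt the comparison (background subtraction is optional in the
  workflow).
* TRA files are written with 17 significant digits, making the text
  round trip bit-exact; the reader parses numbers with exact strtod
  semantics (pandas' fast path is deliberately bypassed).
* Duplicate timestamps and missing cells are hard errors — position
  reconstruction needs strict ordering, and imputation would silently
  fabricate data; interrupted-run tolerance lives in the segmentation
  (short/missing lines become masked rows).
* Multi-file order is an explicit ordered list everywhere; nothing is
  inferred from file names.
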