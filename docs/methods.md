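# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Conventions

**Images.** 8-bit transmitted-light frames, dark plasmodium/tubes on a
bright agar background. Default calibration 0.0625 mm/px (the mid-range of
the 0.06–0.08 mm/px camera resolutions this analysis is designed for).
Behavioral stacks are timed in minutes (5-min default interval),
oscillation stacks in seconds (5-s default).

**Angles.** Measured in array coordinates from the +column axis toward the
+row axis, reduced mod 180° (orientations, not directions). The package's
`images.rotate_image` rotates *in this convention* (it negates the angle
passed to `scipy.ndimage.rotate`, whose positive sense is opposite under a
row-down axis order), so "rotate the image by φ ⇒ every reported angle
shifts by +φ" holds throughout.

**Times.** Stage time t starts at t₀ = 0 when the plasmodium begins to
cross the bridge and reaches tₑ when it touches the far (goal-side) bridge
edge. Network time t_n counts backward from the end of the
network-formation phase (t_n = 0); a day's final network state pools
t_n ∈ [−300, 0] min.

## Behavior

Area: |frame(tₑ) − frame(t₀)| is thresholded (Otsu by default, fixed-value
override available) and foreground pixels inside the bridge ROI are counted
and scaled by pixel_size². The Otsu threshold is floored at 10 intensity
units, and a unimodal difference image (Otsu class means closer than the
floor) is treated as all-background or all-foreground by its overall mean:
on a signal-free frame Otsu would otherwise split the camera noise itself,
and on a uniformly covered frame it would split the coverage mode in half.
Whether the original analyses thresholded globally or per image is unknown;
the policy is per-image and configurable.

Crossing detection: t₀ is the first frame whose foreground inside the ROI
contains a connected component of ≥ 20 px (noise guard); tₑ is the first
frame whose foreground touches the far-edge row. A front already at the far
edge at t₀ is rejected as degenerate; a front that never arrives raises a
"not crossed" error. Speed is bridge_length/(tₑ − t₀) in mm/min, reported
raw and normalized by the same-day control mean (median selectable) — the
normalization cancels day effects (humidity, season, parentage), and a
control group normalized by itself has mean exactly 1.

## Orientation

A square goal crop (side ≥ 64 px) is mean-subtracted, Hann-windowed
(suppresses the axis-aligned leakage cross of a nonperiodic scene) and
FFT'd. Each retained bin contributes angle = atan2(f_row, f_col) mod 180°
weighted by spectral power. The radial band keeps frequencies in
[1/(8w), 1/w] cycles/px for tube-width scale w (default 4 px), i.e.
wavelengths of 1–8 tube widths: below that sits the illumination envelope
and DC, above it pixel noise. Tubes of Gaussian cross-section concentrate
their ridge signal in this band.

The characteristic angle is the mode of a weighted kernel density over
[0°, 180°): a weighted histogram at 0.25° resolution convolved with a
wrapped Gaussian kernel (equivalent to replicating the sample at ±180°),
bandwidth by Silverman's rule on the weighted sample with effective
n = (Σw)²/Σw². All local maxima reaching 25% of the global maximum are
reported (global mode first, ties toward the smaller angle); maxima within
15° of a stronger one are absorbed by it, which suppresses near-duplicate
modes on noisy densities while leaving genuinely distinct modes (≥ 30°
apart by design) untouched. A degenerate all-one-angle distribution
short-circuits to that angle.

Spectral angles are orthogonal to the physical tube direction; the +90°
correction is applied exactly once, at reporting time, and logged. Reported
angles are relative to the plasmodium's advancing direction (angle 0).

## Morphology

Tree: every characteristic angle deviates < 45° (acute deviation) from the
advancing direction. Mesh: any peak at ≥ 45° — a single oblique peak at
exactly 45° is mesh, since the parallel criterion is strictly "< 45°". The
4-day sequence maps to Type 0–4 for the five monotone tree→mesh
trajectories and Type 5 otherwise; missing days raise an error rather than
defaulting to Type 5. This deterministic rule replaces blindfolded manual
classification; the evidence angles are kept on the state object for audit.

## Oscillation

The 320 × 320-px start-block region is reduced to 32 × 32 block means
(10 × 10 px each, 1024 series). Each series is smoothed by lowess
(statsmodels), span fraction 0.1 of the 121-frame window (~60 s): local
linear fits reproduce constants and ramps exactly, kill frame noise, and
pass 60–200-s oscillations. Periods are gaps between successive local
maxima (prominence ≥ 10% of the series IQR, falling back to 10% of the
peak-to-peak range when the IQR is degenerate; plateau peaks take their
left edge). The block period T is the mode of the period histogram at
frame-interval (5-s) bin width, ties broken toward the longer period
(conservative against the noise cutoff); ω = 2π/T. Blocks with ω above
half the Nyquist frequency — 2π·(fₙ/2) with fₙ = 1/(2Δt) = 0.1 Hz, i.e.
T < 20 s — are omitted as noise, as are blocks with fewer than two peaks.
The sample statistic is the median ω over retained blocks; quinine samples
are normalized by the same-day control median. The 10-min movie is taken
to contain 121 frames (inclusive of t = 0).

## Connection

Tubes are binarized as the minority class of an Otsu split (invariant to
inversion and brightness shifts), with the split discarded when the two
class means differ by < 20 intensity units (a noise-only frame has no
tubes). The mask inside the bridge ROI is skeletonized; each connected
skeleton component reaching within 4 px of both boundary rows counts as
one spanning connection — skeletonization trims path endpoints, so an
exact-touch test would miss genuine tubes. Components whose mean boundary
columns lie within 12 px (3 × a typical 4-px tube width) of a counted one
merge into it. Counts map to n/s/d/t as {0}/{1}/{2}/{≥3}. A plasmodium
sitting on the bridge without a boundary-to-boundary path is type n by
construction.

## Statistics

Gate: Shapiro per group and Bartlett across groups at α = 0.05 (the gate
level is a package choice; the procedure prescribes the tests but no
level). Both non-rejected → Dunnett (scipy), else Steel. Zero-variance
groups fail the gate and route to Steel; all-identical-constant inputs to
Dunnett return p = 1 directly (the test statistic is undefined at zero
pooled variance, but the data show no difference by construction).

Steel test (implemented here; no installed package provides it): each
treatment is jointly ranked with the shared control (pairwise ranking),
giving tie-corrected standardized rank-sum statistics Z_i. Under the null
the Z vector is asymptotically multivariate normal with correlation
ρ_ij = √(n_i n_j/((n₀+n_i)(n₀+n_j))) — exactly a one-factor structure
with the control as the common factor — so the familywise (max-statistic)
p-value is a single integral over that factor, evaluated by dense
deterministic quadrature. Adjusted p-values are therefore monotone in |Z|
and never smaller than the unadjusted normal p. When any group has n < 6
the normal approximation is poor and a conservative fallback is used:
exact pairwise rank-sum p-values Bonferroni-multiplied by the number of
contrasts. One-sided "greater" follows the direction the daily-change
analyses use; elsewhere two-sided is the default.

Mann–Whitney uses scipy's exact enumeration for small tie-free samples
(the fully separated 3-vs-3 case gives p = 1/20 = 0.05 one-sided).

Contrast scheme: within each condition, Days 2–4 against the Day 1
reference; for Day-5 manipulation experiments, cutoff/horizontal/reverse
against intact. Tiers: * p < 0.1, ** p < 0.05, *** p < 0.01.

## Synthetic generators

What they emulate: the optical and statistical structure each stage
assumes — dark Gaussian-cross-section tube segments (FWHM = tube width,
σ = width/2.355) whose directions are drawn from a programmable
orientation mixture; a footprint mask (string / branched / sheet)
advancing linearly across the bridge, darkened onto the background,
optionally blurred and noised; blockwise-constant sinusoidal intensity
with programmable per-block periods plus Gaussian noise; study tables with
per-day additive effects per condition under a normal or lognormal family.
All generators are bit-reproducible per seed, keep intensities in
[0, 255], and return ground truth recomputable from the spec.

Generator conventions worth knowing:

- Crossing movies put an empty background frame at index 0 and an 8-row
  entry sliver (above the 20-px guard) on frame 1; the front touches the
  far edge on the last frame, so the detected tₑ − t₀ equals the
  programmed crossing time exactly. A layout where the front starts from
  zero coverage loses one frame interval to quantization.
- Crossing specs require the crossing time to be an integer number of
  frames; oscillation specs require the duration to divide by the frame
  interval (121 frames for 10 min at 5 s).
- Oscillation-movie default periods sit in the 60–200-s range typical of
  plasmodial thickness oscillation; that range is a plausibility choice,
  not a measured value.
- Study-table defaults (area 60 mm², speed 0.12 mm/min, ω 0.05 rad/s;
  dispersions 12 / 0.025 / 0.008; n = 15 per cell) are plausible
  magnitudes chosen once for testing the statistics workflow; real
  experiments set their own.
- Zero dispersion is allowed (degenerate constant tables, used to test
  identities); such groups route to Steel at the gate.
- `make_bridge_connection_image` exists because connection counting needs
  guaranteed boundary-to-boundary tubes, which the random-segment network
  generator cannot promise.

What they do not emulate: growth dynamics, shuttle streaming, tube-width
adaptation, uneven illumination, moving shadows, or anything biophysical.
Passing recovery tests therefore demonstrates that the analysis inverts
its own forward model at realistic noise levels — not that it is robust to
every artifact of real recordings.

## Problem sizes used in the test suite and acceptance script

Tube-network images are 256² px with 60–90 tubes; crossing movies 288² px
(18 mm at 0.0625 mm/px) at 5-min frames; oscillation movies the full
320²/121-frame geometry; cohort recovery uses 20 seeds per condition;
statistical calibration uses 1000 null tables per branch and 200 tables
for power. These sizes give stable rates (binomial SE ≤ ~2 points on the
calibration estimates) while keeping a full run in a few minutes on one
core.

## Known limitations

- The FFT band and KDE bandwidth are tuned for tube-like textures a few
  pixels wide; very thick or very sparse networks may need the band and
  tube-width scale adjusted.
- The tree/mesh rule inherits the 45° threshold; networks with genuine
  oblique (~45°) single modes sit on the boundary and classify as mesh by
  the strict rule.
- Period estimation by peak gaps quantizes to the frame interval; at
  T = 150 s and 5-s sampling the mode can land one bin off, which bounds
  the achievable median accuracy (documented as the "one histogram bin"
  effect).
- The Steel MVN approximation assumes moderate group sizes; below n = 6
  the Bonferroni fallback is deliberately conservative.
- Connection counting assumes roughly transverse tubes; a tube wandering
  more than the merge distance laterally near the boundaries could be
  double-counted or merged with a neighbor.
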