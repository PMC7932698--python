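# Methods

This note documents the models the package implements, the assumptions
behind them, the tunable parameters and their defaults, what the
synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Curtain kymograms and end tracking

A kymogram is a time × position intensity matrix for one DNA strand,
built by averaging the three pixel columns local to the strand in each
movie frame. Position index 0 is the tethered (barrier) end; during
compaction the free end moves toward it.

The end detector smooths the kymogram with a Gaussian along the
position axis (`smooth_sigma`, default 1.0 px), takes the positional
derivative oriented from the tether outward, and takes its per-frame
argmin: the sharpest intensity drop, where DNA signal falls to
background. Temporal smoothing is off by default (`smooth_sigma_t` = 0)
because averaging frames displaces a moving edge in the direction of
motion. Two filters follow:

- edge exclusion (`edge_margin`, default 3 px): argmin values at the
  border of the allowed window are flagged `edge_excluded`;
- trajectory smoothness: a Savitzky–Golay curve (window 11 frames,
  order 2) through the raw positions; frames deviating by more than
  `outlier_px` (default 3 px) are flagged `outlier_rejected`.

Flagged frames are excluded from fits, never interpolated. The detector
has a sub-pixel systematic offset (up to ~1 px toward background when a
bright punctum sits at the end, since the derivative extremum of a
smoothed spike lies one smoothing length beyond it); this offset is
constant along a trajectory and cancels exactly in the compaction-rate
slope. The rate fit is ordinary least squares of accepted end positions
vs time over a user-chosen window, reported in px/frame and, via pixel
size and frame interval, in µm/s. `fit_compaction_rate` accepts as few
as two points (an exact slope); analysis drivers require ≥ 5.

## Binding kinetics

Let ρ(t) be the mean background-subtracted intensity per pixel of the
uncompacted segment. The model assumptions are: ρ grows linearly
(ρ = κt, pseudo-first-order association at constant free protein), and
the end moves at constant speed v, so the captured length is
l_c(t) = vt.

- Equal binding to both segments: the compacted intensity is the
  current density times the captured length, I_a(t) = ρ(t)·l_c(t) = κvt².
- Blocked binding to compacted DNA: each captured element is frozen at
  its capture-time density, I_b(t) = v∫₀ᵗ ρ(s) ds = ½κvt².

The ratio I_b/I_a is exactly ½ at every time, independent of κ and v.
The measured diagnostic is I_c(t)/(ρ(t)·l_c(t)), which centers on 1
under equal binding and on ½ under blocked binding; values below 1
indicate impaired association to compacted DNA. Frames with captured
length below `min_lc` (default 1 px, drivers use 20 px) are masked —
at small l_c the ratio is dominated by the few boundary pixels shared
with the uncompacted segment.

Segment totals are measured by splitting each kymogram row at the
tracked end position: pixels between the tether and
(end − `punctum_halfwidth`) are uncompacted; the rest, including the
punctum, compacted. Background defaults to the median of off-DNA pixels
(beyond the initial end position); an explicit value can be supplied.
The dye-conservation statistic fits I_u to a line in time and reports
(I_c − I_u,fit)/max(I_c); under conserved dye and complete compaction
it spans [−1, 1] and crosses zero at the compaction midpoint. It
presumes the trace covers the compaction window and the dye is at
equilibrium (no net association, κ = 0 channel).

## Droplet segmentation and radius statistics

Brightfield condensates have near-background interiors and paired
bright/dark edge rings, so thresholding fails. The chain is:

1. Fourier high-pass with Gaussian rolloff at `cutoff_frac` of Nyquist
   (default 0.02): removes illumination structure, preserves rims, zero
   mean output.
2. Canny edge detection over a sigma ladder (default {1, 2, 4, 8} px)
   with hysteresis thresholds at per-image gradient quantiles
   (0.90/0.98). Each edge map is closed (disk radius 1) and hole-filled.
3. Scale-aware combination, fine to coarse: a coarse-scale region is
   added only if finer scales have not already segmented a substantial
   part of it (> 10% pixel overlap). Coarse smoothing displaces edges
   outward, so the finest detection of a droplet is kept; stray
   fine-scale edge fragments do not block a coarse region.
4. Filters: area strictly greater than 3 px; eccentricity (from second
   central moments) at or below 0.94.

Region radius is √(area/π). Because the segmented boundary lies beyond
the outer dark ring, an optional rim-refined radius (default on in
`segment_droplets`) locates the bright-rim peak of the azimuthal
intensity profile with parabolic sub-pixel refinement; on synthetic
droplets it is unbiased to ~0.1 px where the area-equivalent radius
carries a rim-width offset. Drivers pool rim radii.

The CCD is CCD(r) = fraction of radii ≥ r, evaluated on the observed
support. The expected radius is the exact integral of this piecewise-
constant function over its support, which for a non-negative variable
equals the sample mean identically; a literal trapezoid across the
jumps would not satisfy that identity, so the step function is
integrated exactly. Confidence bands are percentile bootstrap
(`n_boot` = 1000, level 0.95) over resamples of the pooled radii;
pooling assumes ≥ 5 images per condition in real use. The power law
E[R] = A·c^b is fit by ordinary least squares on log–log axes; standard
errors come from the regression (delta method for A).

## FRAP

Line FRAP: background is subtracted from the bleached-ROI trace and
from each threshold-segmented unbleached droplet trace; unbleached
traces are averaged (a per-droplet option exists); I(0) is the mean
over all pre-bleach frames; the normalized recovery is
(I_FRAP(t)/I_FRAP(0)) / (I_unb(t)/I_unb(0)), which cancels
field-common acquisition photobleaching.

The biexponential recovery y(t) = plateau − a·e^(−k₁t) − b·e^(−k₂t) is
fit by nonlinear least squares with a, b ≥ 0 and k ∈ (10⁻⁴, 10³) s⁻¹;
rates are seeded from a two-segment log-linear fit of the deficit from
the final level and reported fast-first. t½ is the time at which the
fitted curve crosses halfway between its post-bleach floor y(0) and its
fitted plateau, solved by bisection on the fitted curve; for a single
exponential this reduces to ln2/k exactly. A series without measurable
recovery depth is flagged non-converged with t½ undefined.

Whole-droplet FRAP over minutes requires a photobleach model. Each
unbleached droplet's trace (boundary pixels omitted by a 2-px mask
erosion; droplets within `exclusion_factor` × ROI diagonal of the
bleach strike removed, default 3×) is fit to a·e^(−k₁t) + b·e^(−k₂t)
after normalization to its initial value, so a + b are population
fractions. The fast and slow rates are then regressed linearly on the
droplet centroid: k_i(x, y) = k_i0 + αᵢx + βᵢy, capturing
non-homogeneous illumination. The bleached droplet's trace, normalized
to its pre-bleach mean, is divided by
ȳ(t) = ⟨a⟩e^(−k₁(x,y)t) + ⟨b⟩e^(−k₂(x,y)t) evaluated at its own
centroid and referenced to the same pre-bleach window; unbleached
droplets corrected the same way form the expected spread around 1. At
least 6 unbleached droplets with non-collinear centroids are required;
with zero gradients the model reduces exactly to a global-decay
normalization.

## Force-extension energetics

The bare-DNA reference is the Marko–Siggia worm-like-chain
interpolation, F = (k_BT/L_p)[¼(1 − x/L₀)⁻² − ¼ + x/L₀], with
L_p = 50 nm, k_BT = 4.114 pN·nm (25 °C) by default; an optional
enthalpic stretch modulus is available but off, since the correction
is second-order below ~40 pN. The formula's low-extension deviation
from the entropic spring 3k_BTx/(2L_pL₀) is 0.5·(x/L₀) to leading
order — 5% agreement holds for x/L₀ ≲ 0.08.

The energy stored in protein-compacted DNA is the trapezoid integral of
(F_protein − F_bare) over the shared extension range after linear
interpolation onto the union grid, converted at 1 k_BT = 4.114×10⁻³
pN·µm and divided by the compacted base pairs. Compacted length is
measured from the extension deficit at a query force:
Δx / (x_bare(F)/N_bp), i.e. sequestered DNA is removed at the same
fractional extension as the rest of the tether; it can also be supplied
directly. Stretch and relax passes are analyzed separately, never
averaged. Sudden force drops (> 2 pN per grid step) are flagged as
ruptures, not modeled. Binding-site size divides a protein dimer span
by 0.34 nm/bp and rounds to the nearest base pair.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given one integer seed per spec and
always emit their ground truth. Noise is additive Gaussian by default
(a Poisson option exists for the kymogram generator); defaults such as
pixel size 0.16 µm are placeholders exposed in the spec objects.

- Kymograms: linear end motion plus linear association, with the
  captured intensity concentrated in a single-pixel punctum at the end
  and fractional pixel coverage at the boundary so noiseless intensity
  is conserved to machine precision (gain 1). `binding_mode`
  ("equal"/"blocked") selects the post-capture behavior. Not emulated:
  polymer fluctuations, stalling, photobleaching of the dye, or
  diffraction blur of the punctum.
- Droplet fields: an annular bright rim centered exactly on the droplet
  radius with a shallower dark ring outside (amplitude ratio 0.6,
  offset 2.5 ring widths), near-background interiors, optional
  per-droplet rim widths. Droplets may not overlap, so counts are
  recoverable. Not emulated: defocus variation across the field,
  droplet coalescence, or realistic speckle.
- FRAP movies: uniform disks whose intensity follows the spatial
  biexponential decay at their centroid; the bleach multiplies ROI
  droplet pixels by the ground-truth recovery curve. Not emulated:
  diffusive recovery fronts within a droplet or droplet drift (the
  motivation for boundary erosion in real data).
- Force-extension: per-curve grids to 97.5% of each contour length
  (2000 points in the drivers, matching dense trap sampling); the
  protein curve is a WLC with contour reduced by the sequestered
  fraction plus an optional Gaussian force bump; the ground-truth area
  is computed by adaptive quadrature of the closed forms, independent
  of the trapezoid estimator under test. Not emulated: rupture
  cascades, hysteresis between passes, force-clock drift.

Passing recovery tests on these generators validates the estimators
under the stated models; it does not certify performance on real images
with drift, uneven focus, or model misfit, which is why every tracker
and fit exposes its QC flags and the pipeline keeps a manual-rejection
hook for fits.

## Numerical choices and limitations

- Tie-breaks: the end detector takes the first argmin; region matching
  is greedy nearest-centroid, one-to-one.
- Degenerate inputs raise `ValueError` with specific messages (all
  frames rejected, empty droplet set, zero pre-bleach intensity,
  collinear centroids, disjoint extension ranges) rather than returning
  silent NaNs; genuinely flat fits return flagged results instead.
- The biexponential fit is only weakly identifiable when k₁ ≈ k₂ or an
  amplitude is small; parameters are reported fast-first and the
  convergence flag must be checked.
- Problem sizes in the drivers and tests (100-frame kymograms, 128–256
  px fields, 8 unbleached droplets, 20-seed ensembles) were chosen as
  the smallest ensembles at which the recovery medians are stable.
- The segmentation sigma ladder and Canny quantiles are data-dependent
  choices exposed in configuration; the defaults suit fields whose
  droplet radii span roughly 3–30 px.
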