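# Methods

This note documents the models, estimators and numerical choices behind
`cellmig`, and what the synthetic-data generators do and do not emulate.

## Persistent random walks and the persistence fit

**Heading model.** Tracks are generated by discrete-time rotational
diffusion: the heading angle takes increments Δθ ~ N(0, 2·Δt/τ) per frame,
which makes the direction autocorrelation exactly e^(−t/τ) at every lag
(E[cos Δθ] = e^(−σ²/2)). This closed form is the oracle for the fitting
layer: the planted τ must be recovered as the fitted decay constant *a*.
Speeds are drawn per step, N(µ, σ) truncated at 0 (defaults 0.5 ± 0.1
µm/min), independent of direction, so speed and persistence read out
independently. A drift fraction `bias` ∈ [0, 1) mixes a fixed unit vector
into each step direction; the induced long-lag plateau has no convenient
closed form and is instead measured once by long simulation
(`synthetic.measure_plateau`) and used as ground truth.

**Autocorrelation.** For a track with steps s_i, value(k) = mean_i cos ∠(s_i,
s_{i+k}); value(0) = 1 by construction. Zero-length steps have no direction:
any pair containing one is dropped rather than scored as angle 0. Tracks
whose steps are all zero-length are rejected as degenerate. The maximum lag
defaults to half the number of steps — the standard autocorrelation
practice, limiting the noisy tail.

**Fit.** y(t) = (1 − b)·e^(−t/a) + b is fitted by bounded least squares
(trust-region reflective; a > 0, −1 ≤ b ≤ 1), unweighted, with lag 0
included so the model is anchored at y(0) = 1. Initialisation: a ←
duration/4, b ← mean of the last quartile of lags, with up to 20 jittered
restarts if the solver fails. A curve within 1e−6 of 1 everywhere is the
plateau-only limit and reported as b = 1, a = +∞ (converged). On noiseless
model curves the fitter recovers (a, b) to 1e−6 relative and matches a
brute-force grid search at 0.1% resolution.

**Per-cell versus cohort-mean fits.** Per-cell fits (the default of
`fit_cohort`, matching how individual cells are analysed in tracking
assays) are statistically rough at typical scale: a 6.5-h track at 10-min
frames has 39 steps, the per-lag noise is ≈ 0.16, and the per-cell plateau
estimate is strongly skewed (roughly 14% of fits pin at b = −1; the pooled
median b is ≈ −0.08 even when the true plateau is 0). This is a property of
the estimator at that track length, not a solver artefact — a dense grid
search lands on the same optima. The median per-cell *a* remains a usable
τ estimate (within 15% at n = 60). For unbiased parameter recovery the
toolkit therefore fits the cohort-mean autocorrelation curve
(`mean_autocorrelation` then `fit_persistence`), whose per-lag noise is
≈ 0.02 at n = 60; across 200 simulated cohorts this recovers a = 60.0 min
(median; true 60) and b = 0.001 (true 0), both means within one Monte-Carlo
SE of truth. Consumers comparing conditions should compare per-cell fit
parameters (robust statistics); consumers estimating the underlying (τ,
plateau) should fit the cohort mean.

**Cohort comparison.** `compare_persistence` bootstraps (10,000 resamples,
seeded) the difference in group-mean fitted plateau b (primary) and decay
constant a (secondary), with a two-sided tail probability against zero
difference. This is a documented substitute for per-cell statistical
procedures that are not reproducible from typical methods sections; it is
symmetric under label swap and returns p ≈ 1 for identical groups.

## PIV

Single-pass windowed correlation at fixed 32-px windows (23.75 µm at the
default 0.7422 µm/px camera scale) with 0.75 overlap — one vector every
8 px. Each window pair is compared by *linear* (zero-padded) normalised
cross-correlation: the Pearson correlation over every overlap region, with
all running sums computed by FFT (match_template-style). Plain circular FFT
correlation was rejected because image textures with a correlation length
of several pixels bias its peak toward zero shift; the normalised linear
form recovers planted integer shifts to < 0.05 px. The search is restricted
to |shift| ≤ window/2 (the validity bound). Subpixel refinement is the
standard 3-point Gaussian fit on the log correlation, independently in x
and y; peak quality is the ratio of the highest to the second-highest peak
outside a 3×3 exclusion zone. Windows with zero intensity variance (e.g.
inside the cell-free wound) are flagged invalid, not NaN-propagated.
Windows overhanging the frame are dropped; no window weighting (top-hat).

Post-processing follows the conventional order: amplitude filter (magnitude
outside mean ± 3 SD of the field) → replacement of invalid vectors by
inverse-distance-weighted means of their valid 8-neighbourhood, iterated
until filled (fields > 50% invalid are rejected) → trailing 4-frame sliding
average (40 min at 10-min frames), labelled by the window's first frame so
t0 stays at the left of time axes. Velocities convert as u[µm/h] =
u[px/frame] · pixel_um · 60/Δt. Measured accuracy on the synthetic
benchmark: integer shifts < 0.05 px, subpixel < 0.1 px, RMS ≈ 0.04–0.07 px
at 5% noise; antisymmetry piv(B,A) = −piv(A,B) holds to numerical
precision.

## Wound segmentation and space-time maps

**Segmentation.** The wound is the low-texture region: local intensity SD
over a disk of radius 8 px (normalised convolution, so image borders do not
produce artificial variance), thresholded automatically. The threshold is
an isodata-style fixed point initialised at Otsu but iterating thr ←
√(median(SD < thr) · median(SD ≥ thr)): Otsu's split drifts as the wound
shrinks (class imbalance) and an arithmetic midpoint sits inside the lower
tail of the textured class, letting flat monolayer patches percolate into
the wound component; the geometric fixed point settles in the gap between
the two SD scales (flat-region floors are kept ≥ 1e−4 of the textured
median so quantisation-flat wounds do not collapse the split). A frame
whose two classes differ by less than 2× has no distinguishable cell-free
region and raises. Because the disk footprint dilates the textured region
by its radius, the selected component is dilated back by the same disk;
the residual edge bias is ≈ 1–2 px, constant in time, so progression slopes
are unaffected (measured ≤ 0.5% error against planted edge speeds).

**Edge and maps.** The leading edge is, per column, the first monolayer
pixel from the wound side; per frame the column mean; progression is the
signed displacement toward the wound since t0 in µm. Each PIV vector is
assigned its distance from the *current* (per-frame) front edge along the
wound normal — matching maps whose top row tracks the advancing front; a
`t0` reference is available as a toggle. The scalar (speed = |v| in µm/h,
or order parameter = cosine of the angle to the wound-ward normal,
zero-magnitude vectors excluded) is averaged within (distance band × time)
cells per movie, then across movies; band width defaults to the PIV grid
step in µm (one vector row per band). Empty cells are NaN with n = 0 and
render as gaps. End-to-end on a synthetic movie with v(d) = v0·e^(−d/λ)
(v0 = 8.9 µm/h ≈ 2 px/frame, λ = 40 µm), the chain PIV → validate → smooth →
heat map reproduces v(d) within 10% over the first five bands and the edge
speed within 5%.

## Synthetic movies: what they emulate, and not

Movies are smoothed-noise textures (grain ≈ 3 px) over a flat low-intensity
wound strip, advected by the planted velocity field and quantised to 16-bit
with per-frame Gaussian noise. Frames are rendered from the sharp base
image through an analytically composed 1-D backward map (one cubic
interpolation per frame), so repeated warping does not blur the texture and
uniform integer displacements are exact translations. The generator
emulates: intensity statistics that separate wound from monolayer, a
coherent advancing front, a depth-decaying speed profile, and sensor noise.
It does not emulate: cell-scale structure (divisions, junction remodelling,
leader-cell fingers), texture turnover, illumination drift, or in-plane
swirls — so passing tests certify the measurement chain, not biological
realism. One caveat of pure advection is material stretching where ∂v/∂d is
large; λ and movie length are kept such that cumulative strain stays ≈ 30%,
which the segmentation tolerates.

## Line scans and enrichment

Profiles sample the image every 1 px along the line with bilinear
interpolation, averaged over `width_px` perpendicular samples (a width-1
scan along a pixel row reproduces that row exactly). Registration shifts
each profile so the reference-channel maximum sits at 0 (cell-edge mode) or
to a user landmark (junction mode), then resamples linearly onto a common
grid spanning a window (default ±2.5 µm); profiles with a flat reference or
a boundary maximum are rejected with a recorded reason. Averaging
normalises each profile per channel to max = 100% by default (per-sum
normalisation available; it weights broad and sharp peaks differently), then
reports pointwise mean ± SEM (ddof = 1). Enrichment is the ratio of mean
intensities of two equal-area (±10%), non-overlapping ROI bands, after
optional constant background subtraction — scale-invariant by construction,
offset-invariant only when the background is subtracted.

## Fragment screen bookkeeping

`make_fragments` places n fragments of `target_len` residues with starts
round((i−1)·(L−target)/(n−1)) + 1, so the first fragment is (1, target) and
the last ends exactly at L; for L = 1046, n = 15, target = 100 this yields
start spacings of 67–68 and overlaps of 32–33. When n is omitted the
smallest count keeping overlaps ≥ 20 is used. Explicit user delimitations
are validated (strictly increasing starts, overlapping, no gaps) and
accepted verbatim. MSA filtering keeps member rows with identity-to-query ≥
25% and coverage ≥ 50% (both measured over query columns; identity over the
columns the row actually covers), collapses exact duplicates, and keeps per
species the row most similar to the query. Pairing concatenates the two
queries, then one row per common species (order of the first alignment),
then unpaired rows gap-padded on the partner block; row and width accounting
is exact. Confidence per model is 0.2·pTM + 0.8·ipTM; candidates are ranked
by the mean ipTM over models and selected when the best per-model confidence
is *strictly* above the threshold (default 0.65); the selector column is
configurable (`avg_confidence` is also computed) since screens differ on
best-versus-average conventions. The predictor is an interface: a mock
backend serves fixture score tables in tests; an external backend shells
out to a user command for real structure-prediction runs.

## Scalar quantifications

Isoform fractions are 2^(−ΔCt), ΔCt = Ct(isoform) − Ct(total) in the same
sample, replicate Cts averaged before the difference. Fractions are
reported per amplicon and not forced to sum to 1 (amplicons may overlap);
`proportion_shares` renormalises when proportions are wanted. The AP-MS
partner filter treats LFQ intensity > 0 as "detected" (the common
zero-imputation convention; no magnitude threshold is applied) and keeps
proteins detected in ≥ 2 of 3 bait replicates, in no control replicate,
with ≥ 2 razor/unique peptides, sorted by mean bait intensity.

## Problem sizes and seeds

Default test and acceptance scales: 60 cells × 39 steps per cohort (200
cohorts for recovery tests, 100 in the acceptance script), 256×256-px
movies of 10 frames (≈ 29×29 vector grids), 10–50 random curves or tables
per oracle comparison. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; identical seeds give bit-identical
outputs everywhere, which the test suite asserts.
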