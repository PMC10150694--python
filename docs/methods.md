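# Methods

This note documents the models, parameter choices and numerical decisions
behind `frontcompete`, in the order the pipeline runs.

## Synthetic decision-making events

No public dataset of bifurcation decision-making movies exists, so the
package carries a generator whose defaults restate the study conditions and
whose ground truth makes every downstream stage testable.

**Geometry.**  Image coordinates are 0-based (row, column), masks use
8-connectivity, and the channel axis points "up" (decreasing row) toward the
obstacle — one convention, stated once and tested everywhere.  The default
geometry is a 180×150 px frame at 0.21 μm/px: a 6 μm-wide stem channel
(channel height 3 μm, metadata only — the cell fills the cross-section), an
oval obstacle with 5 × 3 μm semi-axes, and two branches of width 4.2 μm
wrapping around it.  Branch midlines start at the obstacle apex and offset
smoothly from the obstacle boundary to half a branch width; a pixel's branch
membership and progress coordinate come from projecting it onto the midline
polyline (distance to the tube, arc length at the projection).  The branch
width was chosen so a 400-pixel front region spans a penetration depth of
roughly 4 μm, matching its purpose of covering the front signaling zone.

**Event kinematics (image tier).**  A cell of 12 μm length approaches at
0.75 μm/frame (3 s frames, i.e. 15 μm/min — a typical fast-neutrophil
speed), contacts the apex, and extends both branch fronts at 0.35 μm/frame
while the rear advances at 0.25 μm/frame, so the cell stretches during the
competition.  After the decision interval the losing front retracts at
0.5 μm/frame for 10 frames.  Masks are rasterized from the geometry; the
largest connected component is kept (rasterization of the wrapped branch
tube can shed single-pixel crumbs), preserving the one-component invariant.

**Decision durations** are drawn Normal(45 s, 15 s), rounded to whole
frames; events shorter than 2 frames are redrawn.  The generator's
`retraction_frame` is the first frame whose rendered mask shows retracted
pixels, so the measured contact→retraction-initiation duration equals the
drawn duration exactly.

**Class signal.**  The asymmetry process of real cells is unobserved; the
generator stands in with two knobs.  The class-dependent signal is zero
strictly before frame ⌈τ·duration⌉ (τ = `divergence_onset_fraction`,
default 0.67 — "last third") and grows linearly to `effect_size` (default
1.5 noise-SD units) at the final pre-retraction frame.  In the feature tier
the signal is a ±effect/2 shift of a seed-chosen informative feature subset
(5 of 696 by default — the sparse-signal regime that motivates the lasso);
in the image tier it modulates the two front speeds (±0.3·ramp, capped),
so winning/losing branch areas diverge after onset.  Labels are fair coins;
an optional stimulation response tilts the coin by `stimulation_bias` only
when a pulse lands at or after signal onset — a deliberately
phenomenological stand-in, since no mechanistic model of the biasing exists.

**FRET optics.**  Acceptor/donor pairs are rendered from a ground-truth
ratio field (1.0 in the body, up to 1.8 at front tips) as
truth × (1 + gradient) × (1 − bleach_slope·t) + shot-like noise, where the
gradient is a linear top-to-bottom vignetting ramp of amplitude
`gradient_amplitude` and bleaching is multiplicative-linear in frame index.

**What the generator does *not* emulate** — segmentation errors from
phase-contrast halos, camera registration offsets between FRET cameras,
nonstationary noise, cell-to-cell morphology variation beyond duration, and
any mechanistic link between signaling and motion.  Passing tests therefore
demonstrate the correctness and statistical calibration of the *analysis*,
not biological fidelity of the synthetic movies.

## Image quantification

**Segmentation** follows the sum-image strategy: conservative background
pixels (below the raw Otsu cut) provide a local-median background (51×51 px
window, larger than a cell diameter at 0.21 μm/px; evaluated on a 16 px grid
and bilinearly interpolated), the background-subtracted image is
edge-enhanced by subtracting a Gaussian-smoothed (σ = 5) copy, Otsu's
threshold binarizes it, and the largest 8-connected component (holes filled)
is the cell.  Constant images raise, as no foreground/background split
exists.

**Ratio correction image.**  Per-pixel median of the FRET ratio over a
stack (cell pixels only), reduced to 24×24 px block medians, upsampled, and
Gaussian-smoothed with σ = 5 *pixels*.  Smoothing after upsampling (rather
than on the block image) keeps σ in pixel units independent of block size;
for smooth vignetting fields the two orders agree away from borders.  Blocks
never covered by a cell are filled from the nearest valid block, with a
warning.

**Front regions.**  The front edge point is the farthest-along-branch
intersection of the branch midline with the mask; the region holds the 400
in-branch cell pixels nearest (Euclidean, centre-to-centre) to it, ties
broken by row-major index — deterministic and verified against a brute-force
sort.  Fewer available pixels are all returned, with a warning.

**Front activity** is Σacceptor/Σdonor over the region (sum of sums, not
mean of ratios), divided by the linear bleach model b(t) = 1 + slope·t.  The
slope is the *signed* fitted rate: a fractional loss per frame enters as a
negative slope.  One signed convention serves both the generator and the
correction; bleach and flat-field corrections are multiplicative, so their
order is immaterial.

**Speeds, length, area.**  Protrusion (retraction) speed is the newly
occupied (vacated) area between front-region masks two frames apart, in
μm²/min; protruded − retracted equals the total area change exactly, an
invariant tested on arbitrary mask pairs.  Cell length is the morphological
skeleton's path length with √2-weighted diagonal steps (diagonals that
shortcut an orthogonal link are not double-counted); area is the pixel
count.  Both are reported relative to a caller-chosen reference frame
(contact, or fronts-separated, depending on the analysis).

**Landmarks.**  Contact is the first frame whose mask touches the obstacle
boundary; retraction initiation the first frame with positive retracted area
of exactly one branch front (a simultaneous tie raises); the big retraction
fires when the losing front's *cumulative* retracted area since initiation
exceeds 7.2 μm².  "Projected retraction area" is read as this cumulative
area — the natural one-time trigger — rather than per-frame increments.

## Feature bank

The reference feature list is not published beyond its total (~700; 696
used), so the catalogue fixes explicit per-family counts summing to 696
over one mask family plus three channels: 12 shape descriptors + 30 Zernike
magnitudes (n ≤ 9, centred on the mask centroid, hence translation
invariant); per channel 22 intensity statistics, 8 radial rings × 3
statistics from the intensity-weighted centroid, 13 Haralick statistics ×
4 directions × 3 distances (1, 3, 7 px; 8-bit quantisation inside the
object, background-touching pairs excluded), and a 16-step granularity
spectrum from iterated erosion + reconstruction (entries in [0, 100] % of
initial in-object mean intensity, sum-bounded by 100).  Keeping the four
directions and three distances unaveraged is what closes the count at
218 features per channel; the total — the dimensionality the classifiers
see — is the normative constraint, and numeric equivalence with external
feature software is not claimed.  Objects under 10 px yield missing values,
mean-imputed later within training folds.

## Time synchronisation

Durations outside mean ± 1 SD (computed on the input population, sample SD,
inclusive bounds) are dropped; with the population values 45 ± 15 s the
window is [30, 60] s.  Each kept trajectory is rescaled to [0, 1] and fitted
with a natural cubic smoothing spline minimising
p·Σ(y−f)² + (1−p)·∫f″², p = 0.5 — the quoted convention (0 = line,
1 = total fit).  The solve is the closed-form Green–Silverman system; all
feature columns of an event share the knot factorisation.  The spline is fit
on rescaled time (making t = 0 "contact" comparable across events, as the
figure axes require), evaluated at 15 equally spaced points including both
endpoints.  p = 1 reproduces the natural cubic interpolant to 1e-9; traces
under 4 frames fall back to linear interpolation with a warning.

## Classification

Features at each timepoint are standardized by the *training* mean and the
standard error of the mean (sd/√n_train) — "subtracting the cell average"
is read as the across-events mean per feature; the per-cell-centring
alternative sits behind `standardize_mode="per_cell"`.  Zero-variance
features are zeroed and flagged.  The λ path is glmnet-style (from the
smallest all-zero λ down 3 decades, 20 points); 10-fold stratified CV picks
the minimum-mean-deviance λ ("best model path" read as CV-minimum, with a
`lambda_rule="1se"` switch for the parsimonious alternative).  Lasso fits
use liblinear with the intercept refit unpenalized afterwards (liblinear
shrinks its bias term; the refit restores the glmnet convention, and makes
the λ→∞ limit the majority-class intercept model).  Elastic net (α = 0.8)
uses saga.  Fold counts are capped at the minority-class size for tiny
datasets.  The sparse group lasso forms one group per feature (its full
15-timepoint trajectory), solved by FISTA with the composite
L1 + group-L2 prox (mixing weight 0.5, group weights √T), λ by 5-fold CV
over a short path; per-timepoint elastic-net models are then fit on the
surviving features only.  Accuracy uses the 0.5 probability cut; the
summary statistic is the earliest timepoint with held-out accuracy ≥ 0.70.

Null calibration is a tested property: on zero-signal data every timepoint's
accuracy stays within 3 binomial SE of 0.5, and the earliest predictive
timepoint is monotone in the generator's onset fraction τ.

## Stimulation planning

Onset thresholds are inclusive where the protocol says "at least" (2.2 μm
and 6.6 μm extension past the apex, measured along the branch midline) and
strict for the big-retraction trigger (> 7.2 μm²); "reached the apex
midline" is implemented as a retracting-edge distance ≤ 1 px (0.21 μm).
Target points are the boundary pixel at a target angle (0° by default)
about the mask centroid, measured from the pre-contact motion direction,
with a row-major tie-break.  Pulses repeat every 3 s from the first
onset-satisfying frame; early assays stop at exactly 5 pulses; an onset
never satisfied yields an empty schedule (logged, not an error).  Opsin
photophysics is not modeled: pulses are events consumed only by the
generator's optional behavioural bias.

## Population statistics

Stretch-signal cross-correlation: both series (relative length; |winning −
losing| activity) are loess-smoothed (local quadratic, tricube weights,
span 10 %, truncated windows at the ends) and Pearson-correlated at integer
lags; the lag range is ± min(10, length/3) frames (unstated in the
protocol; chosen to keep ≥ 2/3 of the samples at every lag).  Traces
shorter than 10 frames (30 s) are rejected.  Per-cell curves are returned
individually so callers can average either curves or peaks.  Responder
calls: slow iff y/x < 0.5, with the boundary on the fast side (strict
inequality); y > x is flagged.  Proportions use p̂ = k/n with binomial SD
√(p̂(1−p̂)/n); group comparisons delegate to the standard two-sided
Wilcoxon rank-sum (Mann-Whitney) and Fisher exact implementations, the
latter verified against exhaustive hypergeometric enumeration on small
tables.

## Problem sizes and tolerances

The default analysis scale mirrors the study design: 100 post-filter events,
67/33 split, 15 timepoints, 696 features.  The acceptance script averages
the late-window peak accuracy over 10 seeds and the null contact-timepoint
accuracy over 25 seeds; invariant tests in the suite run the same pipeline
at reduced feature counts (40–150) and seed counts chosen to keep the whole
suite in the minutes range while leaving the statistical conclusions
unambiguous at 3-SE tolerances.  Spline and prox solvers use closed-form or
fixed-point iterations with 1e-6–1e-10 tolerances; all stochastic stages
derive from a single integer seed.

## Known limitations

Branch membership is rasterized, so front leads under ~1 μm near the apex
wedge are below pixel resolution; the image-tier extension measure is
correspondingly coarse near contact.  Donor/acceptor camera registration is
out of scope (synthetic pairs are pre-aligned; a pass-through hook exists).
The sparse-group-lasso λ selection is a short-path CV, not a full path
algorithm.  The feature catalogue matches the published dimensionality, not
any external program's numeric output.
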