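# Methods

## The problem

OCT angiography (OCTA) maps vasculature through the temporal fluctuation
of the complex OCT field caused by moving red blood cells. The standard
repeated-B-scan approach compares frames ~10 ms apart; over that span even
slow capillary flow decorrelates fully, which gives excellent capillary
sensitivity — but multiply scattered photons from large pial vessels carry
the same fluctuation to deeper voxels, producing "tail" (projection)
artifacts that obliterate the vasculature beneath large vessels.
A repeated-A-scan (M-mode) acquisition at the A-line rate observes each
voxel for well under a millisecond: fast flow in large vessels still
decorrelates, tails can be recognized and nulled from their phase
statistics, but slow capillary flow barely moves and is nearly invisible.

`octafuse` implements the dual-acquisition resolution of this trade-off:
compute both contrasts over the same field of view, restrict the
M-mode-derived index to the axial projection columns of large vessels, and
use the B-scan-derived index everywhere else, then enhance the capillary
compartment with an optimally-oriented-flux (OOF) filter.

## Contrast engines

**OMAG (repeated B-scan).** After per-A-line bulk-motion phase correction
(the phase of the depth-summed cross product between adjacent frames is
rotated away, accumulated so all frames are referenced to frame 0), the
index is the mean consecutive complex-difference magnitude

    Id = (1/(N-1)) * sum_t |R(t+1) - R(t)|,   N = 5 frames by default.

The phase correction is one scalar per A-line pair: a per-voxel correction
would subtract the flow signal itself.

**Adaptive g1 (repeated A-scan).** Per voxel, the normalized field
autocorrelation

    g1(tau) = <R*(t) R(t+tau)>_t / <|R(t)|^2>_t ,  tau = 0..49,

using all `n - tau` sample pairs per lag and the full-series (lag-0) power
for normalization. Because the pair count varies with lag while the
normalization does not, the finite-sample |g1| may exceed 1 by an O(1/n)
fluctuation; no clipping is applied. The dynamic index is the maximum
decorrelation within an adaptively chosen horizon n_tau,

    Id = |g1(1)| - min_{1 <= tau <= n_tau} |g1(tau)| ,

which is nonnegative by construction and *exactly zero* when n_tau = 1 —
the suppression mechanism.

**Horizon selection.** True flow imparts a smooth (Doppler-like) phase
drift on g1; tail voxels, fed by multiply scattered light, have chaotic
phase. The chaos statistic is the circular variance of the lag-to-lag
phase increments `arg g1(tau+1) - arg g1(tau)` over `probe_lags`
increments. Voxels above `chaos_threshold` (default 0.4) get
`ntau_short = 1`; the rest get `ntau_long = 49`. The default
`probe_lags = 32` was chosen from a Monte-Carlo analysis of the statistic
under the phantom's own signal model: g1 estimates at neighbouring lags
share most of their sample pairs, so the phase increments of a chaotic
voxel are serially correlated and their circular variance is biased low;
with only ~8 increments roughly a fifth of fully decorrelated
chaotic-phase voxels fall below the 0.4 threshold, while with 32
increments the misclassification rate drops to ~5% without affecting
smooth-drift voxels (capillaries essentially never misclassify, large
vessels < 1%).

## Large-vessel projection mask

The en-face maximum-intensity projection of the OMAG volume is binarized
with Otsu's threshold (re-applied within the foreground if it would cover
more than half the image, so the mask is always the brighter minority
class). Local vessel diameter is twice the Euclidean distance transform
(anisotropy-aware, in um) sampled on the morphological skeleton; skeleton
pixels with diameter >= 20 um (the default threshold; ">=" so a vessel of
exactly threshold width is kept) seed a *radius-bounded geodesic
dilation*: each seed may grow only by its own local radius plus a 1-pixel
halo margin, always restricted to the original foreground. Bounding the
growth per seed (rather than reconstructing the entire connected
component) matters because a real vascular network is connected — an
unbounded geodesic reconstruction would flood from the trunk into every
touching capillary. For the same reason the diameter is measured on the
*un-closed* foreground: the 1-pixel closing used to bridge speckle gaps
before skeletonization fills the concave corners where two capillaries
cross and would otherwise inflate the local radius past the threshold.
The mask is extruded along z into the 3-D projection column.

## Fusion and OOF enhancement

Inside the column the adaptive-g1 volume is used after scaling by
`s = P99(omag in mask) / P99(ag1 in mask)` (percentile matching is robust
to the background-dominated voxel population; the g1 volume is scaled to
OMAG because OMAG occupies most of the output). Outside the column the
OMAG voxels pass through bit-identically. The merge is a hard binary
switch by default so voxel provenance is exact; an optional 1–2 voxel
linear feather exists for rendering only.

The OOF filter computes, at each scale radius r, the Gaussian-derivative
Hessian (sigma = 0.5 r per axis, converted to voxels through the pitch;
reflect boundaries; kernels truncated at 8 sigma so derivative kernels
sum to zero to ~1e-14 — the default 4-sigma support leaves a visible
residue on constant inputs). With lambda_1 the most negative eigenvalue,
the response is

    P = max_r max( -lambda_1(r) / r^2 , 0 ),

positive on bright tubes at the scale matching their radius and clamped
to zero elsewhere. lambda_1 is taken as the *minimum* eigenvalue: for a
bright tube the two cross-axis eigenvalues are strongly negative, so
-lambda_1 > 0; reading it as the largest eigenvalue would make the
response identically zero on the structures the filter targets. Since the
response of large vessels decays with r, OOF is applied only to the
outside-mask (capillary) compartment, rescaled so its 99th percentile
there matches the fused volume's; in-mask voxels pass through unchanged.
A config switch applies it to the whole volume instead.

## Stitching

Volumes acquired at successive focal depths are registered axially by
maximizing cosine similarity between overlapping slabs over integer
z-offsets (ties to the smallest offset; zero-norm slabs score 0), and
blended with a linear ramp of the shallower volume's weight 1 -> 0 across
the overlap (hard mid-cut optional). Lateral registration is assumed
fixed by the scanner; sub-slice interpolation is not implemented.

## The phantom

The phantom emulates the *temporal* physics per voxel, not image
formation — no beam PSF, no photon transport; decorrelation is purely
temporal because every statistic above acts on per-voxel time series.

* Static tissue: a fixed circular-complex-Gaussian speckle draw
  (fully developed speckle), constant in time.
* Lumen voxels: unit-variance complex AR(1) with lag-1 coefficient
  `exp(-dt/tau_c)` — the discretized Ornstein–Uhlenbeck process, the
  minimal process with exactly exponential autocorrelation, which gives a
  closed-form oracle `E[g1(tau)] = exp(-tau/tau_c)` for every test.
  Defaults: tau_c = 0.05 ms in large vessels (fast flow: |g1| < 0.1 by
  the end of the 0.645 ms M-mode span) and 5 ms in capillaries (slow
  flow: |g1| > 0.85 over the whole span, yet fully decorrelated over a
  10 ms frame interval). A deterministic drift of 0.2 rad/sample makes
  "smooth phase" measurable.
* Tail voxels: the lumen model with tau_c = 0.05 ms, amplitude scaled by
  0.6, plus a random-walk phase jitter of 2 rad/step — decorrelating like
  a large vessel but with chaotic phase. The attenuation and jitter
  magnitudes are engineering defaults (exposed in config); they set the
  contrast scale of the artifact, not a claim about tissue.
* Additive circular complex Gaussian noise, sigma = 0.05 of the static
  amplitude.

The reference geometry (64 x 128 x 128 voxels, 3 um isotropic pitch,
near the 3.7/3.5 um optical resolution) holds one 30 um-diameter pial
vessel, a 90 um tail column beneath it, and four 8 um capillaries, one of
which runs inside the tail column — the configuration the method exists
for. Generation is bit-deterministic given (spec, protocol, seed).

What passing phantom tests does *not* show: robustness to bulk motion
beyond a per-A-line phase, to depth-dependent SNR loss, to non-exponential
decorrelation (multiple flow components per voxel), or to partial-volume
effects at vessel boundaries — none of which the generator emulates.

## Evaluation

Detection masks are obtained by thresholding each volume at half its
median over *true* lumen voxels of the class being scored, so no
per-method threshold tuning enters the comparison; Dice is computed
against the truth labels. `tail_suppression_ratio` is the mean fused
index over tail voxels divided by the mean OMAG index there. Capillary
Dice values are far from 1 for every method because a single global
threshold also detects the other vessel classes; the quantity of interest
is the ordering (fused > g1-only for capillaries, fused >= OMAG for large
vessels), not the absolute level.

For the closed-form AR(1) checks the ensemble statistic is the aggregate
numerator over the aggregate power across voxels: the per-voxel-normalized
estimator carries a ratio bias at long lags when the series barely
decorrelates (the sample power is then dominated by a single effective
speckle draw), and would sit ~0.1 below the true autocorrelation at
tau = 49 for capillary voxels.

## Problem sizes and numerical choices

The test suite exercises the full pipeline at 32 x 64 x 64 and the
acceptance suite at the reference 64 x 128 x 128 (a little over 1 M
voxels; about one minute end to end, the g1 stage dominating). Field data
are complex64, g1 fields complex64, indices float32; oracle-equivalence
tests run in float64 where 1e-12 agreement is asserted. Degenerate
inputs: zero-power voxels get g1 = (1, 0, 0, ...) and a flag; zero-energy
A-lines receive no phase correction; an empty mask or zero percentile
makes the brightness scale 1 with a warning; Otsu on a constant image
returns an empty mask.

## Known limitations

* The adaptive horizon is two-valued (1 or 49); a continuum of horizons
  is conceivable but unspecified by the underlying method description.
* The mask derives from the full-depth MIP; slab-wise masking would
  handle vessels at very different depths overlapping en face.
* OMAG's frame count is parameterized (`n_repeats`) and defaults to 5;
  acquisition-time bookkeeping for other repeat counts is the caller's
  concern.
* The OOF implementation is the Hessian form above, not the original
  flux-through-sphere formulation.
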