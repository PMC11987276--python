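# Methods

This note documents the models, estimators and design choices behind
`plusquant`, with emphasis on the numerically delicate parts and on what the
synthetic-phantom tests do and do not demonstrate about real fundus images.

## Preprocessing

The working channel is the green channel (highest vessel/background contrast
in fundus photography); CLAHE runs with a normalized clip limit of 0.01 on an
8×8 tile grid. Illumination correction models the uneven illumination of
contact wide-field imaging as a smooth multiplicative field: a 2-D polynomial
(default order 4) is least-squares fitted to the log of a lightly smoothed
copy of the image and divided out. A polynomial surface is preferred over
division by a large-kernel Gaussian blur because Gaussian smoothing biases a
curved background (it adds ≈ σ²∇²I/2), which leaves several percent of
residual shading; the polynomial fit flattens an analytic vignette to < 2 %.
The pre-fit smoothing (scale `background_scale/8 · min(H, W)`) suppresses the
vessels so they do not drag the fit. The fixed order is channel → CLAHE →
illumination; the correction is idempotent to < 1 % RMS.

## Vessel segmentation

The segmenter is a configurable-depth U-Net (default 3 resolution levels, 16
base channels — trainable in minutes on one CPU core) written directly in
numpy: convolutions are lowered to channel-mixing matrix products over
shifted slices, and all backward passes are hand-derived and verified against
finite differences in the test suite. Training minimizes the soft Tversky
loss with α = 0.7, β = 0.3: penalizing false negatives harder than false
positives counteracts the extreme class imbalance of thin vessels (< 10 % of
pixels). Patches (128×128) are centered on skeleton bifurcation points of the
reference masks — the most geometry-rich locations — with an 80/20
train/validation split; inference tiles the image with overlap averaging and
thresholds at 0.5. Mask cleanup removes connected components below 200 px
(area opening). We interpret cleanup-by-opening as area opening rather than
a literal 200-px structuring element, which would erase the vessels
themselves; a config switch (`clean_mask(min_area=...)`) keeps this
adjustable. Segmentation quality is scored by boundary-F1 with a tolerance
of 0.75 % of the image diagonal.

## Morphometry

A clean mask is skeletonized (topology-preserving thinning), decomposed into
simple paths between junctions (≥ 3 neighbours) and endpoints, and each path
shorter than 10 px is discarded as a skeletonization spur. Junction pixels
belong to no segment; path tracing breaks ties row-major so the decomposition
is deterministic.

### Curvature and SDC tortuosity

Signed curvature is computed by central finite differences of the resampled
centerline; the SDC tortuosity of a segment is

    tau = (1/L) * sum_i ((kappa_{i+1} - kappa_i)/ds)^2 * ds.

On exactly sampled curves this machinery is accurate to < 1 % (see the
acceptance oracles). On *rasterized* centerlines it is dominated by
quantization noise: a ±0.5 px stair pattern passed through a third derivative
exceeds the bending signal of a 2-px-amplitude vessel by orders of magnitude.
The estimator for mask-derived segments therefore works in four stages:

1. **Subpixel refinement.** Each skeleton point moves along the local normal
   to the midpoint of the vessel chord, with the two boundary crossings
   located by linear interpolation of the signed distance field. This removes
   most of the skeleton quantization.
2. **Attenuation-compensated smoothing.** The centerline is Gaussian-smoothed
   before differentiation. Smoothing at scale σ attenuates a bending
   component of arc-length frequency ω by exp(−σ²ω²/2); the dominant ω is
   estimated from the zero crossings of the curvature profile and the
   attenuation divided back out (capped at 5× for safety).
3. **Bending-adaptive scale.** A conservative first pass (σ = 6) estimates
   the bending slope a·ω. Strongly bent segments (slope ≥ 0.5) are
   re-measured with light smoothing, since their signal dwarfs the noise;
   weakly bent segments proceed to step 4.
4. **Dual-scale noise-floor subtraction.** τ is measured at σ = 5 and σ = 7.
   For pointwise position noise the noise contribution scales as σ⁻⁷ while
   the compensated signal is σ-invariant, so the two measurements give a
   2×2 system for (signal, noise); the noise term is subtracted, clamped at
   zero.

Validated against the analytic tortuosity of rendered sine vessels, this
recovers τ within ~15 % (median over rendering geometries) for amplitudes
≥ 5 px, with individual geometries within ~35 %. At 2 px amplitude a
systematic +20–35 % overestimate remains: part of the rasterization error
falls inside the bending-frequency band itself (the stair pattern modulates
with the sine phase), so the extracted centerline genuinely wiggles more than
the generating curve and no smoothing schedule can separate the two. This is
a physical limit of measuring third-derivative quantities from binary masks,
not an implementation artifact; consumers should treat small-amplitude τ
values as upper bounds.

Per-point radius is the Euclidean distance transform sampled at the refined
centerline (diameter = 2r); points that drift off-mask after smoothing take
the nearest in-mask value. Units are pixels throughout — the imaging chain
is never metrically calibrated.

## Regions and features

The 3DD region is the annulus from the optic-disc border to three disc
diameters beyond it (strict inner inequality at the border); an alternative
disk-from-center convention is available. The vascularized region is the
morphological closure of the vessel mask computed with exact Euclidean disks
via two distance transforms, holes filled, frame borders treated as
continuing the region. The closing radius defaults to 15 % of min(H, W): the
radius must bridge inter-vessel gaps for the closure to describe vascularized
*territory*; at 5 % the region collapses onto the vessels and the density
denominator `N_region − N_vessel` becomes a meaningless sliver.

Vessel density is `N_v/(N_region − N_v)`. The 10-feature grid is
{max diameter, mean diameter, mean SDC tortuosity, mean top-1 % |κ|, density}
× {3DD, whole}; segment-level statistics (tortuosity) assign a segment to a
region by its midpoint, point-level statistics by per-point membership.
The modelled quartet is F1 = max diameter (3DD), F2 = mean SDC tortuosity
(3DD), F3 = density (whole), F4 = top-1 % curvature (whole).

## Grading statistics

Grades are integers 1–5 (Normal, pre-Plus, Plus1–3). The reference standard
diagnosis is the strict-majority grade; ties cannot reproduce human
adjudication sessions, so they are resolved by a deterministic rule
(round-half-up of the mean by default, `lowest`/`highest` available) and
always flagged. The average score is the plain mean of present grades;
missing grades are excluded pairwise everywhere. Weighted kappa uses linear
weights `w_ij = |i−j|/(n−1)` and population proportions (standard Cohen
formulation); two constant, equal raters define κ = 1. Per-expert MSE/MAE
are computed against the average score.

## Severity model

NCA for regression minimizes the leave-one-out soft-neighbour loss
`Σ_i Σ_{j≠i} p_ij |y_i − y_j| + λ Σ_r w_r²` with
`p_ij ∝ exp(−Σ_r w_r² |x_ir − x_jr|)`, by gradient descent from w = 1 with a
step-halving line search (the objective trace is non-increasing by
construction). λ defaults to 1/n. Features are standardized before both NCA
and the OLS fit; the linear model includes an intercept and stores its
standardization so predictions are reproducible from the saved JSON.
Predictions are reported raw and clamped to [1, 5]. Cross-validation
shuffles under the given seed into balanced folds and reports per-fold
MSE/MAE means and standard deviations against the average score. Group
comparisons use Welch's t-test with the conventional star annotation and no
multiple-testing correction (raw p-values, flagged as such in the output).

## Synthetic phantoms

Vessels are sine-perturbed radial rays from the disc border:
`P(t) = c + (r_d + t)u + A sin(2πt/λ + φ)n`, rendered as anti-aliased tubes
(max-blend of disk stamps at 0.25-px spacing) with linearly decaying width;
the truth mask is the soft canvas thresholded at 0.5, with analytic τ per
curve obtained by high-resolution quadrature of (dκ/ds)². Defaults: 600×800
frame, disc diameter 60 px, 6 main vessels with branching probability 0.3,
amplitude 2.5 px, wavelength 60 px, width 6 px, multiplicative vignette and
Gaussian pixel noise (sd 0.02). The wavelength/amplitude defaults keep the
bend radius above the tube radius — sharper bends make the tube self-overlap
and the mask physically loses tortuosity information.

Latent severity θ ∈ [1, 5] scales amplitude (+55 %/level), width (+12 %/level),
vessel count (+0.75/level) and branching (+0.1/level), so dilation,
tortuosity and density all increase with severity as they do clinically;
θ = 1 is the unmodified base. The simulated panel grades θ through per-expert
cut-points (canonical {1.5, 2.5, 3.5, 4.5} jittered with sd 0.25) plus
grading noise (sd 0.3) — values chosen to produce moderate pairwise kappas
with higher expert-vs-RSD kappas, the pattern reported for real ROP panels.

What the phantoms do **not** emulate: real fundus texture, the ridge and
avascular periphery, artery/vein differences, imaging artifacts beyond
vignette + Gaussian noise, and grader biases other than cut-point shifts.
Passing phantom tests therefore demonstrates correctness of the measurement
chain, not clinical performance.

## Problem sizes and determinism

Scaled-down study sizes used by the test suite and acceptance script, chosen
to exercise every component at desk scale: segmenter training on 200 patches
from 4 phantoms for 10 epochs (held-out Dice ≈ 0.95); severity recovery on
n = 200 feature cohorts (noise sd 0.2, standardized effects ≈ 0.5 sd); a
50-image rendered cohort for the end-to-end prediction-versus-θ correlation
(r ≈ 0.92); NCA selection over 20 seeded replicates. All randomness flows
from explicit integer seeds; reruns with the same seed reproduce CSV outputs
byte-for-byte. The single known nondeterminism risk — BLAS reduction order —
does not arise in the pure-numpy float32 training loop on a single thread.

## Known limitations

- Tortuosity at small amplitudes is biased upward (see above).
- The vessel graph does not separate arteries from veins, though clinical
  criteria emphasize arterial tortuosity.
- Tie adjudication is a deterministic stand-in for human consensus sessions,
  and is always flagged.
- The U-Net is intentionally small; on real RetCam images a larger model and
  expert-corrected masks would be needed to approach published BF scores.
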