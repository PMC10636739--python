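# Methods

## Problem and model

Endoscopic video frames view close-range tissue under a light source
that moves with the camera. Any single pairwise registration method
eventually fails on such footage: sparse keypoint matching starves on
texture-poor tissue, direct photometric alignment is misled by saturated
specular highlights and illumination drift, and dense optical flow is
corrupted by floating material moving independently of the camera. A
mosaic is ruined by a handful of bad pairwise registrations, so
robustness of the *data association*, not blending, is the core
difficulty.

The package registers consecutive frames with three independent
sources — SIFT-style feature matching, dense optical flow, and direct
photometric alignment — and fuses all of them in an affine pose graph.
Planar inter-frame motion is modelled as a homography restricted to the
affine form (h31 = h32 = 0, h33 = 1): 6 degrees of freedom, a
non-singular 2×2 linear block plus translation, which is markedly more
stable than the full 8-DOF projective model on endoscopic imagery.

### Pose graph

Vertices x₁…xₙ are per-frame absolute affine transforms (frame k →
first-frame coordinates; the first frame is the gauge anchor and stays
identity). Every pairwise estimate z_ij (up to three parallel edges per
consecutive pair, plus loop-closure edges) constrains two vertices
through the Lie-algebra residual

    e(x_i, x_j, z_ij) = log(z_ij⁻¹ x_i⁻¹ x_j)∨ ,

and the graph cost is Σ eᵀ Ω e with a per-edge 6×6 diagonal information
matrix Ω. The ∨ coordinates are ordered (B11, B12, B21, B22, t1, t2):
first four = linear block, last two = translation, matching how Ω is
specified.

### Information matrices

For correspondence-based sources with N_inl RANSAC inliers:
Ω = diag(100·N, 100·N, 100·N, 100·N, N, N). For direct registration
with final mean photometric residual e_res: Ω = diag(100/e, …, 1/e,
1/e). The linear block is always weighted 100× the translation — the
linear coefficients are dimensionless while translation is in pixels, so
equal weighting would let translation residuals swamp shape errors. An
estimate is *failed* — Ω set to zero, edge inert — when it has too few
inliers (< 10), its residual is too large (> 0.01 mean-squared intensity
on the [0, 1] scale), the solver did not converge, or a consecutive-pair
RANSAC returned an exact identity (the signature of a stalled
estimator; loop pairs are exempt because a perfect revisit *is* a
near-identity transform). These Ω rules are a fixed design, not a
calibrated covariance model; their known blind spot is a source that is
*biased but confident* (small residual, wrong transform), discussed
under Limitations.

### Optimisation

Levenberg–Marquardt on the Lie algebra: per iteration, assemble
b = Σ Jᵀ Ω e and K = Σ Jᵀ Ω J over active edges with numerically
differentiated Jacobians (central differences of the edge residual
under right-perturbation x·exp(±δₖ), step 1e-6), solve
(K + λI) ξ = −b with the anchor block removed, and right-update every
free vertex x ← x·exp(ξ∧). Steps are accepted only when the cost
decreases **and** the gain ratio (actual / model-predicted reduction)
is at least 0.25; λ is divided by 10 on accept, multiplied by 10 on
reject, starting from 1e-4. The gain-ratio gate matters: the
quadratic-on-log cost is non-convex, and with a grossly wrong edge a
full Gauss–Newton step can jump into a distorted configuration in which
inflated linear blocks shrink the log-map translation coordinates.
Gating keeps the solve inside the linearisation regime around the
chained odometry initialisation. Convergence: relative cost change
< 1e-9 or 100 iterations. The damped system is solved densely (the
graphs here have ≤ a few hundred unknowns).

Vertex initialisation chains, per consecutive pair, the non-failed
estimate with the largest Ω trace. A pair where *all* sources failed
would disconnect the graph, so an identity bridge edge with
Ω = 1e-6·I is inserted (with a warning) — solvable, and too weak to
bias connected parts.

### Exponential and logarithm maps

`affine_exp` is the dense 3×3 matrix exponential (scipy). `affine_log`
uses the closed form for the affine group: the principal log of the 2×2
linear block A via the Cayley–Hamilton identity (A = m·I + N,
N² = d²·I, so log A = ½·log det A · I + c₁N with the divided
difference c₁ = artanh(d/m)/d, numerically stable as the eigenvalues
coalesce; the artanh form is used only in the right half-plane m > 0,
the direct log-difference otherwise), then the translation coordinates
from solving φ₁(B)·u = t, with φ₁(B) = (e^B − I)B⁻¹ evaluated by a 4×4
block exponential. The principal log exists iff no eigenvalue of the
linear block lies on the closed negative real axis; such inputs raise a
domain error naming the offending frame pair. The closed form agrees
with the generic dense routine to ~1e-12 and is what makes
numerically-differentiated graph optimisation affordable.

## Registration sources

**Features.** SIFT keypoints and 128-D descriptors (scikit-image), DoG
contrast threshold 0.007 (low, because endoscopy-like scenes are
low-contrast), Lowe ratio 0.75, mutual-nearest check. Detection runs
once per frame and is shared between odometry, loop detection and loop
verification.

**Dense flow.** Iterative Lucas–Kanade (`ilk`, radius 7) by default;
TV-L1 selectable; a `.flo`-file adapter accepts externally computed
flow so a learned estimator can be plugged in without this package
shipping weights. The field is subsampled on a stride-8 grid with a
4 px border margin (flow is least reliable at borders), giving each
pair ~10²–10³ point correspondences.

Both point sources feed the same estimator: linear least squares on the
stacked 2n×6 affine system inside RANSAC (4-point samples — one more
than the affine minimum, never under-determined; collinear samples
rejected by an area test; inlier threshold eps = 2 px on reprojection
distance; 1000 iterations; final least-squares refit on the consensus
set; deterministic per seed).

**Direct.** Coarse-to-fine Gauss–Newton/L–M on the six parameters of
the inverse warp, minimising the mean squared intensity difference over
valid (in-bounds) pixels; 3 pyramid levels, downscale 2 with Gaussian
anti-aliasing, additive parameter updates, λ schedule 1e-3 ×10/÷10,
accepted steps never increase the loss. The residual reported is the
*mean* per valid pixel, making it resolution-independent — required for
the Ω = 100/e_res rule to transfer across image sizes. On featureless
input the image gradient vanishes and the solver stays at its
initialisation with a flat loss; the result is then handled by the
failure rules downstream.

## Loop closure

Keyframes: frame 0 always; afterwards a frame becomes a keyframe when
the chained translation since the last keyframe exceeds half the image
width or the frame gap exceeds 30. Keyframe descriptors are quantised
against a k-means vocabulary (256 words, retrained when the keyframe
count doubles) into tf-idf-weighted, L2-normalised bag-of-words
histograms. A frame whose histogram has cosine similarity ≥ 0.75 with a
keyframe at least 20 frames older is a loop candidate; candidates are
verified by feature matching + RANSAC, and a verified pair becomes a
feature-source loop edge with the usual inlier-based Ω. All thresholds
are config-surface — none is prescribed by the method itself.

## Panorama and evaluation

For display the optimised states are re-anchored so the middle frame
(1-based n/2 for even n, (n+1)/2 for odd) is identity. The canvas is
the bounding box of all warped image corners (floor/ceil outward);
frames are warped by inverse mapping with bilinear sampling
(nearest-neighbour available for bit-exact tests) and blended
first-write-wins: each later frame writes only canvas pixels still
blank. Blankness is a boolean mask, not a pixel-value test, so black
content is preserved. First-write-wins means every canvas pixel is
written at most once; no seam finding or exposure compensation is
attempted.

Mosaic quality is measured without ground truth as the mean SSIM
(7×7 Gaussian-weighted window, greyscale, standard constants) between
each frame and its partner at temporal distance d = 1…5, warped into a
common frame by the *estimated* relative transform; windows touching
invalid pixels are excluded and pairs with < 20% overlap are recorded
as missing rather than scored zero. Misregistration lowers SSIM, so
per-distance and pooled means rank mosaicking variants.

## Synthetic data: what it emulates, what it does not

`synthetic_data` renders frame sequences from a large textured scene
through a known affine trajectory, so every stage is testable with
exact ground truth and no external data. Scene kinds: `textured`
(multi-octave value noise, ~100 SIFT keypoints per 100 px frame),
`vessel_like` (dark curvilinear structures on a smooth background),
`featureless_patches` (a designated box whose contrast is crushed to
15% — low-texture tissue retains faint structure, which yields few and
poorly-localised keypoints rather than none; the designated patch still
yields < 5 keypoints). Effects: a multiplicative illumination gradient
whose direction drifts with the frame index (the light moves with the
camera); saturated specular blobs (intensity exactly 1.0) travelling
with their own velocities, inconsistent with camera motion; additive
Gaussian sensor noise. Rendering is a pure function of (config, seed).

The standard **corrupted benchmark** (endomosaic.benchmarks) is a
60-frame, 4 px/step pan at 100×100 px over a 512 px
`featureless_patches` scene with 16 blobs at up to 10 px/frame during
frames 12–30 and sensor noise σ = 0.015 throughout. These magnitudes
were chosen so each corruption phase actually produces its intended
per-source behaviour — the blob sweep drives the direct residual
decisively above the failure threshold (blobs barely overlap themselves
between frames), and the noise degrades sparse keypoint localisation
much more than the dense sources, which average it out — and then
frozen. The **loop study** is a 50-frame out-and-back pan (peak step
5 px, σ = 0.02) using feature odometry alone, comparing end-of-sequence
drift with and without detected loop edges.

The **recoverability study** is a 60-frame pan under a 0.1 illumination
gradient and σ = 0.01 sensor noise, requiring the fused optimised
trajectory to stay within 3 px mean corner error of ground truth. The
corruption set here is deliberately restricted to effects that perturb
pairwise estimates without biasing them systematically: an open
60-frame chain amplifies any systematic per-pair bias ~60-fold, so a
tight absolute bound is only meaningful in that regime. Saturated
specular phases do bias the (heavily weighted) direct source by a few
tenths of a pixel per pair; their effect on mosaic quality is assessed
by the corrupted benchmark's SSIM metric, which measures local
alignment and is insensitive to accumulated drift — and correcting
accumulated drift is precisely the loop-closure study's subject.

Ground truth is affine by construction, so there is no model mismatch:
passing these studies shows the estimation, weighting, fusion and
blending machinery works as designed, *not* that the affine model
suffices for strongly non-planar or deforming tissue. The renderer has
no parallax, no non-rigid deformation, no motion blur, no rolling
shutter, and its noise is white — all of which real endoscopy has.

## Numerical choices and degenerate inputs

- Pixel convention: 0-based (u, v) = (column, row), origin top-left,
  everywhere.
- RANSAC and the benchmark pipeline are bit-reproducible given a seed;
  per-pair RANSAC seeds are derived from the run seed and pair index.
- Degenerate estimation inputs (n < 3, collinear sources, singular
  fits) return failure signals, never exceptions, and flow into the
  zero-Ω rule.
- A non-positive photometric residual would imply infinite confidence;
  it is logged and treated as a failure.
- Sub-pixel canvas bounds are rounded outward; warped-corner
  containment is asserted by test.
- Zero-information edges are skipped exactly (not down-weighted), so
  deleting them provably changes neither cost nor optimum.

## Limitations

- The Ω heuristics over-trust a biased-but-confident source; in
  particular direct registration in low-texture regions has a small
  residual for the wrong reason (weak constraint, not good alignment).
  The fused result can then track the overconfident source. Outlier-
  aware robust graph optimisation is deliberately out of scope.
- The quadratic-on-log cost admits distorted low-cost configurations
  under extreme outlier edges with near-isotropic weights; the
  gain-ratio gate confines optimisation to the basin of the odometry
  initialisation rather than globally excluding such configurations.
- Affine planarity: scenes with strong depth variation or deformation
  violate the motion model itself; nothing in the fusion corrects a
  model error shared by all sources.
- Bag-of-words retrieval over value-noise-like texture cannot
  distinguish statistically similar but physically different regions;
  geometric RANSAC verification is the real gatekeeper for loop edges.
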