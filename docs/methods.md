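# Methods

This note documents the models and numerical choices behind `odefgvf`, a
pipeline that classifies the optic disk (OD) in a color fundus photograph as
edematous or non-edematous. The pipeline has four stages: vessel-based OD
localization, level-set boundary segmentation driven by texture
factorization, extraction of 27 appearance features, and a linear SVM.

All geometric quantities are fractions of the retina diameter `D`, estimated
per image as the minimum enclosing circle of the largest Otsu-foreground
component of the max-channel image (capped at the shorter image side). This
estimator is parameter-free and exact to ~1 px on disk-like foregrounds.

## Optic-disk localization

The localizer exploits the vascular tree. Vessels are segmented in two
steps: a multiscale Sato (Hessian ridge) filter on the green channel at
scales {1, 2, 4} px marks centerlines (hysteresis thresholds 0.20/0.35 on
the response normalized by its 99.5th percentile inside the retina), and
vessel *width* comes from a darkness test against a large-scale Gaussian
background estimate (sigma 12 px; hysteresis 0.06/0.15). The mask is the
darkness mask gated to within 2 px of a detected ridge. The split matters:
ridge magnitude alone localizes well but over- or under-estimates caliber,
while the darkness test alone hallucinates vessels at any shadow.

Network completeness is judged by the horizontal extent of the largest
8-connected skeleton component: at least half of `D` means complete. On a
complete network the main arcade is fitted with a horizontally opening
parabola `col = a (row − k)² + h` and the vertex `(k, h)` marks the OD. Two
robustness measures are load-bearing:

* only skeleton points whose local caliber (twice the mask's distance
  transform) is above the 60th percentile enter the fit — the arcade is the
  thickest vessel, and straight daughter branches otherwise out-vote it;
* the fit is a seeded RANSAC over exact 3-point parabolas (400 trials,
  2.5 px inlier tolerance), with candidates rejected unless their inliers
  support both sides of the vertex row (arcades are two-armed). A final
  least-squares refinement runs on the consensus set.

On a fragmented network every skeleton chain of at least 10 px gets a
total-least-squares line, and the OD is the point minimizing the sum of
squared distances to all lines (closed-form 2x2 normal equations). If both
paths fail (e.g. no vessels at all) the pipeline falls back to the centroid
of the brightest retinal region and flags the result; the flag propagates
into the case report.

## Boundary segmentation (FGVF)

The region of interest is a square of side `D/3` centered on the localized
OD — wide enough for a swollen disk, whose diameter exceeds the canonical
`D/6`. Contrast is equalized with CLAHE on the L channel of L\*a\*b\*
(8x8 tiles, clip limit 0.01). Vessels are erased from the green channel by
harmonic inpainting: Gaussian smoothing (sigma 1.5 px), 1-px dilation of the
vessel mask, then a direct sparse solve of the 5-point Laplace equation with
the unmasked pixels as Dirichlet data. Harmonic filling reproduces any
affine surface exactly and obeys the discrete maximum principle, both of
which the tests assert.

Segmentation evolves a level-set function `phi` (negative inside the disk)
under a factorized texture data term and a distance-regularization term:

    E = tau * E_data(phi, R) + upsilon * E_reg(phi)
    E_data = -Int[ H_eps(-phi) * omega_o + H_eps(phi) * omega_b ]
    E_reg  = Int[ (|grad phi| - 1)^2 / 2 ]

with tau = 50, upsilon = 1.5. Per-pixel texture features are local spectral
histograms: a 7-filter bank (identity, Laplacian-of-Gaussian at sigma 1 and
2, and real Gabor responses at four orientations with sigma 2, frequency
0.15), each response min-max normalized, quantized to 11 bins, and pooled
with a sliding mean of side `max(9, round(h/10))` px — 77 bands per pixel.
Min-max normalization makes the features, hence the segmentation, exactly
invariant to global affine intensity rescales. The representative features
`R` (one column per region) are smooth-Heaviside-weighted region means, and
the mixture weights `(omega_o, omega_b)` per pixel are the least squares
solution of `Y ~ R beta` via `(R^T R + lambda I)^{-1} R^T Y` with a ridge of
`1e-8 * tr(R^T R)/2` (the normal matrix is 2x2; the printed form `(R R^T)^{-1}`
is singular for more than two feature bands and is read as this least-squares
solution).

The update is explicit gradient descent,

    phi <- phi + dt * ( -tau * delta_eps(phi) * (omega_o - omega_b)
                        + upsilon * (lap phi - div(grad phi / |grad phi|)) ),

with `H_eps(z) = (1 + (2/pi) arctan(z/eps))/2`, eps = 1.5 px, dt = 0.1,
and `|grad phi|` floored at 1e-8. phi starts as the signed distance to a
circle of radius one quarter of the ROI width at the localized OD (a
quarter of the *retina* width exceeds the ROI half-width; the clipped
variant is selectable via `FGVFParams.init_radius`). `R` is refreshed every
10 iterations. Because `E_data` is linear in the mixture weights, the plain
region-mean refresh is not a descent step of `E`; the refresh is therefore
damped by backtracking (the step toward the region means is halved until
the energy is non-increasing, and skipped for the round otherwise). This
keeps the audited energy monotone at a small cost in adaptation speed.

Convergence is declared when the zero contour stops moving: both contours
are resampled to 256 points by arc length from a common anchor (the point
due north of the centroid), and the mean per-point displacement must fall
below 0.05 px in each axis, checked every 10 iterations (cap 1000). The
returned mask is the largest connected component of `phi < 0` with holes
filled, since level sets can shed islands.

A known limitation, measured rather than hidden: at tau/upsilon = 33 the
data force steepens `phi` around the contour faster than the
distance-regularization flow can flatten it, so at convergence
`|grad phi|` sits near 2-3 in a 5-px band around the contour instead of 1.
This is a force-balance equilibrium (1500 extra iterations change it by
less than 0.1) and is independent of dt; it does not affect the extracted
contour or mask, only the metric quality of `phi` away from its zero set.

## The 27 features

* **GLCM (10)** — autocorrelation, contrast, correlation, cluster
  prominence, cluster shade, dissimilarity, energy, entropy, homogeneity,
  max probability, from a symmetric co-occurrence matrix of the
  CLAHE-enhanced grayscale ROI quantized to 8 levels, averaged over the four
  distance-1 offsets. Level indices are 1-based (0-based indexing would
  zero out autocorrelation contributions at the lowest level); entropy uses
  the natural log with 0·log 0 = 0. Correlation is undefined on a constant
  image and raises rather than returning 0.
* **Vessel (6)** — the number of 8-connected vessel components in the ROI
  (VDI) and inside the segmented OD (VDIP), largest and mean component
  areas, and the population standard deviation and kurtosis of the ROI
  grayscale intensities (kurtosis of a Gaussian is 3; of a symmetric
  two-point distribution, 1).
* **Color (7)** — mean gradient-norm sharpness (central differences,
  symmetric borders), mean H/S/V, mean grayscale intensity, and mean a*/b*.
* **Line profile (4)** — mean, min, max, and population std of the grayscale
  along a horizontal segment of length `D/2` through the OD center.

Undefined features (constant inputs) abort extraction with an error naming
every undefined feature; nothing is silently imputed.

## Classification and evaluation

Features are z-scored with statistics fit on training rows only
(zero-variance features dropped with a warning) and classified by a linear
SVM (hinge loss, C = 1, tol 1e-6). Evaluation is stratified five-fold
cross-validation (80/20) with a seeded shuffle; accuracy is pooled over the
five disjoint test folds. A decision value of exactly zero resolves to
non-edematous: for a prescreening tool a tie should not raise an alarm
silently, and the value is carried in the output for review. Localization
is scored as a hit iff the predicted point lands inside the ground-truth OD
contour; segmentation by pixelwise precision/recall/F1 (F1 is algebraically
the Dice overlap, and the tests cross-check that identity); classification
accuracy as the fraction of correctly labeled cases.

## The phantom generator

Real fundus collections with edema labels are small and not redistributable,
so every stage is exercised on synthetic phantoms with known geometry. A
phantom (default 384x384, retina filling 92% of the frame) has:

* a textured retina on a dark surround;
* a vessel tree drawn as a single connected skeleton: a horizontally
  opening parabolic arcade through the OD center (caliber ~5 px), radial
  daughter branches rooted on the arcade and aimed through the OD
  (caliber ~3 px), and nasal rays on the opposite side — so the arcade is
  the thickest structure, the network spans well over half the retina, and
  fragment lines converge on the disk, matching the assumptions of the
  localizer;
* **non-edematous**: a sharp bright disk of diameter exactly `D/6`, with a
  redder neuroretinal rim and a very bright central cup (cup-to-disk 0.55),
  grainy disk texture;
* **edematous**: a larger disk (radius 0.125-0.155 of `D` in cohorts),
  Gaussian-blurred margin (sigma 3-5 px), reduced contrast (0.45-0.65 of
  the healthy disk/retina contrast), smooth low-frequency hyperemic
  mottling in place of the cup/rim structure, a gentle illumination tilt
  across the frame, and a vessel skeleton with 50-75% of its pixels deleted
  in random gaps.

Each phantom consumes one seeded generator; cohorts derive per-phantom seeds
from the cohort seed, so everything is bit-reproducible. The generator's
appearance parameters were chosen so that the class contrasts the features
are designed to detect (bright vs washed-out disk, sharp vs blurred margin,
connected vs fragmented vessels, peaked vs flattened intensity statistics)
hold as cohort-mean inequalities; the tests assert those directions.

What phantoms do **not** emulate: real optical blur and vignetting, camera
noise statistics, pigmentation diversity, pathologies other than edema
(exudates, hemorrhage fields, myelinated fibers), anatomical variation of
the arcades, and the label noise of real reading. Passing the suite
therefore demonstrates that the algorithms are implemented correctly and
recover known structure under the stated contrasts — not that the reported
accuracies transfer to clinical data.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on 384x384
phantoms (ROI ~118 px): 20-phantom localization suites per network type,
10-phantom segmentation suites per class, and one 60-phantom end-to-end
cohort for classification. A single case takes ~1.5 s; the whole acceptance
script a few minutes. All randomness flows through explicit seeds; repeated
runs are bit-identical.
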