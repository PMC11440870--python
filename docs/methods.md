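# Methods

## Model

The observed planar image is a vector of independent Poisson counts
`y_i` with means `lambda = A x`, where `x >= 0` is the unknown activity
on a `rows x cols` raster (row-major order) and `A` is an `n x m`
nonnegative system matrix.  The package realizes `A` by default as a
shift-invariant Gaussian point-spread function sampled on a
`(2r+1)^2` stencil with `r = ceil(3 sd)`; kernel mass falling off the
grid is dropped, so border rows sum to slightly less than one (counts
lost off-detector).  Arbitrary matrices can be supplied as `(i, j,
value)` triplets.

Priors on `x` are first-order Markov random fields: each pixel interacts
with its up/down/left/right neighbours, pair weight `w_jt = 0.5`, so the
Gibbs energy `kappa(x) = sum_j Phi_j(x)` counts every unordered
neighbour pair's potential exactly once.  Two potentials are supported:

* absolute, `phi(u) = |u|` — the Laplace MRF (LMRF), edge-preserving;
* quadratic, `phi(u) = u^2` — the Gaussian MRF (GMRF), smoothing.

The exact Gibbs normalizer is intractable.  The package adopts
pseudo-independent normalizers — `(2 tau)^m` for the Laplace prior and
`(sqrt(2 pi) tau)^m` for the Gaussian prior — which make the scale
updates well defined while leaving all Metropolis ratios over `x`
unchanged.  For the Gaussian prior the normalizer is chosen
self-consistently with the `u^2 / (2 tau^2)` exponent, i.e. a normal
density with standard deviation `tau`.  All priors are truncated to
`x_j >= 0`; the truncation constants cancel in every acceptance ratio
and are ignored.

The homogeneous scale `tau` carries the scale-invariant hyperprior
`pi(tau) ~ 1/tau` (uniform in `log tau`).

### Locally adaptive mixture prior

A binary spatial factor `theta_j` selects, per pixel, the Laplace local
term (scale `tau_l`) when the neighbourhood is high-contrast or noisy,
and the Gaussian local term (scale `tau_g`) when it is smooth.  With the
same per-pixel pseudo-normalizers, a constant label field degenerates
exactly to the matching homogeneous prior.  The hyperpriors are

* `tau_l ~ N(100, 1)`, `tau_g ~ N(10, 1)` — a wide edge-tolerant scale
  and a tight smoothing scale, deliberately well separated so the two
  components remain identifiable;
* `theta_j ~ Bernoulli(rho)` i.i.d.;
* `rho ~ Beta(0.5, 0.5)` — the U-shaped hyperprior pushes the edge
  probability toward decisive values.

The scale hyperpriors are taken as genuine Gaussian densities in
`(tau - mean)^2 / 2`; an absolute-deviation variant of the same
exponent would not be a normal density and is not used.  Given `x` and
`rho`, the mixture prior factorizes over pixels, so the label full
conditionals are independent Bernoullis — the basis of both the exact
label draw and the classification map.

## Estimation

Metropolis-within-Gibbs, one iteration being:

1. **Pixel sweep** — raster-order Metropolis updates with a Gaussian
   random-walk proposal; negative proposals are rejected outright.
   Acceptance ratios use only local terms: the likelihood rows whose
   system-matrix column touches the pixel (the expected-count vector is
   maintained incrementally and refreshed every 200 iterations against
   float drift) and the neighbour-pair prior terms.  A random
   permutation order is available as an option.
2. **Scales** — homogeneous: one Metropolis step on `tau` targeting
   `pi(x|tau) pi(tau)`.  Mixture: `tau_l` and `tau_g` see disjoint
   pixel subsets given the labels, so their two Metropolis updates are
   conditionally independent (order-irrelevant; "parallel" is a
   contract, not a threading mandate).
3. **Labels** — exact Bernoulli draw from the full conditional by
   default; a per-pixel Metropolis flip mode is retained for fidelity
   to the stepwise description of the algorithm.
4. **Edge probability** — conjugate draw from
   `Beta(alpha + s, beta + m - s)` with `s = sum(theta)` by default; a
   Gaussian random-walk Metropolis mode (proposals outside (0,1)
   rejected) is retained.

Proposal standard deviations are tuned every 10 iterations during
burn-in only, by `scale <- 0.5 scale (1 + r/0.234)` where `r` is the
window acceptance rate; the rule's fixed point is the 0.234 optimum,
and freezing it after burn-in preserves ergodicity.  Defaults:
5000 iterations, burn-in 100, initial proposal sds 10 (pixels and
`tau`), 1 (`tau_l`), 0.5 (`tau_g`), 0.05 (`rho`).

Initialization: `x(0) = y` (square `A`), falling back to a positive
constant if that leaves a zero expected count at an observed pixel
(still-degenerate inputs raise a diagnostic error); labels from
thresholding the first-order neighbour differences of `x(0)` at 50;
`tau(0) = tau_l(0) = 100`, `tau_g(0) = 10`, `rho(0) = 0.5`.  All
randomness flows from one `numpy` Generator per chain, seeded from the
run configuration, so chains are bit-reproducible.

## Synthetic data

The generator freezes one concrete 29x58 reference layout: a circle of
radius 7 centred at (13, 40), an irregular 23-pixel blob at the
circle's lower right, and two rectangles (rows 4-10 x cols 7-19, rows
16-23 x cols 9-22) toward the left.  The hard-edge phantom sets hot
pixels to 1099 on background 0; the smoothed phantom sets 400 on 75 and
convolves with a normalized Gaussian kernel, default sd 1.5 px (reflect
padding, so the pixel sum is conserved).  The degradation PSF default
is sd 1 px — a visible but moderate blur.  Eight fixed rectangular
regions of interest (two hot-edge, two hot-interior, two smooth
background, two background-edge windows) are stored as package data and
used identically for both phantoms; pixels are categorized smooth /
high-contrast by thresholding the largest absolute neighbour difference
at 50 and 500.

The mouse-like phantom is synthetic plumbing for the classification
comparison: a low-uptake body ellipse (level 25 on background 5)
carrying three organ foci whose activity peaks at 350-500 in the core
and decays quadratically to body level at the rim.  The decaying rims
matter: they produce genuinely hot pixels at low intensities, which an
intensity-only classifier tends to assign to background while the
contrast-driven spatial factor can still capture them.

What the generator does *not* emulate: scatter, attenuation,
depth-dependent or anisotropic response, detector calibration and
dead-time, anatomical texture inside organs.  Passing tests therefore
demonstrate correctness of the inference machinery under the stated
forward model, not clinical performance.

## Evaluation

Posterior summaries are pixelwise means with equal-tailed credible
intervals (default 95%) from post-burn-in samples.  Errors are mean
squared differences over RoI masks.  Scale sensitivity is assessed by
refitting fixed-`tau` chains over a grid (the full design is 20
log-spaced points from 1 to 1e4) and recording region-wise MSE of the
posterior-mean image.  Hot-region classification thresholds the
spatial-factor inclusion frequency at 0.5; the baseline is Lloyd's
k-means (k = 2, 10 restarts) on pixel intensities with the
higher-centroid cluster labelled hot, which makes the labelling
invariant to initialization order.  Row/column profiles use 1-based
indices.

## Problem sizes used by the shipped checks

The test suite favours small, oracle-checkable problems: 1x2 and 1x3
toys are compared against dense-grid quadrature and explicit
enumeration over label configurations; distributional checks bin 1e5
thinned samples onto a 3x3 equal-mass partition of the quadrature
target (a partition coarse enough that the Monte-Carlo noise floor of
the empirical total-variation estimate sits below the acceptance
level).  Full-raster checks run 600-5000 iteration chains on the 29x58
phantoms, with seed-replicated majority votes (3 of 5) for stochastic
orderings, and the scale-sensitivity sweeps in the ordering checks use
a reduced 6-point grid from 30 to 3000 spanning the informative range.

## Known limitations

* The posterior scale estimates depend strongly on inputs that the
  reference study leaves unspecified — the exact region geometry (hence
  total edge length), the system blur, and the smoothing bandwidth of
  the second phantom.  Under this package's frozen defaults the two
  homogeneous models give nearly equal scales on the smoothed dataset,
  so their ordering there is not a robust outcome; on the hard-edge
  dataset the Gaussian-model scale clearly exceeds the Laplace-model
  scale.
* The pseudo-normalizer convention makes the scale posteriors
  well-defined but approximate relative to the intractable Gibbs
  normalizer; scale estimates should be read as calibrated smoothing
  levels, not as literal field variances.
* The mixture scales are strongly informed by their sd-1 hyperpriors by
  design; with very different activity scales the means 100/10 should
  be reconsidered.
* Single-site random-walk updates mix slowly for strongly coupled
  (heavily blurred) systems; the chain lengths used here suit the
  29x58 rasters and the default PSF.
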