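# mixmrf

Hierarchical Bayesian restoration of low-count radionuclide (planar
gamma-camera) images, with homogeneous Markov-random-field priors and a
locally adaptive Laplace+Gaussian mixture prior.

## The problem

Planar nuclear-medicine images are blurred by the collimator/detector
response and dominated by Poisson counting noise.  Writing the unknown
activity raster as `x` (m pixels) and the recorded counts as `y`
(n detector bins), the degradation is linear in expectation,

    E[y] = A x,      y_i ~ Poisson(lambda_i),   lambda = A x,

with a nonnegative system matrix `A` (here a truncated Gaussian PSF).
Restoration is posed as Bayesian inversion with a first-order
(4-neighbour) MRF prior on `x` with pair weight `w = 0.5`:

* **LMRF** — absolute potential `phi(u) = |u|`, scale `tau`:
  edge-preserving;
* **GMRF** — quadratic potential `phi(u) = u^2`, scale `tau`: smoothing;
* **mixture prior** — a per-pixel binary spatial factor `theta_j`
  selects the Laplace component (scale `tau_l`, Gaussian hyperprior mean
  100, sd 1) in high-contrast neighbourhoods or the Gaussian component
  (scale `tau_g`, hyperprior mean 10, sd 1) in smooth ones;
  `theta_j ~ Bernoulli(rho)` i.i.d. with `rho ~ Beta(0.5, 0.5)`.

The homogeneous scale carries the scale-invariant hyperprior
`pi(tau) ~ 1/tau`.  Everything is estimated by Metropolis-within-Gibbs
MCMC: a raster-order random-walk pixel sweep (proposals truncated at
zero), Metropolis scale updates, an exact Bernoulli draw of the spatial
factor, and a conjugate Beta draw of `rho`.  Proposal scales are tuned
during burn-in only, by `scale <- 0.5 scale (1 + r/0.234)`, whose fixed
point is the asymptotically optimal acceptance rate 0.234.

Because the spatial factor concentrates on noisy/high-contrast
neighbourhoods, its posterior inclusion map doubles as a hot-region
classifier; the package compares it against a k-means intensity
baseline.

No real acquisitions are needed: a phantom module generates the two
29x58 reference phantoms (hard-edge, values 1099/0; smoothed, base
400/75 blurred with a Gaussian kernel), the eight regions of interest,
and a mouse-like phantom with organ foci whose uptake decays toward the
rim.

## Worked example

```sh
mixmrf simulate --phantom paper1 --seed 1 --outdir sim1
mixmrf fit --model laplace --indir sim1 --seed 2 --outdir chain_lmrf
mixmrf evaluate --chain chain_lmrf --indir sim1 --outdir eval_lmrf
```

which prints

```
wrote truth, observation and system matrix to sim1
chain archived in chain_lmrf
global MSE 1820; reports in eval_lmrf
```

`simulate` writes the hard-edge phantom, its Poisson-degraded
observation and the PSF system matrix (sd 1 px) as CSV.  `fit` runs a
5000-iteration LMRF chain with estimated `tau` and archives samples,
traces and the pixelwise posterior mean with 95% equal-tailed credible
intervals.  The scalar trace gives a posterior mean of `tau = 134.1`
for this realization; the reported global MSE of 1820 is the mean
squared error of the posterior-mean image against the known truth
(activity scale 0-1099, so the RMS error per pixel is about 43).
`mixmrf sweep` tabulates region-wise MSE over a `tau` grid,
and `mixmrf classify` writes the spatial-factor and k-means hot-region
maps with their agreement against the true mask.

The same pipeline is available as a library:

```python
import numpy as np
from mixmrf import (make_phantom, MCMCConfig, PriorSpec,
                    run_homogeneous, posterior_summary)
from mixmrf.forward_model import degrade

truth = make_phantom("paper1", 1099.0, 0.0)
y, A = degrade(truth, kernel_sd=1.0, seed=1)
chain = run_homogeneous(y, A, PriorSpec("absolute", 100.0),
                        MCMCConfig(iterations=5000, burn_in=100, seed=2))
mean, lower, upper = posterior_summary(chain)
print(chain.tau[100:].mean())   # posterior mean of the prior scale
```

## Chain archives

`ChainResult.save(dir)` writes `samples.npz` (image samples, scalar
traces, labels, acceptance trace) plus `meta.json` with the full
configuration and seed; `ChainResult.load(dir)` restores it, and
`export_traces` emits a CSV of the scalar traces.  Every CLI run also
writes a `<command>.log.json` with its parameter echo, seed and package
version, so any output is regenerable from its log.

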