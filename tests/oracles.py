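"""Independent brute-force oracles used by the test suite.

Everything here is written directly from the model definitions with scipy
building blocks (per-element pmf sums, dense grid quadrature, explicit
enumeration of binary label configurations) and deliberately avoids the
package's own energy/posterior code paths.
"""

import numpy as np
from scipy import stats

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def poisson_loglik(y, lam):
    """Sum of independent Poisson log-pmf values."""
    return float(np.sum(stats.poisson.logpmf(np.asarray(y), np.asarray(lam))))


def chain_logprior(x, tau, potential):
    """Homogeneous MRF log-prior on a 1-D chain of pixels (pairs once)."""
    x = np.asarray(x, dtype=float)
    m = x.size
    d = np.diff(x)
    if potential == "absolute":
        return -np.sum(np.abs(d)) / tau - m * np.log(2.0 * tau)
    return -np.sum(d * d) / (2.0 * tau**2) - m * (LOG_SQRT_2PI + np.log(tau))


def quad_2pixel(A, y, tau, potential, hi, n=200):
    """Normalized 2-pixel homogeneous posterior on an n x n grid.

    Returns the cell-centre coordinates and the probability table
    (cells of equal area, probabilities summing to one).
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y)
    edges = np.linspace(0.0, hi, n + 1)
    xs = 0.5 * (edges[:-1] + edges[1:])
    X1, X2 = np.meshgrid(xs, xs, indexing="ij")
    lam1 = A[0, 0] * X1 + A[0, 1] * X2
    lam2 = A[1, 0] * X1 + A[1, 1] * X2
    logp = stats.poisson.logpmf(y[0], lam1) + stats.poisson.logpmf(y[1], lam2)
    d = X1 - X2
    if potential == "absolute":
        logp += -np.abs(d) / tau
    else:
        logp += -(d * d) / (2.0 * tau**2)
    logp -= logp.max()
    P = np.exp(logp)
    P /= P.sum()
    return xs, P


def quad_moments_2pixel(xs, P):
    """Posterior means and sds of both pixels from a quadrature table."""
    p1 = P.sum(axis=1)
    p2 = P.sum(axis=0)
    m1 = float(np.sum(xs * p1))
    m2 = float(np.sum(xs * p2))
    s1 = float(np.sqrt(np.sum((xs - m1) ** 2 * p1)))
    s2 = float(np.sqrt(np.sum((xs - m2) ** 2 * p2)))
    return (m1, m2), (s1, s2)


def equal_mass_partition(xs, P, nbins=3):
    """Per-axis quantile edges giving roughly equal-mass 2-D cells."""
    p1 = np.cumsum(P.sum(axis=1))
    p2 = np.cumsum(P.sum(axis=0))
    qs = np.arange(1, nbins) / nbins
    e1 = np.interp(qs, p1, xs)
    e2 = np.interp(qs, p2, xs)
    return e1, e2


def cell_probabilities(xs, P, e1, e2):
    """Aggregate a quadrature table onto the partition cells."""
    i1 = np.digitize(xs, e1)
    i2 = np.digitize(xs, e2)
    nb = len(e1) + 1
    out = np.zeros((nb, nb))
    for a in range(len(xs)):
        for b in range(len(xs)):
            out[i1[a], i2[b]] += P[a, b]
    return out


def bin_samples(samples, e1, e2):
    """Empirical cell frequencies of 2-pixel samples on the partition."""
    i1 = np.digitize(samples[:, 0], e1)
    i2 = np.digitize(samples[:, 1], e2)
    nb = len(e1) + 1
    out = np.zeros((nb, nb))
    np.add.at(out, (i1, i2), 1.0)
    return out / samples.shape[0]


def mixture_local_logprior(x, theta, tau_l, tau_g):
    """Mixture log-prior on a 1-D chain, written term by term.

    Local energies carry the 0.5 pair weight; each pixel contributes the
    Laplace term when its label is 1 and the Gaussian term otherwise.
    """
    x = np.asarray(x, dtype=float)
    m = x.size
    out = 0.0
    for j in range(m):
        phi_abs = 0.0
        phi_sq = 0.0
        for t in (j - 1, j + 1):
            if 0 <= t < m:
                d = x[j] - x[t]
                phi_abs += 0.5 * abs(d)
                phi_sq += 0.5 * d * d
        if theta[j] == 1:
            out += -phi_abs / tau_l - np.log(2.0 * tau_l)
        else:
            out += -phi_sq / (2.0 * tau_g**2) - (LOG_SQRT_2PI + np.log(tau_g))
    return out


def enum_quad_mixture_1x3(A, y, tau_l, tau_g, rho, hi, n=60):
    """Joint enumeration over all 8 label configurations with 3-D quadrature.

    Returns posterior pixel means, pixel sds and the marginal probability
    that each label equals one, for fixed scales and fixed rho.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y)
    edges = np.linspace(0.0, hi, n + 1)
    xs = 0.5 * (edges[:-1] + edges[1:])
    G = np.stack(np.meshgrid(xs, xs, xs, indexing="ij"), axis=-1).reshape(-1, 3)
    lam = G @ A.T
    loglik = stats.poisson.logpmf(y[None, :], lam).sum(axis=1)
    # per-pixel local energies on the 3-chain, 0.5 pair weight
    d01 = G[:, 0] - G[:, 1]
    d12 = G[:, 1] - G[:, 2]
    phi_abs = np.stack(
        [0.5 * np.abs(d01), 0.5 * (np.abs(d01) + np.abs(d12)), 0.5 * np.abs(d12)], axis=1
    )
    phi_sq = np.stack(
        [0.5 * d01**2, 0.5 * (d01**2 + d12**2), 0.5 * d12**2], axis=1
    )
    lap = -phi_abs / tau_l - np.log(2.0 * tau_l)
    gau = -phi_sq / (2.0 * tau_g**2) - (LOG_SQRT_2PI + np.log(tau_g))
    total = 0.0
    mean = np.zeros(3)
    second = np.zeros(3)
    theta_mass = np.zeros(3)
    parts = []
    for cfg in range(8):
        theta = [(cfg >> b) & 1 for b in range(3)]
        logprior = sum(lap[:, j] if theta[j] == 1 else gau[:, j] for j in range(3))
        logtheta = sum(np.log(rho) if t == 1 else np.log1p(-rho) for t in theta)
        parts.append((theta, loglik + logprior + logtheta))
    shift = max(p.max() for _, p in parts)
    for theta, logp in parts:
        w = np.exp(logp - shift)
        total += w.sum()
        mean += w @ G
        second += w @ (G * G)
        for j in range(3):
            if theta[j] == 1:
                theta_mass[j] += w.sum()
    mean /= total
    second /= total
    sd = np.sqrt(second - mean**2)
    return mean, sd, theta_mass / total


def quad_tau_posterior(energy, m, potential, grid):
    """Normalized posterior of the scale given a fixed image (1-D quadrature).

    Target: pi(x | tau) pi(tau) with the pseudo-normalizers and the 1/tau
    hyperprior, evaluated on the supplied tau grid.
    """
    grid = np.asarray(grid, dtype=float)
    if potential == "absolute":
        logp = -energy / grid - m * np.log(2.0 * grid) - np.log(grid)
    else:
        logp = -energy / (2.0 * grid**2) - m * (LOG_SQRT_2PI + np.log(grid)) - np.log(grid)
    logp -= logp.max()
    p = np.exp(logp)
    return p / np.trapezoid(p, grid)


def batch_se(samples, nbatch=20):
    """Batch-means Monte-Carlo standard error along axis 0."""
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    k = n // nbatch
    means = np.array([samples[i * k:(i + 1) * k].mean(axis=0) for i in range(nbatch)])
    return means.std(axis=0, ddof=1) / np.sqrt(nbatch)
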