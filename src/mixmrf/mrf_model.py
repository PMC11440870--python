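"""Log-density building blocks for the hierarchical Bayesian model.

Likelihood
    Independent Poisson counts, ``log f(y|x) = sum_i y_i log(lambda_i)
    - lambda_i - log(y_i!)`` with ``lambda = A x``.

Markov-random-field priors
    First-order (4-neighbour) Gibbs priors on the pixel raster with pair
    weight ``w_jt = 0.5``, so every unordered neighbour pair contributes its
    potential exactly once to the energy ``kappa(x) = sum_j Phi_j(x)``.
    The absolute potential ``phi(u) = |u|`` gives the edge-preserving
    Laplace MRF (LMRF); the quadratic ``phi(u) = u^2`` gives the smoothing
    Gaussian MRF (GMRF).  The exact Gibbs normalizer is intractable, so the
    package adopts per-pixel pseudo-normalizers ``(2 tau)^m`` (Laplace) and
    ``(sqrt(2 pi) tau)^m`` (Gaussian, self-consistent with an exponent in
    ``tau^2``), which make scale updates well defined.  All priors are
    restricted to ``x_j >= 0``; the truncation constants cancel in
    Metropolis ratios and are ignored.

Mixture prior
    A per-pixel binary spatial factor ``theta_j`` selects the Laplace
    component (scale ``tau_l``, high-contrast neighbourhood) or the
    Gaussian component (scale ``tau_g``, smooth neighbourhood).  Gaussian
    hyperpriors centre the scales at 100 and 10 (sd 1); ``theta`` is
    i.i.d. Bernoulli(rho) with a Beta(0.5, 0.5) hyperprior on rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

ABSOLUTE = "absolute"
QUADRATIC = "quadratic"

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class NeighborGraph:
    """First-order neighbour structure of a ``rows x cols`` raster.

    Stores, for each pixel ``j`` (row-major order), its up/down/left/right
    neighbours clipped at the borders, both as a padded ``(m, 4)`` index
    array (for samplers) and as the list of unordered neighbour pairs (for
    vectorized energies).
    """

    def __init__(self, rows: int, cols: int):
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        self.rows = rows
        self.cols = cols
        self.m = rows * cols
        idx = np.arange(self.m).reshape(rows, cols)
        pairs = []
        if rows > 1:
            pairs.append(np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1))
        if cols > 1:
            pairs.append(np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1))
        self.pairs = (
            np.concatenate(pairs, axis=0) if pairs else np.empty((0, 2), dtype=np.int64)
        )
        nbr = np.full((self.m, 4), -1, dtype=np.int64)
        nnbr = np.zeros(self.m, dtype=np.int64)
        for a, b in self.pairs:
            nbr[a, nnbr[a]] = b
            nnbr[a] += 1
            nbr[b, nnbr[b]] = a
            nnbr[b] += 1
        self.nbr = nbr
        self.nnbr = nnbr
        self.weight = 0.5  # w_jt of the first-order MRF

    def neighbours(self, j: int) -> np.ndarray:
        """Indices of the up/down/left/right neighbours of pixel ``j``."""
        return self.nbr[j, : self.nnbr[j]]


@dataclass(frozen=True)
class PriorSpec:
    """Homogeneous MRF prior: potential family plus scale ``tau = 1/B``."""

    potential: str = ABSOLUTE
    tau: float = 100.0

    def __post_init__(self):
        if self.potential not in (ABSOLUTE, QUADRATIC):
            raise ValueError(f"potential must be '{ABSOLUTE}' or '{QUADRATIC}'")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class MixtureState:
    """Current mixture-prior parameters: labels and scales."""

    theta: np.ndarray
    tau_l: float = 100.0
    tau_g: float = 10.0
    rho: float = 0.5

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.int64).ravel()
        if not np.all((self.theta == 0) | (self.theta == 1)):
            raise ValueError("theta must be binary")
        if self.tau_l <= 0 or self.tau_g <= 0:
            raise ValueError("scales must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


@dataclass(frozen=True)
class HyperpriorSpec:
    """Hyperprior constants of the mixture model."""

    tau_l_mean: float = 100.0
    tau_g_mean: float = 10.0
    scale_sd: float = 1.0
    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.tau_l_mean <= 0 or self.tau_g_mean <= 0 or self.scale_sd <= 0:
            raise ValueError("hyperprior means and sd must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")


def _phi(potential: str, d: np.ndarray) -> np.ndarray:
    if potential == ABSOLUTE:
        return np.abs(d)
    if potential == QUADRATIC:
        return np.square(d)
    raise ValueError(f"unknown potential {potential!r}")


def prior_energy(x: np.ndarray, graph: NeighborGraph, potential: str) -> float:
    """Gibbs energy ``kappa(x)``: each unordered neighbour pair counts once.

    With pair weight 0.5 applied from each direction, the double sum over
    pixels and their neighbour sets reduces to a single sum of potentials
    over unordered pairs.
    """
    flat = np.asarray(x, dtype=float).ravel()
    if flat.size != graph.m:
        raise ValueError("image size does not match graph")
    a, b = graph.pairs[:, 0], graph.pairs[:, 1]
    return float(np.sum(_phi(potential, flat[a] - flat[b])))


def local_energies(x: np.ndarray, graph: NeighborGraph) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel local energies ``Phi_j`` (absolute and quadratic, w=0.5).

    ``Phi_j = sum_{t in d(j)} 0.5 * phi(x_j - x_t)``; summing either array
    over j recovers the corresponding global energy.
    """
    flat = np.asarray(x, dtype=float).ravel()
    a, b = graph.pairs[:, 0], graph.pairs[:, 1]
    d = flat[a] - flat[b]
    phi_abs = np.zeros(graph.m)
    phi_sq = np.zeros(graph.m)
    np.add.at(phi_abs, a, 0.5 * np.abs(d))
    np.add.at(phi_abs, b, 0.5 * np.abs(d))
    np.add.at(phi_sq, a, 0.5 * d * d)
    np.add.at(phi_sq, b, 0.5 * d * d)
    return phi_abs, phi_sq


def log_likelihood(x: np.ndarray, A, y: np.ndarray) -> float:
    """Poisson log-likelihood of counts ``y`` given activity ``x``.

    Uses the convention ``0 * log 0 = 0``; returns ``-inf`` (never raises)
    when some ``lambda_i = 0`` has ``y_i > 0``.
    """
    y = np.asarray(y).ravel()
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    lam = A @ np.asarray(x, dtype=float).ravel()
    lam = np.asarray(lam, dtype=float)
    if lam.shape != y.shape:
        raise ValueError("observation length does not match system matrix")
    pos = y > 0
    if np.any(lam[pos] <= 0):
        return -np.inf
    out = -float(np.sum(lam)) - float(np.sum(special.gammaln(y[pos] + 1.0)))
    out += float(np.sum(y[pos] * np.log(lam[pos])))
    return out


def log_prior_homogeneous(x: np.ndarray, spec: PriorSpec, graph: NeighborGraph) -> float:
    """Homogeneous MRF log-prior with the pseudo-independent normalizer.

    Laplace: ``-kappa_abs / tau - m log(2 tau)``.
    Gaussian: ``-kappa_sq / (2 tau^2) - m log(sqrt(2 pi) tau)``.
    """
    if np.any(np.asarray(x, dtype=float) < 0):
        return -np.inf
    tau = spec.tau
    if spec.potential == ABSOLUTE:
        energy = prior_energy(x, graph, ABSOLUTE)
        return -energy / tau - graph.m * np.log(2.0 * tau)
    energy = prior_energy(x, graph, QUADRATIC)
    return -energy / (2.0 * tau * tau) - graph.m * (_LOG_SQRT_2PI + np.log(tau))


def log_hyperprior_tau(tau: float) -> float:
    """Scale-invariant hyperprior ``pi(tau) ~ 1/tau`` (unnormalized)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return -float(np.log(tau))


def log_mixture_prior(x: np.ndarray, state: MixtureState, graph: NeighborGraph) -> float:
    """Locally adaptive mixture log-prior.

    Each pixel contributes the Laplace local term (scale ``tau_l``) when
    ``theta_j = 1`` and the Gaussian local term (scale ``tau_g``) when
    ``theta_j = 0``, with the same per-pixel pseudo-normalizers as the
    homogeneous priors so that a constant ``theta`` field degenerates to
    the matching homogeneous prior exactly.
    """
    if state.tau_l <= 0 or state.tau_g <= 0:
        raise ValueError("scales must be positive")
    flat = np.asarray(x, dtype=float).ravel()
    if np.any(flat < 0):
        return -np.inf
    phi_abs, phi_sq = local_energies(flat, graph)
    lap = -phi_abs / state.tau_l - np.log(2.0 * state.tau_l)
    gau = -phi_sq / (2.0 * state.tau_g**2) - (_LOG_SQRT_2PI + np.log(state.tau_g))
    return float(np.sum(np.where(state.theta == 1, lap, gau)))


def log_hyperprior_scales(
    tau_l: float, tau_g: float, hyper: HyperpriorSpec = HyperpriorSpec()
) -> float:
    """Gaussian log-hyperpriors on the mixture scales (means 100 and 10, sd 1)."""
    if tau_l <= 0 or tau_g <= 0:
        raise ValueError("scales must be positive")
    sd = hyper.scale_sd
    out = -((tau_l - hyper.tau_l_mean) ** 2) / (2.0 * sd * sd)
    out += -((tau_g - hyper.tau_g_mean) ** 2) / (2.0 * sd * sd)
    return float(out) - 2.0 * (_LOG_SQRT_2PI + np.log(sd))


def log_prior_theta(theta: np.ndarray, rho: float) -> float:
    """i.i.d. Bernoulli(rho) log-probability of the spatial factor."""
    theta = np.asarray(theta).ravel()
    s = float(np.sum(theta))
    m = theta.size
    if rho <= 0.0:
        return 0.0 if s == 0 else -np.inf
    if rho >= 1.0:
        return 0.0 if s == m else -np.inf
    return s * float(np.log(rho)) + (m - s) * float(np.log1p(-rho))


def log_hyperprior_rho(rho: float, alpha: float = 0.5, beta: float = 0.5) -> float:
    """Beta(alpha, beta) log-density of the edge probability rho."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta shape parameters must be positive")
    if not 0.0 < rho < 1.0:
        return -np.inf
    return (
        (alpha - 1.0) * float(np.log(rho))
        + (beta - 1.0) * float(np.log1p(-rho))
        - float(special.betaln(alpha, beta))
    )


def log_posterior_homogeneous(
    x: np.ndarray,
    tau: float,
    potential: str,
    A,
    y: np.ndarray,
    graph: NeighborGraph | None = None,
) -> float:
    """Unnormalized log joint posterior of (x, tau) under a homogeneous prior."""
    x = np.asarray(x, dtype=float)
    if graph is None:
        graph = NeighborGraph(*x.shape)
    spec = PriorSpec(potential=potential, tau=tau)
    lp = log_prior_homogeneous(x, spec, graph)
    if not np.isfinite(lp):
        return -np.inf
    y = np.asarray(y).ravel()
    ll = log_likelihood(x, A, y) if y.size else 0.0
    return ll + lp + log_hyperprior_tau(tau)


def log_posterior_mixture(
    x: np.ndarray,
    state: MixtureState,
    A,
    y: np.ndarray,
    hyper: HyperpriorSpec = HyperpriorSpec(),
    graph: NeighborGraph | None = None,
) -> float:
    """Unnormalized log joint posterior of (x, theta, tau_l, tau_g, rho)."""
    x = np.asarray(x, dtype=float)
    if graph is None:
        graph = NeighborGraph(*x.shape)
    lp = log_mixture_prior(x, state, graph)
    if not np.isfinite(lp):
        return -np.inf
    y = np.asarray(y).ravel()
    ll = log_likelihood(x, A, y) if y.size else 0.0
    return (
        ll
        + lp
        + log_hyperprior_scales(state.tau_l, state.tau_g, hyper)
        + log_prior_theta(state.theta, state.rho)
        + log_hyperprior_rho(state.rho, hyper.alpha, hyper.beta)
    )


def theta_conditional_probs(
    x: np.ndarray, state: MixtureState, graph: NeighborGraph
) -> np.ndarray:
    """Vector of full-conditional probabilities ``P(theta_j = 1 | rest)``.

    ``P = rho L_j / (rho L_j + (1 - rho) G_j)`` with the Laplace and
    Gaussian local terms evaluated in log space, so simultaneous underflow
    cannot occur.  Given x and rho the labels are conditionally
    independent across pixels (the mixture prior factorizes over j).
    """
    phi_abs, phi_sq = local_energies(x, graph)
    log_lap = -phi_abs / state.tau_l - np.log(2.0 * state.tau_l)
    log_gau = -phi_sq / (2.0 * state.tau_g**2) - (_LOG_SQRT_2PI + np.log(state.tau_g))
    if state.rho <= 0.0:
        return np.zeros(graph.m)
    if state.rho >= 1.0:
        return np.ones(graph.m)
    logit = (np.log(state.rho) - np.log1p(-state.rho)) + (log_lap - log_gau)
    return special.expit(logit)


def theta_conditional_prob(
    j: int, x: np.ndarray, state: MixtureState, graph: NeighborGraph
) -> float:
    """Full-conditional probability that pixel ``j`` carries the Laplace label."""
    return float(theta_conditional_probs(x, state, graph)[j])
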