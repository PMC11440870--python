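import numpy as np
import pytest
from scipy import sparse, stats

import oracles
from mixmrf import (
    HyperpriorSpec,
    MCMCConfig,
    MixtureState,
    NeighborGraph,
    PriorSpec,
    adapt_scale,
    log_posterior_homogeneous,
    log_posterior_mixture,
    run_homogeneous,
    run_mixture,
)
from mixmrf.evaluate import mse
from mixmrf.mcmc import (
    ChainResult,
    pixel_sweep,
    sample_rho,
    sample_scales,
    sample_tau,
    sample_theta,
)
from mixmrf.mrf_model import local_energies, prior_energy


class TestAdaptScale:
    def test_target_rate_is_fixed_point(self):
        assert adapt_scale(3.7, 0.234) == pytest.approx(3.7)

    def test_zero_acceptance_halves_scale(self):
        assert adapt_scale(8.0, 0.0) == pytest.approx(4.0)

    def test_full_acceptance_grows_scale(self):
        assert adapt_scale(1.0, 1.0) == pytest.approx(0.5 * (1.0 + 1.0 / 0.234))

    def test_invalid_scale_raises(self):
        with pytest.raises(ValueError):
            adapt_scale(-1.0, 0.2)


def _reference_sweep_homogeneous(x, shape, tau, potential, A, y, sd, z, u):
    """Raster Metropolis sweep recomputing the FULL log posterior per step."""
    x = x.copy()
    for j in range(x.size):
        prop = x[j] + sd * z[j]
        if prop < 0:
            continue
        x_new = x.copy()
        x_new[j] = prop
        dlog = log_posterior_homogeneous(
            x_new.reshape(shape), tau, potential, A, y
        ) - log_posterior_homogeneous(x.reshape(shape), tau, potential, A, y)
        if dlog >= 0 or np.log(u[j]) <= dlog:
            x = x_new
    return x


def _reference_sweep_mixture(x, shape, state, A, y, sd, z, u):
    x = x.copy()
    hyper = HyperpriorSpec()
    for j in range(x.size):
        prop = x[j] + sd * z[j]
        if prop < 0:
            continue
        x_new = x.copy()
        x_new[j] = prop
        dlog = log_posterior_mixture(
            x_new.reshape(shape), state, A, y, hyper
        ) - log_posterior_mixture(x.reshape(shape), state, A, y, hyper)
        if dlog >= 0 or np.log(u[j]) <= dlog:
            x = x_new
    return x


class TestPixelSweep:
    """The kernel's local acceptance ratio must equal the full
    log-posterior difference, checked by replaying identical randoms."""

    @pytest.mark.parametrize("potential", ["absolute", "quadratic"])
    def test_local_ratio_equals_full_difference_homogeneous(self, potential):
        rng = np.random.default_rng(17)
        shape = (3, 4)
        m = 12
        A = sparse.csc_array(rng.uniform(0, 0.5, size=(m, m)) + np.eye(m))
        y = rng.poisson(6.0, size=m)
        tau = 2.5
        graph = NeighborGraph(*shape)
        colsum = np.asarray(A.sum(axis=0)).ravel()
        code = 0 if potential == "absolute" else 1
        for _ in range(5):
            x = rng.uniform(0.5, 8.0, size=m)
            z = rng.standard_normal(m)
            u = rng.random(m)
            expected = _reference_sweep_homogeneous(x, shape, tau, potential, A, y, 1.5, z, u)
            got = x.copy()
            lam = np.asarray(A @ got)
            seeded = _FixedDraws(z, u)
            pixel_sweep(
                got, lam, y.astype(np.int64), A, colsum, graph,
                np.full(m, code, dtype=np.int64), np.full(m, tau), 1.5, seeded,
            )
            assert np.allclose(got, expected, atol=1e-9)
            assert np.allclose(lam, A @ got, atol=1e-9)

    def test_local_ratio_equals_full_difference_mixture(self):
        rng = np.random.default_rng(23)
        shape = (2, 3)
        m = 6
        A = sparse.csc_array(rng.uniform(0, 0.5, size=(m, m)) + np.eye(m))
        y = rng.poisson(5.0, size=m)
        graph = NeighborGraph(*shape)
        colsum = np.asarray(A.sum(axis=0)).ravel()
        state = MixtureState(theta=rng.integers(0, 2, size=m), tau_l=3.0, tau_g=1.2, rho=0.5)
        pcode = np.where(state.theta == 1, 0, 1).astype(np.int64)
        pscale = np.where(state.theta == 1, state.tau_l, state.tau_g)
        for _ in range(5):
            x = rng.uniform(0.5, 8.0, size=m)
            z = rng.standard_normal(m)
            u = rng.random(m)
            expected = _reference_sweep_mixture(x, shape, state, A, y, 1.0, z, u)
            got = x.copy()
            lam = np.asarray(A @ got)
            pixel_sweep(
                got, lam, y.astype(np.int64), A, colsum, graph,
                pcode, pscale, 1.0, _FixedDraws(z, u),
            )
            assert np.allclose(got, expected, atol=1e-9)

    def test_vanishing_proposal_sd_keeps_state(self, rng):
        m = 6
        A = sparse.identity(m, format="csc")
        y = rng.poisson(4.0, size=m).astype(np.int64)
        graph = NeighborGraph(2, 3)
        x = rng.uniform(1, 5, size=m)
        x0 = x.copy()
        lam = np.asarray(A @ x)
        pixel_sweep(
            x, lam, y, A, np.ones(m), graph,
            np.zeros(m, dtype=np.int64), np.full(m, 2.0), 1e-300, rng,
        )
        assert np.allclose(x, x0)


class _FixedDraws:
    """Stub generator feeding predetermined normal/uniform arrays."""

    def __init__(self, z, u):
        self._z = z
        self._u = u

    def standard_normal(self, n):
        return self._z

    def random(self, n):
        return self._u


def _run_2pixel_chain(A, y, tau, potential, sweeps, sd, seed, thin=10):
    """Long fixed-tau chain on a 1x2 model via the block kernel."""
    from mixmrf._kernels import sweep_block

    Asp = sparse.csc_array(A)
    graph = NeighborGraph(1, 2)
    m = 2
    rng = np.random.default_rng(seed)
    x = np.maximum(y.astype(float), 1.0)
    lam = np.asarray(Asp @ x)
    colsum = np.asarray(Asp.sum(axis=0)).ravel()
    code = 0 if potential == "absolute" else 1
    pcode = np.full(m, code, dtype=np.int64)
    pscale = np.full(m, float(tau))
    chunk = 20_000
    out = []
    done = 0
    while done < sweeps:
        k = min(chunk, sweeps - done)
        Z = rng.standard_normal((k, m))
        U = rng.random((k, m))
        rec = np.empty((k // thin, m))
        sweep_block(
            x, lam, y.astype(np.int64), Asp.indptr, Asp.indices, Asp.data, colsum,
            graph.nbr, graph.nnbr, pcode, pscale, sd, Z, U, rec, thin,
        )
        out.append(rec.copy())
        done += k
    return np.concatenate(out, axis=0)


class TestTwoPixelTargets:
    @pytest.mark.parametrize("potential", ["absolute", "quadratic"])
    def test_posterior_mean_matches_quadrature(self, toy2_model, potential):
        A, y = toy2_model
        tau = 3.0
        xs, P = oracles.quad_2pixel(A, y, tau, potential, hi=15.0, n=200)
        (m1, m2), (s1, s2) = oracles.quad_moments_2pixel(xs, P)
        samples = _run_2pixel_chain(A, y, tau, potential, sweeps=200_000, sd=3.0, seed=5)
        burn = 1_000
        kept = samples[burn:]
        se = oracles.batch_se(kept)
        assert abs(kept[:, 0].mean() - m1) < 3 * max(se[0], 1e-3)
        assert abs(kept[:, 1].mean() - m2) < 3 * max(se[1], 1e-3)

    def test_stationary_distribution_chi2(self, toy2_model):
        """Detailed-balance smoke test: binned long-run frequencies match the
        normalized target (chi-square goodness of fit at alpha = 0.01)."""
        A, y = toy2_model
        tau = 3.0
        xs, P = oracles.quad_2pixel(A, y, tau, "absolute", hi=15.0, n=200)
        e1, e2 = oracles.equal_mass_partition(xs, P, nbins=3)
        probs = oracles.cell_probabilities(xs, P, e1, e2)
        samples = _run_2pixel_chain(A, y, tau, "absolute", sweeps=400_000, sd=3.0, seed=8, thin=40)
        kept = samples[200:]
        counts = oracles.bin_samples(kept, e1, e2) * kept.shape[0]
        chi2 = float(np.sum((counts - kept.shape[0] * probs) ** 2 / (kept.shape[0] * probs)))
        crit = stats.chi2.ppf(0.99, df=probs.size - 1)
        assert chi2 < crit

    def test_laplace_pair_distance_matches_quadrature(self):
        """With one anchored pixel and a likelihood-free partner, the pair
        difference follows the truncated Laplace pair prior: its sampled
        mean absolute difference approaches tau, checked by quadrature."""
        tau = 2.0
        # pixel 1 anchored near 20 by data; pixel 2 feels only the prior
        A = np.array([[1.0, 0.0], [0.0, 1e-9]])
        y = np.array([20, 0])
        xs, P = oracles.quad_2pixel(A, y, tau, "absolute", hi=60.0, n=400)
        X1, X2 = np.meshgrid(xs, xs, indexing="ij")
        target = float(np.sum(np.abs(X1 - X2) * P))
        assert target == pytest.approx(tau, rel=0.1)  # far from the zero boundary
        samples = _run_2pixel_chain(A, y, tau, "absolute", sweeps=400_000, sd=4.0, seed=3, thin=20)
        kept = samples[2_000:]
        diff = np.abs(kept[:, 0] - kept[:, 1])
        se = oracles.batch_se(diff)
        assert abs(diff.mean() - target) < max(4 * se, 0.03 * target)


class TestScalarUpdates:
    def test_tau_chain_matches_quadrature_posterior(self, rng):
        x = rng.uniform(0, 30, size=(5, 5))
        graph = NeighborGraph(5, 5)
        energy = prior_energy(x, graph, "absolute")
        grid = np.linspace(0.05, 60.0, 4_000)
        pdf = oracles.quad_tau_posterior(energy, 25, "absolute", grid)
        target_mean = float(np.trapezoid(grid * pdf, grid))
        tau, draws = 5.0, []
        for _ in range(60_000):
            tau, _ = sample_tau(energy, 25, tau, 1.5, "absolute", rng)
            draws.append(tau)
        draws = np.asarray(draws[2_000:])
        se = oracles.batch_se(draws)
        assert abs(draws.mean() - target_mean) < max(4 * se, 0.02 * target_mean)

    def test_tau_identity_proposal_always_accepts(self, rng):
        # acceptance ratio at tau' = tau is exactly 1; with sd -> 0 all
        # positive proposals are accepted
        tau = 7.0
        for _ in range(200):
            tau, accepted = sample_tau(100.0, 10, tau, 1e-12, "absolute", rng)
            assert accepted
        assert tau == pytest.approx(7.0, abs=1e-9)

    def test_scales_with_all_laplace_labels(self, rng):
        """With every pixel Laplace-labelled, tau_g sees no data and samples
        its own hyperprior (mean 10, sd 1)."""
        x = rng.uniform(0, 20, size=(4, 4))
        graph = NeighborGraph(4, 4)
        phi_abs, phi_sq = local_energies(x, graph)
        theta = np.ones(16, dtype=np.int64)
        tau_l, tau_g = 100.0, 10.0
        tg_draws = []
        for _ in range(30_000):
            tau_l, tau_g, _, _ = sample_scales(
                phi_abs, phi_sq, theta, tau_l, tau_g, (1.0, 1.0), rng
            )
            tg_draws.append(tau_g)
        tg = np.asarray(tg_draws[1_000:])
        assert abs(tg.mean() - 10.0) < 0.1
        assert abs(tg.std() - 1.0) < 0.1

    def test_scale_updates_are_order_independent(self, rng):
        """tau_l and tau_g touch disjoint pixel subsets: swapping the update
        order (by relabelling) leaves each marginal target unchanged."""
        x = rng.uniform(0, 20, size=(3, 4))
        graph = NeighborGraph(3, 4)
        phi_abs, phi_sq = local_energies(x, graph)
        theta = rng.integers(0, 2, size=12)
        r1 = np.random.default_rng(99)
        r2 = np.random.default_rng(99)
        # same generator, same draws: the tau_l result cannot depend on tau_g
        a = sample_scales(phi_abs, phi_sq, theta, 100.0, 10.0, (1.0, 0.5), r1)
        b = sample_scales(phi_abs, phi_sq, theta, 100.0, 5.0, (1.0, 0.5), r2)
        assert a[0] == b[0]

    def test_theta_all_one_after_sweep_at_rho_one(self, rng):
        x = np.array([[1.0, 5.0, 2.0]])
        graph = NeighborGraph(1, 3)
        state = MixtureState(theta=np.zeros(3), tau_l=3.0, tau_g=1.0, rho=1.0)
        theta, _ = sample_theta(x, state, graph, rng, mode="gibbs")
        assert np.all(theta == 1)

    def test_theta_gibbs_and_metropolis_agree(self, rng):
        from mixmrf.mrf_model import theta_conditional_probs

        x = np.array([[1.0, 4.0, 2.0]])
        graph = NeighborGraph(1, 3)
        state = MixtureState(theta=np.array([0, 1, 0]), tau_l=3.0, tau_g=1.0, rho=0.5)
        expected = theta_conditional_probs(x, state, graph)
        freq = {}
        for mode in ("gibbs", "metropolis"):
            st_run = MixtureState(theta=np.array([0, 1, 0]), tau_l=3.0, tau_g=1.0, rho=0.5)
            acc = np.zeros(3)
            n = 40_000
            for _ in range(n):
                st_run.theta, _ = sample_theta(x, st_run, graph, rng, mode=mode)
                acc += st_run.theta
            freq[mode] = acc / n
        for mode in freq:
            assert np.allclose(freq[mode], expected, atol=0.02)

    def test_rho_conjugate_posterior(self, rng):
        draws = np.array([sample_rho(np.ones(4), 0.5, 0.5, rng)[0] for _ in range(40_000)])
        # Beta(4.5, 0.5): mean 0.9
        assert draws.mean() == pytest.approx(0.9, abs=0.005)
        assert draws.var() == pytest.approx(4.5 * 0.5 / (5.0**2 * 6.0), rel=0.1)

    def test_rho_label_swap_symmetry(self, rng):
        a = np.array([sample_rho(np.zeros(4), 0.5, 0.5, rng)[0] for _ in range(20_000)])
        b = np.array([sample_rho(np.ones(4), 0.5, 0.5, rng)[0] for _ in range(20_000)])
        assert a.mean() == pytest.approx(1.0 - b.mean(), abs=0.01)

    def test_rho_metropolis_matches_gibbs(self, rng):
        theta = np.array([1, 1, 0, 1, 0])
        gibbs = np.array([sample_rho(theta, 0.5, 0.5, rng)[0] for _ in range(30_000)])
        rho, draws = 0.5, []
        for _ in range(60_000):
            rho, _ = sample_rho(theta, 0.5, 0.5, rng, mode="metropolis", rho=rho, prop_sd=0.2)
            draws.append(rho)
        met = np.asarray(draws[2_000:])
        assert abs(met.mean() - gibbs.mean()) < 0.01


class TestRunHomogeneous:
    def test_fixed_seed_is_bit_identical(self, sim1):
        _, y, A = sim1
        cfg = MCMCConfig(iterations=60, burn_in=20, seed=4)
        a = run_homogeneous(y, A, PriorSpec("absolute", 100.0), cfg)
        b = run_homogeneous(y, A, PriorSpec("absolute", 100.0), cfg)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.tau, b.tau)
        assert np.array_equal(a.accept_pixel, b.accept_pixel)

    def test_two_pixel_estimated_tau_runs(self, toy2_model):
        A, y = toy2_model
        cfg = MCMCConfig(iterations=2_000, burn_in=200, seed=1, pixel_sd=2.0, tau_sd=1.0)
        chain = run_homogeneous(
            y.reshape(1, 2), sparse.csc_array(A), PriorSpec("absolute", 2.0), cfg
        )
        assert chain.tau.shape == (2_000,)
        assert np.all(chain.tau > 0)
        assert 0.0 <= chain.accept_pixel.min() <= chain.accept_pixel.max() <= 1.0

    def test_adaptation_frozen_after_burn_in(self, sim1):
        _, y, A = sim1
        cfg = MCMCConfig(iterations=200, burn_in=100, seed=2)
        chain = run_homogeneous(y, A, PriorSpec("absolute", 100.0), cfg)
        post = chain.scale_trace["pixel"][100:]
        assert np.all(post == post[0])
        pre = chain.scale_trace["pixel"][:100]
        assert np.unique(pre).size > 1  # adaptation did act during burn-in

    def test_unobservable_row_with_counts_raises(self):
        A = sparse.csc_array(np.array([[1.0, 1.0], [0.0, 0.0]]))
        y = np.array([[0, 5]])
        with pytest.raises(ValueError, match="non-finite log-posterior"):
            run_homogeneous(y, A, PriorSpec("absolute", 10.0), MCMCConfig(iterations=10, burn_in=0))

    def test_random_order_sweep_targets_same_posterior(self, toy2_model):
        A, y = toy2_model
        base = MCMCConfig(iterations=4_000, burn_in=500, seed=6, pixel_sd=2.0)
        ras = run_homogeneous(y.reshape(1, 2), sparse.csc_array(A), PriorSpec("absolute", 3.0), base, estimate_tau=False)
        rnd = MCMCConfig(iterations=4_000, burn_in=500, seed=6, pixel_sd=2.0, pixel_order="random")
        per = run_homogeneous(y.reshape(1, 2), sparse.csc_array(A), PriorSpec("absolute", 3.0), rnd, estimate_tau=False)
        assert np.allclose(
            ras.posterior_x().mean(axis=0), per.posterior_x().mean(axis=0), atol=0.3
        )

    def test_mse_decreases_with_iterations(self, sim1):
        """Posterior-mean error shrinks as the chain grows (5 seeds)."""
        truth, y, A = sim1
        short, long_ = [], []
        for seed in range(5):
            for iters, out in ((200, short), (2_000, long_)):
                cfg = MCMCConfig(iterations=iters, burn_in=100, seed=seed)
                chain = run_homogeneous(y, A, PriorSpec("absolute", 150.0), cfg, estimate_tau=False)
                out.append(mse(chain.posterior_mean_image(), truth))
        assert np.mean(long_) < np.mean(short)


class TestRunMixture:
    def test_fixed_seed_is_bit_identical(self, sim1):
        _, y, A = sim1
        cfg = MCMCConfig(iterations=40, burn_in=10, seed=5)
        a = run_mixture(y, A, HyperpriorSpec(), cfg)
        b = run_mixture(y, A, HyperpriorSpec(), cfg)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.rho, b.rho)

    def test_forced_laplace_labels_collapse_to_homogeneous(self, toy2_model):
        """theta pinned at one with fixed scales reproduces the homogeneous
        Laplace posterior within Monte-Carlo error."""
        A, y = toy2_model
        Asp = sparse.csc_array(A)
        tau = 3.0
        init = MixtureState(theta=np.ones(2), tau_l=tau, tau_g=1.0, rho=0.5)
        cfg = MCMCConfig(iterations=30_000, burn_in=2_000, seed=9, pixel_sd=2.0)
        mix = run_mixture(
            y.reshape(1, 2), Asp, HyperpriorSpec(), cfg, init=init,
            estimate_scales=False, estimate_rho=False, estimate_theta=False,
        )
        xs, P = oracles.quad_2pixel(A, y, tau, "absolute", hi=15.0, n=200)
        (m1, m2), _ = oracles.quad_moments_2pixel(xs, P)
        got = mix.posterior_x().mean(axis=0)
        se = oracles.batch_se(mix.posterior_x())
        assert abs(got[0] - m1) < 4 * max(se[0], 1e-3)
        assert abs(got[1] - m2) < 4 * max(se[1], 1e-3)

    def test_mixture_posterior_matches_enumeration_quadrature_1x3(self):
        """Pixel means and label frequencies on a 1x3 toy agree with the
        enumeration (8 label configs) + 3-D quadrature oracle."""
        A = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        y = np.array([5, 9, 3])
        tau_l, tau_g, rho = 2.0, 1.0, 0.4
        mean, sd, tprob = oracles.enum_quad_mixture_1x3(A, y, tau_l, tau_g, rho, hi=18.0, n=60)
        init = MixtureState(theta=np.array([1, 0, 1]), tau_l=tau_l, tau_g=tau_g, rho=rho)
        cfg = MCMCConfig(iterations=40_000, burn_in=2_000, seed=12, pixel_sd=2.0)
        chain = run_mixture(
            y.reshape(1, 3), sparse.csc_array(A), HyperpriorSpec(), cfg, init=init,
            estimate_scales=False, estimate_rho=False,
        )
        got = chain.posterior_x().mean(axis=0)
        se = oracles.batch_se(chain.posterior_x())
        for j in range(3):
            assert abs(got[j] - mean[j]) < max(4 * se[j], 0.02 * mean[j])
        freq = chain.theta_frequency().ravel()
        tse = oracles.batch_se(chain.theta[chain.kept].astype(float))
        for j in range(3):
            assert abs(freq[j] - tprob[j]) < max(5 * tse[j], 0.03)

    def test_chain_archive_round_trip(self, sim1, tmp_path):
        _, y, A = sim1
        cfg = MCMCConfig(iterations=30, burn_in=10, seed=3)
        chain = run_mixture(y, A, HyperpriorSpec(), cfg)
        chain.save(tmp_path / "archive")
        loaded = ChainResult.load(tmp_path / "archive")
        assert loaded.model == "mixture"
        assert np.array_equal(loaded.x, chain.x)
        assert np.array_equal(loaded.theta, chain.theta)
        assert loaded.config["seed"] == 3
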