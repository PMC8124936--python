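"""The Poisson-lognormal spatial model: kernels, summaries, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma, polygamma
from scipy.stats import poisson

from greenrisk.bym import (
    ChainState, ModelData, ModelSpec, diagnostics, dic, icar_full_conditional,
    log_likelihood, psi, relative_risk, run_chains, summarize,
    update_fixed_effects, update_precisions, update_random_effects,
    PosteriorSamples,
)
from greenrisk.simulate import make_lattice
from greenrisk.spatial import build_adjacency

from conftest import tiny_lattice


def small_data(rng, rows=4, cols=5, p=2):
    units = build_adjacency(tiny_lattice(rows, cols), "queen")
    n = rows * cols
    e = rng.uniform(50, 200, size=n)
    x = rng.normal(size=(n, p))
    o = rng.poisson(e).astype(float)
    return ModelData(o, e, x, units.binary_weights(),
                     unit_ids=units.unit_ids), units


def zero_state(data):
    return ChainState(beta=np.zeros(data.p + 1), u=np.zeros(data.n),
                      s=np.zeros(data.n), tau_u=1.0, tau_s=1.0)


class TestLogLikelihood:
    def test_scalar_poisson_oracle(self):
        units = build_adjacency(tiny_lattice(1, 3), "rook")
        o = np.array([3.0, 0.0, 7.0])
        e = np.array([2.5, 1.0, 6.0])
        data = ModelData(o, e, np.zeros((3, 1)), units.binary_weights())
        state = zero_state(data)
        # with all parameters zero, lambda = E
        oracle = sum(poisson.logpmf(int(oi), ei) for oi, ei in zip(o, e))
        assert log_likelihood(state, data) == pytest.approx(oracle, rel=1e-12)

    def test_all_zero_counts(self):
        units = build_adjacency(tiny_lattice(1, 3), "rook")
        e = np.array([1.5, 2.0, 3.0])
        data = ModelData(np.zeros(3), e, np.zeros((3, 1)),
                         units.binary_weights())
        assert log_likelihood(zero_state(data), data) == \
            pytest.approx(-e.sum(), rel=1e-12)

    def test_offset_identity(self, rng):
        data, units = small_data(rng)
        state = zero_state(data)
        ll = log_likelihood(state, data)
        data2 = ModelData(data.O, 2.0 * data.E, data.X,
                          units.binary_weights())
        state2 = zero_state(data2)
        state2.beta[0] = -np.log(2.0)
        assert log_likelihood(state2, data2) == pytest.approx(ll, rel=1e-12)

    def test_nonfinite_state_rejected(self, rng):
        data, _ = small_data(rng)
        state = zero_state(data)
        state.beta[0] = 1e6  # overflow guard
        assert log_likelihood(state, data) == -np.inf


class TestIcarConditional:
    def test_two_neighbor_average(self):
        units = build_adjacency(tiny_lattice(1, 3), "rook")
        w = units.binary_weights()
        s = np.array([2.0, 0.0, 4.0])
        mean, prec = icar_full_conditional(s, 1, 1.0, w)
        assert mean == pytest.approx(3.0)
        assert prec == pytest.approx(2.0)

    def test_equal_neighbors(self, lattice5_queen):
        w = lattice5_queen.binary_weights()
        s = np.full(25, 1.7)
        mean, _ = icar_full_conditional(s, 12, 2.0, w)
        assert mean == pytest.approx(1.7)

    def test_matches_joint_kernel_derivative(self, lattice5_rook, rng):
        """Parabola fit of the joint log-kernel in s_i reproduces the
        conditional mean and precision (numeric oracle)."""
        w = lattice5_rook.binary_weights()
        dense = w.w.toarray()
        tau = 1.7
        s = rng.normal(size=25)

        def log_kernel(svec):
            diff = svec[:, None] - svec[None, :]
            return -tau / 4.0 * float((dense * diff ** 2).sum())  # /4: pairs twice

        for i in (0, 7, 12):
            mean, prec = icar_full_conditional(s, i, tau, w)
            t0 = s[i]
            f = []
            for t in (t0 - 0.5, t0, t0 + 0.5):
                sv = s.copy()
                sv[i] = t
                f.append(log_kernel(sv))
            curv = (f[0] - 2 * f[1] + f[2]) / 0.25        # f''
            slope = (f[2] - f[0]) / 1.0                    # f'
            assert -curv == pytest.approx(prec, rel=1e-9)
            assert t0 - slope / curv == pytest.approx(mean, rel=1e-9)

    def test_island_rejected(self):
        import scipy.sparse as sp

        from greenrisk.spatial import WeightMatrix

        w = WeightMatrix(sp.csr_matrix((3, 3)), "binary", list("abc"))
        with pytest.raises(ValueError, match="island"):
            icar_full_conditional(np.zeros(3), 0, 1.0, w)


class TestUpdates:
    def test_zero_step_keeps_chain_constant(self, rng):
        data, _ = small_data(rng)
        spec = ModelSpec(n_covariates=data.p)
        state = zero_state(data)
        before = state.beta.copy()
        update_fixed_effects(state, data, spec, rng, steps=0.0)
        np.testing.assert_array_equal(state.beta, before)

    def test_flat_intercept_posterior_matches_closed_form(self, rng):
        """With X = 0 and u = s = 0, the b0 posterior is exp-Gamma:
        E[b0] = digamma(sum O) - log(sum E)."""
        units = build_adjacency(tiny_lattice(2, 3), "queen")
        e = np.array([10.0, 20.0, 15.0, 5.0, 30.0, 20.0])
        o = np.array([12.0, 18.0, 17.0, 4.0, 29.0, 25.0])
        data = ModelData(o, e, np.zeros((6, 1)), units.binary_weights())
        spec = ModelSpec(n_covariates=1)
        state = zero_state(data)
        draws = []
        for it in range(6000):
            update_fixed_effects(state, data, spec, rng, steps=0.15)
            if it >= 1000:
                draws.append(state.beta[0])
        draws = np.asarray(draws)
        s_tot, e_tot = o.sum(), e.sum()
        expect = digamma(s_tot) - np.log(e_tot)
        sd = np.sqrt(polygamma(1, s_tot))
        assert draws.mean() == pytest.approx(expect, abs=4 * sd / 10)
        assert draws.std() == pytest.approx(sd, rel=0.2)

    def test_recentring_enforced(self, rng):
        data, _ = small_data(rng)
        spec = ModelSpec(n_covariates=data.p)
        state = zero_state(data)
        state.s = rng.normal(size=data.n)
        state.s -= state.s.mean()
        for _ in range(10):
            update_random_effects(state, data, spec, rng)
            assert abs(state.s.sum()) < 1e-12 * data.n

    def test_dominant_prior_pins_u_at_zero(self, rng):
        data, _ = small_data(rng)
        spec = ModelSpec(n_covariates=data.p)
        state = zero_state(data)
        state.tau_u = 1e12
        for _ in range(50):
            update_random_effects(state, data, spec, rng)
        assert np.max(np.abs(state.u)) < 1e-3

    def test_gibbs_tau_u_closed_form_mean(self, rng):
        """Empirical mean of tau_u draws matches (a + n/2)/(b + sum(u^2)/2)."""
        data, _ = small_data(rng)
        spec = ModelSpec(n_covariates=data.p)
        state = zero_state(data)
        state.u = rng.normal(scale=0.3, size=data.n)
        ssq = 0.5 * float(state.u @ state.u)
        a, b = spec.tau_prior_a, spec.tau_prior_b
        target = (a + data.n / 2) / (b + ssq)
        draws = np.empty(20_000)
        for k in range(draws.size):
            tu_before = state.u.copy()
            update_precisions(state, data, spec, rng)
            draws[k] = state.tau_u
            np.testing.assert_array_equal(state.u, tu_before)
        assert draws.mean() == pytest.approx(target, rel=0.03)


class TestRunChains:
    def test_seed_determinism(self, rng):
        data, _ = small_data(rng)
        spec = ModelSpec(n_covariates=data.p, iterations=300, burn_in=100,
                         seed=42)
        a = run_chains(spec, data)
        b = run_chains(spec, data)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.tau_s, b.tau_s)

    def test_sum_to_zero_every_draw(self, rng):
        data, _ = small_data(rng)
        spec = ModelSpec(n_covariates=data.p, iterations=300, burn_in=100,
                         seed=7)
        samples = run_chains(spec, data)
        np.testing.assert_allclose(samples.s.sum(axis=2), 0.0, atol=1e-10)

    def test_draw_count_contract(self, rng):
        data, _ = small_data(rng)
        spec = ModelSpec(n_covariates=data.p, iterations=500, burn_in=200,
                         thinning=3, seed=1)
        samples = run_chains(spec, data)
        assert samples.beta.shape == (2, 100, data.p + 1)

    def test_offset_identity_posteriors_match(self, rng):
        """E -> cE with b0 init shifted by -log c leaves b1..bp draws
        identical to floating-point roundoff under matched seeds."""
        data, units = small_data(rng)
        c = 2.0
        data2 = ModelData(data.O, c * data.E, data.X, units.binary_weights())
        spec1 = ModelSpec(n_covariates=data.p, iterations=800, burn_in=300,
                          seed=99)
        spec2 = ModelSpec(n_covariates=data.p, iterations=800, burn_in=300,
                          seed=99, init_beta0=-np.log(c))
        s1 = run_chains(spec1, data)
        s2 = run_chains(spec2, data2)
        np.testing.assert_allclose(s2.beta[:, :, 1:], s1.beta[:, :, 1:],
                                   atol=1e-7)
        np.testing.assert_allclose(s2.beta[:, :, 0] - s1.beta[:, :, 0],
                                   -np.log(c), atol=1e-7)


def toy_samples(beta, u, s, tau=1.0, deviance=None, spec=None):
    """Assemble a PosteriorSamples object from explicit per-chain draws."""
    beta = np.asarray(beta, float)
    u = np.asarray(u, float)
    s = np.asarray(s, float)
    chains, draws = beta.shape[:2]
    dev = np.zeros((chains, draws)) if deviance is None else deviance
    return PosteriorSamples(
        beta=beta, u=u, s=s,
        tau_u=np.full((chains, draws), tau),
        tau_s=np.full((chains, draws), tau),
        deviance=dev,
        spec=spec or ModelSpec(iterations=draws + 1, burn_in=0),
    )


class TestPsi:
    def test_u_zero_gives_one(self, rng):
        s = rng.normal(size=(2, 10, 6))
        out = psi(toy_samples(np.zeros((2, 10, 2)), np.zeros((2, 10, 6)), s))
        assert out["mean"] == pytest.approx(1.0)

    def test_equal_sds_give_half(self, rng):
        f = rng.normal(size=(2, 10, 6))
        out = psi(toy_samples(np.zeros((2, 10, 2)), f, -f))
        assert out["mean"] == pytest.approx(0.5)

    def test_matches_hand_computation(self, rng):
        u = rng.normal(size=(2, 5, 8))
        s = rng.normal(size=(2, 5, 8))
        out = psi(toy_samples(np.zeros((2, 5, 2)), u, s))
        up, sp_ = u.reshape(-1, 8), s.reshape(-1, 8)
        hand = np.array([sp_[k].std(ddof=1)
                         / (sp_[k].std(ddof=1) + up[k].std(ddof=1))
                         for k in range(10)])
        assert out["mean"] == pytest.approx(hand.mean(), rel=1e-12)


class TestDic:
    def test_degenerate_samples_zero_pd(self, rng):
        data, _ = small_data(rng)
        beta = np.tile(np.array([0.05] + [0.0] * data.p), (2, 20, 1))
        u = np.zeros((2, 20, data.n))
        s = np.zeros((2, 20, data.n))
        from greenrisk.bym import _deviance_at

        d0 = _deviance_at(beta[0, 0], u[0, 0], s[0, 0], data)
        out = dic(toy_samples(beta, u, s, deviance=np.full((2, 20), d0)), data)
        assert out["pD"] == pytest.approx(0.0, abs=1e-9)
        assert out["DIC"] == pytest.approx(out["Dbar"])


class TestRelativeRisk:
    def test_all_zero_parameters(self, rng):
        data, _ = small_data(rng)
        sm = toy_samples(np.zeros((2, 5, data.p + 1)),
                         np.zeros((2, 5, data.n)), np.zeros((2, 5, data.n)))
        rr = relative_risk(sm, data)
        np.testing.assert_allclose(rr["rr_mean"], 1.0)

    def test_single_term_doubling(self, rng):
        data, _ = small_data(rng)
        data.X[:, 0] = 1.0
        beta = np.zeros((2, 5, data.p + 1))
        beta[:, :, 1] = np.log(2.0)
        sm = toy_samples(beta, np.zeros((2, 5, data.n)),
                         np.zeros((2, 5, data.n)))
        np.testing.assert_allclose(relative_risk(sm, data)["rr_mean"], 2.0)

    def test_matches_per_draw_product(self, rng):
        data, _ = small_data(rng)
        beta = rng.normal(scale=0.1, size=(2, 4, data.p + 1))
        u = rng.normal(scale=0.1, size=(2, 4, data.n))
        s = rng.normal(scale=0.1, size=(2, 4, data.n))
        rr = relative_risk(toy_samples(beta, u, s), data)
        # scalar oracle on unit 3
        i = 3
        draws = []
        for c in range(2):
            for k in range(4):
                draws.append(np.exp(beta[c, k, 0]
                                    + data.X[i] @ beta[c, k, 1:]
                                    + u[c, k, i] + s[c, k, i]))
        assert rr["rr_mean"][i] == pytest.approx(np.mean(draws), rel=1e-12)


class TestDiagnostics:
    def test_identical_chains_rhat_one(self, rng):
        x = rng.normal(size=5000)
        sm = toy_samples(np.stack([x, x])[:, :, None],
                         np.zeros((2, 5000, 3)), np.zeros((2, 5000, 3)))
        d = diagnostics(sm)
        assert d.loc["beta0", "rhat"] <= 1.001

    def test_disjoint_means_large_rhat(self, rng):
        a = rng.normal(size=2000)
        sm = toy_samples(np.stack([a, a + 50.0])[:, :, None],
                         np.zeros((2, 2000, 3)), np.zeros((2, 2000, 3)))
        assert diagnostics(sm).loc["beta0", "rhat"] > 1.5

    def test_iid_mc_error_matches_theory(self, rng):
        """For iid chains, batch-means MCSE ~= SD/sqrt(N) within 20%."""
        n = 10_000
        x = rng.normal(size=(2, n, 1))
        sm = toy_samples(x, np.zeros((2, n, 3)), np.zeros((2, n, 3)))
        d = diagnostics(sm)
        sd = x.reshape(-1).std(ddof=1)
        theory = sd / np.sqrt(2 * n)
        assert d.loc["beta0", "mc_error"] == pytest.approx(theory, rel=0.2)


class TestSummarize:
    def test_significance_flags(self, rng):
        data, _ = small_data(rng)
        ndraw = 4000
        beta = np.zeros((2, ndraw, data.p + 1))
        beta[:, :, 1] = rng.normal(-4.0, 2.0, size=(2, ndraw))   # clearly < 0
        beta[:, :, 2] = rng.normal(0.0, 1.0, size=(2, ndraw))    # straddles 0
        u = rng.normal(scale=0.1, size=(2, ndraw, data.n))
        s = rng.normal(scale=0.3, size=(2, ndraw, data.n))
        fit = summarize(toy_samples(beta, u, s), data)
        assert fit.table.loc["beta1", "significant"]
        assert not fit.table.loc["beta2", "significant"]
        assert 0.6 < fit.psi_mean < 0.9
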