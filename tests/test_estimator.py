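"""Gibbs sampler: convergence diagnostics, state draws, conjugate updates.

The deeper checks validate sampler components against independent oracles:
exhaustive path enumeration for the discrete state full conditional, a
numerical grid posterior for the loading update, and a separately written
loop-based Gibbs sampler for the switching-free reduced model.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from ndlcsem.gibbs import (MCMCConfig, _ChainState, _draw_state_paths,
                           conditional_state_draw, fit, rhat)
from ndlcsem.model import log_prior_density
from ndlcsem.params import ModelDims, ObservedPanel, PriorSpec
from ndlcsem.simulate import (dropout_times_from_mask,
                              inject_dropout_observations, simulate_panel)

from conftest import make_params


class TestRhat:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="two chains"):
            rhat(np.zeros((1, 100)))

    def test_identical_constant_chains_are_nan(self):
        assert math.isnan(rhat(np.ones((2, 100))))

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 2000))
        assert abs(rhat(chains) - 1.0) < 0.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert rhat(chains) > 1.5

    def test_matches_explicit_split_computation(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(0, 1, (2, 500)) + np.array([[0.0], [0.3]])
        halves = []
        for c in chains:
            halves.append(c[:250])
            halves.append(c[250:])
        halves = np.array(halves)
        n = 250
        W = np.mean([h.var(ddof=1) for h in halves])
        B = n * np.var([h.mean() for h in halves], ddof=1)
        expected = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert rhat(chains) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_arviz_on_gaussian_chains(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 1500)) + rng.normal(
            0, 0.05, size=(4, 1))
        ours = rhat(chains)
        theirs = float(np.asarray(
            arviz.rhat(arviz.convert_to_dataset(chains))["x"]))
        assert abs(ours - theirs) < 0.05


def enumerate_state_marginals(params, eta1_i, eta2_i, zeta2_i):
    """Exact P(S_t = 2 | everything else) by enumerating all paths."""
    d, g = params.dynamics, params.switching
    J, T = eta1_i.shape
    probs = {}
    total = 0.0
    for path in itertools.product((1, 2), repeat=T - 1):
        full = (1,) + path
        logw = 0.0
        for t in range(1, T):
            nu = (g.gamma1 + g.gamma2 * eta2_i
                  + eta1_i[:, t - 1] @ g.gamma3
                  + (eta1_i[:, t - 1] @ g.gamma4) * eta2_i)
            p11 = 1.0 / (1.0 + math.exp(-nu))
            if full[t - 1] == 1:
                logw += math.log(p11 if full[t] == 1 else 1 - p11)
            else:
                logw += math.log(g.p12 if full[t] == 1 else 1 - g.p12)
            s = full[t]
            mean = (d.alpha21_state(s) + d.beta2_state(s) * eta2_i + zeta2_i
                    + (d.b1_state(s) + d.omega2_state(s) * eta2_i)
                    * eta1_i[:, t - 1])
            logw += float(np.sum(stats.norm.logpdf(
                eta1_i[:, t], mean, np.sqrt(d.sigma2_zeta1))))
        w = math.exp(logw)
        probs[full] = w
        total += w
    marg2 = np.zeros(T)
    for path, w in probs.items():
        for t in range(T):
            if path[t] == 2:
                marg2[t] += w / total
    return marg2


class TestConditionalStateDraw:
    def _context(self, seed=0):
        dims = ModelDims(n_persons=3, n_occasions=5, horizon=0, n_factors=2,
                         items_per_factor=1, n_items_between=2)
        params = make_params(dims)
        rng = np.random.default_rng(seed)
        eta1 = rng.standard_normal((3, 2, 5))
        eta2 = rng.standard_normal(3)
        zeta2 = 0.2 * rng.standard_normal((3, 2))
        return dims, params, eta1, eta2, zeta2

    def test_matches_enumeration_oracle(self):
        dims, params, eta1, eta2, zeta2 = self._context()
        # push person 0's late factor scores toward the state-2 level
        eta1[0, :, 3:] += 1.5
        exact = enumerate_state_marginals(params, eta1[0], eta2[0], zeta2[0])
        rng = np.random.default_rng(7)
        n = 4000
        freq = np.zeros(5)
        for _ in range(n):
            path = conditional_state_draw(0, params, eta1, eta2, zeta2,
                                          None, rng)
            freq += (path == 2)
        freq /= n
        assert np.all(np.abs(freq - exact) < 4 * np.sqrt(0.25 / n) + 0.01)

    def test_elevated_scores_favor_state_two(self):
        dims, params, eta1, eta2, zeta2 = self._context(1)
        eta1[1, :, :] = 0.0
        eta1[1, :, 2:] = params.dynamics.alpha21_state(2)[:, None] / (
            1 - params.dynamics.b1_state(2)[:, None])
        exact = enumerate_state_marginals(params, eta1[1], eta2[1] * 0,
                                          zeta2[1] * 0)
        assert exact[3] > 0.5

    def test_flat_likelihood_reduces_to_markov_prior(self):
        dims, params, eta1, eta2, zeta2 = self._context(2)
        d, g = params.dynamics, params.switching
        d.delta_alpha21[:] = 0.0
        d.delta_beta2[:] = 0.0
        d.delta_b1[:] = 0.0
        d.delta_omega2[:] = 0.0
        g.gamma1 = g.gamma2 = 0.0
        g.gamma3[:] = 0.0
        g.gamma4[:] = 0.0
        g.p12 = 0.5          # diagnostic value: likelihood-free check
        exact = enumerate_state_marginals(params, eta1[2], eta2[2], zeta2[2])
        # flat everything: the chain is symmetric, P(S_t = 2) = 0.5 for t >= 1
        assert np.allclose(exact[1:], 0.5, atol=1e-12)
        rng = np.random.default_rng(8)
        freq = np.mean([(conditional_state_draw(2, params, eta1, eta2, zeta2,
                                                None, rng) == 2)[1:]
                        for _ in range(2000)], axis=0)
        assert np.all(np.abs(freq - 0.5) < 0.05)

    def test_masked_occasions_forced_to_state_two(self):
        dims, params, eta1, eta2, zeta2 = self._context(3)
        s_obs = np.zeros((3, 5), dtype=bool)
        s_obs[0, 3:] = True
        rng = np.random.default_rng(9)
        for _ in range(50):
            path = conditional_state_draw(0, params, eta1, eta2, zeta2,
                                          s_obs, rng)
            assert np.all(path[3:] == 2)
            assert path[0] == 1


@pytest.fixture(scope="module")
def fitted_small():
    dims = ModelDims(n_persons=12, n_occasions=12, horizon=3)
    params = make_params(dims)
    panel, latent = simulate_panel(params, dims, missing_rate=0.1, seed=5)
    latent = inject_dropout_observations(latent, dims.n_occasions, 1.0, seed=6)
    panel.dropout_time = dropout_times_from_mask(latent)
    cfg = MCMCConfig(n_chains=2, n_iter=200, n_burnin=100, seed=3,
                     n_store_latent=20)
    draws = fit(panel, dims, config=cfg)
    return dims, panel, draws


class TestFit:
    def test_support_constraints_hold_in_every_draw(self, fitted_small):
        dims, _, draws = fitted_small
        for name in draws.names:
            vals = draws.param_trace(name)
            if name.startswith(("delta_alpha21",)):
                assert np.all(vals >= 0), name
            if name.startswith(("sigma2",)):
                assert np.all(vals > 0), name
            if name.startswith(("lambda",)):
                assert np.all(vals > 0), name
            if name == "p12":
                assert np.all((vals >= 0) & (vals <= 0.1))

    def test_observed_dropout_tails_stay_state_two(self, fitted_small):
        dims, panel, draws = fitted_small
        mask = panel.observed_state_mask()[:, :dims.n_occasions]
        assert mask.any()
        for k in range(draws.S.shape[0]):
            assert np.all(draws.S[k][mask] == 2)

    def test_every_stored_draw_inside_prior_support(self, fitted_small):
        dims, _, draws = fitted_small
        for p in draws.params:
            assert np.isfinite(log_prior_density(p, PriorSpec(), dims))

    def test_state_paths_start_in_state_one(self, fitted_small):
        _, _, draws = fitted_small
        assert np.all(draws.S[:, :, 0] == 1)

    def test_mismatched_items_rejected(self, fitted_small):
        dims, panel, _ = fitted_small
        bad = ModelDims(n_persons=12, n_occasions=12, n_factors=4,
                        items_per_factor=3)
        with pytest.raises(ValueError, match="factor structure"):
            fit(panel, bad, config=MCMCConfig(n_iter=2, n_burnin=1))


class TestLoadingUpdateAgainstGridPosterior:
    """Total-variation check of the conjugate loading update on a toy model.

    One person, three occasions, one factor with two items; everything is
    held fixed except the free loading and the factor scores.  The exact
    marginal posterior of the loading integrates the factor scores out
    analytically (joint normality) and is computed on a fine grid.
    """

    def test_tv_distance_below_five_percent(self):
        dims = ModelDims(n_persons=1, n_occasions=3, horizon=0, n_factors=1,
                         items_per_factor=2, n_items_between=2)
        b, s_zeta, v0 = 0.5, 0.3, 2.0
        s_eps = np.array([0.25, 0.25])
        lam_true = 1.2
        rng = np.random.default_rng(11)
        eta = np.zeros(3)
        eta[0] = rng.normal(0, math.sqrt(v0))
        for t in (1, 2):
            eta[t] = b * eta[t - 1] + rng.normal(0, math.sqrt(s_zeta))
        y = np.stack([eta + rng.normal(0, 0.5, 3),
                      lam_true * eta + rng.normal(0, 0.5, 3)])  # (2, 3)

        panel = ObservedPanel(y1=y[None], y2=np.zeros((1, 2)),
                              dropout_time=np.array([-1]))
        state = _ChainState(panel, dims, PriorSpec(),
                            np.random.default_rng(12))
        state.prior_t0_var = v0
        # freeze everything except the free loading and the factor scores
        def freeze():
            state.meas.sigma2_eps1[:] = s_eps
            state.meas.lambda2[:] = 1.0
            state.meas.sigma2_eps2[:] = 1.0
            state.meas.sigma2_eta2 = 1.0
            state.dyn.alpha21[:] = 0.0
            state.dyn.b1[:] = b
            state.dyn.sigma2_zeta1[:] = s_zeta
            state.dyn.beta2[:] = 0.0
            state.dyn.omega2[:] = 0.0
            state.eta2[:] = 0.0
            state.zeta2[:] = 0.0
            state.S[:] = 1
        freeze()
        draws = []
        for it in range(6000):
            state.update_eta1(switching=False)
            state.update_measurement_within()
            freeze()
            if it >= 500:
                draws.append(state.meas.lambda1[1])
        draws = np.array(draws)

        # grid oracle: p(lam | y) with eta integrated out analytically
        S_eta = np.empty((3, 3))
        var = [v0, b ** 2 * v0 + s_zeta, b ** 2 * (b ** 2 * v0 + s_zeta) + s_zeta]
        for t in range(3):
            for u in range(3):
                lo, hi = min(t, u), max(t, u)
                S_eta[t, u] = b ** (hi - lo) * var[lo]
        grid = np.linspace(1e-4, 4.0, 1200)
        logp = np.empty_like(grid)
        yvec = y.reshape(-1)          # items-major: (m, t)
        for k, lam in enumerate(grid):
            L = np.vstack([np.eye(3), lam * np.eye(3)])  # maps eta -> y rows
            Sy = L @ S_eta @ L.T + np.diag(np.repeat(s_eps, 3))
            logp[k] = (stats.multivariate_normal.logpdf(yvec, np.zeros(6), Sy)
                       + stats.norm.logpdf(lam))
        p = np.exp(logp - logp.max())
        p /= p.sum()
        hist, edges = np.histogram(draws, bins=60,
                                   range=(grid[0], grid[-1]), density=False)
        phat = hist / hist.sum()
        pbin = np.add.reduceat(p, np.searchsorted(grid, edges[:-1]))
        tv = 0.5 * np.abs(phat - pbin / pbin.sum()).sum()
        assert tv < 0.05


def independent_reduced_gibbs(y1, y2, n_iter, burnin, seed, v0=2.0):
    """A separately written, loop-based Gibbs sampler for the reduced model.

    Single factor, two within items (loading 1 and free), two between items,
    no regime switching: the standard two-level AR(1) dynamic factor model
    under the same priors.  Used only as an oracle.
    """
    rng = np.random.default_rng(seed)
    n1, _, T = y1.shape
    lam = 0.7
    lam2 = 0.7
    se = np.array([0.5, 0.5])
    se2 = np.array([0.5, 0.5])
    s_eta2 = 1.0
    alpha, beta2, bb, om = 0.0, 0.0, 0.0, 0.0
    s_z1, s_z2 = 0.5, 0.5
    eta = np.zeros((n1, T))
    eta2 = np.zeros(n1)
    zeta2 = np.zeros(n1)
    out = []
    for it in range(n_iter):
        lam_vec = np.array([1.0, lam])
        # factor scores, one site at a time
        for i in range(n1):
            for t in range(T):
                prec = np.sum(lam_vec ** 2 / se)
                num = np.sum(lam_vec * y1[i, :, t] / se)
                slope = bb + om * eta2[i]
                icept = alpha + beta2 * eta2[i] + zeta2[i]
                if t == 0:
                    prec += 1.0 / v0
                else:
                    prec += 1.0 / s_z1
                    num += (icept + slope * eta[i, t - 1]) / s_z1
                if t < T - 1:
                    prec += slope ** 2 / s_z1
                    num += slope * (eta[i, t + 1] - icept) / s_z1
                eta[i, t] = num / prec + rng.standard_normal() / math.sqrt(prec)
        # between factor and random effect
        lam2_vec = np.array([1.0, lam2])
        for i in range(n1):
            prec = 1.0 / s_eta2 + np.sum(lam2_vec ** 2 / se2)
            num = np.sum(lam2_vec * y2[i] / se2)
            for t in range(1, T):
                c = beta2 + om * eta[i, t - 1]
                r = eta[i, t] - alpha - zeta2[i] - bb * eta[i, t - 1]
                prec += c ** 2 / s_z1
                num += c * r / s_z1
            eta2[i] = num / prec + rng.standard_normal() / math.sqrt(prec)
            prec = 1.0 / s_z2 + (T - 1) / s_z1
            num = sum(eta[i, t] - alpha - beta2 * eta2[i]
                      - (bb + om * eta2[i]) * eta[i, t - 1]
                      for t in range(1, T)) / s_z1
            zeta2[i] = num / prec + rng.standard_normal() / math.sqrt(prec)
        # free loadings (truncated normal) and residual precisions
        x = eta.reshape(-1)
        yy = y1[:, 1, :].reshape(-1)
        prec = 1.0 + np.sum(x * x) / se[1]
        mean = np.sum(x * yy) / se[1] / prec
        sd = 1.0 / math.sqrt(prec)
        lam = stats.truncnorm.rvs(-mean / sd, np.inf, loc=mean, scale=sd,
                                  random_state=rng)
        for m in range(2):
            lv = 1.0 if m == 0 else lam
            resid = y1[:, m, :] - lv * eta
            se[m] = 1.0 / rng.gamma(9 + resid.size / 2,
                                    1.0 / (4 + 0.5 * np.sum(resid ** 2)))
        prec = 1.0 + np.sum(eta2 ** 2) / se2[1]
        mean = np.sum(eta2 * y2[:, 1]) / se2[1] / prec
        sd = 1.0 / math.sqrt(prec)
        lam2 = stats.truncnorm.rvs(-mean / sd, np.inf, loc=mean, scale=sd,
                                   random_state=rng)
        for m in range(2):
            lv = 1.0 if m == 0 else lam2
            resid = y2[:, m] - lv * eta2
            se2[m] = 1.0 / rng.gamma(9 + n1 / 2,
                                     1.0 / (4 + 0.5 * np.sum(resid ** 2)))
        s_eta2 = 1.0 / rng.gamma(9 + n1 / 2,
                                 1.0 / (4 + 0.5 * np.sum(eta2 ** 2)))
        # structural coefficients, scalar conditionals
        prev = eta[:, :-1]
        cur = eta[:, 1:]
        for which in range(4):
            designs = [np.ones_like(prev), eta2[:, None] * np.ones_like(prev),
                       prev, eta2[:, None] * prev]
            coef = [alpha, beta2, bb, om]
            fitted = (alpha + beta2 * eta2[:, None] + zeta2[:, None]
                      + (bb + om * eta2[:, None]) * prev)
            xd = designs[which]
            r = cur - fitted + coef[which] * xd
            prec = 1.0 + np.sum(xd * xd) / s_z1
            mean = np.sum(xd * r) / s_z1 / prec
            val = mean + rng.standard_normal() / math.sqrt(prec)
            alpha, beta2, bb, om = [
                val if k == which else c
                for k, c in enumerate([alpha, beta2, bb, om])]
        fitted = (alpha + beta2 * eta2[:, None] + zeta2[:, None]
                  + (bb + om * eta2[:, None]) * prev)
        resid = cur - fitted
        s_z1 = 1.0 / rng.gamma(9 + resid.size / 2,
                               1.0 / (4 + 0.5 * np.sum(resid ** 2)))
        s_z2 = 1.0 / rng.gamma(9 + n1 / 2,
                               1.0 / (4 + 0.5 * np.sum(zeta2 ** 2)))
        if it >= burnin:
            out.append((lam, alpha, bb, s_z1))
    return np.array(out)


class TestReducedModelEquivalence:
    def test_matches_independent_sampler_with_switching_disabled(self):
        dims = ModelDims(n_persons=12, n_occasions=10, horizon=0, n_factors=1,
                         items_per_factor=2, n_items_between=2)
        params = make_params(dims)
        params.switching.gamma1 = 20.0      # no switches in the truth
        params.switching.gamma3[:] = 0.0
        params.switching.gamma4[:] = 0.0
        params.dynamics.b1[:] = 0.45
        panel, _ = simulate_panel(params, dims, seed=21)
        cfg = MCMCConfig(n_chains=1, n_iter=2500, n_burnin=500, seed=4,
                         n_store_latent=10)
        draws = fit(panel, dims, config=cfg, switching=False)
        ref = independent_reduced_gibbs(panel.y1, panel.y2, 2500, 500, seed=5)
        pairs = [("lambda1[1]", 0), ("alpha21[1,0]", 1), ("b1[1,0]", 2),
                 ("sigma2_zeta1[0]", 3)]
        for name, col in pairs:
            ours = draws.param_trace(name).mean()
            theirs = ref[:, col].mean()
            assert abs(ours - theirs) < 0.08, (name, ours, theirs)
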