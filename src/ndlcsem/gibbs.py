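"""Gibbs sampler for the full posterior of the regime-switching factor model.

Every update is a draw from an exact full conditional except three
Metropolis-within-Gibbs steps where the logistic switching likelihood breaks
conjugacy: the within factor scores eta1 and the between factor eta2 use an
independence proposal from their Gaussian part (accepted on the switching
likelihood ratio), and the switching coefficients gamma use per-coefficient
random walks.  The return probability p12 has an exact draw: its conditional
under the Uniform(0, 0.1) prior is a Beta truncated to [0, 0.1].

Discrete state paths are drawn jointly per person by a discrete
forward-backward pass whose emissions are the state-specific structural
densities of the realized factor scores; paths honor S_{i,0} = 1 and the
observed dropout mask.  Missing within-level responses are imputed from the
measurement model at the start of every sweep (missing at random).

Label switching is prevented structurally: the state-2 level shift
delta_alpha21 is censored at zero, so state 2 is always the high-level
("intention to quit") regime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .params import (DynamicsParams, LatentState, MeasurementParams, ModelDims,
                     ModelParams, ObservedPanel, PriorSpec, SwitchParams)
from .simulate import default_gamma4_mask

__all__ = ["MCMCConfig", "PosteriorDraws", "fit", "conditional_state_draw",
           "rhat"]

logger = logging.getLogger(__name__)


def _log_sigmoid(nu: np.ndarray) -> np.ndarray:
    """log(exp(nu) / (exp(nu) + 1)), overflow-safe."""
    return -np.logaddexp(0.0, -nu)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    The full-analysis default is 4 chains x 30,000 iterations (25,000
    burn-in); the simulation-study default is 2 chains x 10,000 (5,000
    burn-in).  ``n_store_latent`` caps, per chain, the number of retained
    draws for which the latent scores and state paths are stored for the
    forecaster (evenly thinned from the kept draws).
    """

    n_chains: int = 2
    n_iter: int = 10_000
    n_burnin: int = 5_000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.12
    n_store_latent: int = 50
    eta1_t0_var: float = 2.0
    gamma_step: float = 0.15

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains and thin must be positive")

    @classmethod
    def full_analysis(cls, **kw) -> "MCMCConfig":
        return cls(n_chains=4, n_iter=30_000, n_burnin=25_000, **kw)


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned posterior draws.

    ``trace`` holds every scalar parameter per chain and kept iteration
    (names in ``names``); the latent stores (params/eta1/eta2/zeta2/S) are a
    coarser, evenly spaced subset pooled across chains, used by the
    forecaster with equal weight per draw.
    """

    names: list[str]
    trace: np.ndarray            # (n_chains, n_kept, n_params)
    params: list[ModelParams]    # K stored draws
    eta1: np.ndarray             # (K, N1, J, T)
    eta2: np.ndarray             # (K, N1)
    zeta2: np.ndarray            # (K, N1, J)
    S: np.ndarray                # (K, N1, T)
    dims: ModelDims
    config: MCMCConfig

    def param_trace(self, name: str) -> np.ndarray:
        return self.trace[:, :, self.names.index(name)]

    def posterior_mean(self, name: str) -> float:
        return float(self.param_trace(name).mean())

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1 - level) / 2
        v = self.param_trace(name).reshape(-1)
        return (float(np.quantile(v, a)), float(np.quantile(v, 1 - a)))

    def state_prob2(self) -> np.ndarray:
        """Posterior P(S = 2) per person-occasion from the stored paths."""
        return (self.S == 2).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long draws table: chain, iteration, parameter, value."""
        n_chains, n_kept, n_par = self.trace.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(n_chains), n_kept * n_par),
            "iteration": np.tile(np.repeat(np.arange(n_kept), n_par), n_chains),
            "parameter": np.tile(self.names, n_chains * n_kept),
            "value": self.trace.reshape(-1),
        })

    def states_frame(self) -> pd.DataFrame:
        """Long state-path table: person_id, occasion, draw, S."""
        K, n1, T = self.S.shape
        return pd.DataFrame({
            "person_id": np.tile(np.repeat(np.arange(n1), T), K),
            "occasion": np.tile(np.arange(1, T + 1), K * n1),
            "draw": np.repeat(np.arange(K), n1 * T),
            "S": self.S.reshape(-1),
        })


# --------------------------------------------------------------------------
# chain state and updates

class _ChainState:
    """Mutable state of one chain (complete data after imputation)."""

    def __init__(self, panel: ObservedPanel, dims: ModelDims, prior: PriorSpec,
                 rng: np.random.Generator):
        self.dims = dims
        self.prior = prior
        self.rng = rng
        n1, p, J = dims.n_persons, dims.n_items_within, dims.n_factors
        T = dims.n_occasions
        q = dims.n_items_between
        self.T = T
        self.y1 = np.nan_to_num(panel.y1[:, :, :T].copy())
        self.miss = panel.missing_mask[:, :, :T]
        self.y2 = panel.y2
        self.s_obs = panel.observed_state_mask()[:, :T]
        self.item_factor = dims.item_factor
        self.free_items = np.setdiff1d(np.arange(p), dims.scaling_items)
        self.prior_t0_var = 2.0
        self.gamma_step = 0.15

        # parameters at prior medians
        lam_med = stats.norm.ppf(0.75) * prior.loading_sd
        sig_med = 1.0 / (stats.gamma.ppf(0.5, a=prior.precision_shape,
                                         scale=1.0 / prior.precision_rate))
        lam1 = np.ones(p)
        lam1[self.free_items] = lam_med
        lam2 = np.ones(q)
        lam2[1:] = lam_med
        self.meas = MeasurementParams(
            lambda1=lam1, sigma2_eps1=np.full(p, sig_med), lambda2=lam2,
            sigma2_eps2=np.full(q, sig_med), sigma2_eta2=sig_med)
        self.dyn = DynamicsParams(
            alpha21=np.zeros(J), delta_alpha21=np.full(J, lam_med),
            beta2=np.zeros(J), delta_beta2=np.zeros(J),
            b1=np.zeros(J), delta_b1=np.zeros(J),
            omega2=np.zeros(J), delta_omega2=np.zeros(J),
            sigma2_zeta1=np.full(J, sig_med), sigma2_zeta2=np.full(J, sig_med))
        mask = default_gamma4_mask(J)
        self.sw = SwitchParams(gamma1=0.0, gamma2=0.0, gamma3=np.zeros(J),
                               gamma4=np.zeros(J), gamma4_mask=mask,
                               p12=0.5 * (prior.p12_lower + prior.p12_upper))
        # latent scores at zero plus a small chain-specific jitter
        self.eta1 = 0.1 * rng.standard_normal((n1, J, T))
        self.eta2 = 0.1 * rng.standard_normal(n1)
        self.zeta2 = 0.1 * rng.standard_normal((n1, J))
        self.S = np.ones((n1, T), dtype=int)
        self.S[self.s_obs] = 2

    # -- helpers ----------------------------------------------------------

    def params(self) -> ModelParams:
        import copy
        return copy.deepcopy(ModelParams(self.meas, self.dyn, self.sw))

    def _coef_state(self, j: int, I2: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Intercept A and slope B of factor j's AR given state indicators I2."""
        d = self.dyn
        A = (d.alpha21[j] + d.delta_alpha21[j] * I2
             + (d.beta2[j] + d.delta_beta2[j] * I2) * self.eta2[:, None]
             + self.zeta2[:, j, None])
        B = (d.b1[j] + d.delta_b1[j] * I2
             + (d.omega2[j] + d.delta_omega2[j] * I2) * self.eta2[:, None])
        return A, B

    def _truncnorm_pos(self, mean, sd):
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                   random_state=self.rng)

    # -- update steps ------------------------------------------------------

    def impute_missing(self) -> None:
        if not self.miss.any():
            return
        lam = self.meas.lambda1[self.item_factor]
        mu = self.eta1[:, self.item_factor, :] * lam[None, :, None]
        sd = np.sqrt(self.meas.sigma2_eps1)[None, :, None]
        draw = mu + sd * self.rng.standard_normal(mu.shape)
        self.y1[self.miss] = draw[self.miss]

    def update_measurement_within(self) -> None:
        pr = self.prior
        n_obs = self.y1.shape[0] * self.T
        for m_idx in range(self.dims.n_items_within):
            j = self.item_factor[m_idx]
            x = self.eta1[:, j, :]
            y = self.y1[:, m_idx, :]
            s2 = self.meas.sigma2_eps1[m_idx]
            if m_idx in self.free_items:
                prec = 1.0 / pr.loading_sd ** 2 + np.sum(x * x) / s2
                mean = (np.sum(x * y) / s2) / prec
                self.meas.lambda1[m_idx] = self._truncnorm_pos(
                    mean, 1.0 / math.sqrt(prec))
            resid = y - self.meas.lambda1[m_idx] * x
            tau = self.rng.gamma(pr.precision_shape + 0.5 * n_obs,
                                 1.0 / (pr.precision_rate + 0.5 * np.sum(resid ** 2)))
            self.meas.sigma2_eps1[m_idx] = 1.0 / tau

    def update_measurement_between(self) -> None:
        pr = self.prior
        n1 = self.eta2.shape[0]
        for m_idx in range(self.dims.n_items_between):
            x = self.eta2
            y = self.y2[:, m_idx]
            s2 = self.meas.sigma2_eps2[m_idx]
            if m_idx > 0:
                prec = 1.0 / pr.loading_sd ** 2 + np.sum(x * x) / s2
                mean = (np.sum(x * y) / s2) / prec
                self.meas.lambda2[m_idx] = self._truncnorm_pos(
                    mean, 1.0 / math.sqrt(prec))
            resid = y - self.meas.lambda2[m_idx] * x
            tau = self.rng.gamma(pr.precision_shape + 0.5 * n1,
                                 1.0 / (pr.precision_rate + 0.5 * np.sum(resid ** 2)))
            self.meas.sigma2_eps2[m_idx] = 1.0 / tau
        tau = self.rng.gamma(pr.precision_shape + 0.5 * n1,
                             1.0 / (pr.precision_rate + 0.5 * np.sum(self.eta2 ** 2)))
        self.meas.sigma2_eta2 = 1.0 / tau

    def _switch_design(self):
        """nu pieces for transitions out of state 1: base + slope * eta2."""
        prev = self.eta1[:, :, :-1]                       # (N1, J, T-1)
        base = self.sw.gamma1 + np.einsum("ijt,j->it", prev, self.sw.gamma3)
        slope = self.sw.gamma2 + np.einsum("ijt,j->it", prev, self.sw.gamma4)
        from1 = self.S[:, :-1] == 1
        stay = self.S[:, 1:] == 1
        return base, slope, from1, stay

    @staticmethod
    def _switch_loglik(nu, from1, stay):
        ll = np.where(stay, _log_sigmoid(nu), _log_sigmoid(-nu))
        return np.sum(ll * from1, axis=1)

    def update_eta2(self, switching: bool = True) -> None:
        m, d = self.meas, self.dyn
        n1, J = self.zeta2.shape
        prec = np.full(n1, 1.0 / m.sigma2_eta2)
        num = np.zeros(n1)
        prec += np.sum(m.lambda2 ** 2 / m.sigma2_eps2)
        num += self.y2 @ (m.lambda2 / m.sigma2_eps2)
        I2 = (self.S[:, 1:] == 2).astype(float)
        for j in range(J):
            prev = self.eta1[:, j, :-1]
            cur = self.eta1[:, j, 1:]
            c = (d.beta2[j] + d.delta_beta2[j] * I2
                 + (d.omega2[j] + d.delta_omega2[j] * I2) * prev)
            r = (cur - (d.alpha21[j] + d.delta_alpha21[j] * I2
                        + self.zeta2[:, j, None])
                 - (d.b1[j] + d.delta_b1[j] * I2) * prev)
            prec += np.sum(c * c, axis=1) / d.sigma2_zeta1[j]
            num += np.sum(c * r, axis=1) / d.sigma2_zeta1[j]
        mean = num / prec
        sd = 1.0 / np.sqrt(prec)
        prop = mean + sd * self.rng.standard_normal(n1)
        if switching:
            base, slope, from1, stay = self._switch_design()
            ll_new = self._switch_loglik(base + slope * prop[:, None],
                                         from1, stay)
            ll_old = self._switch_loglik(base + slope * self.eta2[:, None],
                                         from1, stay)
            accept = np.log(self.rng.random(n1)) < (ll_new - ll_old)
        else:
            accept = np.ones(n1, dtype=bool)
        self.eta2 = np.where(accept, prop, self.eta2)

    def update_zeta2(self) -> None:
        d = self.dyn
        n1, J = self.zeta2.shape
        I2 = (self.S[:, 1:] == 2).astype(float)
        for j in range(J):
            prev = self.eta1[:, j, :-1]
            cur = self.eta1[:, j, 1:]
            A_no = (d.alpha21[j] + d.delta_alpha21[j] * I2
                    + (d.beta2[j] + d.delta_beta2[j] * I2) * self.eta2[:, None])
            B = (d.b1[j] + d.delta_b1[j] * I2
                 + (d.omega2[j] + d.delta_omega2[j] * I2) * self.eta2[:, None])
            r = cur - A_no - B * prev
            prec = 1.0 / d.sigma2_zeta2[j] + (self.T - 1) / d.sigma2_zeta1[j]
            num = np.sum(r, axis=1) / d.sigma2_zeta1[j]
            self.zeta2[:, j] = (num / prec
                                + self.rng.standard_normal(n1) / np.sqrt(prec))

    def update_eta1(self, switching: bool = True) -> None:
        m, d, g = self.meas, self.dyn, self.sw
        n1, J, T = self.eta1.shape
        lam = m.lambda1
        inv_e1 = 1.0 / m.sigma2_eps1
        for j in range(J):
            items = np.where(self.item_factor == j)[0]
            lam_j = lam[items]
            meas_prec = np.sum(lam_j ** 2 * inv_e1[items])
            s2 = d.sigma2_zeta1[j]
            gslope_j = g.gamma3[j] + g.gamma4[j] * self.eta2   # (n1,)
            for t in range(T):
                prec = np.full(n1, meas_prec)
                num = self.y1[:, items, t] @ (lam_j * inv_e1[items])
                if t == 0:
                    prec += 1.0 / self.prior_t0_var
                else:
                    I2c = (self.S[:, t] == 2).astype(float)[:, None]
                    A, B = self._coef_state(j, I2c)
                    A, B = A[:, 0], B[:, 0]
                    prec += 1.0 / s2
                    num += (A + B * self.eta1[:, j, t - 1]) / s2
                if t < T - 1:
                    I2n = (self.S[:, t + 1] == 2).astype(float)[:, None]
                    An, Bn = self._coef_state(j, I2n)
                    An, Bn = An[:, 0], Bn[:, 0]
                    prec += Bn ** 2 / s2
                    num += Bn * (self.eta1[:, j, t + 1] - An) / s2
                mean = num / prec
                sd = 1.0 / np.sqrt(prec)
                prop = mean + sd * self.rng.standard_normal(n1)
                if switching and t < T - 1:
                    from1 = self.S[:, t] == 1
                    if np.any(from1):
                        nu_old = (g.gamma1 + g.gamma2 * self.eta2
                                  + np.einsum("ij,j->i", self.eta1[:, :, t], g.gamma3)
                                  + np.einsum("ij,j->i", self.eta1[:, :, t], g.gamma4)
                                  * self.eta2)
                        nu_new = nu_old + gslope_j * (prop - self.eta1[:, j, t])
                        stay = self.S[:, t + 1] == 1
                        ll_old = np.where(stay, _log_sigmoid(nu_old),
                                          _log_sigmoid(-nu_old))
                        ll_new = np.where(stay, _log_sigmoid(nu_new),
                                          _log_sigmoid(-nu_new))
                        rej = from1 & (np.log(self.rng.random(n1))
                                       >= (ll_new - ll_old))
                        prop = np.where(rej, self.eta1[:, j, t], prop)
                self.eta1[:, j, t] = prop

    def update_structural(self) -> None:
        d = self.dyn
        pr = self.prior
        I2 = (self.S[:, 1:] == 2).astype(float)
        ones = np.ones_like(I2)
        for j in range(d.alpha21.shape[0]):
            prev = self.eta1[:, j, :-1]
            cur = self.eta1[:, j, 1:]
            s2 = d.sigma2_zeta1[j]
            e2 = self.eta2[:, None]
            designs = {
                "alpha21": ones, "delta_alpha21": I2,
                "beta2": e2 * ones, "delta_beta2": e2 * I2,
                "b1": prev, "delta_b1": prev * I2,
                "omega2": e2 * prev, "delta_omega2": e2 * prev * I2,
            }
            def fitted():
                A, B = self._coef_state(j, I2)
                return A + B * prev
            for name, x in designs.items():
                arr = getattr(d, name)
                r_full = cur - fitted() + arr[j] * x
                prior_sd = pr.dalpha_sd if name == "delta_alpha21" else pr.coef_sd
                prec = 1.0 / prior_sd ** 2 + np.sum(x * x) / s2
                mean = (np.sum(x * r_full) / s2) / prec
                sd = 1.0 / math.sqrt(prec)
                if name == "delta_alpha21":
                    arr[j] = self._truncnorm_pos(mean, sd)
                else:
                    arr[j] = mean + sd * self.rng.standard_normal()
            resid = cur - fitted()
            tau = self.rng.gamma(
                pr.precision_shape + 0.5 * resid.size,
                1.0 / (pr.precision_rate + 0.5 * np.sum(resid ** 2)))
            d.sigma2_zeta1[j] = 1.0 / tau
            tau = self.rng.gamma(
                pr.precision_shape + 0.5 * self.zeta2.shape[0],
                1.0 / (pr.precision_rate + 0.5 * np.sum(self.zeta2[:, j] ** 2)))
            d.sigma2_zeta2[j] = 1.0 / tau

    def update_gamma(self) -> None:
        g = self.sw
        pr = self.prior
        step = self.gamma_step
        prev = self.eta1[:, :, :-1]
        from1 = self.S[:, :-1] == 1
        stay = self.S[:, 1:] == 1
        if not np.any(from1):
            return
        coefs: list[tuple[str, int | None, np.ndarray]] = [
            ("gamma1", None, np.ones_like(prev[:, 0, :])),
            ("gamma2", None, np.broadcast_to(self.eta2[:, None], from1.shape)),
        ]
        for j in range(prev.shape[1]):
            coefs.append(("gamma3", j, prev[:, j, :]))
        for j in np.where(g.gamma4_mask)[0]:
            coefs.append(("gamma4", j, prev[:, j, :] * self.eta2[:, None]))
        nu = (g.gamma1 + g.gamma2 * self.eta2[:, None]
              + np.einsum("ijt,j->it", prev, g.gamma3)
              + np.einsum("ijt,j->it", prev, g.gamma4) * self.eta2[:, None])
        ll = np.sum(np.where(stay, _log_sigmoid(nu), _log_sigmoid(-nu))[from1])
        for name, j, x in coefs:
            old = getattr(g, name) if j is None else getattr(g, name)[j]
            delta = step * self.rng.standard_normal()
            nu_new = nu + delta * x
            ll_new = np.sum(np.where(stay, _log_sigmoid(nu_new),
                                     _log_sigmoid(-nu_new))[from1])
            lr = (ll_new - ll
                  - 0.5 * ((old + delta) ** 2 - old ** 2) / pr.coef_sd ** 2)
            if np.log(self.rng.random()) < lr:
                if j is None:
                    setattr(g, name, old + delta)
                else:
                    getattr(g, name)[j] = old + delta
                nu, ll = nu_new, ll_new

    def update_p12(self) -> None:
        pr = self.prior
        prev2 = self.S[:, :-1] == 2
        returns = int(np.sum(prev2 & (self.S[:, 1:] == 1)))
        stays = int(np.sum(prev2 & (self.S[:, 1:] == 2)))
        dist = stats.beta(returns + 1, stays + 1)
        lo, hi = dist.cdf(pr.p12_lower), dist.cdf(pr.p12_upper)
        if hi <= lo:
            self.sw.p12 = pr.p12_upper
            return
        u = lo + (hi - lo) * self.rng.random()
        self.sw.p12 = float(np.clip(dist.ppf(u), pr.p12_lower, pr.p12_upper))

    def update_states(self, switching: bool = True) -> None:
        if not switching:
            return
        self.S = _draw_state_paths(
            ModelParams(self.meas, self.dyn, self.sw), self.eta1, self.eta2,
            self.zeta2, self.s_obs, self.rng)

    def sweep(self, switching: bool = True) -> None:
        self.impute_missing()
        self.update_measurement_within()
        self.update_measurement_between()
        self.update_eta2(switching)
        self.update_zeta2()
        self.update_eta1(switching)
        self.update_states(switching)
        self.update_structural()
        self.update_gamma()
        self.update_p12()


def _draw_state_paths(params: ModelParams, eta1: np.ndarray, eta2: np.ndarray,
                      zeta2: np.ndarray, s_obs: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Joint draw of every person's state path by discrete forward-backward.

    Emissions are the products over factors of the state-specific structural
    densities of eta1 at each occasion; transitions follow the logistic /
    constant-return Markov model evaluated at the lagged factor scores.
    S_{i,0} = 1 and masked (observed-dropout) occasions are forced to 2.
    """
    d, g = params.dynamics, params.switching
    n1, J, T = eta1.shape
    loglik = np.zeros((T, n1, 2))
    for s_idx, s in enumerate((1, 2)):
        alpha = (d.alpha21_state(s)[None, :, None]
                 + d.beta2_state(s)[None, :, None] * eta2[:, None, None]
                 + zeta2[:, :, None])
        slope = (d.b1_state(s)[None, :, None]
                 + d.omega2_state(s)[None, :, None] * eta2[:, None, None])
        mean = alpha + slope * eta1[:, :, :-1]
        z2 = d.sigma2_zeta1[None, :, None]
        ll = -0.5 * np.log(2 * np.pi * z2) - 0.5 * (eta1[:, :, 1:] - mean) ** 2 / z2
        loglik[1:, :, s_idx] = ll.sum(axis=1).T
    nu = (g.gamma1 + g.gamma2 * eta2[:, None]
          + np.einsum("ijt,j->it", eta1[:, :, :-1], g.gamma3)
          + np.einsum("ijt,j->it", eta1[:, :, :-1], g.gamma4) * eta2[:, None])
    p11 = special.expit(nu)                                # (n1, T-1)
    p12 = g.p12
    # forward pass (normalized probabilities)
    fwd = np.zeros((T, n1, 2))
    fwd[0, :, 0] = 1.0
    for t in range(1, T):
        pred1 = fwd[t - 1, :, 0] * p11[:, t - 1] + fwd[t - 1, :, 1] * p12
        pred2 = (fwd[t - 1, :, 0] * (1 - p11[:, t - 1])
                 + fwd[t - 1, :, 1] * (1 - p12))
        lmax = loglik[t].max(axis=1, keepdims=True)
        emis = np.exp(loglik[t] - lmax)
        w1 = pred1 * emis[:, 0]
        w2 = pred2 * emis[:, 1]
        if s_obs is not None:
            w1 = np.where(s_obs[:, t], 0.0, w1)
        tot = w1 + w2
        tot = np.where(tot > 0, tot, 1.0)
        fwd[t, :, 0] = w1 / tot
        fwd[t, :, 1] = w2 / tot
    # backward sampling
    S = np.ones((n1, T), dtype=int)
    S[:, T - 1] = 1 + (rng.random(n1) >= fwd[T - 1, :, 0])
    for t in range(T - 2, 0, -1):
        nxt2 = S[:, t + 1] == 2
        trans1 = np.where(nxt2, 1 - p11[:, t], p11[:, t])   # from state 1
        trans2 = np.where(nxt2, 1 - p12, p12)               # from state 2
        w1 = fwd[t, :, 0] * trans1
        w2 = fwd[t, :, 1] * trans2
        tot = np.where(w1 + w2 > 0, w1 + w2, 1.0)
        S[:, t] = 1 + (rng.random(n1) >= w1 / tot)
    if s_obs is not None:
        S[s_obs] = 2
    return S


def conditional_state_draw(person: int, params: ModelParams,
                           eta1: np.ndarray, eta2: np.ndarray,
                           zeta2: np.ndarray, s_obs: np.ndarray | None,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw one person's state path from its full conditional.

    ``eta1`` is (N1, J, T); the draw combines the transition factors with the
    state-dependent structural density of the realized factor scores, honors
    S_{i,0} = 1 and forces masked occasions to state 2.
    """
    sl = slice(person, person + 1)
    obs = None if s_obs is None else s_obs[sl]
    return _draw_state_paths(params, eta1[sl], eta2[sl], zeta2[sl],
                             obs, rng)[0]


def fit(panel: ObservedPanel, dims: ModelDims, prior: PriorSpec | None = None,
        config: MCMCConfig | None = None, switching: bool = True,
        ) -> PosteriorDraws:
    """Run the Gibbs sampler on the observed window of a panel.

    ``switching=False`` freezes the state path at all-1 and skips the
    switching-model updates, reducing the sampler to a standard two-level
    dynamic factor model (used for validation).
    """
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    if dims.items_per_factor < 1:
        raise ValueError("every factor needs at least one (scaling) item")
    if panel.y1.shape[1] != dims.n_items_within:
        raise ValueError("panel items do not match the configured factor structure")
    n_kept = (config.n_iter - config.n_burnin) // config.thin
    store_every = max(1, n_kept // max(1, config.n_store_latent))

    template: list[str] | None = None
    traces = []
    stored_params: list[ModelParams] = []
    st_eta1, st_eta2, st_zeta2, st_S = [], [], [], []
    for chain in range(config.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, chain)))
        state = _ChainState(panel, dims, prior, rng)
        state.prior_t0_var = config.eta1_t0_var
        state.gamma_step = config.gamma_step
        kept = 0
        chain_trace = None
        for it in range(config.n_iter):
            state.sweep(switching)
            if it < config.n_burnin or (it - config.n_burnin) % config.thin:
                continue
            flat = state.params().to_flat()
            if template is None:
                template = [k for k, v in flat.items()
                            if not isinstance(v, bool)]
            if chain_trace is None:
                chain_trace = np.empty((n_kept, len(template)))
            chain_trace[kept] = [flat[k] for k in template]
            if kept % store_every == 0 and len(st_eta1) < (chain + 1) * config.n_store_latent:
                stored_params.append(state.params())
                st_eta1.append(state.eta1.copy())
                st_eta2.append(state.eta2.copy())
                st_zeta2.append(state.zeta2.copy())
                st_S.append(state.S.copy())
            kept += 1
        traces.append(chain_trace)
    return PosteriorDraws(
        names=template, trace=np.stack(traces), params=stored_params,
        eta1=np.stack(st_eta1), eta2=np.stack(st_eta2),
        zeta2=np.stack(st_zeta2), S=np.stack(st_S), dims=dims, config=config)


def rhat(draws: PosteriorDraws | np.ndarray,
         threshold: float | None = None) -> pd.DataFrame | float:
    """Split-chain potential scale reduction factor.

    Given a :class:`PosteriorDraws`, returns a table with one row per scalar
    parameter (columns parameter, rhat, flagged); given a raw
    (n_chains, n_draws) array, returns the scalar statistic.  Parameters that
    are constant across all draws yield NaN.  Requires at least two chains.
    """
    if isinstance(draws, np.ndarray):
        return _split_rhat(draws)
    if draws.trace.shape[0] < 2:
        raise ValueError("rhat requires at least two chains")
    threshold = draws.config.rhat_threshold if threshold is None else threshold
    rows = []
    for k, name in enumerate(draws.names):
        r = _split_rhat(draws.trace[:, :, k])
        rows.append({"parameter": name, "rhat": r,
                     "flagged": bool(np.isfinite(r) and r >= threshold)})
    return pd.DataFrame(rows)


def _split_rhat(chains: np.ndarray) -> float:
    chains = np.asarray(chains, float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    if chains.shape[0] < 2:
        raise ValueError("rhat requires at least two chains")
    n = chains.shape[1] // 2
    if n < 2:
        return float("nan")
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    if np.ptp(halves) == 0:
        return float("nan")
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W == 0:
        return float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))
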