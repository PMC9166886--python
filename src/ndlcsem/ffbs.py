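"""Forward Filtering Backward Sampling forecaster over regime strata.

Each within-level factor is rewritten as a dynamic linear model (DLM) whose
system vector theta = (alpha21_js, b1_js, beta2_js, omega2_js, 1)' is constant
over time: the quadruple is {F_jt, I_5, sigma2_zeta1j * I_N1, 0_5x5} with
design rows F_i = (1, eta1_j,t-1, eta2, eta1_j,t-1 * eta2, zeta2_j).

Between consecutive occasions the discrete regime can take one of four
transition strata (s, s') = state at t x state at t-1.  A separate DLM filter
is carried per stratum; per-person mixture probabilities over the strata
combine the Markov transition model with the predictive density of the
realized factor scores.  Forecasts H steps ahead propagate the filters
without data (G = I, W = 0 keeps a and R constant) while the lagged factor
entries of F are sampled from the previous horizon's forecast mixture.

Stratum layout used throughout: index k = (s - 1) + 2 * (s' - 1), i.e.
``STRATA = [(1,1), (2,1), (1,2), (2,2)]`` as (state at t, state at t-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

from .model import stay_logit
from .params import ModelDims, ModelParams

__all__ = [
    "STRATA", "DlmQuadruple", "StratumFilter", "ModelProbabilities",
    "ForecastOutput", "make_quadruple", "init_filter", "update_step",
    "h_step_forecast", "joint_posterior_probs", "marginal_predictive",
    "mixture_quantile", "collapse", "forecast_states", "transition_stratum_probs",
    "forecast_from_draws", "filter_state_trajectories",
]

#: The four regime-transition strata as (state at t, state at t-1).
STRATA: tuple[tuple[int, int], ...] = ((1, 1), (2, 1), (1, 2), (2, 2))

_DIM = 5  # length of the DLM system vector theta


@dataclass
class DlmQuadruple:
    """One factor's DLM quadruple {F, G, V, W} at one occasion.

    G is the identity and W the zero matrix for this model (theta constant
    over time); V is diagonal with the factor's innovation variance.
    """

    F: np.ndarray                # (N1, 5)
    sigma2: float                # diagonal value of V
    G: np.ndarray = field(default_factory=lambda: np.eye(_DIM))
    W: np.ndarray = field(default_factory=lambda: np.zeros((_DIM, _DIM)))

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("V must be positive definite (sigma2 > 0)")
        if self.F.ndim != 2 or self.F.shape[1] != _DIM:
            raise ValueError(f"F must be (N1, {_DIM})")


def make_quadruple(eta1_prev_j: np.ndarray, eta2: np.ndarray,
                   zeta2_j: np.ndarray, sigma2_zeta1j: float) -> DlmQuadruple:
    """Build F = (1, eta1_prev, eta2, eta1_prev*eta2, zeta2) and V's diagonal."""
    n1 = eta1_prev_j.shape[0]
    F = np.column_stack([np.ones(n1), eta1_prev_j, eta2,
                         eta1_prev_j * eta2, zeta2_j])
    return DlmQuadruple(F=F, sigma2=float(sigma2_zeta1j))


@dataclass
class StratumFilter:
    """Per-stratum DLM posteriors for one factor.

    ``m`` (4, 5) and ``C`` (4, 5, 5) are the posterior mean/covariance of the
    system vector under each stratum; ``f``, ``q_diag``, ``e`` hold the last
    update's one-step predictive mean, predictive variance (diagonal of Q) and
    residual per person, used by the probability update.
    """

    m: np.ndarray                    # (4, 5)
    C: np.ndarray                    # (4, 5, 5)
    f: np.ndarray | None = None      # (4, N1)
    q_diag: np.ndarray | None = None  # (4, N1)
    e: np.ndarray | None = None      # (4, N1)

    def copy(self) -> "StratumFilter":
        return StratumFilter(m=self.m.copy(), C=self.C.copy(),
                             f=None if self.f is None else self.f.copy(),
                             q_diag=None if self.q_diag is None else self.q_diag.copy(),
                             e=None if self.e is None else self.e.copy())


def init_filter(prior_m: np.ndarray | None = None,
                prior_C: np.ndarray | None = None) -> StratumFilter:
    """Initialize all four strata identically from the theta prior.

    Default is the weakly informative choice: zero mean and unit covariance.
    """
    prior_m = np.zeros(_DIM) if prior_m is None else np.asarray(prior_m, float)
    prior_C = np.eye(_DIM) if prior_C is None else np.asarray(prior_C, float)
    if prior_m.shape != (_DIM,) or prior_C.shape != (_DIM, _DIM):
        raise ValueError(f"prior must be ({_DIM},) mean and ({_DIM},{_DIM}) covariance")
    eig = np.linalg.eigvalsh((prior_C + prior_C.T) / 2)
    if eig.min() < -1e-10:
        raise ValueError(f"prior_C is not positive semidefinite (min eigenvalue {eig.min():.3g})")
    return StratumFilter(m=np.tile(prior_m, (4, 1)),
                         C=np.tile(prior_C, (4, 1, 1)))


def _one_stratum_update(m: np.ndarray, C: np.ndarray, eta: np.ndarray,
                        F: np.ndarray, sigma2: float,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Kalman/DLM update of one stratum: returns (m_new, C_new).

    a = G m, R = G C G' + W (G = I, W = 0), f = F a, Q = F R F' + V,
    A = R F' Q^{-1}, m = a + A e, C = R - A Q A'.
    """
    a, R = m, C
    fvec = F @ a
    Q = F @ R @ F.T + sigma2 * np.eye(F.shape[0])
    cond = np.linalg.cond(Q)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"predictive covariance Q numerically singular (cond={cond:.3g})")
    cho = linalg.cho_factor(Q, lower=True)
    A = linalg.cho_solve(cho, F @ R).T        # R F' Q^{-1}
    e = eta - fvec
    m_new = a + A @ e
    C_new = R - A @ Q @ A.T
    C_new = (C_new + C_new.T) / 2
    return m_new, C_new


def update_step(filt: StratumFilter, eta1_jt: np.ndarray, quad: DlmQuadruple,
                update_sel: list[np.ndarray] | None = None) -> StratumFilter:
    """One filtering step at an observed occasion, per stratum.

    Always records the full-sample one-step predictive quantities
    (f, diag Q, e) per stratum for the probability update.  The (m, C)
    posteriors of stratum k are updated using the persons in
    ``update_sel[k]`` (boolean mask); by default every stratum updates on
    all persons (the literal recursion, used by the degeneracy oracle).
    In the integrated sampler the driver restricts each stratum to the
    person-occasions whose drawn transition lies in that stratum, so each
    stratum's theta estimate tracks its own regime's coefficients.
    """
    F, sigma2 = quad.F, quad.sigma2
    n1 = F.shape[0]
    out = filt.copy()
    out.f = np.empty((4, n1))
    out.q_diag = np.empty((4, n1))
    out.e = np.empty((4, n1))
    for k in range(4):
        a, R = filt.m[k], filt.C[k]
        fvec = F @ a
        out.f[k] = fvec
        out.q_diag[k] = np.einsum("ij,jk,ik->i", F, R, F) + sigma2
        out.e[k] = eta1_jt - fvec
        sel = slice(None) if update_sel is None else update_sel[k]
        Fs = F[sel]
        etas = np.asarray(eta1_jt)[sel]
        if Fs.shape[0] == 0:
            continue  # no person-occasion in this stratum: carry prior forward
        out.m[k], out.C[k] = _one_stratum_update(a, R, etas, Fs, sigma2)
    return out


def h_step_forecast(filt: StratumFilter, F: np.ndarray, sigma2: float,
                    horizon: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum forecast distribution of the factor at a future occasion.

    With G = I and W = 0 the state forecast (a, R) equals the filtered
    (m, C) at the forecast origin for every horizon; only F (through the
    sampled lagged factor) changes between horizons.  Returns (f, q_diag),
    each (4, N1): the mean and variance of eta1 under each stratum.
    """
    if horizon < 1:
        raise ValueError("forecast horizon must be >= 1")
    n1 = F.shape[0]
    f = np.empty((4, n1))
    q = np.empty((4, n1))
    for k in range(4):
        a, R = filt.m[k], filt.C[k]          # G=I, W=0: constant across h
        f[k] = F @ a
        q[k] = np.einsum("ij,jk,ik->i", F, R, F) + sigma2
    return f, q


@dataclass
class ModelProbabilities:
    """Per-person stratum probabilities at one occasion (layout of STRATA)."""

    pi: np.ndarray        # (N1, 4) transition probs P(s | s')
    p_prev: np.ndarray    # (N1, 2) previous-state posteriors
    p_joint: np.ndarray   # (N1, 4) joint posterior model probabilities
    c: np.ndarray         # (N1,) normalization constants
    p_state: np.ndarray   # (N1, 2) collapsed current-state posteriors


def transition_stratum_probs(params: ModelParams, eta1_prev: np.ndarray,
                             eta2: np.ndarray) -> np.ndarray:
    """pi_i(s, s') laid out per STRATA: [P(1|1), P(2|1), P(1|2), P(2|2)]."""
    p11 = special.expit(stay_logit(params.switching, eta1_prev, eta2))
    p12 = params.switching.p12
    return np.column_stack([p11, 1.0 - p11,
                            np.full_like(p11, p12), np.full_like(p11, 1.0 - p12)])


def joint_posterior_probs(pi: np.ndarray, p_prev: np.ndarray,
                          e: np.ndarray, q_diag: np.ndarray,
                          ) -> ModelProbabilities:
    """Joint posterior stratum probabilities after realizing the factor scores.

    p_it(s,s') is proportional to pi_i(s,s') p_{i,t-1}(s') q^{-1/2}
    exp(-e^2 / 2q), normalized over the four strata; computed in log space.
    ``e`` and ``q_diag`` are (N1, 4) for a single factor or (J, N1, 4) when
    the per-factor likelihood terms are multiplied across factors
    (conditional independence given the state).
    """
    e = np.asarray(e, float)
    q = np.asarray(q_diag, float)
    if e.ndim == 2:
        e, q = e[None], q[None]
    loglik = np.sum(-0.5 * np.log(q) - 0.5 * e ** 2 / q, axis=0)   # (N1, 4)
    prev = p_prev[:, [0, 0, 1, 1]]                                  # s' per stratum
    with np.errstate(divide="ignore"):
        logw = np.log(pi) + np.log(prev) + loglik
    finite = logw > -np.inf
    if not np.all(finite.any(axis=1)):
        raise ValueError("all four stratum weights vanished for some person "
                         "(degenerate likelihood)")
    shift = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - shift)
    tot = w.sum(axis=1, keepdims=True)
    p_joint = w / tot
    # c is the reciprocal of the unnormalized sum on the original scale
    c = 1.0 / (tot[:, 0] * np.exp(shift[:, 0]))
    p_state = np.column_stack([p_joint[:, 0] + p_joint[:, 2],
                               p_joint[:, 1] + p_joint[:, 3]])
    return ModelProbabilities(pi=pi, p_prev=p_prev, p_joint=p_joint, c=c,
                              p_state=p_state)


def marginal_predictive(means: np.ndarray, variances: np.ndarray,
                        weights: np.ndarray,
                        level: float | None = None,
                        ) -> dict[str, np.ndarray]:
    """Moments (and optional central interval) of a normal mixture.

    Component arrays share a trailing component axis.  Mixture mean is the
    weighted mean; the variance follows the law of total variance; interval
    endpoints are numerical mixture quantiles.
    """
    w = np.asarray(weights, float)
    if np.any(np.abs(w.sum(axis=-1) - 1.0) > 1e-8):
        raise ValueError("mixture weights must sum to 1 (within 1e-8)")
    mu = np.sum(w * means, axis=-1)
    var = np.sum(w * (variances + means ** 2), axis=-1) - mu ** 2
    out = {"mean": mu, "variance": var}
    if level is not None:
        alpha = (1.0 - level) / 2.0
        sds = np.sqrt(variances)
        out["lower"] = mixture_quantile(means, sds, w, alpha)
        out["upper"] = mixture_quantile(means, sds, w, 1.0 - alpha)
    return out


def mixture_quantile(means: np.ndarray, sds: np.ndarray, weights: np.ndarray,
                     prob: float, iters: int = 70) -> np.ndarray:
    """Quantile of a normal mixture by vectorized bisection on the CDF."""
    lo = np.min(means - 10 * sds, axis=-1)
    hi = np.max(means + 10 * sds, axis=-1)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        cdf = np.sum(weights * stats.norm.cdf(
            (mid[..., None] - means) / sds), axis=-1)
        below = cdf < prob
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def collapse(p_joint: np.ndarray, m: np.ndarray, C: np.ndarray,
             ) -> dict[str, object]:
    """Collapse the four-stratum posterior to one normal per current state.

    p_state(s) = sum_{s'} p(s, s'); the state-s moments are the
    moment-matched mixture over s' (mean as the weighted mean, covariance
    inflated by the between-component mean spread).  A state with zero
    probability has no defined moments and is returned as absent.
    """
    p_joint = np.asarray(p_joint, float)
    out_m: list[np.ndarray | None] = []
    out_C: list[np.ndarray | None] = []
    p_state = np.empty(2)
    for s_idx, comp in enumerate(((0, 2), (1, 3))):     # strata with s=1, s=2
        ps = p_joint[list(comp)].sum()
        p_state[s_idx] = ps
        if ps <= 0.0:
            out_m.append(None)
            out_C.append(None)
            continue
        wk = p_joint[list(comp)] / ps
        ms = sum(w * m[k] for w, k in zip(wk, comp))
        Cs = sum(w * (C[k] + np.outer(ms - m[k], ms - m[k]))
                 for w, k in zip(wk, comp))
        out_m.append(ms)
        out_C.append(Cs)
    return {"p_state": p_state, "m": out_m, "C": out_C}


def forecast_states(p_state2: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Classify person-occasions as state 2 when P(state 2) exceeds threshold.

    The inequality is strict: a probability exactly at the threshold is
    classified as state 1.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return np.where(np.asarray(p_state2) > threshold, 2, 1)


@dataclass
class ForecastOutput:
    """Forecast summaries per person, factor and horizon.

    ``mean``/``variance``/``lower``/``upper`` have shape (N1, J, H);
    ``p_state2`` (N1, H) are forecast state-2 probabilities; the interval
    level is recorded in ``level``.
    """

    mean: np.ndarray
    variance: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    p_state2: np.ndarray
    level: float

    def to_frame(self) -> pd.DataFrame:
        """Long table with the fixed column order
        person_id, factor_id, horizon, mean, variance, lower, upper, p_state2."""
        n1, J, H = self.mean.shape
        person = np.repeat(np.arange(n1), J * H)
        factor = np.tile(np.repeat(np.arange(J), H), n1)
        horizon = np.tile(np.arange(1, H + 1), n1 * J)
        return pd.DataFrame({
            "person_id": person, "factor_id": factor, "horizon": horizon,
            "mean": self.mean.reshape(-1), "variance": self.variance.reshape(-1),
            "lower": self.lower.reshape(-1), "upper": self.upper.reshape(-1),
            "p_state2": np.repeat(self.p_state2, J, axis=0).reshape(-1),
        })


def _stratum_sel(S: np.ndarray, t: int) -> list[np.ndarray]:
    """Boolean person masks of the four drawn transition strata at occasion t."""
    cur2 = S[:, t] == 2
    prev2 = S[:, t - 1] == 2
    return [~cur2 & ~prev2, cur2 & ~prev2, ~cur2 & prev2, cur2 & prev2]


def filter_state_trajectories(params: ModelParams, eta1: np.ndarray,
                              eta2: np.ndarray, zeta2: np.ndarray,
                              S: np.ndarray, dims: ModelDims,
                              per_factor: bool = False,
                              ) -> tuple[list[StratumFilter], np.ndarray]:
    """Run the stratified forward filter over the observed window of one draw.

    Returns the per-factor filters at the forecast origin and the per-person
    state-2 probability trajectory (N1, Nt) from the joint posterior model
    probabilities.  ``per_factor=False`` multiplies the per-factor predictive
    likelihoods inside the probability update (conditional independence given
    the state); ``per_factor=True`` uses the last factor's own update only.
    """
    n1, J, nt = dims.n_persons, dims.n_factors, dims.n_occasions
    d = params.dynamics
    filters = [init_filter() for _ in range(J)]
    p_prev = np.tile([1.0, 0.0], (n1, 1))        # everyone starts in state 1
    p2_traj = np.zeros((n1, nt))
    for t in range(1, nt):
        pi = transition_stratum_probs(params, eta1[:, :, t - 1], eta2)
        sel = _stratum_sel(S, t)
        e_all = np.empty((J, n1, 4))
        q_all = np.empty((J, n1, 4))
        for j in range(J):
            quad = make_quadruple(eta1[:, j, t - 1], eta2, zeta2[:, j],
                                  d.sigma2_zeta1[j])
            filters[j] = update_step(filters[j], eta1[:, j, t], quad, sel)
            e_all[j] = filters[j].e.T
            q_all[j] = filters[j].q_diag.T
        if per_factor:
            probs = joint_posterior_probs(pi, p_prev, e_all[-1], q_all[-1])
        else:
            probs = joint_posterior_probs(pi, p_prev, e_all, q_all)
        p_prev = probs.p_state
        p2_traj[:, t] = probs.p_state[:, 1]
    return filters, p2_traj


def forecast_from_draws(draws, dims: ModelDims, horizon: int,
                        level: float = 0.95, seed: int = 0,
                        per_factor: bool = False) -> ForecastOutput:
    """Integrated H-step forecast across retained posterior draws.

    For each retained draw the observed-window filter is run with that draw's
    parameters and latent scores; forecasting then alternates, per horizon,
    between (i) stratum transition probabilities from the sampled lagged
    factors, (ii) per-stratum normal forecasts of each factor, (iii) sampling
    the next lagged factors from the four-component mixture, and (iv)
    propagating the state distribution through the transition model.  Across
    draws each component enters the final predictive mixture with equal
    draw weight.
    """
    if horizon < 1:
        raise ValueError("forecast horizon must be >= 1")
    rng = np.random.default_rng(seed)
    n1, J = dims.n_persons, dims.n_factors
    K = len(draws.params)
    comp_mean = np.empty((n1, J, horizon, K, 4))
    comp_var = np.empty((n1, J, horizon, K, 4))
    comp_w = np.empty((n1, J, horizon, K, 4))
    p2 = np.zeros((n1, horizon, K))
    for k in range(K):
        params = draws.params[k]
        eta1 = draws.eta1[k]
        eta2 = draws.eta2[k]
        zeta2 = draws.zeta2[k]
        S = draws.S[k]
        d = params.dynamics
        filters, _ = filter_state_trajectories(params, eta1, eta2, zeta2, S,
                                               dims, per_factor)
        # forecast origin: the draw's state at the last observed occasion
        p_prev = np.zeros((n1, 2))
        p_prev[np.arange(n1), (S[:, dims.n_occasions - 1] == 2).astype(int)] = 1.0
        eta_prev = eta1[:, :, dims.n_occasions - 1]
        for h in range(horizon):
            pi = transition_stratum_probs(params, eta_prev, eta2)
            w = pi * p_prev[:, [0, 0, 1, 1]]                      # (N1, 4)
            w = w / w.sum(axis=1, keepdims=True)
            f_all = np.empty((J, 4, n1))
            q_all = np.empty((J, 4, n1))
            for j in range(J):
                quad = make_quadruple(eta_prev[:, j], eta2, zeta2[:, j],
                                      d.sigma2_zeta1[j])
                f_all[j], q_all[j] = h_step_forecast(filters[j], quad.F,
                                                     quad.sigma2, horizon=h + 1)
            comp_mean[:, :, h, k, :] = f_all.transpose(2, 0, 1)
            comp_var[:, :, h, k, :] = q_all.transpose(2, 0, 1)
            comp_w[:, :, h, k, :] = w[:, None, :]
            # sample one stratum per person, then the factors under it
            u = rng.random(n1)
            idx = (w.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(max=3)
            pick_f = f_all[:, idx, np.arange(n1)]                 # (J, N1)
            pick_q = q_all[:, idx, np.arange(n1)]
            eta_prev = (pick_f + np.sqrt(pick_q) * rng.standard_normal((J, n1))).T
            # propagate the state distribution (Markov step along the draw)
            p_next = np.column_stack([w[:, 0] + w[:, 2], w[:, 1] + w[:, 3]])
            p2[:, h, k] = p_next[:, 1]
            p_prev = p_next
    # pool the per-draw mixtures with equal draw weight
    pooled_w = comp_w.reshape(n1, J, horizon, K * 4) / K
    pooled_mean = comp_mean.reshape(n1, J, horizon, K * 4)
    pooled_var = comp_var.reshape(n1, J, horizon, K * 4)
    summ = marginal_predictive(pooled_mean, pooled_var, pooled_w, level=level)
    return ForecastOutput(mean=summ["mean"], variance=summ["variance"],
                          lower=summ["lower"], upper=summ["upper"],
                          p_state2=p2.mean(axis=2), level=level)
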