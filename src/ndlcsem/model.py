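"""Deterministic model equations shared by simulator, estimator and forecaster.

Covers the regime-specific AR(1) structural mean, the logistic Markov
switching model, and the joint log prior density of all parameters.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats

from .params import (DynamicsParams, ModelDims, ModelParams, PriorSpec,
                     SwitchParams)

__all__ = [
    "stay_logit",
    "transition_prob_stay1",
    "transition_matrix",
    "structural_step",
    "log_prior_density",
]


def stay_logit(switch: SwitchParams, eta1_prev: np.ndarray,
               eta2: np.ndarray | float) -> np.ndarray:
    """Linear predictor nu of staying in state 1, vectorized over persons.

    ``eta1_prev`` has shape (..., J); ``eta2`` broadcasts against the leading
    axes.  nu = gamma1 + gamma2*eta2 + gamma3'eta1_prev + gamma4'(eta1_prev*eta2).
    """
    eta1_prev = np.asarray(eta1_prev, dtype=float)
    eta2 = np.asarray(eta2, dtype=float)
    nu = (switch.gamma1
          + switch.gamma2 * eta2
          + eta1_prev @ switch.gamma3
          + (eta1_prev @ switch.gamma4) * eta2)
    return nu


def transition_prob_stay1(switch: SwitchParams, eta1_prev: np.ndarray,
                          eta2: float) -> float | np.ndarray:
    """P(S_t = 1 | S_{t-1} = 1): logistic in the lagged latent variables.

    Computed through :func:`scipy.special.expit`, which is overflow-safe for
    arbitrarily large |nu|.  Raises on non-finite inputs, naming the offending
    position.
    """
    eta1_prev = np.asarray(eta1_prev, dtype=float)
    if not np.all(np.isfinite(eta1_prev)):
        idx = tuple(int(k) for k in np.argwhere(~np.isfinite(eta1_prev))[0])
        raise ValueError(f"non-finite eta1_prev at index {idx}")
    if not np.all(np.isfinite(eta2)):
        raise ValueError("non-finite eta2")
    p = special.expit(stay_logit(switch, eta1_prev, eta2))
    return float(p) if np.ndim(p) == 0 else p


def transition_matrix(switch: SwitchParams, eta1_prev: np.ndarray,
                      eta2: float) -> np.ndarray:
    """2 x 2 row-stochastic transition matrix at one person-occasion.

    Row 1 is the logistic stay/leave split out of state 1; row 2 is the
    constant return probability (p12, 1 - p12).
    """
    if not 0.0 <= switch.p12 <= 1.0:
        raise ValueError(f"p12 must be a probability, got {switch.p12}")
    p11 = transition_prob_stay1(switch, eta1_prev, eta2)
    return np.array([[p11, 1.0 - p11], [switch.p12, 1.0 - switch.p12]])


def structural_step(dyn: DynamicsParams, eta1_prev: np.ndarray,
                    eta2: float, zeta2_i: np.ndarray, s: int) -> np.ndarray:
    """Conditional mean of eta1 at t given the previous occasion and state s.

    alpha_{1is} + B_{1is} eta1_{i,t-1}, where alpha_{1is} = alpha21_s +
    beta2_s * eta2_i + zeta2_i and B_{1is} = diag(b1_s + omega2_s * eta2_i).
    """
    if s not in (1, 2):
        raise ValueError(f"state must be 1 or 2, got {s}")
    eta1_prev = np.asarray(eta1_prev, dtype=float)
    zeta2_i = np.asarray(zeta2_i, dtype=float)
    if eta1_prev.shape != dyn.alpha21.shape or zeta2_i.shape != dyn.alpha21.shape:
        raise ValueError("eta1_prev/zeta2 dimension mismatch with parameters")
    intercept = dyn.alpha21_state(s) + dyn.beta2_state(s) * eta2 + zeta2_i
    slope = dyn.b1_state(s) + dyn.omega2_state(s) * eta2
    return intercept + slope * eta1_prev


def _log_tn01_pos(x: np.ndarray) -> float:
    """Log density of TN(0, 1, 0, inf): standard normal doubled on (0, inf)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x < 0):
        return -math.inf
    return float(np.sum(stats.norm.logpdf(x) - math.log(0.5)))


def _log_gamma_on_precision(sigma2: np.ndarray, shape: float, rate: float) -> float:
    """Gamma(shape, rate) log density evaluated at the precision 1/sigma2."""
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    if np.any(sigma2 <= 0):
        return -math.inf
    tau = 1.0 / sigma2
    return float(np.sum(stats.gamma.logpdf(tau, a=shape, scale=1.0 / rate)))


def log_prior_density(params: ModelParams, prior: PriorSpec,
                      dims: ModelDims) -> float:
    """Joint log prior of all free parameters; -inf outside the support.

    Precisions are evaluated on the precision scale (the Gamma prior is a
    prior over 1/sigma^2; no Jacobian is applied).  Fixed quantities (scaling
    loadings, masked gamma4 entries) contribute nothing.
    """
    m, d, g = params.measurement, params.dynamics, params.switching
    free1 = np.setdiff1d(np.arange(dims.n_items_within), dims.scaling_items)
    total = 0.0
    # loadings: truncated normal on (0, inf)
    total += _log_tn01_pos(m.lambda1[free1] / prior.loading_sd) \
        - free1.size * math.log(prior.loading_sd)
    total += _log_tn01_pos(m.lambda2[1:] / prior.loading_sd) \
        - (m.lambda2.size - 1) * math.log(prior.loading_sd)
    # state-2 level shift: censored at zero
    total += _log_tn01_pos(d.delta_alpha21 / prior.dalpha_sd) \
        - d.delta_alpha21.size * math.log(prior.dalpha_sd)
    # unconstrained coefficients: independent normals
    coefs = np.concatenate([
        d.alpha21, d.beta2, d.delta_beta2, d.b1, d.delta_b1,
        d.omega2, d.delta_omega2,
        [g.gamma1, g.gamma2], g.gamma3, g.gamma4[g.gamma4_mask],
    ])
    total += float(np.sum(stats.norm.logpdf(coefs, scale=prior.coef_sd)))
    # precisions
    for sig in (m.sigma2_eps1, m.sigma2_eps2, [m.sigma2_eta2],
                d.sigma2_zeta1, d.sigma2_zeta2):
        total += _log_gamma_on_precision(np.asarray(sig),
                                         prior.precision_shape,
                                         prior.precision_rate)
    # return probability: uniform on [p12_lower, p12_upper]
    if not prior.p12_lower <= g.p12 <= prior.p12_upper:
        return -math.inf
    total += -math.log(prior.p12_upper - prior.p12_lower)
    return total
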