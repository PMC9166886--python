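# Methods

## The model

`ndlcsem` implements a two-level dynamic factor model with a hidden two-state
Markov regime, of the kind used to describe intensive longitudinal data (ILD)
from, e.g., thrice-weekly affect surveys of university students at risk of
dropping out.  Persons `i = 1..N1` are measured at occasions `t = 0..T-1`.

**Within-level measurement.** `p` centered items load on `J` latent
affective/cognitive state factors with simple structure (each item loads on
exactly one factor; the first item per factor is the scaling item with its
loading fixed to 1):

    Y1_it = Lambda1 eta1_it + eps1_it,   eps1 ~ N(0, diag(sigma2_eps1)).

Residuals are uncorrelated with each other and the factors, within and across
time; the measurement model is regime-invariant.

**Between-level measurement.** `q` baseline items measure one stable trait
factor (e.g., cognitive ability), `Y2_i = Lambda2 eta2_i + eps2_i` with
`eta2 ~ N(0, sigma2_eta2)` and the first loading fixed to 1.

**Within-level structure.** Given the regime `S_it = s` in {1, 2}, each
factor follows a diagonal AR(1) with person-specific random intercepts and
trait-moderated coefficients:

    eta1_it = alpha_{1is} + B_{1is} eta1_{i,t-1} + zeta1_it
    alpha_{1is} = alpha21_s + beta2_s eta2_i + zeta2_i
    B_{1is}     = diag(b1_s + omega2_s eta2_i)

`zeta1 ~ N(0, diag(sigma2_zeta1))` (regime-invariant), `zeta2_i ~ N(0,
diag(sigma2_zeta2))`.  The state-2 parameters are stored as state-1 values
plus shifts; the level shift `delta_alpha21 >= 0` is censored at zero, which
both identifies the regime labels (state 2 = uniformly higher levels, the
"intention to quit" regime) and prevents label switching in the sampler
without any relabeling pass.

**Markov switching.**  Out of state 1, the stay probability is logistic in
the lagged latent states and their interaction with the trait factor,

    P(S_t=1 | S_{t-1}=1) = expit(gamma1 + gamma2 eta2 + gamma3' eta1_{t-1}
                                 + gamma4' eta1_{t-1} eta2),

with `gamma4` nonzero only for designated self-regulatory factors (a mask;
with seven factors the three designated ones, with fewer factors a single
one).  The return probability out of state 2 is a single constant `P12` with
a Uniform(0, 0.1) prior: once a person forms the intention, a quick return is
a priori implausible.  All paths start in state 1.  Where a manifest dropout
is recorded, the path is observed (fixed at 2) from the dropout occasion
onward and latent elsewhere.

**Priors.**  Free loadings and `delta_alpha21`: TN(0, 1, 0, inf); all other
regression coefficients: N(0, 1); all precisions: Gamma(9, 4) (prior mean
2.25, i.e., residual variances around 0.45); `P12 ~ U(0, 0.1)`.  Every
hyperparameter is overridable through `PriorSpec`.

## Estimation

The Gibbs sampler (`ndlcsem.gibbs.fit`) is a native implementation; no
external MCMC engine is used.  All full conditionals are exact conjugate
draws except where the logistic switching likelihood intervenes:

* loadings: truncated-normal; residual/innovation precisions: Gamma;
  structural coefficients: scalar normal (truncated for the level shift);
  random effects and the between factor's Gaussian part: normal.
* `eta1` (per occasion, vectorized over persons) and `eta2` use an
  independence Metropolis proposal drawn from their exact Gaussian part and
  accepted on the switching-likelihood ratio alone; with switching disabled
  they are exact Gibbs draws.
* `gamma`: per-coefficient Gaussian random walks (default step 0.15) on the
  Bernoulli stay/leave likelihood of all transitions out of state 1.
* `P12`: the conditional under the uniform prior is Beta(returns+1, stays+1)
  truncated to [0, 0.1]; drawn exactly by inverse-CDF.  (An exact draw
  dominates a Metropolis step here at no cost.)
* state paths: drawn jointly per person by discrete forward-backward, with
  emissions given by the state-specific structural densities of the realized
  factor scores and the logistic/constant transition matrices; `S_0 = 1` and
  the observed dropout mask are hard constraints.
* missing within-level responses are imputed from the measurement model at
  the start of each sweep (missing at random).

Initialization: parameters at prior medians, latent scores at 0 plus a small
chain-specific Gaussian jitter, states at 1 (2 where observed).  Chains
differ only by seed.  Defaults are 2 chains x 10,000 iterations with 5,000
burn-in (simulation-study setting) and 4 x 30,000 / 25,000
(`MCMCConfig.full_analysis()`); thinning defaults to 1.  Mixing is assessed
with the split-chain potential scale reduction factor (`rhat`), flagged at
the conventional threshold 1.12.

Numerical choices: the occasion-0 factor scores get a fixed diffuse N(0, 2)
prior in the sampler (the simulator draws them from the state-1 stationary
law); using the stationary prior in estimation would couple the occasion-0
scores to the AR coefficient and innovation variance and break the exact
conjugacy of those updates, for a negligible gain with T >= 25.  Logistic
terms are computed with `log(sigmoid(nu)) = -log1p(exp(-nu))` style
expressions, safe for |nu| in the hundreds.

## Forecasting (FFBS)

Each factor is rewritten as a dynamic linear model with constant system
vector `theta_js = (alpha21_js, b1_js, beta2_js, omega2_js, 1)'`, design rows
`F_i = (1, eta1_{j,t-1}, eta2, eta1_{j,t-1} eta2, zeta2_j)`, quadruple
`{F, I_5, sigma2_zeta1j I_N1, 0}`.  Between consecutive occasions the regime
transition lies in one of four strata `(s, s')`; a DLM filter (prior
`m0 = 0`, `C0 = I`, weakly informative) is carried per stratum.

The pass is fully integrated with estimation: it runs per retained posterior
draw, using that draw's parameters, factor scores, random effects and state
path, and the retained draws enter all summaries with equal weight.

One design point deserves emphasis.  The quadruple is regime-invariant, so a
completely literal stratified recursion — four identically initialized
filters updated with identical inputs — would keep the four strata equal
forever and the stratum likelihood terms would cancel out of the probability
update.  In this implementation each stratum's `(m, C)` update therefore
uses the persons whose *drawn* transition at that occasion falls in that
stratum, so the stratum filters track their own regime's coefficients, while
the per-person probability update evaluates every stratum's one-step
predictive for every person (the normalized product of transition
probability, previous state posterior and predictive density, computed in
log space).  With all mass in one stratum this reduces exactly to the plain
DLM recursion, which is verified against an independent brute-force
implementation to 1e-10.

Per-person stratum probabilities multiply the per-factor predictive
likelihood terms across factors by default (conditional independence given
the state); a per-factor mode is available (`per_factor=True`) for exact
fidelity to the per-factor presentation of the update.

**H-step forecasts.**  With identity evolution and zero system noise the
state forecast `(a, R)` equals the filtered `(m, C)` at the forecast origin
for every horizon; only the design matrix changes.  Per draw and horizon the
forecaster (i) computes stratum transition probabilities from the current
lagged factors, (ii) forms the per-stratum normal forecast of each factor,
(iii) samples one stratum per person and the next lagged factor values from
it (so sampled trajectories, not plugged-in means, feed the next horizon —
this is what makes the intervals widen with the horizon), and (iv)
propagates the person's state distribution through the transition model.
Forecast intervals (default 95%, configurable) are numerical quantiles of
the pooled normal mixture across strata and draws; forecast state
probabilities average the propagated state distributions across draws.
Random effects enter as the sampled per-person values; the
marginalized-random-effects variant is out of scope.

The moment-matched collapse of the four-component posterior to one normal
per current state is implemented (`ndlcsem.ffbs.collapse`) but not used in
the default pipeline, matching the procedure the algorithm derives from.

## Synthetic data and the simulation design

The generator (`ndlcsem.simulate`) forward-simulates the full generative
process: trait factor and random effects, then jointly the state path and
factor trajectories (the state at `t` is drawn from the transition matrix
evaluated at the lagged factors), then the item responses.  Occasion-0
factor scores come from the state-1 stationary law.

The study design is the crossed `{25, 50} persons x {25, 50} occasions`
grid with a 10-occasion forecast holdout.  Replication-level parameters are
drawn from independent normals around population values with rejection at
the support boundaries.  The appendix table of population values used by the
original study is not part of the available text, so the shipped table
(`src/ndlcsem/data/population_params.json`) was fixed once from the printed
empirical summaries: positive AR coefficients (0.35) that strengthen under
the quit-intention regime (+0.10), a clear nonnegative level shift (1.0),
negative trait main effects (-0.2), small cross-level interactions, residual
variances around 0.4, innovation and random-effect variances of 0.2 (giving
within-person ICCs in the reported 0.5-0.7 range), a stay logit intercept of
3.0 (a baseline switch hazard near 5% per occasion), negative lagged-factor
effects (-0.4), and a return probability centered at 0.08 (the reported
estimate was 0.097, and the prior support ends at 0.1).  Reproduction of the
original table is therefore approximate by construction.

Manifest dropout: persons in state 2 at the end of the observed window show
an observed dropout with probability 0.5 (roughly half of the empirically
reported state-2 members had actually dropped out); the tail from the start
of their final state-2 run is then marked observed and the state held at 2
(manifest dropout is absorbing).  Missingness in the simulator is completely
at random (default rate 0: the study design is silent on missingness; the
sampler itself handles missing-at-random data by imputation).

What the generator does *not* emulate: informative missingness (real survey
nonresponse correlates with the very states being measured), irregular
spacing, measurement non-invariance across regimes, and cross-factor
residual correlation.  Passing tests therefore show internal consistency of
estimation and forecasting under the model's own assumptions, not robustness
to these violations.

## Evaluation metrics

* Sensitivity/specificity of state extraction, counted at person-occasion
  cell level (chosen because the reported table splits by time windows),
  over three windows: all occasions, the observed window, and the forecast
  window.  Predicted state = posterior (or forecast) probability of state 2
  above 0.5, strict.
* 95% forecast-interval coverage of the true held-out factor scores,
  averaged across persons, factors and forecast occasions (forecast horizons
  only; the observed window has no forecast intervals).
* Quadratic score `delta_h = sum_ij (etahat_ijh - eta_ijh)^2` per horizon,
  with the predictive mean as the point forecast.
* Mean forecast-interval width per horizon.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the study at reduced size —
2-3 replications per condition with 2 chains x 600 iterations (300 burn-in),
20 stored draws per fit — which the package treats as its smoke-test
configuration of the same pipeline; the full-size configuration is a
parameter change (`SimDesign(n_replications=100)`,
`MCMCConfig(n_iter=10_000, n_burnin=5_000)`).  Parameter-recovery checks use
five replications at the largest condition with generating values fixed at
the population means.

## Known limitations

* Cross-condition comparisons at 2-3 replications are noisy; single
  replications with an unlucky parameter draw can dominate condition means
  of `delta_h`.
* The gamma random-walk step is fixed, not adapted; mixing of the switching
  coefficients is adequate at the study sizes but slow for much longer
  series.
* Only two regimes, diagonal AR matrices and diagonal residual covariances
  are supported, matching the model's scope.
* Time-varying DLM quadruples (general `G_t`, `V_t`, `W_t`) are not
  implemented; the model at hand has the constant case only.
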