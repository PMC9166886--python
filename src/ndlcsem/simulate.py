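"""Synthetic-data generation from the regime-switching dynamic factor model.

The generator forward-simulates the full generative process: a between-level
factor and random effects per person, then jointly the discrete state path and
the within-level AR(1) factor trajectories (the state at t is drawn from the
transition matrix driven by the lagged factors), and finally the item
responses of both levels.  The simulation design mirrors a small Monte Carlo
study: crossed conditions of persons x occasions, a forecast holdout block,
and replication-level parameters drawn around population values.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import panel_io
from .model import structural_step, transition_prob_stay1
from .params import (DynamicsParams, LatentState, MeasurementParams, ModelDims,
                     ModelParams, ObservedPanel, SwitchParams)

__all__ = [
    "SimDesign",
    "default_gamma4_mask",
    "load_population_table",
    "draw_replication_params",
    "simulate_panel",
    "inject_dropout_observations",
    "run_design",
]

logger = logging.getLogger(__name__)

_MAX_REJECTIONS = 1000


def default_gamma4_mask(n_factors: int) -> np.ndarray:
    """Which factors carry a cross-level interaction in the transition logit.

    In the seven-factor layout the three designated self-regulatory factors
    (indices 1, 2, 4) interact with the between factor; in smaller layouts a
    single factor (the last) is marked.
    """
    mask = np.zeros(n_factors, dtype=bool)
    if n_factors >= 7:
        mask[[1, 2, 4]] = True
    else:
        mask[n_factors - 1] = True
    return mask


def load_population_table(path: Path | str | None = None) -> dict:
    """Load the population mean/sd table (shipped defaults unless a path given)."""
    if path is None:
        ref = importlib.resources.files("ndlcsem") / "data" / "population_params.json"
        table = json.loads(ref.read_text())
    else:
        table = json.loads(Path(path).read_text())
    return {k: v for k, v in table.items() if not k.startswith("_")}


@dataclass
class SimDesign:
    """A simulation-study design: conditions, replications, population values.

    Parameters
    ----------
    conditions
        (n_persons, n_occasions) pairs; default is the crossed
        {25, 50} x {25, 50} design.
    horizon
        Held-out forecast occasions generated beyond ``n_occasions``.
    n_replications
        Data sets per condition.
    population
        Mapping parameter-group -> {"mean": .., "sd": ..} used for the
        replication-level draws; defaults to the shipped table.
    missing_rate
        Fraction of within-level responses masked completely at random.
    dropout_prob
        Probability that a person ending the observed window in state 2 shows
        a manifest (observed) dropout.
    """

    conditions: list[tuple[int, int]] = field(
        default_factory=lambda: [(25, 25), (25, 50), (50, 25), (50, 50)])
    horizon: int = 10
    n_replications: int = 100
    population: dict | None = None
    missing_rate: float = 0.0
    dropout_prob: float = 0.5
    n_factors: int = 3
    items_per_factor: int = 3
    n_items_between: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_replications < 1:
            raise ValueError("n_replications must be positive")
        if self.population is None:
            self.population = load_population_table()

    def dims(self, n_persons: int, n_occasions: int) -> ModelDims:
        return ModelDims(n_persons=n_persons, n_occasions=n_occasions,
                         horizon=self.horizon, n_factors=self.n_factors,
                         items_per_factor=self.items_per_factor,
                         n_items_between=self.n_items_between)


def _draw_constrained(rng: np.random.Generator, mean: float, sd: float,
                      size: int, check, name: str) -> tuple[np.ndarray, int]:
    """Draw i.i.d. normals with rejection until the support check passes."""
    if sd == 0.0:
        vals = np.full(size, mean)
        if not np.all(check(vals)):
            raise ValueError(
                f"population mean for {name} violates its support "
                f"(mean={mean}, sd={sd})")
        return vals, 0
    out = np.empty(size)
    rejections = 0
    for k in range(size):
        for attempt in range(_MAX_REJECTIONS + 1):
            v = rng.normal(mean, sd)
            if check(np.asarray([v]))[0]:
                out[k] = v
                rejections += attempt
                break
        else:
            raise ValueError(
                f"more than {_MAX_REJECTIONS} consecutive rejections drawing "
                f"{name} from N({mean}, {sd}^2)")
    return out, rejections


def draw_replication_params(design: SimDesign, rng_seed: int,
                            dims: ModelDims | None = None) -> ModelParams:
    """Draw one replication's generating parameters around population values.

    Every constrained parameter (positive loadings and variances, nonnegative
    state-2 level shifts, the return probability on [0, 0.1]) is redrawn until
    it satisfies its support; the total redraw count is logged.
    """
    rng = np.random.default_rng(rng_seed)
    if dims is None:
        dims = design.dims(*design.conditions[0])
    pop = design.population
    J, p, q = dims.n_factors, dims.n_items_within, dims.n_items_between
    pos = lambda x: x > 0
    anyv = lambda x: np.isfinite(x)
    nonneg = lambda x: x >= 0
    unit_interval = lambda x: (x >= 0.0) & (x <= 0.1)

    total_rej = 0

    def draw(name: str, size: int, check) -> np.ndarray:
        nonlocal total_rej
        vals, rej = _draw_constrained(rng, pop[name]["mean"], pop[name]["sd"],
                                      size, check, name)
        total_rej += rej
        return vals

    lam1 = np.ones(p)
    free1 = np.setdiff1d(np.arange(p), dims.scaling_items)
    lam1[free1] = draw("lambda1", free1.size, pos)
    lam2 = np.ones(q)
    lam2[1:] = draw("lambda2", q - 1, pos)
    meas = MeasurementParams(
        lambda1=lam1,
        sigma2_eps1=draw("sigma2_eps1", p, pos),
        lambda2=lam2,
        sigma2_eps2=draw("sigma2_eps2", q, pos),
        sigma2_eta2=float(draw("sigma2_eta2", 1, pos)[0]),
    )
    dyn = DynamicsParams(
        alpha21=draw("alpha21", J, anyv),
        delta_alpha21=draw("delta_alpha21", J, nonneg),
        beta2=draw("beta2", J, anyv),
        delta_beta2=draw("delta_beta2", J, anyv),
        b1=draw("b1", J, anyv),
        delta_b1=draw("delta_b1", J, anyv),
        omega2=draw("omega2", J, anyv),
        delta_omega2=draw("delta_omega2", J, anyv),
        sigma2_zeta1=draw("sigma2_zeta1", J, pos),
        sigma2_zeta2=draw("sigma2_zeta2", J, pos),
    )
    mask = default_gamma4_mask(J)
    gamma4 = np.zeros(J)
    gamma4[mask] = draw("gamma4", int(mask.sum()), anyv)
    sw = SwitchParams(
        gamma1=float(draw("gamma1", 1, anyv)[0]),
        gamma2=float(draw("gamma2", 1, anyv)[0]),
        gamma3=draw("gamma3", J, anyv),
        gamma4=gamma4,
        gamma4_mask=mask,
        p12=float(draw("p12", 1, unit_interval)[0]),
    )
    if total_rej:
        logger.info("replication parameter draw needed %d redraws", total_rej)
    params = ModelParams(measurement=meas, dynamics=dyn, switching=sw)
    params.validate(dims)
    return params


def _stationary_state1(params: ModelParams, eta2: np.ndarray,
                       zeta2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the state-1 stationary AR(1) law, per person/factor."""
    d = params.dynamics
    slope = d.b1[None, :] + d.omega2[None, :] * eta2[:, None]
    intercept = d.alpha21[None, :] + d.beta2[None, :] * eta2[:, None] + zeta2
    stationary = np.abs(slope) < 1.0
    mean = np.where(stationary, intercept / np.where(stationary, 1.0 - slope, 1.0),
                    intercept)
    var = np.where(stationary,
                   d.sigma2_zeta1[None, :] / np.clip(1.0 - slope ** 2, 1e-12, None),
                   d.sigma2_zeta1[None, :])
    return mean, var


def simulate_panel(params: ModelParams, dims: ModelDims,
                   missing_rate: float = 0.0, seed: int = 0,
                   ) -> tuple[ObservedPanel, LatentState]:
    """Forward-simulate one panel (observed window plus forecast holdout).

    Returns the observed panel (missingness applied completely at random) and
    the full latent truth.  Dropout observation of the state path is injected
    separately by :func:`inject_dropout_observations`.
    """
    params.validate(dims)
    rng = np.random.default_rng(seed)
    n1, J, T = dims.n_persons, dims.n_factors, dims.n_total_occasions
    d, m, g = params.dynamics, params.measurement, params.switching

    eta2 = rng.normal(0.0, np.sqrt(m.sigma2_eta2), size=n1)
    zeta2 = rng.normal(0.0, np.sqrt(d.sigma2_zeta2)[None, :], size=(n1, J))

    eta1 = np.zeros((n1, J, T))
    S = np.ones((n1, T), dtype=int)
    mu0, var0 = _stationary_state1(params, eta2, zeta2)
    eta1[:, :, 0] = rng.normal(mu0, np.sqrt(var0))

    sd1 = np.sqrt(d.sigma2_zeta1)
    for t in range(1, T):
        p11 = transition_prob_stay1(g, eta1[:, :, t - 1], eta2)
        u = rng.random(n1)
        prev2 = S[:, t - 1] == 2
        # out of state 1: stay w.p. p11; out of state 2: return w.p. p12
        stay1 = (~prev2) & (u < p11)
        return1 = prev2 & (u < g.p12)
        S[:, t] = np.where(stay1 | return1, 1, 2)
        for s in (1, 2):
            sel = S[:, t] == s
            if not np.any(sel):
                continue
            intercept = (d.alpha21_state(s)[None, :]
                         + d.beta2_state(s)[None, :] * eta2[sel, None]
                         + zeta2[sel])
            slope = (d.b1_state(s)[None, :]
                     + d.omega2_state(s)[None, :] * eta2[sel, None])
            mean = intercept + slope * eta1[sel, :, t - 1]
            eta1[sel, :, t] = mean + rng.normal(0.0, sd1[None, :],
                                                size=(int(sel.sum()), J))

    lam_mat = m.loading_matrix(dims)                       # (p, J)
    y1 = np.einsum("pj,ijt->ipt", lam_mat, eta1)
    y1 += rng.normal(0.0, np.sqrt(m.sigma2_eps1)[None, :, None], size=y1.shape)
    if missing_rate > 0:
        y1[rng.random(y1.shape) < missing_rate] = np.nan
    y2 = eta2[:, None] * m.lambda2[None, :]
    y2 += rng.normal(0.0, np.sqrt(m.sigma2_eps2)[None, :], size=y2.shape)

    panel = ObservedPanel(y1=y1, y2=y2, dropout_time=np.full(n1, -1, dtype=int))
    latent = LatentState(eta1=eta1, eta2=eta2, zeta2=zeta2, S=S,
                         s_observed_mask=np.zeros((n1, T), dtype=bool))
    latent.validate()
    return panel, latent


def inject_dropout_observations(latent: LatentState, n_observed: int,
                                dropout_prob: float = 0.5,
                                seed: int = 0) -> LatentState:
    """Mark manifest dropouts: observed state-2 tails for a subset of persons.

    A person is eligible when their simulated path is in state 2 at the last
    observed occasion.  With probability ``dropout_prob`` the tail from the
    start of that final state-2 run onward is marked observed; the state is
    held at 2 there (manifest dropout is absorbing).  Returns a new
    :class:`LatentState`; the input is not modified.
    """
    rng = np.random.default_rng(seed)
    S = latent.S.copy()
    mask = latent.s_observed_mask.copy()
    n1, T = S.shape
    for i in range(n1):
        if S[i, n_observed - 1] != 2:
            continue
        if rng.random() >= dropout_prob:
            continue
        # start of the final contiguous state-2 run within the observed window
        t = n_observed - 1
        while t > 0 and S[i, t - 1] == 2:
            t -= 1
        mask[i, t:] = True
        S[i, t:] = 2
    out = LatentState(eta1=latent.eta1, eta2=latent.eta2, zeta2=latent.zeta2,
                      S=S, s_observed_mask=mask)
    out.validate()
    return out


def dropout_times_from_mask(latent: LatentState) -> np.ndarray:
    """First observed occasion per person (-1 where never observed)."""
    n1, T = latent.S.shape
    any_obs = latent.s_observed_mask.any(axis=1)
    first = np.where(any_obs, latent.s_observed_mask.argmax(axis=1), -1)
    return first.astype(int)


def run_design(design: SimDesign, out_dir: Path | str) -> pd.DataFrame:
    """Generate and write every (condition, replication) panel plus truth.

    Per-replication seeds are derived reproducibly from the design's master
    seed via :class:`numpy.random.SeedSequence`.  Returns (and writes) the
    manifest listing file prefixes and seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    master = np.random.SeedSequence(design.seed)
    children = master.spawn(len(design.conditions) * design.n_replications)
    k = 0
    for (n1, nt) in design.conditions:
        dims = design.dims(n1, nt)
        for r in range(design.n_replications):
            child = children[k]
            k += 1
            param_seed, panel_seed, drop_seed = [
                int(s.generate_state(1)[0] % (2 ** 31)) for s in child.spawn(3)]
            params = draw_replication_params(design, param_seed, dims)
            panel, latent = simulate_panel(params, dims, design.missing_rate,
                                           panel_seed)
            latent = inject_dropout_observations(latent, dims.n_occasions,
                                                 design.dropout_prob, drop_seed)
            panel.dropout_time = dropout_times_from_mask(latent)
            prefix = out_dir / f"panel_N{n1}_T{nt}_r{r}"
            panel_io.write_panel(panel, prefix, n_observed=nt)
            truth_path = out_dir / f"truth_N{n1}_T{nt}_r{r}.csv"
            panel_io.write_truth(latent, truth_path)
            params.to_json(out_dir / f"params_N{n1}_T{nt}_r{r}.json")
            rows.append({
                "n_persons": n1, "n_occasions": nt, "horizon": design.horizon,
                "replication": r, "param_seed": param_seed,
                "panel_seed": panel_seed, "dropout_seed": drop_seed,
                "panel_prefix": str(prefix), "truth_path": str(truth_path),
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
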