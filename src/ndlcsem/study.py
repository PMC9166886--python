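"""End-to-end replication driver: simulate -> fit -> forecast -> evaluate.

Reproduces the Monte Carlo study design: for each (persons x occasions)
condition, replications draw generating parameters around population values,
simulate a panel with a forecast holdout block, fit the model on the observed
window, forecast the holdout with the FFBS pass and score the result.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import panel_io
from .evaluate import EvalReport, aggregate_table, evaluate_replication
from .ffbs import forecast_from_draws, forecast_states
from .gibbs import MCMCConfig, PosteriorDraws, fit
from .params import ModelDims, ObservedPanel
from .simulate import (SimDesign, draw_replication_params, simulate_panel,
                       inject_dropout_observations, dropout_times_from_mask)

__all__ = ["ReplicationResult", "run_replication", "run_study", "predicted_states"]

logger = logging.getLogger(__name__)


def predicted_states(draws: PosteriorDraws, forecast, threshold: float = 0.5,
                     ) -> np.ndarray:
    """Classified states over observed + forecast occasions.

    Observed window: posterior P(S=2) from the stored Gibbs state paths;
    forecast window: FFBS forecast state probabilities.  Both thresholded at
    ``threshold`` (strict).
    """
    obs = forecast_states(draws.state_prob2(), threshold)
    fc = forecast_states(forecast.p_state2, threshold)
    return np.concatenate([obs, fc], axis=1)


@dataclass
class ReplicationResult:
    report: EvalReport
    draws: PosteriorDraws
    forecast: object
    true_S: np.ndarray
    predicted_S: np.ndarray


def run_replication(design: SimDesign, n_persons: int, n_occasions: int,
                    mcmc: MCMCConfig, seed: int,
                    threshold: float = 0.5, level: float = 0.95,
                    ) -> ReplicationResult:
    """One full simulate/fit/forecast/evaluate cycle at one condition."""
    dims = design.dims(n_persons, n_occasions)
    ss = np.random.SeedSequence(seed)
    param_seed, panel_seed, drop_seed, fit_seed, fc_seed = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]
    params = draw_replication_params(design, param_seed, dims)
    panel, latent = simulate_panel(params, dims, design.missing_rate, panel_seed)
    latent = inject_dropout_observations(latent, dims.n_occasions,
                                         design.dropout_prob, drop_seed)
    panel.dropout_time = dropout_times_from_mask(latent)
    draws = fit(panel, dims,
                config=MCMCConfig(**{**mcmc.__dict__, "seed": fit_seed}))
    forecast = forecast_from_draws(draws, dims, dims.horizon, level=level,
                                   seed=fc_seed)
    pred = predicted_states(draws, forecast, threshold)
    report = evaluate_replication(
        latent.S, pred, dims.n_occasions, forecast,
        latent.eta1[:, :, dims.n_occasions:])
    return ReplicationResult(report=report, draws=draws, forecast=forecast,
                             true_S=latent.S, predicted_S=pred)


def run_study(design: SimDesign, mcmc: MCMCConfig,
              out_dir: Path | str | None = None,
              keep_results: bool = False,
              ) -> tuple[pd.DataFrame, list[EvalReport]]:
    """Run every (condition, replication), aggregating the metric battery.

    Per-replication seeds derive from the design's master seed.  When
    ``out_dir`` is given, finished replications are checkpointed as JSON and
    re-runs resume from the checkpoints; failures are logged, counted and
    excluded from the aggregate.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(design.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in master.spawn(len(design.conditions) * design.n_replications)]
    reports: list[EvalReport] = []
    results: list[ReplicationResult] = []
    failures = 0
    k = 0
    for (n1, nt) in design.conditions:
        for r in range(design.n_replications):
            seed = seeds[k]
            k += 1
            ckpt = (out_dir / f"report_N{n1}_T{nt}_r{r}.json"
                    if out_dir is not None else None)
            if ckpt is not None and ckpt.exists():
                reports.append(_report_from_json(ckpt))
                logger.info("resumed N1=%d Nt=%d rep=%d from checkpoint",
                            n1, nt, r)
                continue
            try:
                res = run_replication(design, n1, nt, mcmc, seed)
            except Exception:
                failures += 1
                logger.exception("replication failed: N1=%d Nt=%d rep=%d seed=%d",
                                 n1, nt, r, seed)
                continue
            reports.append(res.report)
            if keep_results:
                results.append(res)
            if ckpt is not None:
                _report_to_json(res.report, seed, ckpt)
            logger.info("done N1=%d Nt=%d rep=%d seed=%d", n1, nt, r, seed)
    if failures:
        logger.warning("%d replication(s) failed and were excluded", failures)
    table = aggregate_table(reports)
    if out_dir is not None:
        table.to_csv(out_dir / "summary.csv", index=False)
    return table, (results if keep_results else reports)


def _report_to_json(report: EvalReport, seed: int, path: Path) -> None:
    row = report.to_row()
    row["seed"] = seed
    path.write_text(json.dumps(row, indent=1))


def _report_from_json(path: Path) -> EvalReport:
    row = json.loads(path.read_text())
    H = max(int(k.split("delta_h")[1]) for k in row if k.startswith("delta_h"))
    return EvalReport(
        n_persons=row["n_persons"], n_occasions=row["n_occasions"],
        sensitivity={w: row[f"sensitivity_{w}"] for w in ("overall", "observed", "forecast")},
        specificity={w: row[f"specificity_{w}"] for w in ("overall", "observed", "forecast")},
        coverage95=row["coverage95"],
        delta_h=np.array([row[f"delta_h{h}"] for h in range(1, H + 1)]),
        fi_width=np.array([row[f"fi_width_h{h}"] for h in range(1, H + 1)]))
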