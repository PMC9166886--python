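"""Simulation-study metrics: state extraction, forecast score, coverage, widths.

Confusion rates are counted at the person-occasion cell level; the windows
"overall" / "observed" / "forecast" restrict the occasions entering the
counts.  The quadratic score delta_h sums squared forecast errors of the
latent factor scores over persons and factors at each forecast horizon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvalReport", "confusion_rates", "score_function", "interval_coverage",
    "aggregate_table", "evaluate_replication",
]

logger = logging.getLogger(__name__)

WINDOWS = ("overall", "observed", "forecast")


def _window_slice(window: str, n_observed: int, n_total: int) -> slice:
    if window == "overall":
        return slice(0, n_total)
    if window == "observed":
        return slice(0, n_observed)
    if window == "forecast":
        return slice(n_observed, n_total)
    raise ValueError(f"unknown window {window!r}; expected one of {WINDOWS}")


def confusion_rates(true_S: np.ndarray, predicted_S: np.ndarray,
                    window: str = "overall", n_observed: int | None = None,
                    ) -> tuple[float | None, float | None]:
    """Sensitivity and specificity of state-2 extraction over a time window.

    Sensitivity: correctly predicted state-2 cells / true state-2 cells.
    Specificity: analogous for state 1.  A window without true positives (or
    negatives) leaves the corresponding rate undefined (returned as None).
    """
    true_S = np.asarray(true_S)
    predicted_S = np.asarray(predicted_S)
    if true_S.shape != predicted_S.shape:
        raise ValueError("true and predicted state arrays must align")
    if n_observed is None:
        n_observed = true_S.shape[1]
    sl = _window_slice(window, n_observed, true_S.shape[1])
    t, p = true_S[:, sl], predicted_S[:, sl]
    n_pos = np.sum(t == 2)
    n_neg = np.sum(t == 1)
    sens = float(np.sum((t == 2) & (p == 2)) / n_pos) if n_pos else None
    spec = float(np.sum((t == 1) & (p == 1)) / n_neg) if n_neg else None
    return sens, spec


def score_function(eta_hat: np.ndarray, eta_true: np.ndarray) -> float:
    """Quadratic score at one horizon: sum_i sum_j (etahat_ij - eta_ij)^2."""
    eta_hat = np.asarray(eta_hat, float)
    eta_true = np.asarray(eta_true, float)
    if eta_hat.shape != eta_true.shape:
        raise ValueError(
            f"shape mismatch: {eta_hat.shape} vs {eta_true.shape}")
    return float(np.sum((eta_hat - eta_true) ** 2))


def interval_coverage(lower: np.ndarray, upper: np.ndarray,
                      eta_true: np.ndarray) -> float:
    """Fraction of cells whose true factor score lies inside its interval.

    Averaged uniformly across all cells (time points, persons and factors).
    Zero-width intervals count as non-covering and trigger a warning.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    eta_true = np.asarray(eta_true, float)
    zero = upper <= lower
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-width forecast intervals "
                      "counted as non-covering")
    inside = (eta_true >= lower) & (eta_true <= upper) & ~zero
    return float(inside.mean())


@dataclass
class EvalReport:
    """One replication's metric battery."""

    n_persons: int
    n_occasions: int
    sensitivity: dict[str, float | None]
    specificity: dict[str, float | None]
    coverage95: float
    delta_h: np.ndarray          # (H,)
    fi_width: np.ndarray         # (H,) mean interval width per horizon

    def to_row(self) -> dict:
        row = {"n_persons": self.n_persons, "n_occasions": self.n_occasions,
               "coverage95": self.coverage95}
        for w in WINDOWS:
            row[f"sensitivity_{w}"] = self.sensitivity[w]
            row[f"specificity_{w}"] = self.specificity[w]
        for h, (d, fw) in enumerate(zip(self.delta_h, self.fi_width), start=1):
            row[f"delta_h{h}"] = d
            row[f"fi_width_h{h}"] = fw
        return row


def evaluate_replication(true_S: np.ndarray, predicted_S: np.ndarray,
                         n_observed: int, forecast, eta1_true: np.ndarray,
                         ) -> EvalReport:
    """Assemble the full metric battery for one fitted replication.

    ``forecast`` is a :class:`~ndlcsem.ffbs.ForecastOutput`; ``eta1_true``
    (N1, J, H) holds the held-out true factor scores; ``true_S``/
    ``predicted_S`` cover all occasions (observed plus forecast).
    """
    sens: dict[str, float | None] = {}
    spec: dict[str, float | None] = {}
    for w in WINDOWS:
        sens[w], spec[w] = confusion_rates(true_S, predicted_S, w, n_observed)
    H = forecast.mean.shape[2]
    delta = np.array([score_function(forecast.mean[:, :, h], eta1_true[:, :, h])
                      for h in range(H)])
    widths = (forecast.upper - forecast.lower).mean(axis=(0, 1))
    cov = interval_coverage(forecast.lower, forecast.upper, eta1_true)
    return EvalReport(n_persons=true_S.shape[0], n_occasions=n_observed,
                      sensitivity=sens, specificity=spec, coverage95=cov,
                      delta_h=delta, fi_width=widths)


def aggregate_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Condition-level means of every metric across replications.

    Rows are (n_persons, n_occasions) conditions; columns mirror the
    sensitivity/specificity windows plus coverage and the per-horizon
    score/interval-width series.  Empty conditions are simply absent.
    """
    if not reports:
        return pd.DataFrame()
    df = pd.DataFrame([r.to_row() for r in reports])
    return (df.groupby(["n_persons", "n_occasions"], as_index=False)
              .mean(numeric_only=True))
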