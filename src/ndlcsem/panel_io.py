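"""Delimited-text readers and writers for panels, truth files and draws.

All tabular artifacts are plain CSV with headers.  Occasions are written with
1-based labels; in memory everything is 0-based.  Missing within-level
responses are written as empty fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import LatentState, ModelDims, ObservedPanel

__all__ = [
    "write_panel", "read_panel", "write_truth", "read_truth",
    "save_draws", "load_draws",
]


def write_panel(panel: ObservedPanel, prefix: Path | str,
                n_observed: int | None = None) -> dict[str, Path]:
    """Write a panel as three CSVs: ``<prefix>_within/_between/_dropout.csv``.

    ``n_observed`` flags occasions up to it as "observed" and the rest as
    "holdout" (default: all observed).  Returns the role -> path mapping.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n1, p, T = panel.y1.shape
    if n_observed is None:
        n_observed = T
    person = np.repeat(np.arange(n1), p * T)
    item = np.tile(np.repeat(np.arange(p), T), n1)
    occ = np.tile(np.arange(1, T + 1), n1 * p)
    within = pd.DataFrame({
        "person_id": person, "occasion": occ, "item_id": item,
        "value": panel.y1.reshape(-1),
        "window": np.where(occ <= n_observed, "observed", "holdout"),
    })
    paths = {
        "within": prefix.with_name(prefix.name + "_within.csv"),
        "between": prefix.with_name(prefix.name + "_between.csv"),
        "dropout": prefix.with_name(prefix.name + "_dropout.csv"),
    }
    within.to_csv(paths["within"], index=False, na_rep="")
    q = panel.y2.shape[1]
    between = pd.DataFrame({
        "person_id": np.repeat(np.arange(n1), q),
        "item_id": np.tile(np.arange(q), n1),
        "value": panel.y2.reshape(-1),
    })
    between.to_csv(paths["between"], index=False)
    drop = pd.DataFrame({
        "person_id": np.arange(n1),
        "dropout_occasion": [t + 1 if t >= 0 else "" for t in panel.dropout_time],
    })
    drop.to_csv(paths["dropout"], index=False)
    return paths


def read_panel(prefix: Path | str) -> ObservedPanel:
    """Read a panel written by :func:`write_panel`."""
    prefix = Path(prefix)
    within_path = prefix.with_name(prefix.name + "_within.csv")
    try:
        within = pd.read_csv(within_path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed panel file {within_path}: {err}") from err
    required = {"person_id", "occasion", "item_id", "value"}
    if not required.issubset(within.columns):
        raise ValueError(f"{within_path} lacks columns {sorted(required - set(within.columns))}")
    n1 = int(within["person_id"].max()) + 1
    p = int(within["item_id"].max()) + 1
    T = int(within["occasion"].max())
    y1 = np.full((n1, p, T), np.nan)
    y1[within["person_id"], within["item_id"], within["occasion"] - 1] = within["value"]
    between = pd.read_csv(prefix.with_name(prefix.name + "_between.csv"))
    q = int(between["item_id"].max()) + 1
    y2 = np.zeros((n1, q))
    y2[between["person_id"], between["item_id"]] = between["value"]
    drop = pd.read_csv(prefix.with_name(prefix.name + "_dropout.csv"))
    dropout = np.full(n1, -1, dtype=int)
    occ = pd.to_numeric(drop["dropout_occasion"], errors="coerce")
    has = occ.notna()
    dropout[drop.loc[has, "person_id"].to_numpy()] = occ[has].astype(int) - 1
    return ObservedPanel(y1=y1, y2=y2, dropout_time=dropout)


def write_truth(latent: LatentState, path: Path | str) -> Path:
    """Write true factor scores and states: person_id, occasion, factor_id, eta1, S."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n1, J, T = latent.eta1.shape
    df = pd.DataFrame({
        "person_id": np.repeat(np.arange(n1), J * T),
        "occasion": np.tile(np.arange(1, T + 1), n1 * J),
        "factor_id": np.tile(np.repeat(np.arange(J), T), n1),
        "eta1": latent.eta1.reshape(-1),
        "S": np.repeat(latent.S, J, axis=0).reshape(-1),
    })
    df.to_csv(path, index=False)
    return path


def save_draws(draws, out_dir: Path | str) -> Path:
    """Write posterior draws as delimited text plus a JSON sidecar.

    Layout: ``trace.csv`` (chain, iteration, parameter, value), ``states.csv``
    (person_id, occasion, draw, S), ``latent_eta1.csv``, ``latent_person.csv``
    and ``meta.json`` (dims, config, stored parameter draws).
    """
    import json
    from dataclasses import asdict

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    draws.to_frame().to_csv(out_dir / "trace.csv", index=False)
    draws.states_frame().to_csv(out_dir / "states.csv", index=False)
    K, n1, J, T = draws.eta1.shape
    pd.DataFrame({
        "draw": np.repeat(np.arange(K), n1 * J * T),
        "person_id": np.tile(np.repeat(np.arange(n1), J * T), K),
        "factor_id": np.tile(np.repeat(np.arange(J), T), K * n1),
        "occasion": np.tile(np.arange(1, T + 1), K * n1 * J),
        "eta1": draws.eta1.reshape(-1),
    }).to_csv(out_dir / "latent_eta1.csv", index=False)
    person = pd.DataFrame({
        "draw": np.repeat(np.arange(K), n1),
        "person_id": np.tile(np.arange(n1), K),
        "eta2": draws.eta2.reshape(-1),
    })
    for j in range(J):
        person[f"zeta2_{j}"] = draws.zeta2[:, :, j].reshape(-1)
    person.to_csv(out_dir / "latent_person.csv", index=False)
    meta = {
        "dims": asdict(draws.dims),
        "config": asdict(draws.config),
        "stored_params": [p.to_flat() for p in draws.params],
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=1))
    return out_dir


def load_draws(out_dir: Path | str):
    """Reconstruct a :class:`~ndlcsem.gibbs.PosteriorDraws` from ``save_draws`` output."""
    import json

    from .gibbs import MCMCConfig, PosteriorDraws
    from .params import ModelDims, ModelParams

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "meta.json").read_text())
    dims = ModelDims(**meta["dims"])
    config = MCMCConfig(**meta["config"])
    params = [ModelParams.from_flat(f) for f in meta["stored_params"]]
    trace_df = pd.read_csv(out_dir / "trace.csv")
    names = list(trace_df["parameter"].unique())
    n_chains = trace_df["chain"].max() + 1
    n_kept = trace_df["iteration"].max() + 1
    trace = np.empty((n_chains, n_kept, len(names)))
    pivot = trace_df.pivot_table(index=["chain", "iteration"],
                                 columns="parameter", values="value",
                                 sort=False)
    trace[:] = pivot[names].to_numpy().reshape(n_chains, n_kept, len(names))
    K = len(params)
    st = pd.read_csv(out_dir / "states.csv")
    n1 = st["person_id"].max() + 1
    T = st["occasion"].max()
    S = np.ones((K, n1, T), dtype=int)
    S[st["draw"], st["person_id"], st["occasion"] - 1] = st["S"]
    e1 = pd.read_csv(out_dir / "latent_eta1.csv")
    J = e1["factor_id"].max() + 1
    eta1 = np.zeros((K, n1, J, T))
    eta1[e1["draw"], e1["person_id"], e1["factor_id"], e1["occasion"] - 1] = e1["eta1"]
    per = pd.read_csv(out_dir / "latent_person.csv")
    eta2 = np.zeros((K, n1))
    eta2[per["draw"], per["person_id"]] = per["eta2"]
    zeta2 = np.zeros((K, n1, J))
    for j in range(J):
        zeta2[per["draw"], per["person_id"], j] = per[f"zeta2_{j}"]
    return PosteriorDraws(names=names, trace=trace, params=params, eta1=eta1,
                          eta2=eta2, zeta2=zeta2, S=S, dims=dims, config=config)


def read_truth(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    """Read a truth file; returns (eta1 (N1,J,T), S (N1,T))."""
    df = pd.read_csv(path)
    n1 = int(df["person_id"].max()) + 1
    J = int(df["factor_id"].max()) + 1
    T = int(df["occasion"].max())
    eta1 = np.zeros((n1, J, T))
    eta1[df["person_id"], df["factor_id"], df["occasion"] - 1] = df["eta1"]
    S = np.ones((n1, T), dtype=int)
    S[df["person_id"], df["occasion"] - 1] = df["S"]
    return eta1, S
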