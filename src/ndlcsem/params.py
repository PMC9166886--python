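"""Model dimensions, parameter containers, priors and latent/observed data holders.

The model is a two-level dynamic factor model for intensive longitudinal data
(many short surveys per person) with a hidden two-state Markov regime per
person-occasion.  Within-level factors ``eta1`` follow a regime-specific AR(1);
a between-level factor ``eta2`` (a stable trait such as cognitive ability)
shifts both the random intercepts and, through cross-level interactions, the
AR coefficients.  The regime ("no intention to quit" = state 1 vs "intention
to quit" = state 2) switches out of state 1 with a logistic probability driven
by the lagged latent factors, and returns from state 2 with a single constant
probability ``p12`` supported on [0, 0.1].

All containers are plain dataclasses over numpy arrays.  Indexing conventions:

* occasions are 0-based ``t = 0 .. T-1`` internally; external files use
  1-based occasion labels,
* discrete states are coded 1 and 2 (never 0-based),
* the first indicator of each factor is the scaling item (loading fixed to 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ModelDims",
    "MeasurementParams",
    "DynamicsParams",
    "SwitchParams",
    "ModelParams",
    "PriorSpec",
    "LatentState",
    "ObservedPanel",
]


@dataclass(frozen=True)
class ModelDims:
    """Problem sizes shared by simulator, estimator and forecaster.

    Parameters
    ----------
    n_persons
        Number of persons N1.
    n_occasions
        Number of observed measurement occasions Nt.
    horizon
        Forecast horizon H (additional held-out occasions).
    n_factors
        Number of within-level latent factors J.
    items_per_factor
        Within-level indicators per factor (simple structure: each item loads
        on exactly one factor; items are laid out factor-contiguously).
    n_items_between
        Number of between-level indicator items q.
    """

    n_persons: int
    n_occasions: int
    horizon: int = 10
    n_factors: int = 3
    items_per_factor: int = 3
    n_items_between: int = 3
    n_states: int = 2

    def __post_init__(self) -> None:
        for name in ("n_persons", "n_occasions", "n_factors",
                     "items_per_factor", "n_items_between"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.horizon < 0:
            raise ValueError("horizon must be nonnegative")
        if self.n_states != 2:
            raise ValueError("only two discrete states are supported")

    @property
    def n_items_within(self) -> int:
        return self.n_factors * self.items_per_factor

    @property
    def n_total_occasions(self) -> int:
        """Observed occasions plus forecast holdout."""
        return self.n_occasions + self.horizon

    @property
    def item_factor(self) -> np.ndarray:
        """Factor index (0-based) of each within item; a partition."""
        return np.repeat(np.arange(self.n_factors), self.items_per_factor)

    @property
    def scaling_items(self) -> np.ndarray:
        """Index of the item whose loading is fixed to 1, per factor."""
        return np.arange(self.n_factors) * self.items_per_factor


@dataclass
class MeasurementParams:
    """Loadings and residual variances of both measurement models.

    ``lambda1`` holds the nonzero loading of each within item on its factor
    (scaling items carry exactly 1.0); ``lambda2`` likewise for the single
    between factor, with the first entry fixed to 1.
    """

    lambda1: np.ndarray          # (p,)
    sigma2_eps1: np.ndarray      # (p,)
    lambda2: np.ndarray          # (q,)
    sigma2_eps2: np.ndarray      # (q,)
    sigma2_eta2: float

    def loading_matrix(self, dims: ModelDims) -> np.ndarray:
        """Expand to the full p x J simple-structure loading matrix."""
        mat = np.zeros((dims.n_items_within, dims.n_factors))
        mat[np.arange(dims.n_items_within), dims.item_factor] = self.lambda1
        return mat

    def validate(self, dims: ModelDims) -> None:
        if self.lambda1.shape != (dims.n_items_within,):
            raise ValueError("lambda1 has wrong shape")
        if not np.allclose(self.lambda1[dims.scaling_items], 1.0):
            raise ValueError("scaling items must have loading fixed to 1")
        if self.lambda2[0] != 1.0:
            raise ValueError("first between loading must be fixed to 1")
        if np.any(self.sigma2_eps1 <= 0) or np.any(self.sigma2_eps2 <= 0) \
                or self.sigma2_eta2 <= 0:
            raise ValueError("variances must be positive")


@dataclass
class DynamicsParams:
    """Structural (AR) parameters, stored as state-1 values plus state-2 shifts.

    The state-2 level shift ``delta_alpha21`` is constrained nonnegative: the
    "intention to quit" regime has higher (inverted-scale) affect levels on
    every factor, which is also what identifies the state labels.
    """

    alpha21: np.ndarray          # (J,) state-1 intercepts
    delta_alpha21: np.ndarray    # (J,) >= 0
    beta2: np.ndarray            # (J,) state-1 eta2 main effects
    delta_beta2: np.ndarray      # (J,)
    b1: np.ndarray               # (J,) state-1 AR diagonals
    delta_b1: np.ndarray         # (J,)
    omega2: np.ndarray           # (J,) state-1 cross-level interaction diag
    delta_omega2: np.ndarray     # (J,)
    sigma2_zeta1: np.ndarray     # (J,) within innovation variances
    sigma2_zeta2: np.ndarray     # (J,) between residual variances

    def alpha21_state(self, s: int) -> np.ndarray:
        return self.alpha21 if s == 1 else self.alpha21 + self.delta_alpha21

    def beta2_state(self, s: int) -> np.ndarray:
        return self.beta2 if s == 1 else self.beta2 + self.delta_beta2

    def b1_state(self, s: int) -> np.ndarray:
        return self.b1 if s == 1 else self.b1 + self.delta_b1

    def omega2_state(self, s: int) -> np.ndarray:
        return self.omega2 if s == 1 else self.omega2 + self.delta_omega2

    def validate(self, dims: ModelDims) -> None:
        J = dims.n_factors
        for name in ("alpha21", "delta_alpha21", "beta2", "delta_beta2", "b1",
                     "delta_b1", "omega2", "delta_omega2", "sigma2_zeta1",
                     "sigma2_zeta2"):
            if getattr(self, name).shape != (J,):
                raise ValueError(f"{name} must have shape ({J},)")
        if np.any(self.delta_alpha21 < 0):
            raise ValueError("delta_alpha21 must be nonnegative")
        if np.any(self.sigma2_zeta1 <= 0) or np.any(self.sigma2_zeta2 <= 0):
            raise ValueError("innovation variances must be positive")


@dataclass
class SwitchParams:
    """Markov switching model: logit of staying in state 1, constant return prob.

    ``gamma4_mask`` marks the factors whose cross-level interaction with the
    between factor enters the transition logit (the designated self-regulatory
    factors); masked-out entries of ``gamma4`` are identically zero.
    """

    gamma1: float
    gamma2: float
    gamma3: np.ndarray           # (J,)
    gamma4: np.ndarray           # (J,), zero where mask is False
    gamma4_mask: np.ndarray      # (J,) bool
    p12: float

    def validate(self, dims: ModelDims) -> None:
        J = dims.n_factors
        if self.gamma3.shape != (J,) or self.gamma4.shape != (J,):
            raise ValueError(f"gamma3/gamma4 must have shape ({J},)")
        if self.gamma4_mask.shape != (J,):
            raise ValueError(f"gamma4_mask must have shape ({J},)")
        if np.any(self.gamma4[~self.gamma4_mask] != 0.0):
            raise ValueError("masked entries of gamma4 must be exactly zero")
        if not 0.0 <= self.p12 <= 0.1:
            raise ValueError(f"p12 must lie in [0, 0.1], got {self.p12}")


@dataclass
class ModelParams:
    """All parameters of the model, grouped by role."""

    measurement: MeasurementParams
    dynamics: DynamicsParams
    switching: SwitchParams

    def validate(self, dims: ModelDims) -> None:
        self.measurement.validate(dims)
        self.dynamics.validate(dims)
        self.switching.validate(dims)

    # -- flat key-value serialization (JSON-compatible, exact round trip) ----

    def to_flat(self) -> dict:
        """Serialize to a flat ``{key: value}`` mapping.

        Keys follow the pattern ``name[j]`` / ``name[s,j]`` with 0-based item
        and factor indices and 1-based state labels.
        """
        out: dict[str, float] = {}
        m, d, g = self.measurement, self.dynamics, self.switching
        for j, v in enumerate(m.lambda1):
            out[f"lambda1[{j}]"] = float(v)
        for j, v in enumerate(m.sigma2_eps1):
            out[f"sigma2_eps1[{j}]"] = float(v)
        for j, v in enumerate(m.lambda2):
            out[f"lambda2[{j}]"] = float(v)
        for j, v in enumerate(m.sigma2_eps2):
            out[f"sigma2_eps2[{j}]"] = float(v)
        out["sigma2_eta2"] = float(m.sigma2_eta2)
        vec = {"alpha21[1,{}]": d.alpha21, "delta_alpha21[{}]": d.delta_alpha21,
               "beta2[1,{}]": d.beta2, "delta_beta2[{}]": d.delta_beta2,
               "b1[1,{}]": d.b1, "delta_b1[{}]": d.delta_b1,
               "omega2[1,{}]": d.omega2, "delta_omega2[{}]": d.delta_omega2,
               "sigma2_zeta1[{}]": d.sigma2_zeta1,
               "sigma2_zeta2[{}]": d.sigma2_zeta2,
               "gamma3[{}]": g.gamma3, "gamma4[{}]": g.gamma4}
        for pat, arr in vec.items():
            for j, v in enumerate(arr):
                out[pat.format(j)] = float(v)
        for j, v in enumerate(g.gamma4_mask):
            out[f"gamma4_mask[{j}]"] = bool(v)
        out["gamma1"] = float(g.gamma1)
        out["gamma2"] = float(g.gamma2)
        out["p12"] = float(g.p12)
        return out

    @classmethod
    def from_flat(cls, flat: dict) -> "ModelParams":
        def gather(pattern: str, dtype=float) -> np.ndarray:
            vals = []
            j = 0
            while pattern.format(j) in flat:
                vals.append(flat[pattern.format(j)])
                j += 1
            if not vals:
                raise KeyError(f"no keys matching {pattern!r}")
            return np.asarray(vals, dtype=dtype)

        meas = MeasurementParams(
            lambda1=gather("lambda1[{}]"),
            sigma2_eps1=gather("sigma2_eps1[{}]"),
            lambda2=gather("lambda2[{}]"),
            sigma2_eps2=gather("sigma2_eps2[{}]"),
            sigma2_eta2=float(flat["sigma2_eta2"]),
        )
        dyn = DynamicsParams(
            alpha21=gather("alpha21[1,{}]"),
            delta_alpha21=gather("delta_alpha21[{}]"),
            beta2=gather("beta2[1,{}]"),
            delta_beta2=gather("delta_beta2[{}]"),
            b1=gather("b1[1,{}]"),
            delta_b1=gather("delta_b1[{}]"),
            omega2=gather("omega2[1,{}]"),
            delta_omega2=gather("delta_omega2[{}]"),
            sigma2_zeta1=gather("sigma2_zeta1[{}]"),
            sigma2_zeta2=gather("sigma2_zeta2[{}]"),
        )
        sw = SwitchParams(
            gamma1=float(flat["gamma1"]),
            gamma2=float(flat["gamma2"]),
            gamma3=gather("gamma3[{}]"),
            gamma4=gather("gamma4[{}]"),
            gamma4_mask=gather("gamma4_mask[{}]", dtype=bool),
            p12=float(flat["p12"]),
        )
        return cls(measurement=meas, dynamics=dyn, switching=sw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_flat(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_flat(json.load(fh))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the (conditionally conjugate) prior system.

    Defaults: free loadings and the nonnegative state-2 level shifts get
    TN(0, 1, 0, inf); all other regression coefficients N(0, 1); every
    precision (inverse variance) Gamma(shape=9, rate=4); the return
    probability p12 Uniform(0, 0.1).
    """

    loading_sd: float = 1.0
    coef_sd: float = 1.0
    dalpha_sd: float = 1.0
    precision_shape: float = 9.0
    precision_rate: float = 4.0
    p12_lower: float = 0.0
    p12_upper: float = 0.1

    def with_overrides(self, **kw) -> "PriorSpec":
        unknown = set(kw) - set(self.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown prior hyperparameters: {sorted(unknown)}")
        return replace(self, **kw)


@dataclass
class LatentState:
    """Latent quantities of one panel: factor trajectories and state paths."""

    eta1: np.ndarray             # (N1, J, T)
    eta2: np.ndarray             # (N1,)
    zeta2: np.ndarray            # (N1, J)
    S: np.ndarray                # (N1, T) in {1, 2}
    s_observed_mask: np.ndarray  # (N1, T) bool; True => S observed (= 2)

    def validate(self) -> None:
        if not np.all(np.isin(self.S, (1, 2))):
            raise ValueError("S must contain only states 1 and 2")
        if np.any(self.S[:, 0] != 1):
            raise ValueError("every person starts in state 1 at t = 0")
        if np.any(self.S[self.s_observed_mask] != 2):
            raise ValueError("observed (dropout) entries of S must equal 2")


@dataclass
class ObservedPanel:
    """Observed data: within items over time, between items, dropout times.

    ``y1`` uses NaN for missing responses.  ``dropout_time`` holds the 0-based
    occasion from which a person's dropout is manifest (state observed as 2),
    or -1 when the person never manifestly dropped out.
    """

    y1: np.ndarray               # (N1, p, T) with NaN for missing
    y2: np.ndarray               # (N1, q)
    dropout_time: np.ndarray     # (N1,) int, -1 = none

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.y1)

    @property
    def n_occasions(self) -> int:
        return self.y1.shape[2]

    def observed_state_mask(self) -> np.ndarray:
        """Boolean (N1, T) mask: True from each person's dropout time onward."""
        n1, _, T = self.y1.shape
        t_idx = np.arange(T)[None, :]
        drop = self.dropout_time[:, None]
        return (drop >= 0) & (t_idx >= drop)

    def validate(self) -> None:
        T = self.y1.shape[2]
        bad = (self.dropout_time < -1) | (self.dropout_time >= T)
        if np.any(bad):
            raise ValueError("dropout_time outside [0, T) (or -1 for none)")
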