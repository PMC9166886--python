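import numpy as np
import pytest

from ndlcsem.params import (DynamicsParams, MeasurementParams, ModelDims,
                            ModelParams, SwitchParams)


def make_params(dims: ModelDims, **overrides) -> ModelParams:
    """A valid, fully specified parameter set for tests; fields overridable.

    Defaults: free loadings 0.9, residual variances 0.4, state-1 AR 0.4 with
    a +0.1 state-2 shift, level shift +1, small negative between-factor
    effects, switch intercept 2.5 with negative lagged effects.
    """
    J, p, q = dims.n_factors, dims.n_items_within, dims.n_items_between
    lam1 = np.full(p, 0.9)
    lam1[dims.scaling_items] = 1.0
    lam2 = np.full(q, 0.9)
    lam2[0] = 1.0
    meas = MeasurementParams(lambda1=lam1, sigma2_eps1=np.full(p, 0.4),
                             lambda2=lam2, sigma2_eps2=np.full(q, 0.4),
                             sigma2_eta2=1.0)
    dyn = DynamicsParams(
        alpha21=np.zeros(J), delta_alpha21=np.full(J, 1.0),
        beta2=np.full(J, -0.2), delta_beta2=np.zeros(J),
        b1=np.full(J, 0.4), delta_b1=np.full(J, 0.1),
        omega2=np.full(J, 0.05), delta_omega2=np.zeros(J),
        sigma2_zeta1=np.full(J, 0.2), sigma2_zeta2=np.full(J, 0.2))
    mask = np.zeros(J, dtype=bool)
    mask[-1] = True
    gamma4 = np.zeros(J)
    gamma4[-1] = -0.1
    sw = SwitchParams(gamma1=2.5, gamma2=0.3, gamma3=np.full(J, -0.4),
                      gamma4=gamma4, gamma4_mask=mask, p12=0.08)
    params = ModelParams(measurement=meas, dynamics=dyn, switching=sw)
    for path, value in overrides.items():
        group, name = path.split(".")
        setattr(getattr(params, group), name, value)
    params.validate(dims)
    return params


@pytest.fixture
def small_dims() -> ModelDims:
    return ModelDims(n_persons=8, n_occasions=10, horizon=4, n_factors=3,
                     items_per_factor=3, n_items_between=3)


@pytest.fixture
def small_params(small_dims) -> ModelParams:
    return make_params(small_dims)
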