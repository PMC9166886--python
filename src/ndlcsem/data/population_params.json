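{
  "_comment": "Population means/SDs for replication-level parameter draws in the simulation design. Values emulate the printed empirical summaries: positive AR coefficients that strengthen in the quit-intention state, a nonnegative level shift for state 2, negative main effects of the between factor, and a return probability near 0.097.",
  "lambda1": {"mean": 0.9, "sd": 0.1},
  "sigma2_eps1": {"mean": 0.4, "sd": 0.05},
  "lambda2": {"mean": 0.9, "sd": 0.1},
  "sigma2_eps2": {"mean": 0.4, "sd": 0.05},
  "sigma2_eta2": {"mean": 1.0, "sd": 0.1},
  "alpha21": {"mean": 0.0, "sd": 0.1},
  "delta_alpha21": {"mean": 1.0, "sd": 0.2},
  "beta2": {"mean": -0.2, "sd": 0.1},
  "delta_beta2": {"mean": 0.0, "sd": 0.05},
  "b1": {"mean": 0.35, "sd": 0.1},
  "delta_b1": {"mean": 0.1, "sd": 0.05},
  "omega2": {"mean": 0.05, "sd": 0.05},
  "delta_omega2": {"mean": 0.0, "sd": 0.05},
  "sigma2_zeta1": {"mean": 0.2, "sd": 0.03},
  "sigma2_zeta2": {"mean": 0.2, "sd": 0.03},
  "gamma1": {"mean": 3.0, "sd": 0.3},
  "gamma2": {"mean": 0.3, "sd": 0.1},
  "gamma3": {"mean": -0.4, "sd": 0.1},
  "gamma4": {"mean": -0.1, "sd": 0.05},
  "p12": {"mean": 0.08, "sd": 0.01}
}
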