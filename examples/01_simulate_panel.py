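"""Simulate one intensive-longitudinal panel from the generative model.

Draws replication-level parameters around the shipped population values,
forward-simulates latent states and factor scores for 30 persons over 25
observed occasions (plus a 10-occasion holdout), and prints what the panel
looks like.
"""

import numpy as np

import ndlcsem as nd
from ndlcsem.simulate import (dropout_times_from_mask,
                              inject_dropout_observations)

design = nd.SimDesign(conditions=[(30, 25)], horizon=10, n_replications=1,
                      seed=7)
dims = design.dims(30, 25)
params = nd.draw_replication_params(design, rng_seed=7, dims=dims)
panel, latent = nd.simulate_panel(params, dims, missing_rate=0.1, seed=7)
latent = inject_dropout_observations(latent, dims.n_occasions,
                                     design.dropout_prob, seed=7)
panel.dropout_time = dropout_times_from_mask(latent)

frac2 = (latent.S == 2).mean(axis=0)
print(f"panel: {dims.n_persons} persons x {dims.n_items_within} items x "
      f"{dims.n_total_occasions} occasions "
      f"({panel.missing_mask.mean():.0%} missing)")
print(f"state-2 ('intention to quit') share at t=1, 12, 24, 34: "
      f"{frac2[1]:.2f}, {frac2[12]:.2f}, {frac2[24]:.2f}, {frac2[34]:.2f}")
print(f"manifest dropouts observed: {(panel.dropout_time >= 0).sum()} persons")
print(f"generating return probability P12 = {params.switching.p12:.3f}")
# The state-2 share grows over the semester as persons switch and rarely
# return; dropout tails are the occasions where the state is observed.
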