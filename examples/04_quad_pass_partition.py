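"""Quasi-quadruple-pass analysis: splitting the stimulus-driven variance.

Jointly fitting the response agreement across all four passes of the two
double-pass experiments yields three correlations (within-flattened,
within-natural, cross-experiment) which, combined with the thresholds,
solve in closed form for the luminance-driven variance sigma_L^2, the
depth-driven variance sigma_B^2, their covariance, and the internal noise
of each experiment.
"""

import numpy as np

from dvcpass.pipeline import analyze_quad
from dvcpass.synthetic_data import (DesignConfig, GenerativeParams,
                                    build_design, comparison_steps_for,
                                    simulate_observer)

# unit component SDs: truth is rho_flat = 1/2, rho_nat = 2/3,
# rho_cross = 1/sqrt(6) = 0.408, and all variances 1
params = GenerativeParams(sigma_l=1.0, sigma_b=1.0, cov_lb=0.0,
                          sigma_i_flat=1.0, sigma_i_nat=1.0)
config = DesignConfig(pedestals=(-7.5, -3.75), contrast_bins=("high",),
                      repeats_per_comparison=1000, seed=6)
config.comparison_step = comparison_steps_for(params, config)
records = simulate_observer(build_design(config), params, seed=7)

quad = analyze_quad(records)
cols = ["pedestal_arcmin", "rho_flat", "rho_nat", "rho_cross",
        "sigma_l2", "sigma_b2", "cov_lb", "sigma_i2_flat", "sigma_i2_nat"]
print(quad[cols].round(3).to_string(index=False))
print("\ntruth:  rho 0.500 / 0.667 / 0.408; variances 1, 1, cov 0, 1, 1")
print("\nThe luminance component is shared by both experiments; the depth "
      "component exists only for natural stimuli. Their fitted variances "
      "recover the generative values.")
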