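"""Constrained log-linear threshold fits across disparity pedestals.

Thresholds (= decision-variable SDs at criterion d' = 1) are constrained
to follow sigma_T = exp(m * pedestal + b) within each disparity-contrast
bin, fit by joint maximum likelihood over all pedestals.
"""

import numpy as np

from dvcpass.psychometrics import threshold_table
from dvcpass.synthetic_data import (DesignConfig, GenerativeParams,
                                    build_design, comparison_steps_for,
                                    simulate_observer)

# generative SDs follow a log-linear law in the pedestal
peds = (-11.25, -9.38, -7.5, -5.63, -3.75)
law = {(p, "high"): float(np.exp(-0.08 * p - 0.2)) for p in peds}
params = GenerativeParams(sigma_l=law, sigma_b=0.0, cov_lb=0.0,
                          sigma_i_flat=law, sigma_i_nat=law)

config = DesignConfig(pedestals=peds, contrast_bins=("high",), seed=2)
config.comparison_step = comparison_steps_for(params, config)
records = simulate_observer(build_design(config), params, seed=3)

table = threshold_table(records)
nat = table[table["experiment"] == "natural"]
print(nat[["pedestal_arcmin", "sigma_t", "threshold", "m", "b"]]
      .round(3).to_string(index=False))
truth = {p: float(np.sqrt(2.0) * law[(p, "high")]) for p in peds}
print("\ngenerative sigma_T:", {p: round(v, 3) for p, v in truth.items()})
print("\nThresholds rise exponentially as the pedestal moves away from "
      "fixation (a straight line on a semi-log plot); the fitted slope m "
      "and intercept b describe that line.")
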