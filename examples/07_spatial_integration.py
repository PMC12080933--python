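"""Which spatial-integration rule explains trial-by-trial responses?

Candidate decision variables — disparity differences pooled over pillbox
windows of several diameters, or extreme-disparity heuristics — are
scored by logistic regression (AIC, McFadden pseudo-R^2) against the
recorded binary responses.  The generative rule here uses the central
pixel only, so larger windows should not help.
"""

from dvcpass.spatial_integration import compare_models
from dvcpass.synthetic_data import synth_map_trials

trials = synth_map_trials(seed=10, n_per_condition=250,
                          generative_diameter=1, noise_sd=0.8)
rows = compare_models(trials, window_diameters=(1, 4, 8, 16, 32))

print(f"{'model':>12} {'AIC':>10} {'dAIC':>8} {'R2':>7} {'R2 incr':>8}")
for r in rows:
    print(f"{r.model:>12} {r.aic:10.1f} {r.delta_aic:8.1f} "
          f"{r.pseudo_r2:7.3f} {r.pseudo_r2_incremental:8.3f}")
print("\nThe 1-px (central-pixel) model attains the lowest AIC and no "
      "larger window adds explainable variance — the null result expected "
      "when responses are driven by the center of the patch.")
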