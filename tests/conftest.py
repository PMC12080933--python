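"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from dvcpass.synthetic_data import (DesignConfig, GenerativeParams,
                                    build_design, comparison_steps_for,
                                    simulate_observer)


def loglinear_params(pedestals, bins, *, m=-0.08, b_l=-0.1, b_b=-0.3,
                     b_i=-0.05, low_b_scale=0.1, cov=0.0):
    """Generative parameter set with log-linear pedestal laws.

    The depth-driven SD is scaled down in the low disparity-contrast bin;
    the luminance-driven and internal-noise SDs are bin-independent.
    """
    sig_l = {(p, cb): np.exp(m * p + b_l) for p in pedestals for cb in bins}
    sig_b = {(p, cb): (low_b_scale if cb == "low" else 1.0) * np.exp(m * p + b_b)
             for p in pedestals for cb in bins}
    sig_i = {(p, cb): np.exp(m * p + b_i) for p in pedestals for cb in bins}
    return GenerativeParams(sigma_l=sig_l, sigma_b=sig_b, cov_lb=cov,
                            sigma_i_flat=sig_i, sigma_i_nat=sig_i)


@pytest.fixture(scope="session")
def unit_params():
    """All component SDs equal to 1, no interaction."""
    return GenerativeParams(sigma_l=1.0, sigma_b=1.0, cov_lb=0.0,
                            sigma_i_flat=1.0, sigma_i_nat=1.0)


@pytest.fixture(scope="session")
def small_design(unit_params):
    cfg = DesignConfig(pedestals=(-7.5, -3.75), contrast_bins=("high",),
                       repeats_per_comparison=500, seed=7)
    cfg.comparison_step = comparison_steps_for(unit_params, cfg)
    return cfg


@pytest.fixture(scope="session")
def small_records(small_design, unit_params):
    """Two-pedestal, one-bin dataset from the unit generative observer."""
    schedule = build_design(small_design)
    return simulate_observer(schedule, unit_params, seed=11)
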