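"""Variance decompositions of the decision variable and bootstrap CIs.

Decision-variable correlation is the repeatable fraction of decision
variance: ``rho = sigma_E^2 / (sigma_E^2 + sigma_I^2)``.  Combined with
the total variance from thresholds this partitions each condition into an
externally-driven component ``sigma_E^2 = rho * sigma_T^2`` and internal
noise ``sigma_I^2 = sigma_T^2 - sigma_E^2``.

The quasi-quadruple-pass correlations further split the external variance
of natural stimuli into a luminance-pattern component ``sigma_L^2``, a
local-depth component ``sigma_B^2`` and their interaction ``cov[L, B]``,
in closed form:

    sigma_L^2 = rho_flat * sigma_T_flat^2
    cov[L,B]  = rho_cross * sigma_T_flat * sigma_T_nat - sigma_L^2
    sigma_B^2 = rho_nat * sigma_T_nat^2 - sigma_L^2 - 2 cov[L,B]

Sampling error can push the algebraic components slightly negative; they
are reported raw with flags, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "partition_double",
    "rho_from_variances",
    "VarianceComponents",
    "solve_components",
    "correlations_from_components",
    "partial_correlation",
    "bootstrap_ci",
]


def partition_double(sigma_t2: float, rho: float) -> tuple[float, float]:
    """Split total decision variance into (external, internal) parts."""
    if sigma_t2 <= 0:
        raise ValueError("sigma_t2 must be positive")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    sigma_e2 = rho * sigma_t2
    return sigma_e2, sigma_t2 - sigma_e2


def rho_from_variances(sigma_e2: float, sigma_i2: float) -> float:
    """Decision-variable correlation implied by the two variance components."""
    tot = sigma_e2 + sigma_i2
    if tot <= 0:
        raise ValueError("total variance must be positive")
    return sigma_e2 / tot


@dataclass
class VarianceComponents:
    """Variance decomposition for one condition (all entries arcmin^2)."""

    sigma_t2_flat: float
    sigma_t2_nat: float
    sigma_l2: float
    sigma_b2: float
    cov_lb: float
    sigma_i2_flat: float
    sigma_i2_nat: float
    sigma_e2_flat: float
    sigma_e2_nat: float
    negative_flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "sigma_t2_flat", "sigma_t2_nat", "sigma_l2", "sigma_b2",
            "cov_lb", "sigma_i2_flat", "sigma_i2_nat",
            "sigma_e2_flat", "sigma_e2_nat")}


def solve_components(rho_flat: float, rho_nat: float, rho_cross: float,
                     sigma_t_flat: float, sigma_t_nat: float) -> VarianceComponents:
    """Closed-form component solution from the three correlations.

    Also returns the internal-noise variances (``sigma_T^2 - sigma_E^2``
    per experiment).  Conservation holds exactly: components sum back to
    each experiment's total variance.
    """
    if sigma_t_flat <= 0 or sigma_t_nat <= 0:
        raise ValueError("threshold SDs must be positive")
    st2_f = sigma_t_flat ** 2
    st2_n = sigma_t_nat ** 2
    sigma_l2 = rho_flat * st2_f
    cov_lb = rho_cross * sigma_t_flat * sigma_t_nat - sigma_l2
    sigma_b2 = rho_nat * st2_n - sigma_l2 - 2.0 * cov_lb
    sigma_e2_f = sigma_l2
    sigma_e2_n = sigma_l2 + sigma_b2 + 2.0 * cov_lb  # == rho_nat * st2_n
    flags = [name for name, v in (("sigma_l2", sigma_l2),
                                  ("sigma_b2", sigma_b2),
                                  ("sigma_i2_flat", st2_f - sigma_e2_f),
                                  ("sigma_i2_nat", st2_n - sigma_e2_n))
             if v < 0]
    return VarianceComponents(
        sigma_t2_flat=st2_f, sigma_t2_nat=st2_n,
        sigma_l2=sigma_l2, sigma_b2=sigma_b2, cov_lb=cov_lb,
        sigma_i2_flat=st2_f - sigma_e2_f, sigma_i2_nat=st2_n - sigma_e2_n,
        sigma_e2_flat=sigma_e2_f, sigma_e2_nat=sigma_e2_n,
        negative_flags=flags)


def correlations_from_components(sigma_l2: float, sigma_b2: float, cov_lb: float,
                                 sigma_i2_flat: float, sigma_i2_nat: float
                                 ) -> tuple[float, float, float, float, float]:
    """Forward map components -> (rho_flat, rho_nat, rho_cross, sigma_T_flat, sigma_T_nat).

    Exact inverse of :func:`solve_components`; the round trip holds to
    floating-point precision.
    """
    st2_f = sigma_l2 + sigma_i2_flat
    st2_n = sigma_l2 + sigma_b2 + 2.0 * cov_lb + sigma_i2_nat
    st_f, st_n = np.sqrt(st2_f), np.sqrt(st2_n)
    rho_flat = sigma_l2 / st2_f
    rho_nat = (sigma_l2 + sigma_b2 + 2.0 * cov_lb) / st2_n
    rho_cross = (sigma_l2 + cov_lb) / (st_f * st_n)
    return rho_flat, rho_nat, rho_cross, float(st_f), float(st_n)


def partial_correlation(rho12: float, rho11: float, rho22: float) -> float:
    """Between-observer correlation with internal noise removed.

    ``rho12 / sqrt(rho11 * rho22)``; the result is required to lie in
    [-1, 1] (values outside indicate an inconsistent triple and are
    clamped by the caller, see the estimator).
    """
    if rho11 <= 0 or rho22 <= 0:
        raise ValueError("within-observer correlations must be positive "
                         "for the partial correlation to be defined")
    return rho12 / np.sqrt(rho11 * rho22)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(records: pd.DataFrame, estimator, n_boot: int = 1000,
                 level: float = 0.68, seed: int = 0,
                 return_samples: bool = False):
    """Percentile bootstrap CIs for any estimator of trial records.

    The resampling unit is the *unique trial*: all passes of a trial (and
    its cross-experiment partner, which shares the trial id) move
    together, because every estimator conditions on between-pass pairing.
    Trials are resampled with replacement within each (pedestal, bin,
    comparison-level) cell, preserving the design.  ``estimator`` maps a
    records frame to a dict (or Series) of scalars; CIs are percentile at
    the requested ``level``.
    """
    import warnings

    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small for percentile intervals",
                      UserWarning)
    rng = np.random.default_rng(seed)
    cells = (records[["trial_id", "pedestal_arcmin", "contrast_bin",
                      "comparison_arcmin"]]
             .drop_duplicates("trial_id")
             .groupby(["pedestal_arcmin", "contrast_bin", "comparison_arcmin"])
             ["trial_id"].apply(np.asarray))
    by_trial = {tid: df for tid, df in records.groupby("trial_id")}

    samples = []
    for _ in range(n_boot):
        parts = []
        new_tid = 0
        for ids in cells:
            for tid in rng.choice(ids, size=len(ids), replace=True):
                part = by_trial[tid].copy()
                part["trial_id"] = new_tid
                new_tid += 1
                parts.append(part)
        boot = pd.concat(parts, ignore_index=True)
        samples.append(pd.Series(estimator(boot), dtype=float))
    samples = pd.DataFrame(samples)
    alpha = (1.0 - level) / 2.0
    out = pd.DataFrame({
        "lo": samples.quantile(alpha),
        "hi": samples.quantile(1.0 - alpha),
        "median": samples.quantile(0.5),
    })
    if return_samples:
        return out, samples
    return out
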