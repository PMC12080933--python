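"""Cumulative-Gaussian psychometric fitting and threshold conversions.

The decision-variable model underlying a 2IFC disparity-discrimination
trial is ``D = (delta_cmp - delta_std) + V + W`` with total SD ``sigma_T``;
the comparison is chosen when ``D`` exceeds the (zero) criterion, so the
psychometric function is ``PC(delta_cmp) = Phi((delta_cmp - delta_std) /
sigma_T)``.  The fitted sigma of the cumulative Gaussian therefore *is* the
decision-variable SD, and at the criterion d-prime of 1 the discrimination
threshold equals ``sigma_T`` (``sigma_T**2 = T**2``).

``pc_from_dprime`` uses the textbook 2IFC link ``PC = Phi(d'/sqrt(2))``
(single-interval d-prime convention), under which threshold-level
performance at d'_crit = 1 corresponds to the 76% point of the psychometric
function.

Across disparity pedestals, thresholds are constrained to follow a
log-linear law ``sigma_T = exp(m * delta_std + b)`` and the two line
parameters are fit by joint maximum likelihood over all pedestals of one
disparity-contrast bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr, ndtri

__all__ = [
    "pc_from_dprime",
    "dprime_from_pc",
    "dprime",
    "threshold",
    "PsychometricFit",
    "ThresholdFit",
    "fit_psychometric",
    "fit_constrained_thresholds",
    "fit_constrained_cells",
    "threshold_table",
]

_EPS_P = 1e-12


def pc_from_dprime(dprime):
    """Proportion comparison chosen in 2IFC: ``Phi(d' / sqrt(2))``.

    At the criterion d-prime of 1 this is the 76% point that defines
    threshold-level performance.
    """
    return ndtr(np.asarray(dprime, dtype=float) / np.sqrt(2.0))


def dprime_from_pc(pc):
    """Inverse of :func:`pc_from_dprime`."""
    pc = np.clip(np.asarray(pc, dtype=float), _EPS_P, 1 - _EPS_P)
    return ndtri(pc) * np.sqrt(2.0)


def dprime(delta_cmp, delta_std, sigma_t):
    """Sensitivity index ``(delta_cmp - delta_std) / sigma_T`` (sign-preserving)."""
    sigma_t = np.asarray(sigma_t, dtype=float)
    if np.any(sigma_t <= 0):
        raise ValueError("sigma_t must be positive")
    return (np.asarray(delta_cmp, dtype=float) - np.asarray(delta_std, dtype=float)) / sigma_t


def threshold(sigma_t, dprime_crit: float = 1.0):
    """Discrimination threshold ``T = sigma_T * d'_crit`` (arcmin)."""
    return np.asarray(sigma_t, dtype=float) * dprime_crit


# ---------------------------------------------------------------------------
# per-condition ML fit
# ---------------------------------------------------------------------------

@dataclass
class PsychometricFit:
    """ML cumulative-Gaussian fit for one (pedestal, bin) condition."""

    mean: float
    sigma: float
    loglik: float
    converged: bool = True
    degenerate: str | None = None  # 'sigma_floor' / 'sigma_ceiling' / None


def _binomial_cells(records: pd.DataFrame):
    g = records.groupby("comparison_arcmin")["chose_comparison"]
    x = np.array(sorted(g.groups))
    k = g.sum().reindex(x).to_numpy(dtype=float)
    n = g.count().reindex(x).to_numpy(dtype=float)
    return x, k, n


def _bernoulli_ll(x, k, n, mean, sigma):
    p = np.clip(ndtr((x - mean) / sigma), _EPS_P, 1 - _EPS_P)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _probit_start(x, k, n, mean=None):
    """Moment start: probit-regress empirical proportions on the level."""
    p = np.clip((k + 0.5) / (n + 1.0), 0.01, 0.99)
    z = ndtri(p)
    if mean is None:
        A = np.vstack([x, np.ones_like(x)]).T
        slope, icpt = np.linalg.lstsq(A, z, rcond=None)[0]
        if slope <= 1e-6:
            return float(np.mean(x)), float(np.ptp(x) or 1.0)
        return float(-icpt / slope), float(1.0 / slope)
    xc = x - mean
    denom = float(xc @ z)
    if denom <= 1e-9:
        return float(mean), float(np.ptp(x) or 1.0)
    return float(mean), float((xc @ xc) / denom)


def fit_psychometric(records: pd.DataFrame, *, fix_mean: float | None = None,
                     sigma_bounds: tuple[float, float] = (1e-4, 1e4)) -> PsychometricFit:
    """ML cumulative-Gaussian fit of choice data for one condition.

    ``records`` must carry ``comparison_arcmin`` and binary
    ``chose_comparison`` for a single (pedestal, contrast-bin) condition.
    With ``fix_mean`` the mean is pinned (e.g. at the standard disparity)
    and only sigma is free.  Degenerate data (all-same responses, or exact
    50% everywhere) drive sigma to a bound and are flagged rather than
    raised.
    """
    x, k, n = _binomial_cells(records)
    if len(x) < 2:
        raise ValueError("need responses at two or more comparison levels")
    lo, hi = np.log(sigma_bounds[0]), np.log(sigma_bounds[1])

    if fix_mean is not None:
        res = minimize_scalar(
            lambda ls: -_bernoulli_ll(x, k, n, fix_mean, np.exp(ls)),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        mean, sigma, ll = fix_mean, float(np.exp(res.x)), -res.fun
        ok = res.success
    else:
        m0, s0 = _probit_start(x, k, n)
        res = minimize(
            lambda th: -_bernoulli_ll(x, k, n, th[0], np.exp(np.clip(th[1], lo, hi))),
            x0=[m0, np.log(np.clip(s0, *sigma_bounds))],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        mean, sigma, ll = float(res.x[0]), float(np.exp(np.clip(res.x[1], lo, hi))), -res.fun
        ok = res.success
    # degenerate when the data cannot distinguish the fit from a boundary
    # limit (all-same responses push sigma to 0, chance responses to infinity)
    degenerate = None
    if _bernoulli_ll(x, k, n, mean, sigma_bounds[0]) >= ll - 0.25:
        degenerate = "sigma_floor"
    elif _bernoulli_ll(x, k, n, mean, sigma_bounds[1]) >= ll - 0.25:
        degenerate = "sigma_ceiling"
    return PsychometricFit(mean=mean, sigma=sigma, loglik=ll,
                           converged=bool(ok), degenerate=degenerate)


# ---------------------------------------------------------------------------
# log-linear constrained fit across pedestals
# ---------------------------------------------------------------------------

@dataclass
class ThresholdFit:
    """Constrained log-linear threshold fit for one disparity-contrast bin."""

    contrast_bin: str
    m: float
    b: float
    sigma_t: dict = field(default_factory=dict)  # pedestal -> sigma_T (arcmin)
    dprime_crit: float = 1.0
    loglik: float = np.nan
    converged: bool = True

    def sigma_at(self, pedestal: float) -> float:
        return float(np.exp(self.m * pedestal + self.b))

    def threshold_at(self, pedestal: float) -> float:
        return self.sigma_at(pedestal) * self.dprime_crit


def fit_constrained_thresholds(records: pd.DataFrame, *, dprime_crit: float = 1.0,
                               tol: float = 1e-8) -> ThresholdFit:
    """Joint ML fit of the log-linear threshold law for one contrast bin.

    ``records`` must hold trials from a single experiment and contrast bin
    across two or more pedestals.  Each pedestal's psychometric function has
    its mean fixed at the standard disparity and SD ``exp(m * delta_std + b)``;
    (m, b) maximize the summed Bernoulli log-likelihood.  Multi-start
    Nelder-Mead; raises on non-convergence.
    """
    bins = records["contrast_bin"].unique()
    if len(bins) != 1:
        raise ValueError(f"records span several contrast bins: {sorted(bins)}")
    if "experiment" in records and records["experiment"].nunique() > 1:
        raise ValueError("records span several experiments; fit them separately")
    cells = []
    for ped, sub in records.groupby("pedestal_arcmin"):
        x, k, n = _binomial_cells(sub)
        cells.append((float(ped), x, k, n))
    return fit_constrained_cells(cells, contrast_bin=str(bins[0]),
                                 dprime_crit=dprime_crit, tol=tol)


def fit_constrained_cells(cells, *, contrast_bin: str = "", x0=None,
                          dprime_crit: float = 1.0, tol: float = 1e-8,
                          xatol: float = 1e-9) -> ThresholdFit:
    """Constrained log-linear fit from pre-binned cells.

    ``cells`` is a list of ``(pedestal, levels, n_chosen, n_total)``
    tuples.  ``x0`` optionally warm-starts (m, b) — used by bootstrap
    refits, which repeat the fit thousands of times on resampled counts.
    """
    if len(cells) < 2:
        raise ValueError("constrained fit needs two or more pedestals")

    def nll(theta):
        m, b = theta
        tot = 0.0
        for ped, x, k, n in cells:
            sig = np.exp(np.clip(m * ped + b, -30.0, 30.0))
            tot -= _bernoulli_ll(x, k, n, ped, sig)
        return tot

    if x0 is not None:
        starts = [tuple(x0)]
    else:
        # per-pedestal probit sigmas regressed on pedestal, plus fallbacks
        peds = np.array([c[0] for c in cells])
        logsig = []
        for ped, x, k, n in cells:
            _, s0 = _probit_start(x, k, n, mean=ped)
            logsig.append(np.log(np.clip(s0, 1e-3, 1e3)))
        A = np.vstack([peds, np.ones_like(peds)]).T
        m0, b0 = np.linalg.lstsq(A, np.array(logsig), rcond=None)[0]
        starts = [(m0, b0), (0.0, float(np.mean(logsig))), (-0.1, 0.3)]

    best = None
    for s in starts:
        res = minimize(nll, x0=np.asarray(s, dtype=float), method="Nelder-Mead",
                       options={"xatol": xatol, "fatol": tol, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
        if x0 is not None and res.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("constrained threshold fit did not converge")
    m, b = map(float, best.x)
    fit = ThresholdFit(contrast_bin=contrast_bin, m=m, b=b,
                       dprime_crit=dprime_crit, loglik=-float(best.fun),
                       converged=bool(best.success))
    fit.sigma_t = {ped: fit.sigma_at(ped) for ped, *_ in cells}
    return fit


def threshold_table(records: pd.DataFrame, *, dprime_crit: float = 1.0) -> pd.DataFrame:
    """Constrained threshold fits for every (observer, experiment, bin).

    Returns a tidy frame with one row per (observer, experiment, bin,
    pedestal): fitted m, b, sigma_T and threshold.
    """
    rows = []
    for (obs, exp, cbin), sub in records.groupby(
            ["observer_id", "experiment", "contrast_bin"]):
        fit = fit_constrained_thresholds(sub, dprime_crit=dprime_crit)
        for ped, sig in sorted(fit.sigma_t.items()):
            rows.append({"observer_id": obs, "experiment": exp,
                         "contrast_bin": cbin, "pedestal_arcmin": ped,
                         "m": fit.m, "b": fit.b, "sigma_t": sig,
                         "threshold": sig * dprime_crit,
                         "loglik": fit.loglik})
    return pd.DataFrame(rows)
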