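"""Maximum-likelihood decision-variable correlations from response agreement.

Across the passes of a double-pass experiment the joint decision variable
is modeled as multivariate normal with normalized means ``d' = (delta_cmp -
delta_std) / sigma_T`` (thresholds frozen from the constrained log-linear
fits), unit variances, zero criteria, and a correlation equal to the
decision-variable correlation rho.  The count of each joint response
pattern at each comparison level is multinomial with orthant-probability
cell rates; rho maximizes the summed multinomial log-likelihood over
levels, which share one rho per (pedestal, contrast-bin) condition.

The quasi-quadruple-pass estimator does the same over the sixteen response
patterns of the four passes of two double-pass experiments, with the
structured correlation matrix (rho_flat within the flattened pair, rho_nat
within the natural pair, rho_cross between experiments).  Setting the
luminance/depth interaction covariance to zero ties ``rho_cross =
rho_flat * sigma_T_flat / sigma_T_nat`` and removes one free parameter.
The between-observer estimator reuses the same machinery with pass pairs
belonging to two observers in one experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr

from .mvn_orthant import (_bvn_equal_upper, bvn_orthant, pattern_labels,
                          quad_pattern_probs)

__all__ = [
    "AgreementCounts",
    "QuadCorrelations",
    "BetweenObserverCorrelations",
    "tabulate_agreement",
    "double_pass_groups",
    "quad_pass_groups",
    "between_observer_groups",
    "estimate_rho_double",
    "agreement_curve",
    "pass_symmetry_diagnostic",
    "estimate_quad",
    "estimate_between",
]

_RHO_BOUND = 1.0 - 1e-6
_COND = ["pedestal_arcmin", "contrast_bin"]
_CELL = _COND + ["comparison_arcmin"]


# ---------------------------------------------------------------------------
# pattern tabulation
# ---------------------------------------------------------------------------

@dataclass
class AgreementCounts:
    """Joint response-pattern counts per condition and comparison level.

    ``table`` has the condition/level columns plus one count column per
    pattern (canonical order: binary counting, ``-``=0, ``+``=1, first pass
    group most significant).
    """

    n_passes: int
    table: pd.DataFrame

    @property
    def pattern_columns(self) -> list[str]:
        return [f"n_{lab}" for lab in pattern_labels(self.n_passes)]

    def condition(self, pedestal: float, cbin: str):
        """(counts, delta) arrays for one condition: shapes (L, 2**n), (L,)."""
        sub = self.table[(self.table["pedestal_arcmin"] == pedestal)
                         & (self.table["contrast_bin"] == cbin)]
        if sub.empty:
            raise KeyError(f"no counts for condition ({pedestal}, {cbin!r})")
        sub = sub.sort_values("comparison_arcmin")
        counts = sub[self.pattern_columns].to_numpy(dtype=float)
        delta = (sub["comparison_arcmin"] - sub["pedestal_arcmin"]).to_numpy()
        return counts, delta

    def conditions(self):
        return list(self.table.groupby(_COND).groups)


def double_pass_groups(experiment: str) -> list[dict]:
    return [{"experiment": experiment, "pass_idx": p} for p in (1, 2)]


def quad_pass_groups(flat: str = "flattened", nat: str = "natural") -> list[dict]:
    """Pass order (flat-1, flat-2, nat-1, nat-2)."""
    return [{"experiment": flat, "pass_idx": 1},
            {"experiment": flat, "pass_idx": 2},
            {"experiment": nat, "pass_idx": 1},
            {"experiment": nat, "pass_idx": 2}]


def between_observer_groups(obs1: str, obs2: str, experiment: str) -> list[dict]:
    """Pass order (obs1-1, obs1-2, obs2-1, obs2-2) within one experiment."""
    return [{"observer_id": o, "experiment": experiment, "pass_idx": p}
            for o in (obs1, obs2) for p in (1, 2)]


def tabulate_agreement(records: pd.DataFrame, pass_groups: list[dict]) -> AgreementCounts:
    """Exact joint-pattern counts across the given pass groups.

    Each group selector (a dict of column -> value) must match exactly one
    response per unique trial; all groups must cover the same trial set,
    aligned by ``trial_id``.  Mismatched trial ids raise with a listing.
    """
    n = len(pass_groups)
    responses = []
    base = None
    for g in pass_groups:
        sel = records
        for col, val in g.items():
            sel = sel[sel[col] == val]
        if sel["trial_id"].duplicated().any():
            dups = sel[sel["trial_id"].duplicated()]["trial_id"].unique()[:5]
            raise ValueError(f"pass group {g} has duplicated trials, e.g. {list(dups)}")
        sel = sel.sort_values("trial_id").reset_index(drop=True)
        if base is None:
            base = sel[["trial_id"] + _CELL].copy()
        else:
            if len(sel) != len(base) or not np.array_equal(
                    sel["trial_id"].to_numpy(), base["trial_id"].to_numpy()):
                missing = sorted(set(base["trial_id"]) ^ set(sel["trial_id"]))[:10]
                raise ValueError(
                    f"pass group {g} is not aligned with the first group; "
                    f"mismatched trial ids (first few): {missing}")
        responses.append(sel["chose_comparison"].to_numpy(dtype=int))

    pattern = np.zeros(len(base), dtype=int)
    for i, r in enumerate(responses):
        pattern |= r << (n - 1 - i)
    base = base.assign(_pattern=pattern)
    counts = (base.groupby(_CELL)["_pattern"]
              .apply(lambda s: np.bincount(s, minlength=2 ** n))
              .reset_index(name="_counts"))
    cols = [f"n_{lab}" for lab in pattern_labels(n)]
    mat = pd.DataFrame(np.vstack(counts["_counts"].to_numpy()), columns=cols)
    table = pd.concat([counts[_CELL], mat], axis=1)
    return AgreementCounts(n_passes=n, table=table)


def pass_symmetry_diagnostic(records: pd.DataFrame) -> pd.DataFrame:
    """Per-condition check that choice rates match across passes.

    The orthant likelihoods assume equal normalized means and zero
    criteria on every pass.  This diagnostic compares each pass's overall
    proportion-comparison-chosen within a condition and reports a
    two-proportion z statistic; |z| persistently above ~2 suggests
    criterion drift between passes.  Diagnostic only — no estimator
    consumes it.
    """
    rows = []
    for (exp, ped, cbin), sub in records.groupby(
            ["experiment"] + _COND):
        rates = sub.groupby("pass_idx")["chose_comparison"].agg(["mean", "count"])
        if len(rates) != 2:
            continue
        (p1, n1), (p2, n2) = rates.to_numpy()
        pool = (p1 * n1 + p2 * n2) / (n1 + n2)
        se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        rows.append({"experiment": exp, "pedestal_arcmin": ped,
                     "contrast_bin": cbin, "rate_pass1": p1, "rate_pass2": p2,
                     "z": (p1 - p2) / se if se > 0 else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# double-pass estimator
# ---------------------------------------------------------------------------

def _double_pattern_probs(d, rho):
    """(L, 4) pattern probabilities (--, -+, +-, ++) for equal means d."""
    d = np.atleast_1d(d)
    pp = _bvn_equal_upper(d, rho)
    ph = ndtr(d)
    mm = np.clip(pp + 1.0 - 2.0 * ph, 0.0, 1.0)
    pm = np.clip(ph - pp, 0.0, 1.0)
    return np.stack([mm, pm, pm, pp], axis=-1)


def _nll_double(rho, counts, d):
    p = np.clip(_double_pattern_probs(d, rho), 1e-300, 1.0)
    return -float(np.sum(counts * np.log(p)))


def _fit_rho(counts, d):
    res = minimize_scalar(_nll_double, args=(counts, d),
                          bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(res.x)
    return rho, -float(res.fun), bool(res.success), abs(rho) > 0.999


def _sigma_for(sigma_t, pedestal, cbin) -> float:
    if isinstance(sigma_t, dict):
        return float(sigma_t[(pedestal, cbin)])
    if hasattr(sigma_t, "sigma_at"):  # ThresholdFit
        return float(sigma_t.sigma_at(pedestal))
    return float(sigma_t)


def estimate_rho_double(counts: AgreementCounts, sigma_t) -> pd.DataFrame:
    """ML decision-variable correlation per (pedestal, bin) condition.

    ``sigma_t`` supplies the frozen threshold SD per condition (scalar,
    ``{(pedestal, bin): sigma}`` dict, or a
    :class:`~dvcpass.psychometrics.ThresholdFit`).  Levels within a
    condition share one rho; each level contributes its own normalized mean.
    """
    if counts.n_passes != 2:
        raise ValueError("double-pass estimation needs 2-pass counts")
    rows = []
    for ped, cbin in counts.conditions():
        N, delta = counts.condition(ped, cbin)
        if N.sum() == 0:
            raise ValueError(f"no trials in condition ({ped}, {cbin!r})")
        d = delta / _sigma_for(sigma_t, ped, cbin)
        rho, ll, ok, boundary = _fit_rho(N, d)
        rows.append({"pedestal_arcmin": ped, "contrast_bin": cbin,
                     "rho": rho, "loglik": ll, "n_trials": int(N.sum()),
                     "converged": ok, "boundary": boundary})
    return pd.DataFrame(rows)


def agreement_curve(dprime, rho):
    """Expected proportion of between-pass response agreement.

    ``P(++) + P(--)`` of the 2-D orthant model at normalized mean
    ``dprime`` (so the per-pass proportion comparison chosen is
    ``Phi(dprime)``).
    """
    p = _double_pattern_probs(np.asarray(dprime, dtype=float), rho)
    out = p[..., 0] + p[..., 3]
    return out.item() if out.size == 1 else out


# ---------------------------------------------------------------------------
# quadruple-pass estimators
# ---------------------------------------------------------------------------

@dataclass
class QuadCorrelations:
    """Quasi-quadruple-pass correlations for one condition."""

    pedestal_arcmin: float
    contrast_bin: str
    rho_flat: float
    rho_nat: float
    rho_cross: float
    loglik: float
    converged: bool
    cov_zero: bool = False


@dataclass
class BetweenObserverCorrelations:
    """Between-observer correlations for one condition of one experiment."""

    pedestal_arcmin: float
    contrast_bin: str
    rho_11: float
    rho_22: float
    rho_12: float
    partial_rho: float
    clamped: bool
    loglik: float
    converged: bool


def _psd_violation(a, b, c):
    return 4.0 * c * c - (1.0 + a) * (1.0 + b)


def _nll_quad(counts, d1, d2, a, b, c, gh_order=48):
    viol = _psd_violation(a, b, c)
    if viol > 0:
        return 1e8 * (1.0 + viol)
    p = np.clip(quad_pattern_probs(d1, d2, a, b, c, gh_order=gh_order),
                1e-300, 1.0)
    return -float(np.sum(counts * np.log(p)))


def _collapse(counts16, bit1, bit2):
    """Collapse 16-pattern counts onto the joint pattern of two passes."""
    out = np.zeros(counts16.shape[:-1] + (4,))
    for j in range(16):
        b = ((j >> (3 - bit1)) & 1, (j >> (3 - bit2)) & 1)
        out[..., (b[0] << 1) | b[1]] += counts16[..., j]
    return out


def _fit_rho_pair(counts4, m1, m2):
    """ML correlation of one pass pair with unequal normalized means."""
    signs = [(-1, -1), (-1, 1), (1, -1), (1, 1)]

    def nll(rho):
        p = np.stack([bvn_orthant(m1, m2, rho, s1, s2) for s1, s2 in signs],
                     axis=-1)
        return -float(np.sum(counts4 * np.log(np.clip(p, 1e-300, 1.0))))

    res = minimize_scalar(nll, bounds=(-_RHO_BOUND, _RHO_BOUND),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x)


def _fit_quad_condition(counts, d1, d2, *, cov_zero=False, sigma_ratio=1.0,
                        x0=None, xatol=1e-6, fatol=1e-9, gh_order=48):
    """Joint ML over (rho within group 1, within group 2, across groups)."""
    t = np.arctanh

    if x0 is None:
        a0 = _fit_rho(_collapse(counts, 0, 1), d1)[0]
        b0 = _fit_rho(_collapse(counts, 2, 3), d2)[0]
        c0 = _fit_rho_pair(_collapse(counts, 0, 2), d1, d2)
        cmax = 0.49 * np.sqrt(max((1 + a0) * (1 + b0), 1e-12)) * 2
        c0 = float(np.clip(c0, -cmax, cmax))
        x0 = (a0, b0, c0)
    x0 = np.clip(np.asarray(x0, dtype=float), -0.999, 0.999)

    if cov_zero:
        def unpack(th):
            a, b = np.tanh(th)
            return a, b, a * sigma_ratio
        starts = [t(x0[:2]), t([0.3, 0.3]), t([0.0, 0.0])]
    else:
        def unpack(th):
            return tuple(np.tanh(th))
        starts = [t(x0), t([0.3, 0.3, 0.2]), t([0.0, 0.0, 0.0])]

    warm = x0 is not None
    best = None
    for i, s in enumerate(starts):
        opts = {"xatol": xatol, "fatol": fatol, "maxiter": 3000}
        if warm and i == 0:
            # small simplex around the warm start: bootstrap refits move little
            opts["initial_simplex"] = s + 0.08 * np.vstack(
                [np.zeros(len(s)), np.eye(len(s))])
        res = minimize(lambda th: _nll_quad(counts, d1, d2, *unpack(th),
                                            gh_order=gh_order),
                       x0=s, method="Nelder-Mead", options=opts)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if i == 0 and res.success and res.fun < 1e7:
            break  # warm start converged; skip cold starts
    a, b, c = unpack(best.x)
    return (float(a), float(b), float(c), -float(best.fun), bool(best.success))


def estimate_quad(counts: AgreementCounts, sigma_t_flat, sigma_t_nat, *,
                  cov_zero: bool = False, x0: dict | None = None,
                  xatol: float = 1e-6, fatol: float = 1e-9,
                  gh_order: int = 48) -> list[QuadCorrelations]:
    """Quasi-quadruple-pass ML correlations per condition.

    ``counts`` must be 4-pass counts in (flat-1, flat-2, nat-1, nat-2)
    order; the two sigma arguments supply the frozen threshold SDs of the
    flattened and natural experiments.  ``cov_zero=True`` refits with the
    luminance/depth interaction pinned to zero, tying the cross-experiment
    correlation to the within-flattened one.  ``x0`` optionally maps
    condition -> (a, b, c) warm starts (used by the bootstrap).
    """
    if counts.n_passes != 4:
        raise ValueError("quadruple-pass estimation needs 4-pass counts")
    out = []
    for ped, cbin in counts.conditions():
        N, delta = counts.condition(ped, cbin)
        s1 = _sigma_for(sigma_t_flat, ped, cbin)
        s2 = _sigma_for(sigma_t_nat, ped, cbin)
        a, b, c, ll, ok = _fit_quad_condition(
            N, delta / s1, delta / s2, cov_zero=cov_zero,
            sigma_ratio=s1 / s2,
            x0=None if x0 is None else x0.get((ped, cbin)),
            xatol=xatol, fatol=fatol, gh_order=gh_order)
        out.append(QuadCorrelations(ped, cbin, a, b, c, ll, ok, cov_zero))
    return out


def estimate_between(counts: AgreementCounts, sigma_t_1, sigma_t_2, *,
                     x0: dict | None = None,
                     xatol: float = 1e-6) -> list[BetweenObserverCorrelations]:
    """Between-observer ML correlations per condition (one experiment).

    ``counts`` must be 4-pass counts in (obs1-1, obs1-2, obs2-1, obs2-2)
    order.  The partial correlation ``rho_12 / sqrt(rho_11 rho_22)``
    removes each observer's internal noise; values outside [-1, 1] are
    clamped and flagged.
    """
    if counts.n_passes != 4:
        raise ValueError("between-observer estimation needs 4-pass counts")
    out = []
    for ped, cbin in counts.conditions():
        N, delta = counts.condition(ped, cbin)
        s1 = _sigma_for(sigma_t_1, ped, cbin)
        s2 = _sigma_for(sigma_t_2, ped, cbin)
        a, b, c, ll, ok = _fit_quad_condition(
            N, delta / s1, delta / s2, sigma_ratio=s1 / s2,
            x0=None if x0 is None else x0.get((ped, cbin)), xatol=xatol)
        if a > 0 and b > 0:
            raw = c / np.sqrt(a * b)
            partial, clamped = float(np.clip(raw, -1.0, 1.0)), abs(raw) > 1
        else:
            partial, clamped = np.nan, False
        out.append(BetweenObserverCorrelations(ped, cbin, a, b, c,
                                               partial, clamped, ll, ok))
    return out
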