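"""Spatial-integration models of the trial-by-trial decision variable.

The headline analyses define a stimulus' disparity as the disparity of the
central pixel.  Observers might instead pool disparity over some
integration area.  This module builds alternative per-trial decision
variables — window-averaged disparity differences for pillbox windows of
several diameters, and three heuristics (largest near disparity, largest
far disparity, maximally deviant disparity) — and compares how well each
predicts the recorded binary responses by logistic regression, scored with
McFadden's pseudo-R^2 and AIC.

Convention: more negative disparity is farther (uncrossed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus_metrics import central_region

__all__ = [
    "DisparityMapTrial",
    "ModelComparisonRow",
    "windowed_dv",
    "heuristic_dv",
    "compare_models",
    "save_map_trials",
    "load_map_trials",
    "HEURISTICS",
]

HEURISTICS = ("nearest", "farthest", "max_deviant")


@dataclass
class DisparityMapTrial:
    """Per-trial disparity maps (arcmin/pixel) and the recorded response."""

    trial_id: int
    std_map: np.ndarray
    cmp_map: np.ndarray
    chose_comparison: int
    pedestal_arcmin: float = np.nan
    contrast_bin: str = ""
    observer_id: str = ""

    def __post_init__(self):
        self.std_map = np.asarray(self.std_map, dtype=float)
        self.cmp_map = np.asarray(self.cmp_map, dtype=float)
        if self.std_map.shape != self.cmp_map.shape:
            raise ValueError("standard and comparison maps must share a shape")


@dataclass
class ModelComparisonRow:
    """Fit quality of one candidate decision-variable model."""

    model: str
    pseudo_r2: float
    pseudo_r2_incremental: float
    aic: float
    delta_aic: float
    n_trials: int
    separation_flag: bool = False


def _pillbox(shape, diameter_px):
    if diameter_px >= max(shape):
        # the largest window is the entire patch, corners included
        return np.ones(shape, dtype=bool)
    if shape[0] != shape[1]:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        c = (shape[0] // 2, shape[1] // 2)
        return np.hypot(yy - c[0], xx - c[1]) <= diameter_px / 2.0 + 1e-9
    return central_region(shape[0], diameter_px)


def windowed_dv(trial: DisparityMapTrial, diameter_px: int) -> float:
    """Mean disparity difference within a central pillbox window (arcmin).

    At the full patch diameter the window covers every pixel, so the value
    equals the unweighted patch-mean difference.
    """
    shape = trial.std_map.shape
    if diameter_px < 1 or diameter_px > shape[0]:
        raise ValueError("diameter must lie in [1, patch width]")
    w = _pillbox(shape, diameter_px)
    if not w.any():
        raise ValueError("empty integration window")
    return float(np.mean(trial.cmp_map[w]) - np.mean(trial.std_map[w]))


def _heuristic_value(dmap: np.ndarray, heuristic: str) -> float:
    c = (dmap.shape[0] // 2, dmap.shape[1] // 2)
    if heuristic == "nearest":        # largest near = most positive (crossed)
        return float(dmap.max())
    if heuristic == "farthest":       # largest far = most negative (uncrossed)
        return float(dmap.min())
    if heuristic == "max_deviant":    # largest |deviation| from the center pixel
        center = dmap[c]
        flat = dmap.ravel()
        return float(flat[np.argmax(np.abs(flat - center))])
    raise ValueError(f"unknown heuristic {heuristic!r}; pick from {HEURISTICS}")


def heuristic_dv(trial: DisparityMapTrial, heuristic: str) -> float:
    """Decision variable from a disparity heuristic applied to both maps."""
    return (_heuristic_value(trial.cmp_map, heuristic)
            - _heuristic_value(trial.std_map, heuristic))


# ---------------------------------------------------------------------------
# on-disk layout: per-trial CSV matrices plus an index JSON
# ---------------------------------------------------------------------------

def save_map_trials(trials: list[DisparityMapTrial], directory) -> None:
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    index = []
    for t in trials:
        for role, m in (("std", t.std_map), ("cmp", t.cmp_map)):
            np.savetxt(d / f"trial{t.trial_id}_{role}.csv", m, delimiter=",")
        index.append({"trial_id": t.trial_id,
                      "chose_comparison": int(t.chose_comparison),
                      "pedestal_arcmin": t.pedestal_arcmin,
                      "contrast_bin": t.contrast_bin,
                      "observer_id": t.observer_id})
    (d / "index.json").write_text(json.dumps(index))


def load_map_trials(directory) -> list[DisparityMapTrial]:
    import json
    from pathlib import Path

    d = Path(directory)
    out = []
    for e in json.loads((d / "index.json").read_text()):
        tid = e["trial_id"]
        std = np.loadtxt(d / f"trial{tid}_std.csv", delimiter=",")
        cmp_ = np.loadtxt(d / f"trial{tid}_cmp.csv", delimiter=",")
        out.append(DisparityMapTrial(tid, std, cmp_, e["chose_comparison"],
                                     e["pedestal_arcmin"], e["contrast_bin"],
                                     e["observer_id"]))
    return out


# ---------------------------------------------------------------------------
# model comparison by logistic regression
# ---------------------------------------------------------------------------

def _fit_logistic(dv, chose, groups, group_slopes=True):
    """Logistic fit of responses on a decision variable with group terms.

    Group-indexed intercepts and (optionally) slopes realize the
    "conditioned by pedestal, disparity-contrast and observer" random
    effects structure as fixed group interactions.  Returns
    (loglik, k_params, loglik_null, separation_flag).
    """
    import statsmodels.api as sm

    dv = np.asarray(dv, dtype=float)
    chose = np.asarray(chose, dtype=int)
    g = pd.Categorical(groups)
    inter = pd.get_dummies(g, drop_first=False).to_numpy(dtype=float)
    X = [inter]
    if group_slopes:
        X.append(inter * dv[:, None])
    else:
        X.append(dv[:, None])
    X = np.hstack(X)
    sep = False
    try:
        res = sm.GLM(chose, X, family=sm.families.Binomial()).fit(maxiter=200)
        ll = float(res.llf)
        k = X.shape[1]
        if not np.isfinite(ll) or np.abs(res.params).max() > 1e3:
            raise RuntimeError("separation")
    except Exception:
        # quasi-separated data: refit with a weak ridge penalty and flag it
        sep = True
        res = sm.GLM(chose, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-4, L1_wt=0.0)
        mu = np.clip(1 / (1 + np.exp(-(X @ res.params))), 1e-12, 1 - 1e-12)
        ll = float(np.sum(chose * np.log(mu) + (1 - chose) * np.log1p(-mu)))
        k = X.shape[1]
    null = sm.GLM(chose, inter, family=sm.families.Binomial()).fit()
    return ll, k, float(null.llf), sep


def compare_models(trials: list[DisparityMapTrial],
                   window_diameters=(1, 4, 8, 16, 32),
                   heuristics=HEURISTICS,
                   group_slopes: bool = True) -> list[ModelComparisonRow]:
    """Score candidate decision-variable models on one trial set.

    Every model is fit to the identical trials: logistic regression of the
    binary response on the model's decision variable, with
    (pedestal, bin, observer)-indexed intercepts and slopes.  Reports
    McFadden's pseudo-R^2 against the intercept-only null (absolute) and
    against the group-intercept null (incremental), plus AIC and the AIC
    difference from the 1-px central-pixel model (or the first model when
    1 px is not in the sweep).
    """
    if not trials:
        raise ValueError("no trials to compare")
    chose = np.array([t.chose_comparison for t in trials], dtype=int)
    groups = [f"{t.observer_id}|{t.pedestal_arcmin}|{t.contrast_bin}"
              for t in trials]
    n = len(trials)

    candidates: list[tuple[str, np.ndarray]] = []
    for d in window_diameters:
        dv = np.array([windowed_dv(t, d) for t in trials])
        candidates.append((f"window_{d}px", dv))
    for h in heuristics:
        dv = np.array([heuristic_dv(t, h) for t in trials])
        candidates.append((h, dv))

    import statsmodels.api as sm
    ll0 = float(sm.GLM(chose, np.ones((n, 1)),
                       family=sm.families.Binomial()).fit().llf)

    rows = []
    for name, dv in candidates:
        ll, k, ll_group, sep = _fit_logistic(dv, chose, groups, group_slopes)
        rows.append(ModelComparisonRow(
            model=name,
            pseudo_r2=1.0 - ll / ll0 if ll0 != 0 else np.nan,
            pseudo_r2_incremental=(1.0 - ll / ll_group
                                   if ll_group != 0 else np.nan),
            aic=2.0 * k - 2.0 * ll, delta_aic=np.nan,
            n_trials=n, separation_flag=sep))
    ref = next((r for r in rows if r.model == "window_1px"), rows[0])
    for r in rows:
        r.delta_aic = r.aic - ref.aic
    return rows
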