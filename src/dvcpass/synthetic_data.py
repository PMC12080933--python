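"""Synthetic observers and stimuli for the double-pass study design.

The study design: two double-pass experiments (natural-depth and flattened
stimuli) share one set of unique trials.  Each unique trial pairs a
standard-disparity stimulus with a comparison stimulus; the observer
reports which interval was farther.  Five uncrossed disparity pedestals
crossed with two disparity-contrast bins define ten conditions; the method
of constant stimuli places five comparison levels (including the standard
itself) around each pedestal, with one hundred repeats each, so an
experiment has 5000 unique trials and an observer contributes 20,000
presentations across the four passes.

The generative observer realizes the decision-variable model.  Per unique
trial a luminance-pattern perturbation ``L`` is drawn once and shared by
all four passes of both experiments; a local-depth perturbation ``B``
(jointly normal with ``L``) is drawn once and enters only the
natural-depth experiment; each pass adds fresh internal noise ``W``.  The
decision variable is ``D = (delta_cmp - delta_std) + L (+ B) + W`` and the
comparison is chosen when ``D`` exceeds the criterion (default zero).
Perturbations attach to the unique trial — the decision variable operates
on the standard/comparison difference — not to individual stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "GenerativeParams",
    "CondParams",
    "build_design",
    "simulate_observer",
    "comparison_steps_for",
    "loglinear_sd_table",
    "synth_patch",
    "synth_map_trials",
    "write_trials",
    "read_trials",
    "TRIAL_COLUMNS",
    "STUDY_PEDESTALS",
]

STUDY_PEDESTALS = (-11.25, -9.38, -7.5, -5.63, -3.75)  # arcmin, uncrossed

TRIAL_COLUMNS = [
    "observer_id", "experiment", "pass_idx", "trial_id", "pedestal_arcmin",
    "contrast_bin", "comparison_arcmin", "interval_of_comparison",
    "chose_comparison",
]

EXP_NATURAL = "natural"
EXP_FLATTENED = "flattened"


@dataclass
class DesignConfig:
    """Factorial layout of the two double-pass experiments.

    ``comparison_step`` is the spacing (arcmin) between adjacent comparison
    levels; a scalar applies everywhere, a dict keyed by
    ``(pedestal, bin)`` sets it per condition (see
    :func:`comparison_steps_for` to derive steps from generative
    parameters so the psychometric function spans roughly 10-90%).
    """

    pedestals: tuple = STUDY_PEDESTALS
    contrast_bins: tuple = ("low", "high")
    comparisons_per_pedestal: int = 5
    repeats_per_comparison: int = 100
    n_passes: int = 2
    experiments: tuple = (EXP_NATURAL, EXP_FLATTENED)
    comparison_step: float | dict = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("comparisons_per_pedestal", "repeats_per_comparison",
                     "n_passes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not self.pedestals or not self.contrast_bins:
            raise ValueError("pedestals and contrast_bins must be non-empty")

    def step_for(self, pedestal: float, cbin: str) -> float:
        if isinstance(self.comparison_step, dict):
            return float(self.comparison_step[(pedestal, cbin)])
        return float(self.comparison_step)

    def comparison_levels(self, pedestal: float, cbin: str) -> np.ndarray:
        """Equally spaced levels symmetric about (and including) the standard."""
        n = self.comparisons_per_pedestal
        offsets = np.arange(n) - (n - 1) / 2.0
        return pedestal + offsets * self.step_for(pedestal, cbin)

    @property
    def n_unique_trials(self) -> int:
        return (len(self.pedestals) * len(self.contrast_bins)
                * self.comparisons_per_pedestal * self.repeats_per_comparison)


class CondParams(NamedTuple):
    sigma_l: float
    sigma_b: float
    cov_lb: float
    sigma_i_flat: float
    sigma_i_nat: float


def _resolve(value, pedestal, cbin) -> float:
    if isinstance(value, dict):
        return float(value[(pedestal, cbin)])
    return float(value)


@dataclass
class GenerativeParams:
    """Per-condition SDs of the decision-variable components (arcmin).

    Each field is either a scalar (applies to every condition) or a dict
    keyed by ``(pedestal, bin)``.  ``sigma_b`` never contributes to the
    flattened experiment.  A log-linear pedestal law can be encoded by
    building the dicts with ``exp(m * pedestal + b)`` values.
    """

    sigma_l: float | dict = 1.0
    sigma_b: float | dict = 0.0
    cov_lb: float | dict = 0.0
    sigma_i_flat: float | dict = 1.0
    sigma_i_nat: float | dict = 1.0
    criterion: float = 0.0

    def lookup(self, pedestal: float, cbin: str) -> CondParams:
        try:
            p = CondParams(
                _resolve(self.sigma_l, pedestal, cbin),
                _resolve(self.sigma_b, pedestal, cbin),
                _resolve(self.cov_lb, pedestal, cbin),
                _resolve(self.sigma_i_flat, pedestal, cbin),
                _resolve(self.sigma_i_nat, pedestal, cbin),
            )
        except KeyError:
            raise KeyError(
                f"no generative parameters for condition "
                f"(pedestal={pedestal}, bin={cbin!r})") from None
        if min(p.sigma_l, p.sigma_b, p.sigma_i_flat, p.sigma_i_nat) < 0:
            raise ValueError(f"negative SD in condition ({pedestal}, {cbin!r})")
        if abs(p.cov_lb) > p.sigma_l * p.sigma_b + 1e-12:
            raise ValueError(
                f"|cov_lb| exceeds sigma_l*sigma_b in ({pedestal}, {cbin!r})")
        return p

    def sigma_t2(self, pedestal: float, cbin: str, experiment: str) -> float:
        """Total decision-variable variance implied for one condition."""
        p = self.lookup(pedestal, cbin)
        if experiment == EXP_FLATTENED:
            return p.sigma_l ** 2 + p.sigma_i_flat ** 2
        return (p.sigma_l ** 2 + p.sigma_b ** 2 + 2 * p.cov_lb
                + p.sigma_i_nat ** 2)


def loglinear_sd_table(m: float, b: float, pedestals, bins) -> dict:
    """Per-condition SDs following ``exp(m * pedestal + b)`` (arcmin).

    Convenience for building :class:`GenerativeParams` fields whose SDs
    obey the log-linear threshold law.
    """
    return {(p, cb): float(np.exp(m * p + b)) for p in pedestals for cb in bins}


def comparison_steps_for(params: GenerativeParams, config: DesignConfig,
                         experiment: str = EXP_NATURAL,
                         dprime_max: float | None = None) -> dict:
    """Steps placing the extreme comparisons at ~10% and ~90% chosen.

    The outermost of ``n`` symmetric levels sits ``(n-1)/2`` steps from the
    standard; choosing the step so that point reaches the target normalized
    mean (default ``ndtri(0.9)``) reproduces the intended 10-90% span.
    """
    from scipy.special import ndtri

    zmax = ndtri(0.9) if dprime_max is None else dprime_max
    half_span = (config.comparisons_per_pedestal - 1) / 2.0
    steps = {}
    for ped in config.pedestals:
        for cbin in config.contrast_bins:
            sig = np.sqrt(params.sigma_t2(ped, cbin, experiment))
            steps[(ped, cbin)] = zmax * sig / max(half_span, 1.0)
    return steps


def build_design(config: DesignConfig) -> pd.DataFrame:
    """Trial-record stubs (responses empty) for every experiment and pass.

    Unique trials are numbered once and shared one-to-one across the two
    experiments (paired scene locations); the interval carrying the
    comparison is randomized per unique trial from the config seed and held
    fixed across passes and experiments.
    """
    rows = {"trial_id": [], "pedestal_arcmin": [], "contrast_bin": [],
            "comparison_arcmin": []}
    tid = 0
    for ped in config.pedestals:
        for cbin in config.contrast_bins:
            levels = config.comparison_levels(ped, cbin)
            for lv in levels:
                for _ in range(config.repeats_per_comparison):
                    rows["trial_id"].append(tid)
                    rows["pedestal_arcmin"].append(ped)
                    rows["contrast_bin"].append(cbin)
                    rows["comparison_arcmin"].append(float(lv))
                    tid += 1
    unique = pd.DataFrame(rows)
    rng = np.random.default_rng(config.seed)
    unique["interval_of_comparison"] = rng.integers(1, 3, size=len(unique))

    parts = []
    for exp in config.experiments:
        for p in range(1, config.n_passes + 1):
            part = unique.copy()
            part.insert(0, "observer_id", "")
            part.insert(1, "experiment", exp)
            part.insert(2, "pass_idx", p)
            parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out["chose_comparison"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out[TRIAL_COLUMNS]


def simulate_observer(schedule: pd.DataFrame, params: GenerativeParams,
                      seed: int, observer_id: str = "obs1") -> pd.DataFrame:
    """Fill a schedule with responses from the generative observer model.

    Per unique trial, (L, B) are drawn once from their joint normal and
    reused across passes (and, for L, across experiments); internal noise
    is fresh per presentation, with the flattened/natural SD of the trial's
    condition.  All draws derive from ``seed`` via independent substreams
    (stimulus perturbations; one noise stream per experiment).
    """
    df = schedule.copy()
    df["observer_id"] = observer_id

    unique = (df[["trial_id", "pedestal_arcmin", "contrast_bin",
                  "comparison_arcmin"]]
              .drop_duplicates("trial_id").sort_values("trial_id")
              .reset_index(drop=True))
    conds = list(unique.groupby(["pedestal_arcmin", "contrast_bin"]).groups)
    par = {c: params.lookup(*c) for c in conds}

    key = list(zip(unique["pedestal_arcmin"], unique["contrast_bin"]))
    sig_l = np.array([par[c].sigma_l for c in key])
    sig_b = np.array([par[c].sigma_b for c in key])
    cov = np.array([par[c].cov_lb for c in key])

    ss = np.random.SeedSequence(seed)
    stim_ss, *noise_ss = ss.spawn(1 + df["experiment"].nunique())
    stim_rng = np.random.default_rng(stim_ss)
    z1 = stim_rng.standard_normal(len(unique))
    z2 = stim_rng.standard_normal(len(unique))
    L = sig_l * z1
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(sig_l > 0, cov / np.where(sig_l > 0, sig_l, 1.0), 0.0)
    B = a * z1 + np.sqrt(np.maximum(sig_b ** 2 - a ** 2, 0.0)) * z2

    stim = pd.DataFrame({"trial_id": unique["trial_id"], "_L": L, "_B": B})
    df = df.merge(stim, on="trial_id", how="left")

    noise_rngs = {exp: np.random.default_rng(s)
                  for exp, s in zip(sorted(df["experiment"].unique()), noise_ss)}
    sig_i = np.empty(len(df))
    w = np.empty(len(df))
    for exp, sub in df.groupby("experiment"):
        k = [(p, b) for p, b in zip(sub["pedestal_arcmin"], sub["contrast_bin"])]
        col = "sigma_i_flat" if exp == EXP_FLATTENED else "sigma_i_nat"
        sig_i[sub.index] = [getattr(par[c], col) for c in k]
        w[sub.index] = noise_rngs[exp].standard_normal(len(sub))

    delta = df["comparison_arcmin"].to_numpy() - df["pedestal_arcmin"].to_numpy()
    ext = df["_L"].to_numpy() + np.where(
        df["experiment"].to_numpy() == EXP_FLATTENED, 0.0, df["_B"].to_numpy())
    d_var = delta + ext + sig_i * w
    df["chose_comparison"] = pd.array((d_var > params.criterion).astype(int),
                                      dtype="Int64")
    return df.drop(columns=["_L", "_B"])[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# synthetic range-registered patches
# ---------------------------------------------------------------------------

def synth_patch(seed: int, size_px: int = 32, disparity_contrast_target: float = 0.0,
                pedestal: float = 0.0, halfocc_fraction: float = 0.0,
                central_diam_px: int = 4, smooth_px: float = 2.0):
    """Synthetic stereo patch hitting an exact disparity-contrast target.

    The half-images are smoothed Gaussian noise around a photopic mean; the
    vergence-demand map is constant at the pedestal demand inside the
    central pillbox and carries a smooth perturbation outside, scaled so the
    whole-patch disparity-contrast equals the target to ~1e-12 arcmin (the
    statistic is linear in a common scaling of the deviations).  An optional
    fraction of surround pixels is marked half-occluded; those pixels are
    excluded from the statistic, so the target is hit on the valid pixels.
    """
    from scipy.ndimage import gaussian_filter

    from .stimulus_metrics import StereoPatch, central_region, disparity_contrast

    if size_px < 8:
        raise ValueError("size_px must be at least 8")
    if disparity_contrast_target < 0:
        raise ValueError("disparity-contrast target must be non-negative")
    rng = np.random.default_rng(seed)

    base = gaussian_filter(rng.standard_normal((size_px, size_px)), smooth_px)
    base = base / max(base.std(), 1e-12)
    lum = 100.0 * (1.0 + 0.3 * base)
    left = lum
    right = lum.copy()

    center = central_region(size_px, central_diam_px)
    mask = np.zeros((size_px, size_px), dtype=bool)
    if halfocc_fraction > 0:
        mask = (rng.random((size_px, size_px)) < halfocc_fraction) & ~center

    vmap = np.full((size_px, size_px), float(pedestal))
    patch = StereoPatch(left, right, vmap, v0=float(pedestal), halfocc_mask=mask)
    if disparity_contrast_target == 0:
        return patch

    pert = gaussian_filter(rng.standard_normal((size_px, size_px)), smooth_px)
    pert = np.where(center, 0.0, pert)
    trial = StereoPatch(left, right, pedestal + pert, v0=float(pedestal),
                        halfocc_mask=mask)
    dc = disparity_contrast(trial)
    if dc <= 0:
        raise ValueError("disparity-contrast target unreachable: "
                         "perturbation vanished outside the central region")
    vmap = pedestal + (disparity_contrast_target / dc) * pert
    return StereoPatch(left, right, vmap, v0=float(pedestal), halfocc_mask=mask)


# ---------------------------------------------------------------------------
# synthetic disparity-map trials for the spatial-integration analysis
# ---------------------------------------------------------------------------

def synth_map_trials(seed: int, n_per_condition: int = 150, size_px: int = 32,
                     pedestals=(-7.5,), contrast_bins=("high",),
                     comparison_step: float = 1.0, n_levels: int = 5,
                     generative_diameter: int = 1, noise_sd: float = 1.0,
                     map_sd: float = 1.0, smooth_px: float = 3.0,
                     observer_id: str = "obs1") -> list:
    """Disparity-map trials with responses from a known integration rule.

    Each stimulus map is its nominal disparity plus smooth spatial noise
    (SD ``map_sd`` arcmin); the simulated observer pools the
    comparison-minus-standard map difference over a pillbox of
    ``generative_diameter`` px (1 = the central pixel), adds internal
    noise, and responds on the sign.  Ground truth for testing which
    window size the model comparison should select.
    """
    from scipy.ndimage import gaussian_filter

    from .spatial_integration import DisparityMapTrial, windowed_dv

    rng = np.random.default_rng(seed)
    offsets = np.arange(n_levels) - (n_levels - 1) / 2.0
    trials = []
    tid = 0
    for ped in pedestals:
        for cbin in contrast_bins:
            for off in offsets:
                cmp_val = ped + off * comparison_step
                for _ in range(n_per_condition):
                    maps = []
                    for nominal in (ped, cmp_val):
                        noise = gaussian_filter(
                            rng.standard_normal((size_px, size_px)), smooth_px)
                        sd = noise.std()
                        noise = noise / sd * map_sd if sd > 0 else noise
                        maps.append(nominal + noise)
                    t = DisparityMapTrial(tid, maps[0], maps[1], 0,
                                          pedestal_arcmin=ped,
                                          contrast_bin=cbin,
                                          observer_id=observer_id)
                    dv = windowed_dv(t, generative_diameter)
                    t.chose_comparison = int(dv + noise_sd
                                             * rng.standard_normal() > 0)
                    trials.append(t)
                    tid += 1
    return trials


# ---------------------------------------------------------------------------
# trial-record CSV
# ---------------------------------------------------------------------------

def write_trials(records: pd.DataFrame, path: str | Path) -> None:
    """Write trial records with the canonical header."""
    records[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    df["chose_comparison"] = df["chose_comparison"].astype("Int64")
    return df[TRIAL_COLUMNS]
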