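"""Stimulus statistics for windowed stereo-image patches.

A stereo patch pairs left/right-eye luminance images with a per-pixel
vergence-demand map (the eye-rotation angle needed to fixate each scene
point; differences in demand are relative disparities).  Two statistics
characterize a patch:

* *disparity-contrast* — the window-weighted RMS deviation of vergence
  demand from the central corresponding point, the measure of local-depth
  variability (arcmin);
* *RMS contrast* — the window-weighted binocular RMS of the Weber-contrast
  half-images (unitless).

The module also implements contrast fixing (rescaling both half-images to a
target RMS contrast), flattening (duplicating one half-image so the depth
profile becomes a fronto-parallel plane), and the vetting filter that
rejects patches whose central region has substantial disparity variation or
half-occluded pixels and assigns the surviving patches to low/high
disparity-contrast bins.

Pixels flagged half-occluded (visible to one eye only) have undefined
disparity and are excluded, with weight renormalization, from the
disparity-contrast sums.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "StereoPatch",
    "VettingReport",
    "hann_window",
    "disparity_contrast",
    "rms_contrast",
    "rms_of_contrast",
    "weber_contrast",
    "fix_contrast",
    "flatten",
    "vet_patch",
    "write_vetting_reports",
    "read_vetting_reports",
    "central_region",
    "save_patch",
    "load_patch",
    "DEFAULT_BINS",
]

PX_PER_DEG = 32  # patch convention: 32 px subtend 1 degree of visual angle
DEFAULT_BINS = {"low": (0.025, 0.117), "high": (0.393, 1.375)}  # arcmin


def hann_window(size: int, *, separable: bool = True) -> np.ndarray:
    """Raised-cosine window, peak at the center pixel ``size // 2``.

    ``separable=True`` gives the outer product of two 1-D Hann profiles;
    ``False`` gives a radial raised cosine.  Both conventions are exposed
    because either is a defensible reading of "raised-cosine window".
    """
    if size < 2:
        raise ValueError("window size must be at least 2")
    c = size // 2
    if separable:
        i = np.arange(size)
        w1 = 0.5 * (1.0 + np.cos(np.pi * (i - c) / c))
        w1 = np.clip(w1, 0.0, None)
        return np.outer(w1, w1)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    return np.where(r <= c, 0.5 * (1.0 + np.cos(np.pi * r / c)), 0.0)


@dataclass
class StereoPatch:
    """Left/right luminance images + vergence-demand map under one window."""

    left_img: np.ndarray
    right_img: np.ndarray
    vergence_map: np.ndarray       # arcmin
    v0: float                      # vergence demand of the central point, arcmin
    window: np.ndarray | None = None
    halfocc_mask: np.ndarray | None = None  # True where half-occluded
    px_per_deg: int = PX_PER_DEG

    def __post_init__(self):
        self.left_img = np.asarray(self.left_img, dtype=float)
        self.right_img = np.asarray(self.right_img, dtype=float)
        self.vergence_map = np.asarray(self.vergence_map, dtype=float)
        shp = self.left_img.shape
        if self.window is None:
            self.window = hann_window(shp[0])
        if self.halfocc_mask is None:
            self.halfocc_mask = np.zeros(shp, dtype=bool)
        for name, arr in (("right_img", self.right_img),
                          ("vergence_map", self.vergence_map),
                          ("window", self.window),
                          ("halfocc_mask", self.halfocc_mask)):
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != left_img {shp}")
        if np.any(self.window < 0):
            raise ValueError("window weights must be non-negative")
        c = shp[0] // 2
        if not np.isclose(self.vergence_map[c, c], self.v0, atol=1e-9):
            raise ValueError("v0 must equal the vergence demand at the center pixel")

    @property
    def size(self) -> int:
        return self.left_img.shape[0]

    @property
    def center(self) -> tuple[int, int]:
        c = self.size // 2
        return c, c


def central_region(size: int, diameter_px: int) -> np.ndarray:
    """Boolean pillbox of the given diameter centered on the center pixel.

    A pixel belongs to the region if its center lies within ``diameter/2``
    of the patch center; boundary ties are included.
    """
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(yy - c, xx - c) <= diameter_px / 2.0 + 1e-9


def _resolve_region(patch: StereoPatch, region) -> np.ndarray:
    if region is None:
        return np.ones_like(patch.vergence_map, dtype=bool)
    if np.isscalar(region):
        return central_region(patch.size, int(region))
    return np.asarray(region, dtype=bool)


def disparity_contrast(patch: StereoPatch, region=None) -> float:
    """Windowed RMS deviation of vergence demand from the center (arcmin).

    ``region`` restricts the sum (None = whole patch, an int = a central
    pillbox of that diameter in px, or a boolean mask).  Half-occluded
    pixels are excluded and the window renormalized over the remainder.
    """
    sel = _resolve_region(patch, region) & ~patch.halfocc_mask
    w = patch.window[sel]
    if w.sum() <= 0:
        raise ValueError("no unmasked pixels with positive weight in region")
    dev = patch.vergence_map[sel] - patch.v0
    return float(np.sqrt(np.sum(dev * dev * w) / np.sum(w)))


def weber_contrast(img: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Weber-contrast image ``(I - Ibar) / Ibar`` with windowed mean ``Ibar``."""
    mean = float(np.sum(img * window) / np.sum(window))
    if mean <= 0:
        raise ValueError("mean luminance must be positive")
    return (img - mean) / mean


def rms_of_contrast(c_left: np.ndarray, c_right: np.ndarray,
                    window: np.ndarray) -> float:
    """Binocular windowed RMS of a pair of Weber-contrast images."""
    num = np.sum((c_left ** 2 + c_right ** 2) * window)
    return float(np.sqrt(num / np.sum(window)))


def rms_contrast(patch: StereoPatch) -> float:
    """RMS contrast of the patch (unitless)."""
    cl = weber_contrast(patch.left_img, patch.window)
    cr = weber_contrast(patch.right_img, patch.window)
    return rms_of_contrast(cl, cr, patch.window)


def fix_contrast(patch: StereoPatch, target: float) -> StereoPatch:
    """Rescale both half-images by one factor so RMS contrast hits ``target``.

    The Weber-contrast images scale linearly under a common luminance gain
    about the mean, so the factor is simply ``target / current``.  The
    luminance images are reconstructed about their original windowed means.
    """
    current = rms_contrast(patch)
    if current <= 0:
        raise ValueError("cannot fix the contrast of a zero-contrast patch")
    s = target / current
    out = {}
    for name, img in (("left_img", patch.left_img), ("right_img", patch.right_img)):
        mean = float(np.sum(img * patch.window) / np.sum(patch.window))
        out[name] = mean + s * (img - mean)
    return replace(patch, **out)


def flatten(patch: StereoPatch, keep_eye: str = "random",
            seed: int | None = None) -> StereoPatch:
    """Duplicate one half-image into the other and flatten the depth profile.

    The vergence-demand map becomes constant at ``v0`` (zero
    disparity-contrast, a fronto-parallel plane) and the half-occlusion mask
    empties: identical half-images have no monocular regions.  Idempotent.
    """
    if keep_eye == "random":
        rng = np.random.default_rng(seed)
        keep_eye = "left" if rng.integers(2) == 0 else "right"
    if keep_eye not in ("left", "right"):
        raise ValueError("keep_eye must be 'left', 'right' or 'random'")
    img = patch.left_img if keep_eye == "left" else patch.right_img
    return replace(patch,
                   left_img=img.copy(), right_img=img.copy(),
                   vergence_map=np.full_like(patch.vergence_map, patch.v0),
                   halfocc_mask=np.zeros_like(patch.halfocc_mask))


@dataclass
class VettingReport:
    """Outcome of the central-coherence vetting filter for one patch."""

    accepted: bool
    reasons: list = field(default_factory=list)
    central_dc_arcsec: float = np.nan
    bin: str = "none"   # 'low' / 'high' / 'none'


def vet_patch(patch: StereoPatch, central_diam_px: int = 4,
              central_tol_arcsec: float = 20.0,
              bins: dict | None = None) -> VettingReport:
    """Vet a patch for inclusion and assign its disparity-contrast bin.

    Rejects when the central pillbox region has disparity-contrast above
    ``central_tol_arcsec`` (the center must be a coherent depth target) or
    contains half-occluded pixels.  The bin is assigned from the whole-patch
    disparity-contrast; 'none' if it falls outside every range.
    """
    if central_diam_px > patch.size:
        raise ValueError("central region does not fit inside the patch")
    bins = DEFAULT_BINS if bins is None else bins
    reasons = []
    sel = central_region(patch.size, central_diam_px)
    if np.any(patch.halfocc_mask & sel):
        reasons.append("half-occluded pixels in the central region")
        central_dc = np.nan
    else:
        central_dc = disparity_contrast(patch, region=sel) * 60.0  # arcsec
        if central_dc > central_tol_arcsec:
            reasons.append(
                f"central disparity-contrast {central_dc:.1f} arcsec "
                f"> {central_tol_arcsec:g} arcsec")
    whole = disparity_contrast(patch)
    label = "none"
    for name, (lo, hi) in bins.items():
        if lo <= whole <= hi:
            label = name
            break
    return VettingReport(accepted=not reasons, reasons=reasons,
                         central_dc_arcsec=float(central_dc), bin=label)


# ---------------------------------------------------------------------------
# on-disk layout: TIFF half-images + CSV vergence map sharing a basename
# ---------------------------------------------------------------------------

def write_vetting_reports(reports: list[VettingReport], path: str | Path) -> None:
    """Append-style JSON-lines dump of vetting outcomes."""
    with open(path, "w") as fh:
        for r in reports:
            fh.write(json.dumps({
                "accepted": bool(r.accepted), "reasons": list(r.reasons),
                "central_dc_arcsec": (None if np.isnan(r.central_dc_arcsec)
                                      else float(r.central_dc_arcsec)),
                "bin": r.bin}) + "\n")


def read_vetting_reports(path: str | Path) -> list[VettingReport]:
    out = []
    for line in Path(path).read_text().splitlines():
        d = json.loads(line)
        out.append(VettingReport(
            accepted=d["accepted"], reasons=d["reasons"],
            central_dc_arcsec=(np.nan if d["central_dc_arcsec"] is None
                               else d["central_dc_arcsec"]),
            bin=d["bin"]))
    return out


def save_patch(patch: StereoPatch, basename: str | Path) -> None:
    import tifffile

    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(base.with_suffix(".L.tif"), patch.left_img.astype(np.float32))
    tifffile.imwrite(base.with_suffix(".R.tif"), patch.right_img.astype(np.float32))
    np.savetxt(base.with_suffix(".vmap.csv"), patch.vergence_map, delimiter=",")
    if patch.halfocc_mask.any():
        np.savetxt(base.with_suffix(".mask.csv"),
                   patch.halfocc_mask.astype(int), fmt="%d", delimiter=",")
    meta = {"v0": patch.v0, "px_per_deg": patch.px_per_deg,
            "window": "hann_separable"}
    base.with_suffix(".meta.json").write_text(json.dumps(meta))


def load_patch(basename: str | Path) -> StereoPatch:
    import tifffile

    base = Path(basename)
    left = np.asarray(tifffile.imread(base.with_suffix(".L.tif")), dtype=float)
    right = np.asarray(tifffile.imread(base.with_suffix(".R.tif")), dtype=float)
    vmap = np.loadtxt(base.with_suffix(".vmap.csv"), delimiter=",")
    meta = json.loads(base.with_suffix(".meta.json").read_text())
    mask_path = base.with_suffix(".mask.csv")
    mask = (np.loadtxt(mask_path, delimiter=",").astype(bool)
            if mask_path.exists() else None)
    return StereoPatch(left, right, vmap, v0=float(meta["v0"]),
                       halfocc_mask=mask, px_per_deg=int(meta["px_per_deg"]))
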