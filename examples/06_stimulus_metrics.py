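"""Stimulus statistics on synthetic range-registered stereo patches.

Disparity-contrast is the windowed RMS deviation of per-pixel vergence
demand from the central corresponding point; RMS contrast pools the
Weber-contrast half-images binocularly under the same raised-cosine
window.
"""

from dvcpass.stimulus_metrics import (disparity_contrast, fix_contrast,
                                      flatten, rms_contrast, vet_patch)
from dvcpass.synthetic_data import synth_patch

patch = synth_patch(seed=9, disparity_contrast_target=0.75, pedestal=-7.5,
                    halfocc_fraction=0.05)
print(f"disparity-contrast          : {disparity_contrast(patch):.6f} arcmin")
print(f"central region (4 px)       : "
      f"{disparity_contrast(patch, region=4) * 60:.2f} arcsec")
print(f"RMS contrast (raw)          : {rms_contrast(patch):.4f}")

fixed = fix_contrast(patch, 0.3)
print(f"RMS contrast (fixed)        : {rms_contrast(fixed):.4f}")

report = vet_patch(fixed)
print(f"vetting                     : accepted={report.accepted}, "
      f"bin={report.bin!r}")

flat = flatten(fixed, keep_eye="left")
print(f"after flattening            : disparity-contrast = "
      f"{disparity_contrast(flat):.1f}, images identical = "
      f"{(flat.left_img == flat.right_img).all()}")
print("\nA flat center (under 20 arcsec) makes the patch a coherent depth "
      "target; whole-patch disparity-contrast of 0.75 arcmin lands in the "
      "'high' local-depth-variability bin. Flattening removes all "
      "stereo-specified depth structure while keeping the luminance image.")
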