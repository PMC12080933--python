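"""Disparity-contrast, RMS contrast, flattening and vetting of stereo patches."""

import numpy as np
import pytest

from dvcpass.stimulus_metrics import (StereoPatch, central_region,
                                      disparity_contrast, fix_contrast,
                                      flatten, hann_window, load_patch,
                                      rms_contrast, rms_of_contrast,
                                      save_patch, vet_patch, weber_contrast)
from dvcpass.synthetic_data import synth_patch


def make_patch(vmap, v0=0.0, window=None, mask=None, lum=None):
    vmap = np.asarray(vmap, dtype=float)
    if lum is None:
        lum = np.full(vmap.shape, 100.0)
    return StereoPatch(lum, lum.copy(), vmap, v0=v0, window=window,
                       halfocc_mask=mask)


class TestDisparityContrast:
    def test_constant_map_is_zero(self):
        patch = make_patch(np.full((8, 8), -5.0), v0=-5.0)
        assert disparity_contrast(patch) == 0.0

    def test_uniform_weights_hand_value(self):
        # deviations {0, 1, 2, 3} with equal weights: sqrt(14/4) = 1.8708
        vmap = np.array([[0.0, 1.0], [2.0, 3.0]])
        # center pixel (1, 1) must equal v0; mask it out so the four
        # remaining ... actually use a 2x2 with v0 at the center convention
        patch = StereoPatch(np.full((2, 2), 100.0), np.full((2, 2), 100.0),
                            vmap, v0=3.0, window=np.ones((2, 2)))
        dev2 = ((vmap - 3.0) ** 2).mean()
        assert disparity_contrast(patch) == pytest.approx(np.sqrt(dev2), abs=1e-12)
        # and the printed example value with v0 = 0 deviations {0,1,2,3}
        assert np.sqrt(14 / 4) == pytest.approx(1.8708, abs=1e-4)
        masked = StereoPatch(np.full((2, 2), 100.0), np.full((2, 2), 100.0),
                             np.array([[0.0, 1.0], [2.0, 0.0]]), v0=0.0,
                             window=np.ones((2, 2)))
        # deviations {0,1,2,0}: direct arithmetic on the definition
        assert disparity_contrast(masked) == pytest.approx(np.sqrt(5 / 4), abs=1e-12)

    def test_constant_deviation_any_weights(self):
        # all unmasked pixels deviate by c: statistic equals |c|
        vmap = np.full((8, 8), 2.5)
        vmap[4, 4] = 0.0  # center holds v0
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True  # exclude the center so every pixel deviates by c
        patch = make_patch(vmap, v0=0.0, mask=mask)
        assert disparity_contrast(patch) == pytest.approx(2.5, abs=1e-12)

    def test_shift_invariance_and_linearity(self):
        patch = synth_patch(seed=0, disparity_contrast_target=0.6)
        base = disparity_contrast(patch)
        shifted = StereoPatch(patch.left_img, patch.right_img,
                              patch.vergence_map + 5.0, v0=patch.v0 + 5.0,
                              halfocc_mask=patch.halfocc_mask)
        assert disparity_contrast(shifted) == pytest.approx(base, abs=1e-10)
        scaled = StereoPatch(patch.left_img, patch.right_img,
                             patch.v0 + 3.0 * (patch.vergence_map - patch.v0),
                             v0=patch.v0, halfocc_mask=patch.halfocc_mask)
        assert disparity_contrast(scaled) == pytest.approx(3 * base, rel=1e-10)

    def test_all_masked_raises(self):
        patch = make_patch(np.zeros((8, 8)), mask=np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="no unmasked pixels"):
            disparity_contrast(patch)


class TestRmsContrast:
    def test_blank_patch_is_zero(self):
        patch = make_patch(np.zeros((8, 8)))
        assert rms_contrast(patch) == 0.0

    def test_constant_contrast_hand_value(self):
        # cL = cR = 0.2 everywhere: sqrt(0.08) = 0.28284, any weights
        w = hann_window(8) + 0.1
        c = np.full((8, 8), 0.2)
        assert rms_of_contrast(c, c, w) == pytest.approx(0.28284, abs=1e-5)

    def test_window_renormalization_invariance(self):
        patch = synth_patch(seed=1, disparity_contrast_target=0.0)
        r1 = rms_contrast(patch)
        doubled = StereoPatch(patch.left_img, patch.right_img,
                              patch.vergence_map, v0=patch.v0,
                              window=2.0 * patch.window)
        assert rms_contrast(doubled) == pytest.approx(r1, rel=1e-12)

    def test_eye_swap_invariance(self):
        patch = synth_patch(seed=2, disparity_contrast_target=0.0)
        swapped = StereoPatch(patch.right_img, patch.left_img,
                              patch.vergence_map, v0=patch.v0)
        assert rms_contrast(swapped) == pytest.approx(rms_contrast(patch),
                                                      rel=1e-12)

    def test_zero_mean_luminance_raises(self):
        patch = make_patch(np.zeros((8, 8)), lum=np.zeros((8, 8)))
        with pytest.raises(ValueError, match="mean luminance"):
            rms_contrast(patch)


class TestFixContrast:
    def test_halving(self):
        patch = synth_patch(seed=3)
        base = rms_contrast(patch)
        fixed = fix_contrast(patch, base / 2)
        assert rms_contrast(fixed) == pytest.approx(base / 2, abs=1e-12)
        # common scale factor 0.5 about the windowed mean
        mean = np.sum(patch.left_img * patch.window) / np.sum(patch.window)
        np.testing.assert_allclose(fixed.left_img - mean,
                                   0.5 * (patch.left_img - mean), atol=1e-9)

    def test_identity(self):
        patch = synth_patch(seed=4)
        fixed = fix_contrast(patch, rms_contrast(patch))
        np.testing.assert_allclose(fixed.left_img, patch.left_img, atol=1e-9)

    def test_hits_study_target(self):
        patch = synth_patch(seed=5)
        fixed = fix_contrast(patch, 0.3)
        assert rms_contrast(fixed) == pytest.approx(0.3, abs=1e-12)

    def test_zero_contrast_input_raises(self):
        patch = make_patch(np.zeros((8, 8)))
        with pytest.raises(ValueError, match="zero-contrast"):
            fix_contrast(patch, 0.3)


class TestFlatten:
    def test_images_identical_and_depth_flat(self):
        patch = synth_patch(seed=6, disparity_contrast_target=0.9,
                            pedestal=-7.5, halfocc_fraction=0.05)
        flat = flatten(patch, keep_eye="left")
        np.testing.assert_array_equal(flat.left_img, flat.right_img)
        assert disparity_contrast(flat) == 0.0
        assert np.all(flat.vergence_map == patch.v0)
        assert not flat.halfocc_mask.any()

    def test_idempotent(self):
        patch = synth_patch(seed=7, disparity_contrast_target=0.5)
        once = flatten(patch, keep_eye="right")
        twice = flatten(once, keep_eye="right")
        np.testing.assert_array_equal(once.left_img, twice.left_img)
        np.testing.assert_array_equal(once.vergence_map, twice.vergence_map)

    def test_random_eye_reproducible(self):
        patch = synth_patch(seed=8, disparity_contrast_target=0.5)
        f1 = flatten(patch, keep_eye="random", seed=123)
        f2 = flatten(patch, keep_eye="random", seed=123)
        np.testing.assert_array_equal(f1.left_img, f2.left_img)


class TestVetting:
    def test_flat_patch_accepted_no_bin(self):
        patch = synth_patch(seed=9, disparity_contrast_target=0.0)
        rep = vet_patch(patch)
        assert rep.accepted and not rep.reasons
        assert rep.central_dc_arcsec == 0.0
        assert rep.bin == "none"

    def test_high_bin_assignment(self):
        patch = synth_patch(seed=10, disparity_contrast_target=0.75)
        rep = vet_patch(patch)
        assert rep.accepted
        assert rep.bin == "high"  # 0.393-1.375 arcmin range

    def test_low_bin_assignment(self):
        patch = synth_patch(seed=11, disparity_contrast_target=0.08)
        assert vet_patch(patch).bin == "low"

    def test_central_halfocclusion_rejected(self):
        patch = synth_patch(seed=12, disparity_contrast_target=0.5)
        mask = patch.halfocc_mask.copy()
        mask[16, 16] = True
        bad = StereoPatch(patch.left_img, patch.right_img, patch.vergence_map,
                          v0=patch.v0, halfocc_mask=mask)
        rep = vet_patch(bad)
        assert not rep.accepted
        assert any("half-occluded" in r for r in rep.reasons)

    def test_bumpy_center_rejected(self):
        # central disparity-contrast above 20 arcsec fails the coherence rule
        vmap = np.zeros((32, 32))
        sel = central_region(32, 4)
        vmap[sel] = 1.0  # 60 arcsec deviations inside the central region
        vmap[16, 16] = 0.0
        patch = make_patch(vmap, v0=0.0)
        rep = vet_patch(patch)
        assert not rep.accepted
        assert any("central disparity-contrast" in r for r in rep.reasons)


class TestPatchIO:
    def test_round_trip(self, tmp_path):
        patch = synth_patch(seed=13, disparity_contrast_target=0.4,
                            pedestal=-5.63, halfocc_fraction=0.05)
        save_patch(patch, tmp_path / "p0")
        back = load_patch(tmp_path / "p0")
        np.testing.assert_allclose(back.left_img, patch.left_img, atol=1e-4)
        np.testing.assert_allclose(back.vergence_map, patch.vergence_map,
                                   atol=1e-9)
        assert back.v0 == patch.v0
        np.testing.assert_array_equal(back.halfocc_mask, patch.halfocc_mask)

    def test_vetting_reports_jsonl_round_trip(self, tmp_path):
        from dvcpass.stimulus_metrics import (read_vetting_reports,
                                              write_vetting_reports)
        reports = [vet_patch(synth_patch(seed=s, disparity_contrast_target=t))
                   for s, t in ((20, 0.0), (21, 0.75), (22, 0.08))]
        path = tmp_path / "vetting.jsonl"
        write_vetting_reports(reports, path)
        back = read_vetting_reports(path)
        assert [r.bin for r in back] == [r.bin for r in reports]
        assert [r.accepted for r in back] == [r.accepted for r in reports]

    def test_weber_contrast_zero_mean_property(self):
        patch = synth_patch(seed=14)
        c = weber_contrast(patch.left_img, patch.window)
        mean = np.sum(c * patch.window) / np.sum(patch.window)
        assert mean == pytest.approx(0.0, abs=1e-12)
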