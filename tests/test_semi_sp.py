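"""ROI geometry, loading, resizing and CLAHE behavior."""

import numpy as np
import pytest
from PIL import Image

from sffnet.semi_sp import (
    ImageSlice,
    LesionMask,
    SquareROI,
    apply_strategy,
    clahe_enhance,
    crop_resize,
    lesion_bbox,
    load_slice,
    read_patch,
    square_roi,
    write_patch,
)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadSlice:
    def test_png_binary_values_normalize_to_unit_endpoints(self, tmp_path):
        arr = np.zeros((16, 16), np.uint8)
        arr[4:8, 4:8] = 255
        Image.fromarray(arr).save(tmp_path / "img.png")
        Image.fromarray((arr > 0).astype(np.uint8) * 255).save(tmp_path / "mask.png")
        sl, mask = load_slice(tmp_path / "img.png", tmp_path / "mask.png")
        assert set(np.unique(sl.pixels)) == {0.0, 1.0}
        assert mask.num_foreground == 16

    def test_constant_image_maps_to_zero(self, tmp_path):
        arr = np.full((16, 16), 128, np.uint8)
        Image.fromarray(arr).save(tmp_path / "img.png")
        m = np.zeros((16, 16), np.uint8)
        m[8, 8] = 255
        Image.fromarray(m).save(tmp_path / "mask.png")
        sl, _ = load_slice(tmp_path / "img.png", tmp_path / "mask.png")
        assert np.all(sl.pixels == 0.0)

    def test_nrrd_16bit_midpoint_maps_to_half(self, tmp_path):
        import SimpleITK as sitk

        arr = np.linspace(100, 4000, 16 * 16).reshape(16, 16).astype(np.int16)
        arr[0, 0], arr[0, 1], arr[0, 2] = 100, 4000, 2050
        sitk.WriteImage(sitk.GetImageFromArray(arr), str(tmp_path / "img.nrrd"))
        m = np.zeros((16, 16), np.uint8)
        m[5:8, 5:8] = 1
        sitk.WriteImage(sitk.GetImageFromArray(m), str(tmp_path / "mask.nrrd"))
        sl, mask = load_slice(tmp_path / "img.nrrd", tmp_path / "mask.nrrd")
        assert sl.pixels[0, 2] == pytest.approx(0.5, abs=1e-6)
        assert mask.num_foreground == 9

    def test_nifti_roundtrip(self, tmp_path):
        import nibabel as nib

        vol = np.random.default_rng(0).integers(0, 1000, (16, 16, 3)).astype(np.int16)
        nib.save(nib.Nifti1Image(vol, np.eye(4)), tmp_path / "img.nii.gz")
        m = np.zeros((16, 16, 3), np.uint8)
        m[4:6, 4:6, 1] = 1
        nib.save(nib.Nifti1Image(m, np.eye(4)), tmp_path / "mask.nii.gz")
        sl, mask = load_slice(tmp_path / "img.nii.gz", tmp_path / "mask.nii.gz", slice_index=1)
        assert sl.shape == (16, 16)
        assert mask.num_foreground == 4

    def test_shape_mismatch_names_both_shapes(self, tmp_path):
        Image.fromarray(np.zeros((16, 16), np.uint8)).save(tmp_path / "img.png")
        Image.fromarray(np.ones((16, 20), np.uint8)).save(tmp_path / "mask.png")
        with pytest.raises(ValueError, match=r"\(16, 16\).*\(16, 20\)"):
            load_slice(tmp_path / "img.png", tmp_path / "mask.png")

    def test_unsupported_format_rejected(self, tmp_path):
        (tmp_path / "img.xyz").write_bytes(b"junk")
        with pytest.raises(ValueError, match="unsupported"):
            load_slice(tmp_path / "img.xyz", tmp_path / "img.xyz")


# ---------------------------------------------------------------------------
# bounding box and square ROI
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_bbox_single_pixel(self):
        m = np.zeros((128, 128), np.uint8)
        m[100, 40] = 1
        assert lesion_bbox(LesionMask(m)) == (100, 40, 100, 40)

    def test_bbox_filled_rectangle(self):
        m = np.zeros((64, 64), np.uint8)
        m[10:20, 30:50] = 1
        assert lesion_bbox(LesionMask(m)) == (10, 30, 19, 49)

    def test_bbox_matches_bruteforce_scan(self, rng):
        m = (rng.random((40, 52)) > 0.92).astype(np.uint8)
        m[17, 23] = 1  # guarantee non-empty
        got = lesion_bbox(LesionMask(m))
        fg = [(r, c) for r in range(40) for c in range(52) if m[r, c]]
        expect = (
            min(r for r, _ in fg),
            min(c for _, c in fg),
            max(r for r, _ in fg),
            max(c for _, c in fg),
        )
        assert got == expect

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no foreground"):
            lesion_bbox(LesionMask(np.zeros((16, 16), np.uint8)))

    def test_side_is_max_extent_and_scales(self):
        m = np.zeros((128, 128), np.uint8)
        m[50:60, 40:60] = 1  # 10 rows x 20 cols
        assert square_roi(LesionMask(m), (128, 128), 1).side == 20
        assert square_roi(LesionMask(m), (128, 128), 2).side == 40
        assert square_roi(LesionMask(m), (128, 128), 3).side == 60

    def test_tiny_mask_clamped_to_floor(self):
        m = np.zeros((64, 64), np.uint8)
        m[30, 30] = 1
        assert square_roi(LesionMask(m), (64, 64), 1).side == 8

    @pytest.mark.parametrize("dr,dc", [(5, 0), (0, -7), (3, 4), (-6, -2)])
    def test_translation_equivariance(self, dr, dc):
        m = np.zeros((100, 100), np.uint8)
        m[40:55, 42:50] = 1
        base = square_roi(LesionMask(m), (100, 100), 1)
        shifted = square_roi(LesionMask(np.roll(m, (dr, dc), (0, 1))), (100, 100), 1)
        assert (shifted.center_row, shifted.center_col) == (
            base.center_row + dr,
            base.center_col + dc,
        )
        assert shifted.side == base.side


# ---------------------------------------------------------------------------
# crop + resize
# ---------------------------------------------------------------------------

def bilinear_oracle(src: np.ndarray, out_shape):
    """Direct per-pixel bilinear interpolation, half-pixel centers, clamped."""
    hi, wi = src.shape
    ho, wo = out_shape
    out = np.zeros(out_shape)
    for r in range(ho):
        for c in range(wo):
            sr = min(max((r + 0.5) * hi / ho - 0.5, 0), hi - 1)
            sc = min(max((c + 0.5) * wi / wo - 0.5, 0), wi - 1)
            r0, c0 = int(np.floor(sr)), int(np.floor(sc))
            r1, c1 = min(r0 + 1, hi - 1), min(c0 + 1, wi - 1)
            tr, tc = sr - r0, sc - c0
            out[r, c] = (
                src[r0, c0] * (1 - tr) * (1 - tc)
                + src[r0, c1] * (1 - tr) * tc
                + src[r1, c0] * tr * (1 - tc)
                + src[r1, c1] * tr * tc
            )
    return out


class TestCropResize:
    def test_constant_region_stays_constant(self):
        sl = ImageSlice(np.full((64, 64), 0.37, np.float32))
        roi = SquareROI(center_row=32, center_col=32, side=20)
        out = crop_resize(sl, roi, 224)
        assert out.shape == (224, 224)
        assert np.allclose(out, 0.37, atol=1e-6)

    def test_exact_size_roi_is_identity(self, rng):
        pix = rng.random((256, 256)).astype(np.float32)
        sl = ImageSlice(pix)
        roi = SquareROI(center_row=128, center_col=128, side=224)
        out = crop_resize(sl, roi, 224)
        r0, c0 = roi.row_start, roi.col_start
        assert np.allclose(out, pix[r0 : r0 + 224, c0 : c0 + 224], atol=1e-6)

    def test_upscale_matches_bruteforce_oracle(self, rng):
        from sffnet.semi_sp import resize_bilinear

        src = rng.random((3, 3)).astype(np.float32)
        assert np.allclose(resize_bilinear(src, (6, 6)), bilinear_oracle(src, (6, 6)), atol=1e-6)

    @pytest.mark.parametrize("shape_in,shape_out", [((4, 7), (9, 5)), ((8, 8), (3, 11)), ((2, 5), (5, 2))])
    def test_resize_matches_oracle_on_small_inputs(self, rng, shape_in, shape_out):
        from sffnet.semi_sp import resize_bilinear

        src = rng.random(shape_in).astype(np.float32)
        assert np.allclose(
            resize_bilinear(src, shape_out), bilinear_oracle(src, shape_out), atol=1e-6
        )

    def test_out_of_bounds_region_zero_padded(self):
        sl = ImageSlice(np.ones((32, 32), np.float32))
        roi = SquareROI(center_row=0, center_col=0, side=32)
        out = crop_resize(sl, roi, 32)
        # the square hangs off the top-left corner: those quadrants are 0
        assert np.all(out[:10, :10] == 0.0)
        assert np.all(out[20:, 20:] == 1.0)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

class TestClahe:
    def test_constant_patch_unchanged(self):
        patch = np.full((224, 224), 0.6, np.float32)
        assert np.array_equal(clahe_enhance(patch), patch)

    def test_step_patch_contrast_increases_to_frozen_value(self):
        patch = np.full((224, 224), 0.3, np.float32)
        patch[:, 112:] = 0.7
        out = clahe_enhance(patch, clip_limit=2.0, tile_grid=(8, 8))
        assert out.std() >= patch.std()
        # regression value computed once with the default parameters
        assert out.std() == pytest.approx(0.49997, abs=0.005)

    def test_output_range_contract(self, rng):
        out = clahe_enhance(rng.random((64, 64)).astype(np.float32))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_nonpositive_clip_rejected(self):
        with pytest.raises(ValueError, match="clip_limit"):
            clahe_enhance(np.zeros((16, 16), np.float32), clip_limit=0.0)


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------

class TestStrategies:
    @pytest.mark.parametrize(
        "strategy", ["semi_sp", "double", "triple", "whole_image", "lesion_only"]
    )
    def test_output_contract_all_strategies(self, blob_slice_and_mask, strategy):
        sl, mask = blob_slice_and_mask
        patch = apply_strategy(sl, mask, strategy)
        assert patch.pixels.shape == (224, 224)
        assert patch.pixels.min() >= 0.0 and patch.pixels.max() <= 1.0
        assert patch.provenance["strategy"] == strategy

    def test_whole_image_resizes_any_slice(self, rng):
        sl = ImageSlice(rng.random((512, 448)).astype(np.float32))
        patch = apply_strategy(sl, None, "whole_image")
        assert patch.pixels.shape == (224, 224)
        assert patch.strategy == "whole_image"

    def test_mask_required_except_whole_image(self, blob_slice_and_mask):
        sl, _ = blob_slice_and_mask
        with pytest.raises(ValueError, match="requires a lesion mask"):
            apply_strategy(sl, None, "semi_sp")

    def test_semi_sp_side_follows_lesion_diameter(self):
        pix = np.random.default_rng(3).random((128, 128)).astype(np.float32)
        m = np.zeros((128, 128), np.uint8)
        rows, cols = np.mgrid[0:128, 0:128]
        m[(rows - 64) ** 2 + (cols - 64) ** 2 <= 20**2] = 1  # 41-px diameter disk
        patch = apply_strategy(ImageSlice(pix), LesionMask(m), "semi_sp")
        assert patch.provenance["roi"]["side"] == 41

    def test_lesion_only_zeroes_outside_mask_before_resize(self, blob_slice_and_mask):
        sl, mask = blob_slice_and_mask
        from sffnet.semi_sp import square_roi as sq

        roi = sq(mask, sl.shape, 1.0)
        # reproduce the pre-resize crop at native resolution
        masked = ImageSlice(sl.pixels * mask.pixels)
        crop = crop_resize(masked, roi, roi.side)  # identity-size resize
        r0, c0 = roi.row_start, roi.col_start
        sub_mask = mask.pixels[r0 : r0 + roi.side, c0 : c0 + roi.side]
        assert np.all(crop[sub_mask == 0] == 0.0)

    def test_lesion_only_bounded_by_semi_sp_crop(self, blob_slice_and_mask):
        sl, mask = blob_slice_and_mask
        from sffnet.semi_sp import square_roi as sq

        roi = sq(mask, sl.shape, 1.0)
        plain = crop_resize(sl, roi, roi.side)
        masked = crop_resize(ImageSlice(sl.pixels * mask.pixels), roi, roi.side)
        assert np.all(masked <= plain + 1e-6)

    def test_patch_roundtrip_through_png(self, tmp_path, blob_slice_and_mask):
        sl, mask = blob_slice_and_mask
        patch = apply_strategy(sl, mask, "semi_sp")
        write_patch(patch, tmp_path / "p.png")
        back = read_patch(tmp_path / "p.png")
        assert back.strategy == "semi_sp"
        assert np.allclose(back.pixels, patch.pixels, atol=1.0 / 65535)
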