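"""Gray-standard calibration, resampling, and scene I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camoquant import (
    RawImage,
    RegionMask,
    SCALE_MAX,
    SceneSpec,
    apply_calibration,
    calibrate_scene,
    fit_gray_calibration,
    generate_scene,
    load_scene,
    rescale_to_resolution,
)
from camoquant.calibration import (
    CalibrationError,
    CalibrationMap,
    MultispectralStack,
    SceneFormatError,
    read_stack_tiff,
    write_stack_tiff,
)
from camoquant.scenes import write_scene

from _oracles import ols_line_oracle


def _measured(per_channel_values):
    """Replicate per-patch values across the three channels."""
    return np.array([[v, v, v] for v in per_channel_values], dtype=float)


class TestFitGrayCalibration:
    def test_two_point_line_interpolates_exactly(self):
        cmap = fit_gray_calibration(_measured([100.0, 200.0]), np.array([0.10, 0.20]))
        assert np.allclose(cmap.gain, 65.535)
        assert np.allclose(cmap.offset, 0.0, atol=1e-9)

    def test_identical_measured_values_are_degenerate(self):
        with pytest.raises(CalibrationError):
            fit_gray_calibration(_measured([50.0, 50.0]), np.array([0.10, 0.20]))

    def test_single_patch_rejected(self):
        with pytest.raises(CalibrationError):
            fit_gray_calibration(_measured([50.0]), np.array([0.10]))

    def test_matches_normal_equations_oracle(self):
        # three collinear patches plus one perturbed off the line
        measured = np.array([100.0, 200.0, 300.0, 405.0])
        known = np.array([0.10, 0.20, 0.30, 0.40])
        cmap = fit_gray_calibration(_measured(measured), known)
        slope, intercept = ols_line_oracle(measured, known * 65535.0)
        assert cmap.gain == pytest.approx([slope] * 3, abs=1e-9)
        assert cmap.offset == pytest.approx([intercept] * 3, abs=1e-6)


class TestApplyCalibration:
    def test_clips_at_scale_top(self):
        raw = RawImage(np.full((4, 4, 3), 1000.0), bit_depth=16, pixels_per_mm=17.0)
        cmap = CalibrationMap(gain=[65.535] * 3, offset=[0.0] * 3)
        stack = apply_calibration(raw, cmap)
        assert np.all(stack.reflectance == SCALE_MAX)

    def test_identity_map_preserves_values(self):
        pixels = np.arange(48, dtype=float).reshape(4, 4, 3)
        raw = RawImage(pixels, bit_depth=16, pixels_per_mm=17.0)
        stack = apply_calibration(raw, CalibrationMap(gain=[1.0] * 3, offset=[0.0] * 3))
        assert np.array_equal(stack.reflectance, pixels)
        assert stack.pixels_per_mm == 17.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        gain=st.floats(0.1, 100.0),
        offset=st.floats(-1000.0, 1000.0),
        u=st.floats(0.0, 65535.0),
        v=st.floats(0.0, 65535.0),
    )
    def test_monotone_per_channel(self, gain, offset, u, v):
        u, v = min(u, v), max(u, v)
        cmap = CalibrationMap(gain=[gain] * 3, offset=[offset] * 3)
        lo = apply_calibration(
            RawImage(np.full((1, 1, 3), u), 16, 17.0), cmap
        ).reflectance
        hi = apply_calibration(
            RawImage(np.full((1, 1, 3), v), 16, 17.0), cmap
        ).reflectance
        assert np.all(lo <= hi)


class TestGeneratorCalibrationRecovery:
    def test_noise_free_scene_recovers_truth_line(self):
        spec = SceneSpec(seed=3, noise_sd=0.0)
        bundle = generate_scene(spec)
        _, cmap = calibrate_scene(bundle.raw, bundle.standards)
        assert cmap.gain == pytest.approx(spec.cal_gain, rel=1e-6)
        assert cmap.offset == pytest.approx(spec.cal_offset, rel=1e-4, abs=1e-2)

    def test_sensor_noise_bias_shrinks_with_patch_area(self):
        errs = {}
        for ps in (8, 28):
            gains = []
            for seed in range(6):
                spec = SceneSpec(seed=seed, noise_sd=150.0, patch_size=ps)
                bundle = generate_scene(spec)
                _, cmap = calibrate_scene(bundle.raw, bundle.standards)
                gains.append(cmap.gain[0])
            errs[ps] = abs(np.mean(gains) - SceneSpec().cal_gain[0])
        assert errs[28] < errs[8] + 0.01  # bias shrinks (allow noise floor)
        assert errs[28] < 0.02

    def test_full_reflectance_patch_maps_to_scale_max(self):
        spec = SceneSpec(seed=1, noise_sd=0.0, gray_patches=((1.0, None), (0.5, None), (0.2, None)))
        bundle = generate_scene(spec)
        stack, _ = calibrate_scene(bundle.raw, bundle.standards)
        white_mask = bundle.standards.patches[0][0]
        for c in range(3):
            assert stack.reflectance[:, :, c][white_mask].mean() == pytest.approx(
                SCALE_MAX, abs=0.5
            )


class TestRescale:
    def test_halving_resolution_halves_dimensions(self):
        stack = MultispectralStack(np.zeros((64, 64, 3)), pixels_per_mm=34.0)
        out = rescale_to_resolution(stack, 17.0)
        assert out.shape == (32, 32)
        assert out.pixels_per_mm == 17.0

    def test_identity_resolution_returns_same_grid(self):
        arr = np.random.default_rng(0).uniform(0, SCALE_MAX, (16, 16, 3))
        stack = MultispectralStack(arr, pixels_per_mm=17.0)
        out = rescale_to_resolution(stack, 17.0)
        assert np.array_equal(out.reflectance, arr)

    def test_constant_image_preserved_at_any_factor(self):
        stack = MultispectralStack(np.full((40, 40, 3), 1234.5), pixels_per_mm=23.0)
        out = rescale_to_resolution(stack, 17.0)
        assert np.allclose(out.reflectance, 1234.5, atol=1e-6)

    def test_upsampling_warns_but_proceeds(self):
        stack = MultispectralStack(np.zeros((16, 16, 3)), pixels_per_mm=17.0)
        with pytest.warns(UserWarning, match="upsampling"):
            out = rescale_to_resolution(stack, 34.0)
        assert out.shape == (32, 32)

    def test_nonpositive_target_rejected(self):
        stack = MultispectralStack(np.zeros((16, 16, 3)), pixels_per_mm=17.0)
        with pytest.raises(ValueError):
            rescale_to_resolution(stack, 0.0)


class TestSceneIO:
    def test_tiff_roundtrip_preserves_rounded_values(self, tmp_path, rng):
        arr = rng.uniform(0, SCALE_MAX, (20, 20, 3))
        stack = MultispectralStack(arr, pixels_per_mm=17.0)
        path = tmp_path / "stack.tiff"
        write_stack_tiff(stack, path)
        back = read_stack_tiff(path, 17.0)
        assert np.array_equal(back.reflectance, np.rint(arr))

    def test_generator_scene_roundtrip(self, tmp_path, default_scene):
        paths = write_scene(default_scene, tmp_path, "scene")
        raw, masks, standards = load_scene(
            paths["image"], [paths["target"], paths["background"]], paths["annotation"]
        )
        assert raw.bit_depth == 16
        assert raw.pixels_per_mm == default_scene.raw.pixels_per_mm
        roles = {m.role for m in masks}
        assert roles == {"target", "background"}
        target = next(m for m in masks if m.role == "target")
        assert np.array_equal(target.mask, default_scene.target.mask)
        assert len(standards.patches) == len(default_scene.standards.patches)
        assert np.allclose(raw.pixels, np.rint(default_scene.raw.pixels))

    def test_wrong_shape_mask_rejected(self, tmp_path, default_scene):
        import imageio.v3 as iio

        paths = write_scene(default_scene, tmp_path, "scene")
        bad = tmp_path / "scene_target_mask.png"
        iio.imwrite(bad, np.zeros((8, 8), dtype=np.uint8) + 255)
        with pytest.raises(SceneFormatError, match="shape"):
            load_scene(paths["image"], [bad, paths["background"]], paths["annotation"])

    def test_unknown_mask_role_rejected(self, tmp_path, default_scene):
        paths = write_scene(default_scene, tmp_path, "scene")
        ann = paths["annotation"]
        text = ann.read_text().replace("target\n", "leg\n")
        ann.write_text(text)
        with pytest.raises(SceneFormatError, match="role"):
            load_scene(paths["image"], [paths["target"], paths["background"]], ann)


class TestRegionMask:
    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            RegionMask(mask=np.zeros((4, 4), dtype=bool), role="target")

    def test_unknown_role_rejected(self):
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            RegionMask(mask=m, role="leg")
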