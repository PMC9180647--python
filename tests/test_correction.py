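"""Reflectance correction, ROI segmentation, and mean-spectrum extraction."""

import numpy as np
import pytest

import grapesense as gs
from grapesense.correction import (
    DegenerateReferenceError,
    DimensionError,
    SegmentationError,
    SpectralCube,
    RoiMask,
)
from grapesense.synthetic import SceneConfig


WL8 = np.linspace(476, 890, 8)


def scene_config(**overrides):
    defaults = dict(wavelength_grid=np.linspace(476, 890, 16),
                    image_shape=(48, 48), seed=0)
    defaults.update(overrides)
    return SceneConfig(**defaults)


class TestCorrectReflectance:
    def test_raw_equal_white_gives_ones(self):
        shape = (4, 5, 8)
        white = SpectralCube(np.full(shape, 900.0), WL8, "reference_white")
        dark = SpectralCube(np.full(shape, 100.0), WL8, "reference_dark")
        raw = SpectralCube(np.full(shape, 900.0), WL8, "raw")
        out = gs.correct_reflectance(raw, white, dark)
        np.testing.assert_array_equal(out.values, np.ones(shape))
        assert out.kind == "reflectance"

    def test_raw_equal_dark_gives_zeros(self):
        shape = (4, 5, 8)
        white = SpectralCube(np.full(shape, 900.0), WL8, "reference_white")
        dark = SpectralCube(np.full(shape, 100.0), WL8, "reference_dark")
        raw = SpectralCube(np.full(shape, 100.0), WL8, "raw")
        out = gs.correct_reflectance(raw, white, dark)
        np.testing.assert_array_equal(out.values, np.zeros(shape))

    def test_recovers_generator_ground_truth(self):
        cfg = scene_config(noise_sd=0.0)
        scene = gs.generate_scene(cfg, level=2, seed=3)
        refl = gs.correct_reflectance(*gs.cubes_from_scene(scene))
        assert np.abs(refl.values - scene.truth_reflectance).max() < 1e-10

    def test_scale_invariance_of_digital_numbers(self):
        scene = gs.generate_scene(scene_config(), level=1, seed=4)
        raw, white, dark = gs.cubes_from_scene(scene)
        base = gs.correct_reflectance(raw, white, dark)
        scaled = gs.correct_reflectance(
            SpectralCube(raw.values * 7.5, raw.wavelengths_nm, "raw"),
            SpectralCube(white.values * 7.5, white.wavelengths_nm, "reference_white"),
            SpectralCube(dark.values * 7.5, dark.wavelengths_nm, "reference_dark"),
        )
        np.testing.assert_allclose(scaled.values, base.values, atol=1e-12)

    def test_shape_mismatch_raises(self):
        white = SpectralCube(np.full((4, 5, 8), 2.0), WL8, "reference_white")
        dark = SpectralCube(np.full((4, 5, 8), 1.0), WL8, "reference_dark")
        raw = SpectralCube(np.full((4, 4, 8), 1.5), WL8, "raw")
        with pytest.raises(DimensionError):
            gs.correct_reflectance(raw, white, dark)

    def test_gray_reference_reading_is_algebraically_identical(self):
        """The 50%-gray-panel reading cancels to the plain formula for ideal frames."""
        scene = gs.generate_scene(scene_config(), level=0, seed=6)
        raw, white, dark = gs.cubes_from_scene(scene)
        plain = gs.correct_reflectance(raw, white, dark)
        gray = gs.correct_reflectance(raw, white, dark, gray_reference=True)
        np.testing.assert_allclose(gray.values, plain.values, atol=1e-12)

    def test_degenerate_reference_names_first_offending_index(self):
        white = np.full((2, 2, 8), 2.0)
        white[1, 0, 3] = 1.0
        cubes = (SpectralCube(np.full((2, 2, 8), 1.5), WL8, "raw"),
                 SpectralCube(white, WL8, "reference_white"),
                 SpectralCube(np.full((2, 2, 8), 1.0), WL8, "reference_dark"))
        with pytest.raises(DegenerateReferenceError, match=r"\(1, 0, 3\)"):
            gs.correct_reflectance(*cubes)


class TestSegmentRoi:
    @staticmethod
    def _disk_cube():
        values = np.full((40, 40, 8), 0.05)
        yy, xx = np.mgrid[0:40, 0:40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
        values[disk] = 0.60
        return SpectralCube(values, WL8, "reflectance"), disk

    def test_fixed_threshold_recovers_disk(self):
        cube, disk = self._disk_cube()
        roi = gs.segment_roi(cube, band_nm=804.0, method="fixed", threshold=0.3)
        np.testing.assert_array_equal(roi.mask, disk)

    def test_otsu_matches_truth_mask_on_synthetic_scenes(self):
        """Jaccard overlap with the generator truth mask stays >= 0.95."""
        for seed in range(20):
            cfg = scene_config(seed=seed)
            scene = gs.generate_scene(cfg, level=seed % 4, seed=seed)
            refl = gs.correct_reflectance(*gs.cubes_from_scene(scene))
            roi = gs.segment_roi(refl, band_nm=804.0)
            inter = (roi.mask & scene.truth_mask).sum()
            union = (roi.mask | scene.truth_mask).sum()
            assert inter / union >= 0.95

    def test_constant_image_fails_loudly(self):
        cube = SpectralCube(np.full((10, 10, 8), 0.4), WL8, "reflectance")
        with pytest.raises(SegmentationError):
            gs.segment_roi(cube, band_nm=600.0)

    def test_min_area_removes_speckle(self):
        cube, disk = self._disk_cube()
        cube.values[2, 2, :] = 0.9  # single-pixel speckle
        roi = gs.segment_roi(cube, band_nm=804.0, method="fixed", threshold=0.3)
        assert not roi.mask[2, 2]
        np.testing.assert_array_equal(roi.mask, disk)


class TestExtractMeanSpectrum:
    def test_identical_pixels_return_their_spectrum(self):
        spec = np.linspace(0.2, 0.8, 8)
        cube = SpectralCube(np.tile(spec, (5, 5, 1)), WL8, "reflectance")
        roi = RoiMask(np.ones((5, 5), bool), 804.0, 0.3)
        np.testing.assert_allclose(gs.extract_mean_spectrum(cube, roi), spec)

    def test_two_pixel_average(self):
        values = np.zeros((1, 2, 8))
        values[0, 0] = 0.2
        values[0, 1] = 0.4
        cube = SpectralCube(values, WL8, "reflectance")
        roi = RoiMask(np.ones((1, 2), bool), 804.0, 0.0)
        np.testing.assert_allclose(gs.extract_mean_spectrum(cube, roi), 0.3)

    def test_close_to_class_mean_for_large_roi(self):
        """With band noise sd 0.01 and >= 500 ROI pixels the mean spectrum is
        within 0.005 of the generator class mean (standard-error bound)."""
        cfg = SceneConfig(wavelength_grid=np.linspace(476, 890, 16),
                          image_shape=(64, 64), scatter_sd=0.0, baseline_sd=0.0,
                          noise_sd=0.01, seed=2)
        scene = gs.generate_scene(cfg, level=1, seed=2)
        assert scene.truth_mask.sum() >= 500
        refl = gs.correct_reflectance(*gs.cubes_from_scene(scene))
        roi = RoiMask(scene.truth_mask, 804.0, 0.0)
        spectrum = gs.extract_mean_spectrum(refl, roi)
        assert np.abs(spectrum - cfg.class_mean_spectrum(1)).max() < 0.005

    def test_permutation_invariance_and_linearity(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.1, 0.9, (6, 6, 8))
        cube = SpectralCube(values, WL8, "reflectance")
        mask = rng.random((6, 6)) > 0.4
        roi = RoiMask(mask, 804.0, 0.0)
        base = gs.extract_mean_spectrum(cube, roi)
        # linearity
        double = SpectralCube(values * 2.0, WL8, "reflectance")
        np.testing.assert_allclose(gs.extract_mean_spectrum(double, roi), 2 * base)
        # permutation of pixel order (spatial transpose preserves the multiset)
        transposed = SpectralCube(values.transpose(1, 0, 2), WL8, "reflectance")
        roi_t = RoiMask(mask.T, 804.0, 0.0)
        np.testing.assert_allclose(gs.extract_mean_spectrum(transposed, roi_t), base)


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_cube_survives_disk_round_trip(self, tmp_path, interleave):
        from grapesense import envi

        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, (6, 7, 8)).astype(np.float32)
        path = str(tmp_path / f"cube_{interleave}.hdr")
        envi.write_envi(path, values, WL8, interleave=interleave)
        back, wl = envi.read_envi(path)
        np.testing.assert_array_equal(back, values)
        np.testing.assert_allclose(wl, WL8, atol=1e-4)
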