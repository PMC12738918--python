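"""Cube model, calibration, band trimming, masking, ROI spectra and file I/O."""

import numpy as np
import pytest

from weedspec.errors import (
    DegenerateReferenceError,
    DegenerateThresholdError,
    EmptySelectionError,
    FormatError,
    IntegrityError,
    ParameterError,
)
from weedspec.hsi_core import (
    CalibrationFrames,
    HSICube,
    PixelMask,
    Spectrum,
    WavelengthGrid,
    calibrate_reflectance,
    drop_noisy_bands,
    extract_roi_mean_spectrum,
    read_cube,
    spectra_from_csv,
    spectra_to_csv,
    threshold_mask,
    write_cube,
)


class TestWavelengthGrid:
    def test_rejects_non_increasing_and_non_positive(self):
        with pytest.raises(ParameterError):
            WavelengthGrid(np.array([500.0, 500.0, 600.0]))
        with pytest.raises(ParameterError):
            WavelengthGrid(np.array([-400.0, 500.0]))

    def test_nearest_band_tie_prefers_lower_wavelength(self):
        grid = WavelengthGrid(np.array([530.0, 532.0]))
        assert grid.nearest_band(531.0) == 0

    def test_nearest_band_exact_and_derived(self):
        grid = WavelengthGrid(np.arange(400.0, 1001.0, 100.0))
        assert grid.nearest_band(600.0) == 2
        # 649 is 49 nm from 600 and 51 nm from 700
        assert grid.nearest_band(649.0) == 2


class TestCalibration:
    def _frames(self, grid10, raw):
        dark = np.full(grid10.count, 100.0)
        white = np.full(grid10.count, 4000.0)
        return CalibrationFrames(raw=raw, dark=dark, white=white, grid=grid10)

    def test_raw_equal_dark_gives_zero(self, grid10):
        raw = np.full((3, 4, 10), 100.0)
        cube = calibrate_reflectance(self._frames(grid10, raw))
        np.testing.assert_allclose(cube.values, 0.0)

    def test_raw_equal_white_gives_one(self, grid10):
        raw = np.full((3, 4, 10), 4000.0)
        cube = calibrate_reflectance(self._frames(grid10, raw))
        np.testing.assert_allclose(cube.values, 1.0)

    def test_midpoint_gives_half(self, grid10):
        raw = np.full((3, 4, 10), 2050.0)
        cube = calibrate_reflectance(self._frames(grid10, raw))
        np.testing.assert_allclose(cube.values, 0.5)

    def test_matches_direct_formula_full_frames(self, grid10, rng):
        """Per-pixel frames: output equals (raw-dark)/(white-dark) element-wise."""
        raw = rng.uniform(0, 5000, size=(4, 3, 10))
        dark = rng.uniform(0, 200, size=(4, 3, 10))
        white = dark + rng.uniform(1000, 4000, size=(4, 3, 10))
        frames = CalibrationFrames(raw=raw, dark=dark, white=white, grid=grid10)
        out = calibrate_reflectance(frames)
        np.testing.assert_allclose(out.values, (raw - dark) / (white - dark))
        assert out.grid is grid10

    def test_degenerate_reference(self, grid10):
        raw = np.full((2, 2, 10), 1.0)
        dark = np.full(10, 50.0)
        white = dark.copy()  # white == dark everywhere
        frames = CalibrationFrames(raw=raw, dark=dark, white=white, grid=grid10)
        with pytest.raises(DegenerateReferenceError):
            calibrate_reflectance(frames)
        masked = calibrate_reflectance(frames, on_degenerate="mask")
        np.testing.assert_allclose(masked.values, 0.0)


class TestDropNoisyBands:
    def test_derived_retained_count(self, small_cube):
        """Centers 400, 466.7, ..., 1000; exactly 7 lie in [400, 800]."""
        out = drop_noisy_bands(small_cube, 400.0, 800.0)
        assert out.grid.count == 7
        assert out.values.shape == (6, 5, 7)
        np.testing.assert_array_equal(
            out.values, small_cube.values[:, :, :7]
        )

    def test_full_range_is_identity_and_idempotent(self, small_cube):
        once = drop_noisy_bands(small_cube, 397.0, 1003.0)
        np.testing.assert_array_equal(once.values, small_cube.values)
        twice = drop_noisy_bands(drop_noisy_bands(small_cube, 450.0, 900.0), 450.0, 900.0)
        np.testing.assert_array_equal(
            twice.values, drop_noisy_bands(small_cube, 450.0, 900.0).values
        )

    def test_disjoint_range_raises(self, small_cube):
        with pytest.raises(EmptySelectionError):
            drop_noisy_bands(small_cube, 1500.0, 1600.0)
        with pytest.raises(ParameterError):
            drop_noisy_bands(small_cube, 900.0, 500.0)


def _brute_force_otsu(gray: np.ndarray) -> float:
    """Exhaustive between-class-variance maximization over 256 thresholds."""
    lo, hi = gray.min(), gray.max()
    best_t, best_v = lo, -1.0
    for t in np.linspace(lo, hi, 256, endpoint=False):
        fg = gray > t
        if fg.all() or not fg.any():
            continue
        w1, w0 = fg.mean(), 1 - fg.mean()
        v = w0 * w1 * (gray[fg].mean() - gray[~fg].mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestThresholdMask:
    def _cube(self, gray, grid10):
        values = np.repeat(gray[:, :, None], 10, axis=2)
        return HSICube(values=values, grid=grid10)

    def test_otsu_separates_two_level_image(self, grid10):
        gray = np.full((8, 8), 0.1)
        gray[2:6, 3:7] = 0.9
        cube = self._cube(gray, grid10)
        mask = threshold_mask(cube, band_nm=800.0, method="otsu")
        oracle = gray > _brute_force_otsu(gray)
        np.testing.assert_array_equal(mask.flags, oracle)
        np.testing.assert_array_equal(mask.flags, gray > 0.5)

    def test_fixed_threshold(self, grid10):
        gray = np.array([[0.4, 0.6]])
        mask = threshold_mask(self._cube(gray, grid10), 800.0, method="fixed", t=0.5)
        np.testing.assert_array_equal(mask.flags, [[False, True]])

    def test_constant_image_degenerate(self, grid10):
        with pytest.raises(DegenerateThresholdError):
            threshold_mask(self._cube(np.full((4, 4), 0.3), grid10), 800.0)

    def test_band_outside_span(self, small_cube):
        with pytest.raises(ParameterError):
            threshold_mask(small_cube, band_nm=2000.0)


class TestRoiMeanSpectrum:
    def test_constant_cube(self, grid10):
        cube = HSICube(values=np.full((4, 4, 10), 0.37), grid=grid10)
        roi = PixelMask(flags=np.ones((4, 4), dtype=bool))
        s = extract_roi_mean_spectrum(cube, roi, "a", 3)
        np.testing.assert_allclose(s.reflectance, 0.37)
        assert s.species_id == 3

    def test_two_pixel_mean(self, grid10):
        values = np.zeros((1, 2, 10))
        values[0, 0] = 0.2
        values[0, 1] = 0.4
        roi = PixelMask(flags=np.ones((1, 2), dtype=bool))
        s = extract_roi_mean_spectrum(HSICube(values=values, grid=grid10), roi)
        np.testing.assert_allclose(s.reflectance, 0.3)

    def test_matches_brute_force_accumulation(self, small_cube, rng):
        flags = rng.random((6, 5)) > 0.5
        flags[0, 0] = True
        roi = PixelMask(flags=flags)
        s = extract_roi_mean_spectrum(small_cube, roi)
        acc = np.zeros(10)
        cnt = 0
        for i in range(6):
            for j in range(5):
                if flags[i, j]:
                    acc += small_cube.values[i, j]
                    cnt += 1
        np.testing.assert_allclose(s.reflectance, acc / cnt)

    def test_empty_roi_raises(self, small_cube):
        with pytest.raises(EmptySelectionError):
            extract_roi_mean_spectrum(small_cube, PixelMask(flags=np.zeros((6, 5), bool)))


class TestFileIO:
    def test_archive_roundtrip_bit_exact(self, small_cube, tmp_path):
        p = tmp_path / "cube.npz"
        write_cube(small_cube, p)
        back = read_cube(p)
        np.testing.assert_array_equal(back.values, small_cube.values)
        np.testing.assert_array_equal(back.grid.centers_nm, small_cube.grid.centers_nm)

    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_envi_roundtrip(self, small_cube, tmp_path, interleave):
        p = tmp_path / "cube.raw"
        write_cube(small_cube, p, dialect="envi", interleave=interleave)
        back = read_cube(p, dialect="envi")
        np.testing.assert_allclose(back.values, small_cube.values, atol=1e-6)
        np.testing.assert_allclose(back.grid.centers_nm, small_cube.grid.centers_nm)

    def test_envi_header_declares_grid(self, small_cube, tmp_path):
        p = tmp_path / "c.raw"
        write_cube(small_cube, p, dialect="envi")
        hdr = (tmp_path / "c.raw.hdr").read_text()
        assert "bands = 10" in hdr and "wavelength" in hdr

    def test_band_count_mismatch_is_integrity_error(self, small_cube, tmp_path):
        p = tmp_path / "c.raw"
        write_cube(small_cube, p, dialect="envi")
        hdr_path = tmp_path / "c.raw.hdr"
        hdr_path.write_text(hdr_path.read_text().replace("bands = 10", "bands = 9"))
        with pytest.raises(IntegrityError):
            read_cube(p, dialect="envi")

    def test_truncated_payload_is_integrity_error(self, small_cube, tmp_path):
        p = tmp_path / "c.raw"
        write_cube(small_cube, p, dialect="envi")
        data = p.read_bytes()
        p.write_bytes(data[: len(data) - 6 * 5 * 4])  # drop one band plane
        with pytest.raises(IntegrityError):
            read_cube(p, dialect="envi")

    def test_missing_header_is_format_error(self, tmp_path):
        payload = tmp_path / "orphan.raw"
        payload.write_bytes(b"\x00" * 16)
        with pytest.raises(FormatError):
            read_cube(payload, dialect="envi")
        with pytest.raises(FormatError):
            read_cube(tmp_path / "nothing.npz")

    def test_spectra_csv_roundtrip(self, grid10, rng, tmp_path):
        spectra = [
            Spectrum(rng.uniform(0, 1, 10), grid10, sample_id=f"s{i}", species_id=i + 1)
            for i in range(3)
        ]
        p = tmp_path / "spectra.csv"
        spectra_to_csv(spectra, p)
        back = spectra_from_csv(p)
        assert [s.sample_id for s in back] == ["s0", "s1", "s2"]
        assert [s.species_id for s in back] == [1, 2, 3]
        for a, b in zip(spectra, back):
            np.testing.assert_array_equal(a.reflectance, b.reflectance)
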