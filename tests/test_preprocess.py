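"""Reflectance correction, spike removal, absorbance, crop and SNV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from nirlipid import preprocess, synth
from nirlipid.preprocess import (
    HyperspectralCube,
    ReflectanceCube,
    crop_wavelengths,
    mean_sample_spectrum,
    remove_spikes,
    snv,
    to_absorbance,
    to_reflectance,
)


def make_frames(raw_fn, n=16, shape=(3, 4)):
    """Frames on a small strictly increasing axis; dark=100, white=1100."""
    wl = 1000.0 + 10.0 * np.arange(n)
    dark = HyperspectralCube(np.full((*shape, n), 100.0), wl, "dark")
    white = HyperspectralCube(np.full((*shape, n), 1100.0), wl, "white")
    raw = HyperspectralCube(raw_fn(dark.intensities, white.intensities), wl, "raw")
    return raw, dark, white


class TestReflectance:
    def test_raw_equals_white_gives_one(self):
        raw, dark, white = make_frames(lambda d, w: w.copy())
        refl = to_reflectance(raw, dark, white)
        assert refl.mask.all()
        np.testing.assert_allclose(refl.values, 1.0)

    def test_raw_equals_dark_gives_zero(self):
        raw, dark, white = make_frames(lambda d, w: d.copy())
        np.testing.assert_allclose(to_reflectance(raw, dark, white).values, 0.0)

    def test_quarter_interpolation(self):
        raw, dark, white = make_frames(lambda d, w: d + 0.25 * (w - d))
        np.testing.assert_allclose(to_reflectance(raw, dark, white).values, 0.25)

    def test_white_equal_dark_pixel_masked_not_infinite(self):
        raw, dark, white = make_frames(lambda d, w: w.copy())
        white.intensities[1, 2, :] = dark.intensities[1, 2, :]
        refl = to_reflectance(raw, dark, white)
        assert not refl.mask[1, 2]
        assert refl.mask.sum() == refl.mask.size - 1
        assert np.isfinite(refl.values).all()

    def test_axis_mismatch_rejected(self):
        raw, dark, white = make_frames(lambda d, w: w.copy())
        dark.wavelengths = dark.wavelengths + 1.0
        with pytest.raises(ValueError):
            to_reflectance(raw, dark, white)

    def test_all_masked_rejected(self):
        raw, dark, white = make_frames(lambda d, w: w.copy())
        white.intensities[:] = dark.intensities
        with pytest.raises(ValueError):
            to_reflectance(raw, dark, white)


class TestAbsorbance:
    @pytest.mark.parametrize("r, a", [(1.0, 0.0), (0.1, 1.0), (0.5, 0.3010299956639812)])
    def test_decadic_log_spot_values(self, r, a):
        wl = np.arange(5.0)
        cube = ReflectanceCube(
            np.full((2, 2, 5), r), wl, np.ones((2, 2), bool)
        )
        np.testing.assert_allclose(to_absorbance(cube).values, a, atol=1e-12)

    def test_nonpositive_reflectance_masked(self):
        wl = np.arange(5.0)
        vals = np.full((2, 2, 5), 0.5)
        vals[0, 0, 3] = 0.0
        cube = ReflectanceCube(vals, wl, np.ones((2, 2), bool))
        out = to_absorbance(cube)
        assert not out.mask[0, 0]
        assert out.mask.sum() == 3


class TestSpikeRemoval:
    def test_spike_free_cube_unchanged(self, rng):
        wl = np.arange(50.0)
        vals = 0.5 + 0.1 * np.sin(wl / 5)[None, None, :] * np.ones((2, 2, 1))
        cube = ReflectanceCube(vals, wl, np.ones((2, 2), bool))
        np.testing.assert_array_equal(remove_spikes(cube).values, vals)

    def test_single_band_outlier_removed_others_untouched(self):
        wl = np.arange(60.0)
        base = 0.4 + 0.02 * np.sin(wl / 7)
        vals = np.tile(base, (2, 2, 1))
        vals[1, 1, 30] += 5.0  # isolated huge spike
        cube = ReflectanceCube(vals, wl, np.ones((2, 2), bool))
        out = remove_spikes(cube).values
        assert abs(out[1, 1, 30] - base[30]) < 0.05
        untouched = np.delete(out[1, 1], 30)
        np.testing.assert_array_equal(untouched, np.delete(vals[1, 1], 30))

    def test_real_absorption_band_untouched(self):
        """A ~12 nm Gaussian band on the 2.2 nm grid survives the filter."""
        wl = synth.instrument_wavelengths()
        band = synth.GaussianBand(1175.0, 12.0, 0.3).profile(wl)
        vals = (0.3 + band)[None, None, :] * np.ones((2, 2, 1))
        cube = ReflectanceCube(vals, wl, np.ones((2, 2), bool))
        np.testing.assert_array_equal(remove_spikes(cube).values, vals)


class TestCrop:
    def test_instrument_grid_keeps_closed_interval(self):
        wl = synth.instrument_wavelengths()
        spectra = np.zeros_like(wl)
        kept, _ = crop_wavelengths(wl, spectra)
        assert kept.min() >= 1000.0 and kept.max() <= 1400.0
        # nothing inside the window was dropped
        assert kept.size == ((wl >= 1000) & (wl <= 1400)).sum()

    def test_inside_axis_is_identity(self):
        wl = np.linspace(1100, 1300, 40)
        x = np.sin(wl)
        kept, y = crop_wavelengths(wl, x)
        np.testing.assert_array_equal(kept, wl)
        np.testing.assert_array_equal(y, x)

    def test_exact_endpoints_kept(self):
        wl = np.array([998.0, 1000.0, 1200.0, 1400.0, 1402.0])
        kept, _ = crop_wavelengths(wl, np.zeros(5))
        np.testing.assert_array_equal(kept, [1000.0, 1200.0, 1400.0])

    def test_empty_result_rejected(self):
        wl = np.array([500.0, 600.0])
        with pytest.raises(ValueError):
            crop_wavelengths(wl, np.zeros(2))


class TestMeanSampleSpectrum:
    def make_cube(self, pixel_spectra):
        """Stack (y=1, x=n_pixels) reflectance spectra on a kept-range axis."""
        arr = np.asarray(pixel_spectra)[None, :, :]
        wl = np.linspace(1000, 1400, arr.shape[2])
        return ReflectanceCube(arr, wl, np.ones(arr.shape[:2], bool))

    def test_single_pixel_is_that_spectrum(self):
        r = np.linspace(0.2, 0.8, 20)
        cube = self.make_cube([r])
        spec = mean_sample_spectrum(cube)
        np.testing.assert_allclose(spec.absorbance, -np.log10(r))
        assert spec.n_pixels == 1

    def test_mean_of_two_groups_is_bandwise_average(self):
        s = np.linspace(0.2, 0.4, 20)
        t = np.linspace(0.7, 0.5, 20)
        cube = self.make_cube([s, s, t, t])
        spec = mean_sample_spectrum(cube)
        np.testing.assert_allclose(spec.absorbance, -np.log10((s + t) / 2))

    def test_empty_roi_rejected(self):
        cube = self.make_cube([np.full(20, 0.5)])
        with pytest.raises(ValueError):
            mean_sample_spectrum(cube, roi=np.zeros((1, 1), bool))


finite_spectra = hnp.arrays(
    np.float64,
    st.integers(8, 64),
    elements=st.floats(-10, 10, allow_nan=False),
).filter(lambda x: np.std(x, ddof=1) > 1e-6)


class TestSNV:
    def test_hand_value_sample_sd(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    @given(finite_spectra)
    @settings(deadline=None, max_examples=200)
    def test_mean_zero_sd_one(self, x):
        z = snv(x)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    @given(finite_spectra,
           st.floats(0.1, 50), st.floats(-100, 100))
    @settings(deadline=None, max_examples=200)
    def test_affine_invariance(self, x, a, b):
        np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-8)

    @given(finite_spectra)
    @settings(deadline=None, max_examples=100)
    def test_idempotence(self, x):
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            snv(np.full(10, 3.0))


class TestPipelineRoundTrip:
    def test_zero_noise_recovers_generated_absorbance(self):
        """Rendering then preprocessing at zero noise recovers the band
        model's absorbance to 1e-6 on every kept band."""
        profiles = synth.default_diet_profiles()
        prof = profiles["HFD"]
        fixed = synth.DietProfile(
            name="fixed", mean_fractions=prof.mean_fractions,
            lipid_mean=prof.lipid_mean, lipid_sd=0.0, concentration=np.inf,
        )
        scene = synth.SceneSpec(
            height=8, width=8,
            regions=(synth.Region("lobe", synth.elliptical_mask(8, 8), fixed),),
            noise=synth.NoiseModel.none(),
            seed=11,
            baseline_offset_range=(0.2, 0.2),
            baseline_slope_range=(0.01, 0.01),
            lipid_pixel_cv=0.0,
        )
        bands = synth.BandModel()
        raw, dark, white = synth.render_cube(scene, bands)
        expected_full = synth.absorption_spectrum(
            fixed.mean_fractions, fixed.lipid_mean, bands,
            scene.wavelengths, baseline=(0.2, 0.01),
        )
        _, expected = crop_wavelengths(scene.wavelengths, expected_full)
        refl = to_reflectance(raw, dark, white)
        spec = mean_sample_spectrum(refl, roi=scene.tissue_mask)
        np.testing.assert_allclose(spec.absorbance, expected, atol=1e-6)
        # per-pixel route agrees too
        cube = preprocess.pixel_snv_spectra(raw, dark, white)
        pix = cube.values[scene.tissue_mask][0]
        np.testing.assert_allclose(pix, snv(expected), atol=1e-6)

    def test_masks_only_shrink(self):
        raw, dark, white = make_frames(lambda d, w: d + 0.5 * (w - d))
        refl = to_reflectance(raw, dark, white)
        despiked = remove_spikes(refl)
        absorb = to_absorbance(despiked)
        assert not (absorb.mask & ~refl.mask).any()
        assert not (despiked.mask & ~refl.mask).any()
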