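"""Evaluation windows, azimuthal profiles, sector detection, color fusion."""

import numpy as np
import pytest

from mdoct import direction, phantom
from mdoct.direction import (
    EvaluationWindow,
    circular_separation,
    color_average,
    color_mip,
    detect_sectors,
    dominant_channel_sectors,
    enface_color_mip,
    intensity_average,
    intensity_mip,
    isos_cost_window,
    normalize_to_rpe,
    rnfl_window,
    smooth_profile,
    window_mean,
)
from mdoct.segment import LayerMap


class TestWindowArithmetic:
    def test_isos_cost_rows_exact(self):
        rpe = np.array([100, 120, 97])
        top, bottom = isos_cost_window().rows(rpe)
        np.testing.assert_array_equal(top, rpe - 29)
        np.testing.assert_array_equal(bottom, rpe - 10)

    def test_rnfl_rows_exact(self):
        ilm = np.array([50, 61])
        top, bottom = rnfl_window().rows(ilm)
        np.testing.assert_array_equal(top, ilm + 3)
        np.testing.assert_array_equal(bottom, ilm + 17)

    def test_window_depths_match_protocol(self):
        assert isos_cost_window().depth == 20
        assert rnfl_window().depth == 15

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            EvaluationWindow("RPE", -10, 0)


class TestWindowMean:
    def test_constant_image(self):
        img = np.full((64, 8), 3.25)
        out = window_mean(img, isos_cost_window(), np.full(8, 50))
        np.testing.assert_allclose(out, 3.25)

    def test_zero_window_below_bright_band(self):
        img = np.zeros((64, 8))
        img[50, :] = 1000.0  # bright RPE row outside the window
        out = window_mean(img, isos_cost_window(), np.full(8, 50))
        np.testing.assert_allclose(out, 0.0)

    def test_matches_analytic_profile_speckle_free(self, cp_stack_nospeckle):
        stack, truth, geometry, pattern, layers = cp_stack_nospeckle
        w = isos_cost_window()
        rpe = truth.rpe_reference()[0]
        for c in range(3):
            got = window_mean(stack.data[c, 0], w, rpe)
            expected_field = phantom.expected_intensity(truth, pattern, layers, geometry, c)[0]
            top, bottom = w.rows(rpe)
            cols = np.arange(rpe.size)
            manual = np.array(
                [expected_field[top[i] : bottom[i] + 1, i].mean() for i in cols]
            )
            np.testing.assert_allclose(got, manual, atol=1e-9)

    def test_out_of_bounds_window_rejected(self):
        img = np.zeros((40, 4))
        with pytest.raises(ValueError):
            window_mean(img, isos_cost_window(), np.full(4, 20))


class TestNormalize:
    def test_profile_equal_to_band_gives_unity(self):
        prof = np.full(32, 7.0)
        band = np.full(32, 7.0)
        out = normalize_to_rpe(prof, band, rescale_max=False)
        np.testing.assert_allclose(out, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        prof = rng.random(64) + 0.5
        band = rng.random(64) + 1.0
        a = normalize_to_rpe(prof, band)
        b = normalize_to_rpe(2.0 * prof, 2.0 * band)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonpositive_normalizer_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_rpe(np.ones(8), np.zeros(8))

    def test_rpe_reflectivity_change_cancels(self, geometry):
        pattern = phantom.ScanPattern.circumpapillary(ascans=128)
        truth = phantom.default_truth(pattern, vessels=())
        prof = {}
        for scale in (1.0, 2.0):
            layers = [
                l if l.name != "RPE"
                else phantom.LayerModel("RPE", l.base_reflectivity * scale)
                for l in phantom.default_layers()
            ]
            # scale everything: directional profile shape must be unchanged
            layers = [
                phantom.LayerModel(l.name, l.base_reflectivity * scale,
                                   l.directional_kind, l.concentration, l.modulation_depth)
                for l in phantom.default_layers()
            ]
            stack = phantom.render_multichannel(
                truth, geometry, pattern, layers, seed=0, noise_sigma=0.0, speckle=False
            )
            w = isos_cost_window()
            rpe = truth.rpe_reference()[0]
            raw = window_mean(stack.data[0, 0], w, rpe)
            band = direction.rpe_band_mean(stack.data[0, 0], rpe)
            prof[scale] = normalize_to_rpe(raw, band)
        np.testing.assert_allclose(prof[1.0], prof[2.0], atol=1e-9)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        out = smooth_profile(np.full(100, 4.0), "lowess", span=0.1)
        np.testing.assert_allclose(out, 4.0, atol=1e-9)

    @pytest.mark.parametrize("method", ["lowess", "loess"])
    def test_cosine_peak_preserved(self, method):
        az = np.linspace(0, 360, 720, endpoint=False)
        y = np.cos(np.deg2rad(az - 137.0))
        sm = smooth_profile(y, method, span=0.1)
        peak = az[np.argmax(sm)]
        assert circular_separation(peak, 137.0) < 2.0

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=6144)
        sm = smooth_profile(y, "lowess", span=0.05)
        assert np.var(y) / np.var(sm) >= 5.0

    def test_circular_wraparound_no_edge_artifacts(self):
        az = np.linspace(0, 360, 360, endpoint=False)
        y = np.cos(np.deg2rad(az))  # peak at 0 = wrap point
        sm = smooth_profile(y, "lowess", span=0.1, circular=True)
        assert circular_separation(az[np.argmax(sm)], 0.0) < 2.0

    def test_agrees_with_statsmodels_lowess(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

        rng = np.random.default_rng(2)
        x = np.arange(500, dtype=float)
        y = np.sin(x / 40.0) + 0.05 * rng.normal(size=500)
        ours = smooth_profile(y, "lowess", span=0.1, circular=False)
        ref = sm_lowess(y, x, frac=0.1, it=0, return_sorted=False)
        interior = slice(40, -40)
        assert np.abs(ours[interior] - ref[interior]).max() < 0.02

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.ones(5))

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(np.ones(100), span=0.0)


class TestDetectSectors:
    def _von_mises(self, az, center, kappa=2.0):
        return np.exp(kappa * (np.cos(np.deg2rad(az - center)) - 1.0))

    def test_three_pure_lobes_120_apart(self):
        az = np.linspace(0, 360, 720, endpoint=False)
        profiles = [self._von_mises(az, c) for c in (90.0, 210.0, 330.0)]
        summary = detect_sectors(profiles, azimuth_deg=az)
        seps = summary.cross_channel_separations()
        np.testing.assert_allclose(seps, 120.0, atol=1.0)

    def test_bilobed_profile_two_peaks_180_apart(self):
        az = np.linspace(0, 360, 720, endpoint=False)
        y = 0.4 + 0.6 * np.cos(np.deg2rad(az - 30.0)) ** 2
        summary = detect_sectors([y], azimuth_deg=az)
        assert summary.sector_count(0) == 2
        assert summary.within_channel_separations(0)[0] == pytest.approx(180.0, abs=1.0)

    def test_no_peaks_raises(self):
        with pytest.raises(ValueError):
            detect_sectors([np.ones(100)])

    def test_azimuth_origin_rotation_rotates_peaks(self, geometry):
        # rotating the beam triangle by delta rotates the detected peaks by delta
        delta = 40.0
        az = None
        peaks = {}
        for off in (0.0, delta):
            g = phantom.BeamGeometry(
                channel_azimuths_deg=tuple((a + off) % 360 for a in (90.0, 210.0, 330.0))
            )
            pattern = phantom.ScanPattern.circumpapillary(ascans=512)
            truth = phantom.default_truth(pattern, vessels=())
            stack = phantom.render_multichannel(
                truth, g, pattern, phantom.default_layers(), seed=0,
                noise_sigma=0.0, speckle=False,
            )
            w = isos_cost_window()
            rpe = truth.rpe_reference()[0]
            profs = []
            for c in range(3):
                raw = window_mean(stack.data[c, 0], w, rpe)
                profs.append(smooth_profile(raw / raw.max(), span=0.05))
            az = pattern.azimuths()[0]
            summary = detect_sectors(profs, azimuth_deg=az)
            peaks[off] = [p[0] for p in summary.peak_azimuths]
        for a, b in zip(peaks[0.0], peaks[delta]):
            assert circular_separation((a + delta) % 360, b) < 2.0


class TestDominantChannelSectors:
    def test_three_lobes_three_sectors(self):
        az = np.linspace(0, 360, 720, endpoint=False)
        profs = np.stack(
            [np.exp(2.0 * (np.cos(np.deg2rad(az - c)) - 1.0)) for c in (90, 210, 330)]
        )
        assert dominant_channel_sectors(profs) == 3

    def test_single_dominant_channel_one_sector(self):
        profs = np.stack([np.full(360, 2.0), np.ones(360), np.ones(360)])
        assert dominant_channel_sectors(profs) == 1

    def test_short_glitches_merged(self):
        az = np.linspace(0, 360, 720, endpoint=False)
        profs = np.stack(
            [np.exp(2.0 * (np.cos(np.deg2rad(az - c)) - 1.0)) for c in (90, 210, 330)]
        )
        profs[0, 400:404] += 10.0  # 4-sample glitch inside channel-2's sector
        assert dominant_channel_sectors(profs) == 3


class TestColorFusion:
    def test_equal_intensities_achromatic(self):
        ch = np.full((3, 4, 4), 0.9)
        rgb = color_average(ch)
        np.testing.assert_allclose(rgb, 0.6)
        assert np.ptp(rgb, axis=-1).max() == pytest.approx(0.0, abs=1e-12)

    def test_single_channel_cyan_hue(self):
        ch = np.zeros((3, 2, 2))
        ch[0] = 1.0
        rgb = color_average(ch)
        np.testing.assert_allclose(rgb[..., 0], 0.0)
        np.testing.assert_allclose(rgb[..., 1], 1 / 3)
        np.testing.assert_allclose(rgb[..., 2], 1 / 3)

    def test_all_zero_black(self):
        np.testing.assert_allclose(color_average(np.zeros((3, 2, 2))), 0.0)

    def test_color_mip_equal_channels_gray_at_full_value(self):
        ch = np.full((3, 2, 2), 0.7)
        rgb = color_mip(ch)
        np.testing.assert_allclose(rgb, 0.7)

    def test_color_mip_single_channel_exact_tint(self):
        ch = np.zeros((3, 2, 2))
        ch[1] = 0.8  # magenta
        rgb = color_mip(ch)
        np.testing.assert_allclose(rgb[..., 0], 0.8)
        np.testing.assert_allclose(rgb[..., 1], 0.0)
        np.testing.assert_allclose(rgb[..., 2], 0.8)

    def test_color_mip_dominates_color_average(self):
        rng = np.random.default_rng(3)
        ch = rng.random((3, 8, 8))
        assert np.all(color_mip(ch) >= color_average(ch) - 1e-12)

    def test_unregistered_stack_rejected(self, geometry):
        pattern = phantom.ScanPattern.circumpapillary(ascans=32)
        truth = phantom.default_truth(pattern, channel_depth_offsets=(0, 5, -5))
        stack = phantom.render_multichannel(
            truth, geometry, pattern, phantom.default_layers(), seed=0
        )
        with pytest.raises(ValueError):
            color_average(stack)
        with pytest.raises(ValueError):
            intensity_mip(stack)


class TestIntensityProjections:
    def test_identical_channels_identity(self, geometry):
        pattern = phantom.ScanPattern.circumpapillary(ascans=32)
        truth = phantom.default_truth(pattern)
        stack = phantom.render_multichannel(
            truth, geometry, pattern, [phantom.LayerModel("RPE", 100.0)],
            seed=0, noise_sigma=0.0, speckle=False,
        )
        np.testing.assert_allclose(intensity_mip(stack), stack.data[0])
        np.testing.assert_allclose(intensity_average(stack), stack.data[0])

    def test_mip_dominates_average_and_channels(self, cp_stack_small):
        stack = cp_stack_small[0]
        mip = intensity_mip(stack)
        avg = intensity_average(stack)
        assert np.all(mip >= avg - 1e-12)
        for c in range(3):
            assert np.all(mip >= stack.data[c] - 1e-12)

    def test_average_reduces_speckle_variance(self, geometry):
        pattern = phantom.ScanPattern.circumpapillary(ascans=1024)
        truth = phantom.default_truth(pattern, undulation_px=0, vessels=())
        layers = [phantom.LayerModel("RPE", 1000.0)]
        stack = phantom.render_multichannel(
            truth, geometry, pattern, layers, seed=13, noise_sigma=0.0
        )
        band = slice(285, 289)
        single_var = np.mean([stack.data[c, 0, band, :].var() for c in range(3)])
        avg_var = intensity_average(stack)[0, band, :].var()
        assert single_var / avg_var == pytest.approx(3.0, rel=0.15)


class TestEnfaceColorMip:
    def test_uniform_volume_uniform_map(self):
        vols = np.full((3, 8, 40, 8), 5.0)
        anchor = np.full((8, 8), 20)
        rgb = enface_color_mip(vols, anchor, 0, 4)
        assert np.ptp(rgb) == pytest.approx(0.0, abs=1e-12)

    def test_zero_thickness_rejected(self):
        vols = np.zeros((3, 4, 32, 4))
        with pytest.raises(ValueError):
            enface_color_mip(vols, np.full((4, 4), 10), 0, 0)

    def test_slab_outside_volume_rejected(self):
        vols = np.zeros((3, 4, 32, 4))
        with pytest.raises(ValueError):
            enface_color_mip(vols, np.full((4, 4), 30), 0, 8)

    def test_hfl_sectors_hue_matches_channel(self, geometry):
        pattern = phantom.ScanPattern.raster(ascans=48, bscans=48)
        truth = phantom.default_truth(pattern, undulation_px=0)
        stack = phantom.render_multichannel(
            truth, geometry, pattern, phantom.default_layers(), seed=17
        )
        anchor = truth.boundaries["HFL"]
        rgb = enface_color_mip(stack.data, anchor, 1, 7)
        az = pattern.azimuths()
        # channel tints: cyan lacks R, magenta lacks G, yellow lacks B
        missing = {0: 0, 1: 1, 2: 2}
        for c, phi_c in enumerate(geometry.channel_azimuths_deg):
            d = np.abs((az - phi_c + 180) % 360 - 180)
            sector = d < 30.0
            mean_rgb = rgb[sector].mean(axis=0)
            assert np.argmin(mean_rgb) == missing[c]


class TestAzimuthalProfiles:
    def test_deterministic_and_flagged(self, cp_stack_small):
        stack, truth, geometry, pattern, layers = cp_stack_small
        lm = LayerMap(
            boundaries={
                "ILM": truth.ilm()[0].astype(float),
                "RPE": truth.rpe_reference()[0].astype(float),
            },
            depth=truth.depth,
            vessel_flags=truth.vessel_mask(pattern)[0],
        )
        a = direction.azimuthal_profiles(stack, lm, n_bscans=3)
        b = direction.azimuthal_profiles(stack, lm, n_bscans=3)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.smoothed, pb.smoothed)
        assert all(p.normalized.max() == pytest.approx(1.0) for p in a)

    def test_warns_when_fewer_bscans(self, cp_stack_small):
        stack, truth, geometry, pattern, layers = cp_stack_small
        lm = LayerMap(
            boundaries={
                "ILM": truth.ilm()[0].astype(float),
                "RPE": truth.rpe_reference()[0].astype(float),
            },
            depth=truth.depth,
        )
        with pytest.warns(UserWarning):
            direction.azimuthal_profiles(stack, lm, n_bscans=10)

    def test_isotropic_phantom_flat_profiles(self, geometry):
        pattern = phantom.ScanPattern.circumpapillary(ascans=512, bscans=6)
        truth = phantom.default_truth(pattern, vessels=())
        layers = [
            phantom.LayerModel(l.name, l.base_reflectivity)  # strip directionality
            for l in phantom.default_layers()
        ]
        stack = phantom.render_multichannel(truth, geometry, pattern, layers, seed=19)
        lm = LayerMap(
            boundaries={
                "ILM": truth.ilm()[0].astype(float),
                "RPE": truth.rpe_reference()[0].astype(float),
            },
            depth=truth.depth,
        )
        profiles = direction.azimuthal_profiles(stack, lm, n_bscans=6)
        for p in profiles:
            # flat within a few percent after averaging + smoothing
            assert np.ptp(p.smoothed) / p.smoothed.mean() < 0.15

    def test_photoreceptor_peaks_near_channel_azimuths(self, cp_stack_small):
        stack, truth, geometry, pattern, layers = cp_stack_small
        lm = LayerMap(
            boundaries={
                "ILM": truth.ilm()[0].astype(float),
                "RPE": truth.rpe_reference()[0].astype(float),
            },
            depth=truth.depth,
            vessel_flags=truth.vessel_mask(pattern)[0],
        )
        profiles = direction.azimuthal_profiles(stack, lm, preset="isos_cost", n_bscans=3)
        summary = detect_sectors(profiles)
        for c, phi_c in enumerate(geometry.channel_azimuths_deg):
            assert circular_separation(summary.peak_azimuths[c][0], phi_c) < 10.0
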