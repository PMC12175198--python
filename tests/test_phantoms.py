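import numpy as np
import pytest

from fpmkit import ComplexObject, simulate_stack
from fpmkit.metrics import (amplitude_rmse, phase_correlation,
                            resolution_probe, two_point_resolved)
from fpmkit.phantoms import (PhantomSpec, TwoPlaneScene, make_phantom,
                             marker_occluder, simulate_two_plane_stack,
                             two_point_positions)

from _oracles import two_plane_capture_oracle


class TestPhantoms:
    def test_uniform_kind_is_clear_glass(self):
        obj = make_phantom(PhantomSpec(kind="uniform", size=32))
        assert np.all(obj.absorption == 0)
        assert np.all(obj.phase == 0)
        assert np.allclose(obj.values, 1.0)

    @pytest.mark.parametrize("kind", ["tissue", "two_point", "star", "bars"])
    def test_deterministic_given_seed(self, kind):
        a = make_phantom(PhantomSpec(kind=kind, size=64, seed=9))
        b = make_phantom(PhantomSpec(kind=kind, size=64, seed=9))
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.absorption, b.absorption)

    def test_distinct_seeds_give_distinct_tissue(self):
        a = make_phantom(PhantomSpec(kind="tissue", size=64, seed=1))
        b = make_phantom(PhantomSpec(kind="tissue", size=64, seed=2))
        assert not np.array_equal(a.absorption, b.absorption)

    def test_two_point_geometry(self):
        sep = 0.9
        spec = PhantomSpec(kind="two_point", size=64, feature_scale=sep)
        obj = make_phantom(spec)
        clear = np.argwhere(obj.absorption == 0)
        assert len(clear) == 2
        d = np.linalg.norm(clear[0] - clear[1]) * spec.pixel_size
        assert d == pytest.approx(round(sep / spec.pixel_size)
                                  * spec.pixel_size)
        (r0, c0), (r1, c1) = two_point_positions(64, round(sep / spec.pixel_size))
        assert {tuple(p) for p in clear} == {(r0, c0), (r1, c1)}

    def test_tissue_respects_bounds_and_band_limit(self):
        spec = PhantomSpec(kind="tissue", size=128, seed=5)
        obj = make_phantom(spec)
        assert obj.absorption.min() >= 0
        assert obj.phase.max() <= spec.phi_range[1] + 1e-9
        for field in (obj.absorption, obj.phase):
            f = np.fft.fftshift(np.fft.fft2(field - field.mean()))
            k = np.fft.fftshift(np.fft.fftfreq(128, d=spec.pixel_size))
            kx, ky = np.meshgrid(k, k)
            outside = np.hypot(kx, ky) > spec.band_limit
            assert np.abs(f[outside]).max() < 1e-8 * np.abs(f).max()

    def test_sub_pixel_feature_rejected(self):
        with pytest.raises(ValueError, match="feature_scale"):
            make_phantom(PhantomSpec(kind="two_point", size=32,
                                     feature_scale=0.01))

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            PhantomSpec(kind="checkerboard")


class TestTwoPlaneSimulation:
    def test_transparent_occluder_reduces_to_single_plane(self, small_config,
                                                          small_phantom):
        n = small_config.hr_side
        clear = ComplexObject(phase=np.zeros((n, n)),
                              absorption=np.zeros((n, n)),
                              pixel_size=small_config.hr_pixel)
        scene = TwoPlaneScene(tissue=small_phantom, occluder=clear,
                              separation=150.0,
                              occluder_mask=np.zeros((n, n), bool))
        two = simulate_two_plane_stack(scene, small_config, focal_z=0.0)
        one = simulate_stack(small_phantom, small_config, z=0.0)
        assert np.abs(two.images - one.images).max() < 1e-12

    def test_zero_separation_limit_is_pointwise_product(self, small_config,
                                                        small_phantom):
        n = small_config.hr_side
        occ, _ = marker_occluder(n, small_config.hr_pixel, seed=4)
        scene = TwoPlaneScene(tissue=small_phantom, occluder=occ,
                              separation=1e-9,
                              occluder_mask=np.zeros((n, n), bool))
        two = simulate_two_plane_stack(scene, small_config, focal_z=0.0)
        product = ComplexObject(phase=small_phantom.phase + occ.phase,
                                absorption=small_phantom.absorption
                                + occ.absorption,
                                pixel_size=small_config.hr_pixel)
        one = simulate_stack(product, small_config, z=0.0)
        rel = np.abs(two.images - one.images).max() / one.images.max()
        assert rel < 1e-8

    def test_matches_direct_sum_oracle(self, tiny_config, tiny_phantom):
        from fpmkit.optics import (_angular_spectrum, led_wavevectors,
                                   make_pupil)
        cfg = tiny_config
        n = cfg.hr_side
        occ, mask = marker_occluder(n, cfg.hr_pixel, seed=7)
        scene = TwoPlaneScene(tissue=tiny_phantom, occluder=occ,
                              separation=40.0, occluder_mask=mask)
        got = simulate_two_plane_stack(scene, cfg, focal_z=0.0)
        il = led_wavevectors(cfg)
        pupil = make_pupil(cfg, [0.0])
        kxh, kyh = cfg.hr_freq_grid()
        h_sep = _angular_spectrum(kxh, kyh, cfg.wavelength, 40.0)
        kxl, kyl = cfg.lr_freq_grid()
        h_img = _angular_spectrum(kxl, kyl, cfg.wavelength, -40.0)
        for m in range(len(il)):
            want = two_plane_capture_oracle(
                tiny_phantom.values, occ.values, il.wavevectors[m],
                pupil.values, h_sep, h_img, 1.0, cfg.lr_side, cfg.lr_pixel)
            rel = np.abs(got.images[m] - want).max() / max(want.max(), 1e-30)
            assert rel < 1e-10

    def test_mismatched_grids_rejected(self, small_phantom):
        occ, _ = marker_occluder(16, 0.325, seed=0)
        with pytest.raises(ValueError, match="grids"):
            TwoPlaneScene(tissue=small_phantom, occluder=occ,
                          separation=100.0, occluder_mask=np.zeros((16, 16),
                                                                   bool))

    def test_zero_separation_scene_rejected(self, small_phantom):
        n = small_phantom.phase.shape[0]
        with pytest.raises(ValueError, match="separation"):
            TwoPlaneScene(tissue=small_phantom, occluder=small_phantom,
                          separation=0.0,
                          occluder_mask=np.zeros((n, n), bool))


class TestMetrics:
    def test_perfect_recovery_scores_perfectly(self, small_phantom):
        assert amplitude_rmse(small_phantom, small_phantom) == 0.0
        assert phase_correlation(small_phantom, small_phantom) == pytest.approx(1.0)

    def test_global_scale_is_gauge(self, small_phantom):
        amp = np.abs(small_phantom.values)
        assert amplitude_rmse(2.0 * amp, amp) == pytest.approx(0.0, abs=1e-12)

    def test_noise_floor_matches_closed_form(self):
        # RMSE of (a + noise) vs a after the scale fit: sqrt(m/(m+1))
        # with m = mean(a^2)/sigma^2, derived from the least-squares scalar.
        rng = np.random.default_rng(1)
        a = rng.uniform(1.0, 3.0, (128, 128))
        noisy = a + rng.standard_normal((128, 128))
        m = np.mean(a ** 2)
        expected = np.sqrt(m / (m + 1))
        assert amplitude_rmse(noisy, a) == pytest.approx(expected, rel=0.05)

    def test_constant_phase_conventions(self):
        flat = np.zeros((8, 8))
        assert phase_correlation(flat, flat + 2.0) == 1.0
        with pytest.raises(ValueError, match="constant"):
            phase_correlation(flat, np.linspace(0, 1, 64).reshape(8, 8))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            amplitude_rmse(np.ones((4, 4)), np.ones((8, 8)))


class TestResolutionProbe:
    @staticmethod
    def _two_peak_image(n, sep_px, valley, width=1.2):
        x = np.arange(n)
        c = n // 2
        x0 = c - sep_px // 2
        x1 = x0 + sep_px
        row = (np.exp(-((x - x0) / width) ** 2)
               + np.exp(-((x - x1) / width) ** 2))
        row = row / row.max()
        img = np.zeros((n, n))
        img[c - 1:c + 2, :] = row
        img[c - 1:c + 2, x0 + 1:x1] = valley   # plateau between the peaks
        return img

    def test_dip_criterion(self):
        deep = self._two_peak_image(64, 8, valley=0.5)
        shallow = self._two_peak_image(64, 8, valley=0.95)
        assert two_point_resolved(deep, 1.0, 8.0)
        assert not two_point_resolved(shallow, 1.0, 8.0)

    def test_sub_two_pixel_separation_unresolvable(self):
        img = self._two_peak_image(64, 8, valley=0.1)
        assert not two_point_resolved(img, 1.0, 1.5)

    def test_probe_reports_minima_and_warning(self):
        seps = [8.0, 4.0]
        rec = [self._two_peak_image(64, 8, 0.3),
               self._two_peak_image(64, 4, 0.3)]
        lr = [self._two_peak_image(64, 8, 0.3),
              self._two_peak_image(64, 4, 0.99)]
        res = resolution_probe(rec, lr, seps, 1.0, 1.0)
        assert res.smallest_recon == 4.0
        assert res.smallest_lr == 8.0
        assert res.warning is None
        res2 = resolution_probe([self._two_peak_image(64, 8, 0.99)],
                                [self._two_peak_image(64, 8, 0.99)],
                                [8.0], 1.0, 1.0)
        assert res2.smallest_recon == float("inf")
        assert res2.warning is not None
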