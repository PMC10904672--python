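import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.special import erf

from ctsim.metrics import (MetricsError, MTFCurve, line_profile, noise_std,
                           recon_nps, slanted_edge_mtf, ssp_from_tilted_wire,
                           wire_mtf)
from ctsim.recon import Volume


def _vol(data, voxel=(1.0, 0.5, 0.5)):
    return Volume(np.asarray(data, dtype=float), voxel)


class TestF10Readout:
    def test_linear_interpolation_at_first_downward_crossing(self):
        curve = MTFCurve(np.array([0.0, 1.0, 2.0, 3.0]),
                         np.array([1.0, 0.4, 0.05, 0.2]))
        # crossing between f=1 (0.4) and f=2 (0.05)
        assert curve.f10 == pytest.approx(1.0 + (0.4 - 0.1) / (0.4 - 0.05))

    def test_never_crossing_curve_gives_nan(self):
        curve = MTFCurve(np.linspace(0, 1, 5), np.linspace(1.0, 0.5, 5))
        assert np.isnan(curve.f10)


class TestSlantedEdge:
    @staticmethod
    def _edge_image(sigma_px=0.0, angle_deg=5.0, n=96):
        """Gaussian ESF sampled at centers, or an aperture-integrated sharp
        edge (8x8 sub-pixel average of the step)."""
        slope = np.tan(np.radians(angle_deg))
        cosA = np.cos(np.radians(angle_deg))

        def dist(jj, ii):
            return (jj - (n / 2 + slope * (ii - n / 2))) * cosA

        if sigma_px > 0:
            jj, ii = np.meshgrid(np.arange(n), np.arange(n))
            return 0.5 * (1.0 + erf(dist(jj, ii) / (sigma_px * np.sqrt(2.0))))
        img = np.zeros((n, n))
        sub = (np.arange(8) + 0.5) / 8 - 0.5
        for dy in sub:
            for dx in sub:
                jj, ii = np.meshgrid(np.arange(n) + dx, np.arange(n) + dy)
                img += (dist(jj, ii) > 0)
        return img / 64.0

    def test_gaussian_blurred_edge_matches_analytic_mtf(self):
        sigma = 1.2  # pixels
        pitch = 0.5  # mm
        img = self._edge_image(sigma_px=sigma)
        curve = slanted_edge_mtf(img, pitch)
        nyq2 = 0.25 / pitch
        f = np.linspace(0.05, nyq2, 15)
        expected = np.exp(-2 * np.pi**2 * (sigma * pitch) ** 2 * f**2)
        assert curve.at(f) == pytest.approx(expected, abs=0.03)

    def test_sharp_edge_gives_pixel_aperture_sinc(self):
        pitch = 0.5
        angle = 5.0
        img = self._edge_image(sigma_px=0.0, angle_deg=angle)
        curve = slanted_edge_mtf(img, pitch)
        f = np.linspace(0.05, 0.25 / pitch, 12)
        # projecting the square pixel aperture onto the edge normal
        c, s = np.cos(np.radians(angle)), np.sin(np.radians(angle))
        expected = np.abs(np.sinc(f * pitch * c) * np.sinc(f * pitch * s))
        assert curve.at(f) == pytest.approx(expected, abs=0.04)

    def test_flat_image_raises_no_edge(self):
        with pytest.raises(MetricsError, match="no edge"):
            slanted_edge_mtf(np.full((32, 32), 3.0), 0.5)


class TestWireMTF:
    @staticmethod
    def _psf_volume(sigma_x_px, sigma_y_px, n=256, pitch=0.076):
        yy, xx = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2,
                             indexing="ij")
        img = np.exp(-0.5 * ((xx / sigma_x_px) ** 2
                             + (yy / sigma_y_px) ** 2))
        return Volume(img[None], (1.0, pitch, pitch))

    def test_gaussian_psf_f10_matches_closed_form(self):
        sigma_px, pitch = 4.0, 0.076
        vol = self._psf_volume(sigma_px, sigma_px, pitch=pitch)
        curve = wire_mtf(vol, "radial")
        sigma_mm = sigma_px * pitch
        f10_true = np.sqrt(np.log(10.0) / (2 * np.pi**2 * sigma_mm**2))
        assert curve.f10 == pytest.approx(f10_true, rel=0.02)

    def test_single_pixel_impulse_gives_flat_spectrum(self):
        n = 64
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        vol = Volume(img[None], (1.0, 0.1, 0.1))
        curve = wire_mtf(vol, "radial", min_snr=1.0)
        band = curve.mtf[curve.freq_per_mm < 0.25 / 0.1]
        # Hann windowing of the flat LSF perturbs the spectrum only mildly
        assert np.all(band > 0.9)

    def test_anisotropic_psf_orders_radial_vs_tangential(self):
        vol = self._psf_volume(sigma_x_px=3.0, sigma_y_px=6.0)
        radial = wire_mtf(vol, "radial")       # x direction: sharper
        tangential = wire_mtf(vol, "tangential")
        assert radial.f10 > tangential.f10

    def test_azimuth_rotation_aligns_radial_axis(self):
        """A PSF elongated along y, viewed at 90 deg azimuth, has its
        radial direction along that elongation."""
        vol = self._psf_volume(sigma_x_px=3.0, sigma_y_px=6.0)
        rot = wire_mtf(vol, "radial", wire_azimuth_deg=90.0)
        ref = wire_mtf(vol, "tangential")
        assert rot.f10 == pytest.approx(ref.f10, rel=0.05)

    def test_missing_wire_signal_raises(self, rng):
        vol = Volume(rng.standard_normal((1, 64, 64)), (1.0, 0.1, 0.1))
        with pytest.raises(MetricsError, match="threshold"):
            wire_mtf(vol, "radial", min_snr=50.0)


class TestSSP:
    @staticmethod
    def _streak_volume(profile, tilt_deg=8.0, n=256, pitch_y=0.076):
        """Slice whose lateral streak encodes SSP(z = y*tan(tilt))."""
        y = (np.arange(n) - n / 2) * pitch_y
        z = y * np.tan(np.radians(tilt_deg))
        img = np.tile(profile(z)[:, None], (1, 8)) / 8.0
        return Volume(img[None], (1.0, pitch_y, 0.076))

    def test_gaussian_slice_profile_recovered(self):
        sigma_z = 0.4  # mm
        vol = self._streak_volume(lambda z: np.exp(-0.5 * (z / sigma_z) ** 2))
        curve = ssp_from_tilted_wire(vol, tilt_deg=8.0)
        f = np.linspace(0.1, 0.8, 10)
        expected = np.exp(-2 * np.pi**2 * sigma_z**2 * f**2)
        assert curve.at(f) == pytest.approx(expected, abs=0.03)

    def test_rect_slice_profile_gives_sinc_with_first_zero(self):
        w = 1.0  # mm slice width
        vol = self._streak_volume(lambda z: (np.abs(z) < w / 2).astype(float))
        curve = ssp_from_tilted_wire(vol, tilt_deg=8.0)
        # |sinc| has its first zero at 1/w; the measured spectrum should dip
        near_zero = curve.at(np.array([1.0 / w]))
        assert near_zero[0] < 0.08
        assert curve.at(np.array([0.5 / w]))[0] > 0.5

    def test_zero_tilt_rejected(self):
        vol = self._streak_volume(lambda z: np.exp(-z**2))
        with pytest.raises(ValueError, match="tilt"):
            ssp_from_tilted_wire(vol, tilt_deg=0.0)

    def test_missing_wire_raises(self, rng):
        vol = Volume(rng.standard_normal((1, 64, 64)), (1.0, 0.1, 0.1))
        with pytest.raises(MetricsError, match="threshold"):
            ssp_from_tilted_wire(vol, tilt_deg=8.0, min_snr=50.0)


class TestReconNPS:
    def test_white_noise_flat_radial_and_unit_areas(self, rng):
        vol = _vol(rng.standard_normal((80, 96, 96)), (1.0, 0.4, 0.4))
        rep = recon_nps(vol, roi_size=64)
        areas = rep.areas()
        for v in areas.values():
            assert v == pytest.approx(1.0, abs=1e-6)
        prof = rep.radial_nnps[1:-2]
        mad = np.mean(np.abs(prof - prof.mean())) / prof.mean()
        assert mad < 0.05

    def test_structure_separates_structured_from_unstructured(self, rng):
        noise = rng.standard_normal((60, 64, 64))
        yy = np.linspace(0, 4 * np.pi, 64)
        structure = 3.0 * np.sin(yy)[None, :, None]
        vol_noisy = _vol(noise + structure, (1.0, 0.4, 0.4))
        vol_clean = _vol(noise, (1.0, 0.4, 0.4))
        rep = recon_nps(vol_noisy, roi_size=64)
        rep_clean = recon_nps(vol_clean, roi_size=64)
        d_struct = np.abs(rep.nps2d - rep_clean.nps2d).sum()
        d_unstruct = np.abs(rep.nps2d_unstructured
                            - rep_clean.nps2d_unstructured).sum()
        assert d_unstruct < 0.1 * d_struct

    def test_colored_noise_radial_profile_tracks_kernel(self, rng):
        from scipy.signal import fftconvolve
        kern = np.ones((3, 3)) / 9.0
        frames = [fftconvolve(rng.standard_normal((80, 80)), kern,
                              mode="same")[8:72, 8:72] for _ in range(60)]
        vol = _vol(np.stack(frames), (1.0, 0.4, 0.4))
        rep = recon_nps(vol, roi_size=64)
        h2 = np.abs(np.fft.fft2(kern, (64, 64))) ** 2
        from ctsim.corruption import radial_average
        _, want = radial_average(h2, 0.4, 0.4)
        got = rep.radial_nnps
        want_n = want[1:25] / want[1:25].sum()
        got_n = got[1:25] / got[1:25].sum()
        assert got_n == pytest.approx(want_n, abs=0.12 * want_n.max())

    def test_oversized_roi_rejected(self, rng):
        vol = _vol(rng.standard_normal((10, 32, 32)))
        with pytest.raises(ValueError, match="ROI"):
            recon_nps(vol, roi_size=64)


class TestNoiseStdAndProfiles:
    def test_constant_volume_has_zero_std(self):
        assert noise_std(_vol(np.full((70, 70, 70), 5.0)), 64) == 0.0

    def test_unit_variance_noise_measured(self, rng):
        vol = _vol(rng.standard_normal((70, 70, 70)))
        assert noise_std(vol, 64) == pytest.approx(1.0, rel=0.02)

    def test_voi_picks_requested_region(self, rng):
        data = np.concatenate([rng.standard_normal((70, 35, 70)),
                               3.0 * rng.standard_normal((70, 35, 70))],
                              axis=1)
        vol = _vol(data)
        lo = noise_std(vol, (64, 16, 64), center=(35, 10, 35))
        hi = noise_std(vol, (64, 16, 64), center=(35, 60, 35))
        assert lo == pytest.approx(1.0, rel=0.05)
        assert hi == pytest.approx(3.0, rel=0.05)

    def test_voi_outside_volume_rejected(self, rng):
        with pytest.raises(ValueError, match="VOI"):
            noise_std(_vol(rng.standard_normal((32, 32, 32))), 64)

    def test_uniform_volume_gives_constant_profile(self):
        coords, prof = line_profile(_vol(np.full((40, 80, 80), 7.0)))
        assert np.ptp(prof) == 0.0
        assert coords.size == 80

    def test_linear_ramp_recovers_slope(self):
        ramp = np.broadcast_to(np.arange(80.0), (40, 80, 80)).copy()
        vol = _vol(ramp, (1.0, 0.5, 0.5))
        coords, prof = line_profile(vol, axis="x")
        slope = np.polyfit(coords, prof, 1)[0]
        assert slope == pytest.approx(1.0 / 0.5, rel=1e-9)

    def test_cupping_magnitude_measured(self):
        x = np.linspace(-1.0, 1.0, 80)
        cup = 10.0 * (x**2)[None, None, :]
        vol = _vol(np.broadcast_to(cup, (40, 80, 80)).copy(), (1.0, 0.5, 0.5))
        coords, prof = line_profile(vol, axis="x")
        assert prof[40] - prof.max() == pytest.approx(-10.0, abs=0.3)
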