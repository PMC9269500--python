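import numpy as np
import pytest

from scintidose import synthetic, tomography as tomo


def reconstruction_mask(n, radius):
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return np.hypot(xx - c, yy - c) <= radius


def nrmse(a, b, mask):
    return np.sqrt(np.mean((a[mask] - b[mask]) ** 2)) / np.sqrt(np.mean(b[mask] ** 2))


@pytest.fixture(scope="module")
def tbar_truth():
    return tomo.phantom_slice_truth(tomo.TBarPhantomSpec())


class TestForwardRadon:
    def test_uniform_disk_matches_chord_formula(self):
        n, radius, mu = 129, 40.0, 1.0
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n]
        disk = np.where(np.hypot(xx - c, yy - c) <= radius, mu, 0.0)
        sino = tomo.forward_radon(disk, np.arange(0.0, 180.0, 5.0))
        s = np.arange(n) - c
        expected = 2 * mu * np.sqrt(np.clip(radius**2 - s**2, 0.0, None))
        # discretisation bound: worst case two detector bins at the rim
        edge_bound = 2 * mu * np.sqrt(radius**2 - (radius - 2) ** 2)
        assert np.abs(sino.intensities - expected[None, :]).max() < edge_bound
        assert nrmse(sino.intensities, np.tile(expected, (36, 1)), np.ones_like(sino.intensities, bool)) < 0.05

    def test_center_pixel_stays_at_detector_center(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        sino = tomo.forward_radon(img, np.arange(0.0, 180.0, 10.0))
        positions = np.argmax(sino.intensities, axis=1)
        assert np.all(np.abs(positions - 32) <= 1)
        # energy stays concentrated near the centre at every angle
        central = sino.intensities[:, 30:35].sum(axis=1)
        assert np.all(central > 0.9 * sino.intensities.sum(axis=1))

    def test_mass_conserved_across_angles(self, tbar_truth):
        sino = tomo.forward_radon(tbar_truth, np.arange(0.0, 180.0, 2.0))
        sums = sino.intensities.sum(axis=1)
        assert (sums.max() - sums.min()) / sums.mean() < 1e-3

    def test_translated_point_traces_sinusoid(self):
        img = np.zeros((129, 129))
        img[64, 94] = 1.0  # 30 px right of centre
        angles = np.arange(0.0, 360.0, 5.0)
        sino = tomo.forward_radon(img, angles)
        trace = np.argmax(sino.intensities, axis=1) - 64.0
        expected = 30.0 * np.cos(np.deg2rad(angles))
        assert np.abs(trace - expected).max() <= 1.5

    def test_non_square_image_rejected(self):
        with pytest.raises(ValueError):
            tomo.forward_radon(np.zeros((10, 12)), [0.0, 90.0])


class TestInverseRadon:
    def test_tbar_roundtrip_below_ten_percent(self, tbar_truth):
        sino = tomo.forward_radon(tbar_truth, np.arange(180.0))
        rec = tomo.inverse_radon_fbp(sino)
        mask = reconstruction_mask(tbar_truth.shape[0], 70)
        assert nrmse(rec.image, tbar_truth, mask) < 0.1

    def test_unfiltered_backprojection_loses_contrast(self, tbar_truth):
        sino = tomo.forward_radon(tbar_truth, np.arange(180.0))
        ramp = tomo.inverse_radon_fbp(sino, "ramp").image
        blur = tomo.inverse_radon_fbp(sino, "none").image
        mask = reconstruction_mask(tbar_truth.shape[0], 70)

        def rel_contrast(img):
            vals = img[mask]
            return (vals.max() - vals.min()) / abs(vals.mean())

        assert rel_contrast(blur) < rel_contrast(ramp)

    def test_point_recovered_within_one_pixel(self):
        img = np.zeros((101, 101))
        img[30, 62] = 1.0
        sino = tomo.forward_radon(img, np.arange(180.0))
        rec = tomo.inverse_radon_fbp(sino).image
        peak = np.unravel_index(np.argmax(rec), rec.shape)
        assert abs(peak[0] - 30) <= 1 and abs(peak[1] - 62) <= 1

    def test_reconstruction_linear_in_intensity(self, tbar_truth):
        sino = tomo.forward_radon(tbar_truth, np.arange(0.0, 180.0, 3.0))
        rec1 = tomo.inverse_radon_fbp(sino).image
        scaled = tomo.Sinogram(3.0 * sino.intensities, sino.angles)
        rec3 = tomo.inverse_radon_fbp(scaled).image
        np.testing.assert_allclose(rec3, 3.0 * rec1, atol=1e-9)

    def test_span_below_180_rejected(self, tbar_truth):
        sino = tomo.forward_radon(tbar_truth, np.arange(0.0, 120.0, 2.0))
        with pytest.raises(tomo.InsufficientCoverageError):
            tomo.inverse_radon_fbp(sino)

    def test_fold_360_matches_direct_use(self, tbar_truth):
        sino = tomo.forward_radon(tbar_truth, np.arange(0.0, 360.0, 2.0))
        mask = reconstruction_mask(tbar_truth.shape[0], 70)
        direct = tomo.inverse_radon_fbp(sino).image
        folded = tomo.inverse_radon_fbp(sino, fold_360=True).image
        assert nrmse(direct, tbar_truth, mask) < 0.1
        assert nrmse(folded, tbar_truth, mask) < 0.1

    def test_double_sampling_beats_half_on_perturbed_data(self, tbar_truth):
        spec = synthetic.RotPhantomSpec(
            frames_per_rev=180, n_frames=180, refraction_amp=2.0, noise_sigma=0.004, seed=3
        )
        stack = synthetic.render_rotation_frames(spec)
        att = tomo.attenuation_sinogram(tomo.sinogram_from_frames(stack), i0=1.0)
        half = tomo.Sinogram(
            att.intensities[att.angles < 180.0], att.angles[att.angles < 180.0]
        )
        mask = reconstruction_mask(tbar_truth.shape[0], 70)
        r360 = nrmse(tomo.inverse_radon_fbp(att).image, tbar_truth, mask)
        r180 = nrmse(tomo.inverse_radon_fbp(half).image, tbar_truth, mask)
        assert r360 <= r180


class TestSinogramFromFrames:
    def test_identical_frames_give_identical_rows(self):
        frames = np.tile(np.linspace(0, 1, 32)[None, None, :], (8, 16, 1))
        stack = tomo.FrameStack(frames, rotation_period=4, baseline_row=7)
        sino = tomo.sinogram_from_frames(stack)
        assert np.allclose(sino.intensities, sino.intensities[0])

    def test_period_four_angles(self):
        frames = np.zeros((4, 8, 8))
        stack = tomo.FrameStack(frames, rotation_period=4, baseline_row=4)
        sino = tomo.sinogram_from_frames(stack)
        np.testing.assert_allclose(sino.angles, [0.0, 90.0, 180.0, 270.0])

    def test_revolutions_average_suppresses_noise(self, rng):
        base = rng.uniform(0, 1, (5, 1, 16))
        noisy = np.concatenate([base + rng.normal(0, 0.1, base.shape) for _ in range(8)])
        stack = tomo.FrameStack(noisy, rotation_period=5, baseline_row=0)
        sino = tomo.sinogram_from_frames(stack)
        assert np.abs(sino.intensities - base[:, 0, :]).max() < 0.15

    def test_rotating_point_sinusoid_amplitude(self):
        stack = synthetic.render_rotating_point(30.0, frames_per_rev=90, n_frames=90)
        sino = tomo.sinogram_from_frames(stack)
        trace = np.argmax(sino.intensities, axis=1) - (128 - 1) / 2.0
        amp = (trace.max() - trace.min()) / 2.0
        assert amp == pytest.approx(30.0, abs=1.0)

    def test_rgb_frames_reduced_by_luma(self):
        frames = np.zeros((4, 4, 6, 3))
        frames[..., 1] = 0.5  # green only
        stack = tomo.FrameStack(frames, rotation_period=4, baseline_row=2)
        sino = tomo.sinogram_from_frames(stack)
        assert sino.intensities == pytest.approx(0.5 * 0.7152)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            tomo.FrameStack(np.zeros((3, 8, 8)), rotation_period=4, baseline_row=2)


class TestPhantomTruth:
    def test_empty_spec_is_zero(self):
        spec = tomo.TBarPhantomSpec(vial_radius=0.0, vial_wall=0.0, bar_radius=0.0)
        assert np.all(tomo.phantom_slice_truth(spec) == 0.0)

    def test_vial_only_annulus_levels(self):
        spec = tomo.TBarPhantomSpec()
        img = tomo.phantom_slice_truth(spec, with_bar=False)
        c = (img.shape[0] - 1) / 2.0
        assert img[int(c), int(c)] == pytest.approx(spec.mu_liquid)
        rim = int(c + spec.vial_radius - spec.vial_wall / 2)
        assert img[int(c), rim] == pytest.approx(spec.mu_wall, rel=0.2)
        outside = img[0, 0]
        assert outside == 0.0

    def test_holes_must_fit_inside_bar(self):
        with pytest.raises(ValueError):
            tomo.TBarPhantomSpec(hole_offsets=(30.0,), bar_radius=28.0)


class TestRotationPeriodEstimate:
    def test_recovers_known_period(self):
        stack = synthetic.render_rotating_point(25.0, frames_per_rev=40, n_frames=160)
        rows = stack.frames[:, stack.baseline_row]
        # use the detector position of the blob as the per-frame signal
        signal = np.argmax(rows, axis=1).astype(float)
        assert abs(tomo.estimate_rotation_period(signal) - 40) <= 1
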