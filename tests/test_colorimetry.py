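import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scintidose import colorimetry as col
from scintidose import synthetic, transport


def one_pixel(r, g, b, colorspace="srgb"):
    return col.RGBImage(np.array([[[r, g, b]]], dtype=float), colorspace)


class TestSrgbTransfer:
    @pytest.mark.parametrize("value, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.21404)])
    def test_decode_values(self, value, expected):
        out = col.srgb_decode(one_pixel(value, value, value)).pixels[0, 0, 0]
        assert out == pytest.approx(expected, abs=1e-4)

    def test_decode_encode_inverse(self, rng):
        vals = rng.uniform(0, 1, (8, 8, 3))
        img = col.srgb_decode(col.RGBImage(vals, "srgb"))
        np.testing.assert_allclose(col.srgb_encode(img.pixels), vals, atol=1e-12)

    def test_decode_linear_warns(self):
        with pytest.warns(UserWarning):
            col.srgb_decode(one_pixel(0.5, 0.5, 0.5, "linear"))


class TestXyzDecomposition:
    def test_white_maps_to_d65(self):
        dec = col.rgb_to_xyz(one_pixel(1, 1, 1, "linear"))
        assert dec.X[0, 0] == pytest.approx(0.9505, abs=2e-4)
        assert dec.Y[0, 0] == pytest.approx(1.0000, abs=2e-4)
        assert dec.Z[0, 0] == pytest.approx(1.0890, abs=2e-3)

    def test_black_is_zero_everywhere(self):
        dec = col.rgb_to_xyz(one_pixel(0, 0, 0, "linear"))
        for plane in (dec.X, dec.Y, dec.Z, dec.x, dec.y, dec.z):
            assert plane[0, 0] == 0.0

    def test_pure_blue_chromaticity_z_dominant(self):
        dec = col.rgb_to_xyz(one_pixel(0, 0, 1, "linear"))
        assert dec.x[0, 0] == pytest.approx(0.150, abs=0.002)
        assert dec.y[0, 0] == pytest.approx(0.060, abs=0.002)
        assert dec.z[0, 0] == pytest.approx(0.79, abs=0.01)

    def test_requires_linear_input(self):
        with pytest.raises(ValueError):
            col.rgb_to_xyz(one_pixel(1, 1, 1, "srgb"))

    @given(st.integers(0, 2**32 - 1))
    def test_chromaticities_sum_to_one(self, seed):
        vals = np.random.default_rng(seed).uniform(0, 1, (4, 4, 3))
        dec = col.rgb_to_xyz(col.RGBImage(vals, "linear"))
        total = dec.X + dec.Y + dec.Z
        s = dec.x + dec.y + dec.z
        np.testing.assert_allclose(s[total > 0], 1.0, atol=1e-6)


class TestHsv:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((0, 0, 1), (240.0, 1.0, 1.0)),
            ((0.6, 0.6, 0.6), (0.0, 0.0, 0.6)),
            ((0.25, 0.5, 1.0), (220.0, 0.75, 1.0)),
        ],
    )
    def test_hexcone_examples(self, rgb, expected):
        hsv = col.rgb_to_hsv(one_pixel(*rgb))
        assert hsv.H[0, 0] == pytest.approx(expected[0], abs=1e-6)
        assert hsv.S[0, 0] == pytest.approx(expected[1], abs=1e-9)
        assert hsv.V[0, 0] == pytest.approx(expected[2], abs=1e-9)

    def test_roundtrip_identity_on_color_grid(self):
        axis = np.linspace(0, 1, 10)
        r, g, b = np.meshgrid(axis, axis, axis, indexing="ij")
        img = col.RGBImage(np.stack([r, g, b], axis=-1).reshape(100, 10, 3))
        back = col.hsv_to_rgb(col.rgb_to_hsv(img))
        assert np.abs(back.pixels - img.pixels).max() < 1e-9


class TestVHistogramAndThreshold:
    def test_constant_image_single_bin(self):
        hsv = col.rgb_to_hsv(col.RGBImage(np.full((10, 10, 3), 0.42)))
        counts, _ = col.v_histogram(hsv, 20)
        assert counts.max() == 100
        assert np.count_nonzero(counts) == 1

    def test_two_level_counts(self):
        v = np.concatenate([np.full(25, 0.35), np.full(75, 0.65)]).reshape(10, 10)
        hsv = col.HSVImage(np.zeros_like(v), np.zeros_like(v), v)
        counts, edges = col.v_histogram(hsv, 10)
        assert counts[3] == 25 and counts[6] == 75
        assert counts.sum() == 100

    def test_threshold_edge_cases(self):
        v = np.array([[0.2, 0.7], [0.7, 0.2]])
        hsv = col.HSVImage(np.zeros_like(v), np.zeros_like(v), v)
        assert col.v_threshold(hsv, 0.0).mask.all()
        assert not col.v_threshold(hsv, 0.8).mask.any()
        sel = col.v_threshold(hsv, 0.3)
        assert sel.mask.sum() == 2
        np.testing.assert_array_equal(sel.masked_V, np.where(v >= 0.3, v, 0.0))

    @given(cuts=st.lists(st.floats(0, 1), min_size=2, max_size=6))
    def test_mask_size_non_increasing_in_cut(self, cuts):
        v = np.random.default_rng(99).uniform(0, 1, (16, 16))
        hsv = col.HSVImage(np.zeros_like(v), np.zeros_like(v), v)
        sizes = [col.v_threshold(hsv, c).mask.sum() for c in sorted(cuts)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestDoseMap:
    def test_noise_free_roundtrip_correlation(self):
        z = np.linspace(0, 4, 150)
        truth = np.outer(np.exp(-((z - 1.2) ** 2)), np.ones(100))
        cam = synthetic.CameraModel(psf_sigma=0.0, noise_gauss=0.0, seed=0)
        img = synthetic.render_fluorescence_image(
            transport.DoseGrid2D(truth, 0.03, None), cam
        )
        rec = col.dose_map_from_image(img, v_cut=0.0, calibration=0.03)
        r = np.corrcoef(rec.deposited.ravel(), truth.ravel())[0, 1]
        assert r > 0.999

    def test_uniform_image_gives_uniform_map(self):
        img = col.RGBImage(np.full((20, 20, 3), 0.5))
        rec = col.dose_map_from_image(img, v_cut=0.0, calibration=1.0)
        np.testing.assert_allclose(rec.deposited, 100.0)

    def test_vcut_removes_generator_reflection_bands(self, mc6_grid):
        cam = synthetic.electron_camera(seed=3)
        img = synthetic.render_fluorescence_image(mc6_grid, cam)
        rec = col.dose_map_from_image(img, v_cut=0.3, calibration=0.05)
        # bottom reflection band (V = 0.25 < cut): essentially all removed,
        # save for the few pixels that sensor noise pushes past the threshold
        assert (rec.deposited[-8:] > 0).mean() < 0.02
        no_cut = col.dose_map_from_image(img, v_cut=0.0, calibration=0.05)
        assert (no_cut.deposited[-8:] > 0).mean() > 0.98

    def test_empty_mask_raises(self):
        img = col.RGBImage(np.full((5, 5, 3), 0.1))
        with pytest.raises(ValueError):
            col.dose_map_from_image(img, v_cut=0.9, calibration=1.0)

    def test_bad_calibration_raises(self):
        img = col.RGBImage(np.full((5, 5, 3), 0.5))
        with pytest.raises(ValueError):
            col.dose_map_from_image(img, v_cut=0.1, calibration=0.0)


@pytest.fixture(scope="module")
def gamma_hsv():
    dose, cam = synthetic.gamma_style_scene(seed=5)
    img = synthetic.render_fluorescence_image(dose, cam)
    return col.rgb_to_hsv(img)


class TestGammaStyleScene:
    def test_v_histogram_is_bimodal(self, gamma_hsv):
        counts, edges = col.v_histogram(gamma_hsv, 50)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # local maxima of the histogram, ignoring empty bins
        peaks = [
            centers[i]
            for i in range(1, 49)
            if counts[i] > counts[i - 1] and counts[i] >= counts[i + 1] and counts[i] > 50
        ]
        assert any(abs(p - 0.30) < 0.05 for p in peaks)
        assert any(abs(p - 0.62) < 0.05 for p in peaks)

    def test_point6_cut_separates_populations(self, gamma_hsv):
        refl = gamma_hsv.V[:20]  # reflection band rows
        signal = gamma_hsv.V[20:180]
        assert (refl >= 0.6).mean() == 0.0
        assert (signal >= 0.6).mean() >= 0.95

    def test_raising_cut_removes_noise_keeps_signal(self, gamma_hsv):
        low = col.v_threshold(gamma_hsv, 0.3)
        high = col.v_threshold(gamma_hsv, 0.6)
        # the 0.3 cut keeps a large part of the reflection band (its V values
        # straddle the cut), the 0.6 cut drops it entirely
        assert low.mask[:20].mean() > 0.3
        assert high.mask[:20].mean() == 0.0
        assert high.mask[20:180].mean() >= 0.95
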