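"""Binarization, noise removal and envelope tracing against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import coroflow as cf
from coroflow.envelope_extraction import extract_envelope, preprocess


def exhaustive_otsu(hist):
    """Independent oracle: scan all 256 thresholds for max between-class
    variance, smallest threshold on ties."""
    hist = np.asarray(hist, dtype=float)
    n = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[:t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:t + 1] * np.arange(t + 1)).sum() / w0
        m1 = (hist[t + 1:] * np.arange(t + 1, 256)).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v + 1e-9 * max(best_v, 1.0):
            best_t, best_v = t, v
    return best_t


class TestPreprocess:
    def test_sigma_zero_length_one_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (20, 30)).astype(np.uint8)
        assert np.array_equal(preprocess(img, 0.0, 1), img)

    def test_horizontal_dilation_spreads_a_point(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 200
        out = preprocess(img, 0.0, 5)
        assert (out[4] == 200).sum() == 5
        assert out[3].max() == 0 and out[5].max() == 0

    def test_matches_naive_convolve_then_sliding_max(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, (16, 40)).astype(np.uint8)
        out = preprocess(img, 1.2, 5)
        smooth = ndimage.gaussian_filter(img.astype(float), 1.2)
        naive = np.zeros_like(smooth)
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                lo, hi = max(0, c - 2), min(img.shape[1], c + 3)
                naive[r, c] = smooth[r, lo:hi].max()
        assert np.array_equal(out, np.clip(np.rint(naive), 0, 255)
                              .astype(np.uint8))

    def test_rejects_color_input(self):
        with pytest.raises(cf.ValidationError):
            preprocess(np.zeros((4, 4, 3), dtype=np.uint8), 1.0, 3)


class TestOtsu:
    def test_equals_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            hist = rng.integers(0, 50, 256)
            hist[rng.integers(0, 128)] += rng.integers(100, 1000)
            hist[rng.integers(128, 256)] += rng.integers(100, 1000)
            img = np.repeat(np.arange(256, dtype=np.uint8), hist)
            assert cf.otsu_threshold(img[None, :]) == exhaustive_otsu(hist)

    def test_agrees_with_skimage_between_modes(self):
        skfilters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(7)
        img = np.concatenate([
            np.clip(rng.normal(50, 8, 4000), 0, 255),
            np.clip(rng.normal(200, 8, 4000), 0, 255),
        ]).astype(np.uint8).reshape(80, 100)
        ours = cf.otsu_threshold(img)
        theirs = skfilters.threshold_otsu(img)
        assert 50 < ours < 200
        assert abs(ours - theirs) <= 1   # independent implementation check

    def test_half_black_half_white(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        t = cf.otsu_threshold(img)
        assert t == exhaustive_otsu(np.bincount(img.ravel(), minlength=256))
        assert 0 <= t < 255

    def test_constant_image_errors(self):
        with pytest.raises(cf.ValidationError):
            cf.otsu_threshold(np.full((5, 5), 7, dtype=np.uint8))


class TestBinarize:
    def test_offset_zero_selects_bright_class(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        t = cf.otsu_threshold(img)
        mask = cf.binarize(img, t, 0)
        assert np.array_equal(mask.astype(bool), img == 255)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 40), st.integers(1, 40))
    def test_mask_is_antitone_in_offset(self, seed, off_small, delta):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 255, (12, 12)).astype(np.uint8)
        off_big = min(off_small + delta, 155)
        m_small = cf.binarize(img, 100, off_small).astype(bool)
        m_big = cf.binarize(img, 100, off_big).astype(bool)
        assert not np.any(m_big & ~m_small)

    def test_out_of_range_effective_threshold(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(cf.ValidationError):
            cf.binarize(img, 250, 20)
        with pytest.raises(cf.ValidationError):
            cf.binarize(img, 5, -20)

    def test_negative_offset_recovers_faint_cycles(self):
        """A faint cycle missed at the Otsu level is recovered at -15."""
        spec = cf.default_strip_spec("baseline", seed=3, faint=(2,),
                                     faint_intensity=0.46, speckle_sd=2.0)
        strip, truth = cf.generate_strip(spec)
        thr = cf.otsu_threshold(strip.doppler)
        b0, b1 = truth.cycle_bounds[2], truth.cycle_bounds[3]
        faint_truth = truth.mask.astype(bool)[:, b0:b1]
        rec = {}
        for off in (0, -15):
            m = cf.binarize(strip.doppler, thr, off).astype(bool)[:, b0:b1]
            rec[off] = (m & faint_truth).sum() / faint_truth.sum()
        assert rec[-15] >= 0.99
        assert rec[0] < 0.5


def flood_fill_noise_oracle(mask, baseline_row, proximity):
    """Literal re-statement of the rule with an independent labeling."""
    skmeasure = pytest.importorskip("skimage.measure")
    labels = skmeasure.label(mask.astype(bool), connectivity=2)
    out = np.zeros_like(mask, dtype=bool)
    for lab in range(1, labels.max() + 1):
        rows = np.nonzero(labels == lab)[0]
        if np.abs(rows - baseline_row).min() <= proximity:
            out |= labels == lab
    return out


class TestRemoveNoise:
    def test_top_blob_removed_entirely(self):
        mask = np.zeros((200, 50), dtype=np.uint8)
        mask[0:20, 10:20] = 1            # top noise
        mask[170:180, 30:40] = 1         # envelope fragment at baseline
        out = cf.remove_noise(mask, baseline_row=180)
        assert out[0:20].sum() == 0
        assert np.array_equal(out[170:180, 30:40],
                              mask[170:180, 30:40])

    def test_component_touching_baseline_kept_whole(self):
        mask = np.zeros((100, 30), dtype=np.uint8)
        mask[10:90, 5:10] = 1   # tall object reaching the baseline band
        out = cf.remove_noise(mask, baseline_row=85)
        assert np.array_equal(out, mask)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((80, 120)) < 0.08).astype(np.uint8)
        mask[60:78, 20:90] = rng.random((18, 70)) < 0.7
        out = cf.remove_noise(mask, baseline_row=70, proximity_px=10)
        oracle = flood_fill_noise_oracle(mask, 70, 10)
        assert np.array_equal(out.astype(bool), oracle)

    def test_empty_mask_allowed(self):
        out = cf.remove_noise(np.zeros((10, 10), dtype=np.uint8), 5)
        assert out.sum() == 0


def border_flood_oracle(mask, max_area):
    """Fill oracle: label background from the border, fill small islands."""
    skmeasure = pytest.importorskip("skimage.measure")
    bg = skmeasure.label(~mask.astype(bool), connectivity=1)
    out = mask.astype(bool).copy()
    border_ids = set(bg[0]) | set(bg[-1]) | set(bg[:, 0]) | set(bg[:, -1])
    for lab in range(1, bg.max() + 1):
        if lab in border_ids:
            continue
        sel = bg == lab
        if sel.sum() <= max_area:
            out |= sel
    return out


class TestFillHoles:
    def test_small_hole_filled(self):
        mask = np.ones((10, 10), dtype=np.uint8)
        mask[4:7, 4:7] = 0
        out = cf.fill_holes(mask, max_hole_area_px=50)
        assert out.all()

    def test_large_hole_kept(self):
        mask = np.ones((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = 0
        out = cf.fill_holes(mask, max_hole_area_px=50)
        assert np.array_equal(out, mask)

    def test_border_connected_background_never_filled(self):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[3:7, 3:7] = 1
        out = cf.fill_holes(mask, max_hole_area_px=1000)
        assert np.array_equal(out, mask)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_border_flood_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = (rng.random((40, 60)) < 0.55).astype(np.uint8)
        out = cf.fill_holes(mask, max_hole_area_px=20)
        assert np.array_equal(out.astype(bool),
                              border_flood_oracle(mask, 20))


class TestExtractTrace:
    CAL = cf.Calibration(scale_max_v=500.0, ms_per_px=0.5, baseline_row=100)

    def test_top_pixel_at_baseline_is_zero(self):
        mask = np.zeros((120, 3), dtype=np.uint8)
        mask[100, 1] = 1
        tr = cf.extract_trace(mask, self.CAL)
        assert tr.v[1] == 0.0

    def test_top_pixel_at_row_zero_is_scale_max(self):
        mask = np.zeros((120, 3), dtype=np.uint8)
        mask[0:101, 1] = 1
        tr = cf.extract_trace(mask, self.CAL)
        assert tr.v[1] == pytest.approx(500.0)

    def test_empty_columns_are_zero_and_time_uniform(self):
        mask = np.zeros((120, 5), dtype=np.uint8)
        tr = cf.extract_trace(mask, self.CAL)
        assert np.all(tr.v == 0)
        assert np.allclose(np.diff(tr.t), 0.5)

    def test_traces_synthetic_strip_within_two_pixels(self, baseline_strip):
        """Extracted velocity within a 2-pixel band of the truth.

        Two pixels in both axes: smoothing and dilation may shift a steep
        envelope edge by a column or two, so each column is compared with
        the true velocity within +-2 neighboring columns.
        """
        _, strip, truth = baseline_strip
        cal = strip.calibration
        res = extract_envelope(strip.doppler, cal)
        v = res.trace.v
        errs = np.full(v.size, np.inf)
        for shift in range(-2, 3):
            shifted = np.roll(truth.velocity, shift)
            errs = np.minimum(errs, np.abs(v - shifted))
        assert errs.max() <= 2 * cal.v_per_row


def test_end_to_end_envelope_precision_and_recall(baseline_strip):
    _, strip, truth = baseline_strip
    res = extract_envelope(strip.doppler, strip.calibration)
    m, t = res.mask.astype(bool), truth.mask.astype(bool)
    tp = (m & t).sum()
    assert tp / m.sum() >= 0.95
    assert tp / t.sum() >= 0.95
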