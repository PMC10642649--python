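"""Filters and thresholds against independent per-pixel / brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mycofd.preprocess import (
    KuwaharaConfig,
    ThresholdMethod,
    binarize,
    compute_threshold,
    huang_threshold,
    kuwahara,
    line_offsets,
    sobel_magnitude,
)


# ---------------------------------------------------------------------------
# independent reference implementations (slow, per pixel)


def _kuwahara_classic_reference(img, window):
    """Direct evaluation: replicate-pad, scan the four quadrants per pixel."""
    q = (window + 1) // 2
    pad = np.pad(img.astype(float), q, mode="edge")
    H, W = img.shape
    out = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            best = None
            for dr, dc in [(-q + 1, -q + 1), (-q + 1, 0), (0, -q + 1), (0, 0)]:
                r0, c0 = i + q + dr, j + q + dc
                win = pad[r0 : r0 + q, c0 : c0 + q]
                m, v = win.mean(), win.var()
                if best is None or v < best[0] - 1e-12:
                    best = (v, m)
            out[i, j] = best[1]
    return np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)


def _kuwahara_linear_reference(img, length, n_orientations):
    pad_w = length // 2
    pad = np.pad(img.astype(float), pad_w, mode="edge")
    H, W = img.shape
    out = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            best = None
            for k in range(n_orientations):
                angle = k * math.pi / n_orientations
                vals = [
                    pad[i + pad_w + dy, j + pad_w + dx]
                    for dy, dx in line_offsets(length, angle)
                ]
                m, v = np.mean(vals), np.var(vals)
                if best is None or v < best[0] - 1e-12:
                    best = (v, m)
            out[i, j] = best[1]
    return np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)


def _huang_reference(hist):
    """Brute-force fuzziness scan written directly from the definition:
    for every candidate t compute both class means afresh, build the
    membership of every grey level, and sum the Shannon fuzziness."""
    hist = np.asarray(hist, dtype=float)
    g = np.arange(256, dtype=float)
    nz = np.flatnonzero(hist)
    gmin, gmax = int(nz[0]), int(nz[-1])
    C = float(gmax - gmin)
    best_t, best_s = None, None
    for t in range(gmin, gmax):
        m0 = np.average(g[gmin : t + 1], weights=hist[gmin : t + 1])
        m1 = np.average(g[t + 1 : gmax + 1], weights=hist[t + 1 : gmax + 1])
        centre = np.where(g <= t, m0, m1)
        mu = 1.0 / (1.0 + np.abs(g - centre) / C)
        ent = -mu * np.log(mu)
        anti = 1.0 - mu
        ent[anti > 0] -= anti[anti > 0] * np.log(anti[anti > 0])
        s = float(np.dot(hist[gmin : gmax + 1], ent[gmin : gmax + 1]))
        if best_s is None or s < best_s - 1e-12:
            best_s, best_t = s, t
    return best_t


def _otsu_reference(hist):
    """Smallest t maximising between-class variance (class 1 = g <= t)."""
    total = sum(hist)
    mean_all = sum(g * h for g, h in enumerate(hist)) / total
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = sum(hist[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(g * hist[g] for g in range(t + 1)) / w0
        m1 = (total * mean_all - w0 * m0) / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v + 1e-9:
            best_v, best_t = v, t
    return best_t


# ---------------------------------------------------------------------------
# Kuwahara


class TestKuwahara:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 77, dtype=np.uint8)
        for variant in ("classic", "linear"):
            assert np.array_equal(kuwahara(img, KuwaharaConfig(variant, 5, 8)), img)

    def test_linear_preserves_step_edge_exactly(self, step_image):
        out = kuwahara(step_image, KuwaharaConfig("linear", 5, 8))
        assert set(np.unique(out)) <= {0, 255}  # no intermediate values created
        assert np.array_equal(out, step_image)

    def test_linear_matches_per_pixel_reference_on_step(self, step_image):
        ref = _kuwahara_linear_reference(step_image, 5, 8)
        out = kuwahara(step_image, KuwaharaConfig("linear", 5, 8))
        assert np.array_equal(out, ref)

    def test_classic_matches_per_pixel_reference_on_step(self, step_image):
        ref = _kuwahara_classic_reference(step_image, 5)
        out = kuwahara(step_image, KuwaharaConfig("classic", 5))
        assert np.array_equal(out, ref)

    def test_classic_single_bright_pixel_takes_min_variance_quadrant_mean(self):
        # hand evaluation: 16x16 zeros with one 90 at (8, 8); for pixel (5, 5)
        # the NW quadrant (rows/cols 3..5) is all zero -> output 0 there;
        # at the bright pixel itself every quadrant contains it once, so the
        # minimum-variance quadrant mean is 90/9 = 10.
        img = np.zeros((16, 16), dtype=np.uint8)
        img[8, 8] = 90
        out = kuwahara(img, KuwaharaConfig("classic", 5))
        assert out[5, 5] == 0
        assert out[8, 8] == 10
        ref = _kuwahara_classic_reference(img, 5)
        assert np.array_equal(out, ref)

    def test_output_within_input_range(self, rng):
        img = rng.integers(40, 200, (40, 40), dtype=np.uint8)
        for variant in ("classic", "linear"):
            out = kuwahara(img, KuwaharaConfig(variant, 5, 8))
            assert out.min() >= img.min() and out.max() <= img.max()

    def test_idempotent_on_two_region_image(self):
        img = np.zeros((24, 24), dtype=np.uint8)
        img[:, 12:] = 200
        for variant in ("classic", "linear"):
            once = kuwahara(img, KuwaharaConfig(variant, 5, 8))
            twice = kuwahara(once, KuwaharaConfig(variant, 5, 8))
            assert np.array_equal(once, twice)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            kuwahara(np.zeros((4, 4), dtype=np.uint8), KuwaharaConfig("classic", 5))

    @pytest.mark.parametrize("variant, window, n_orient", [
        ("classic", 4, 8), ("classic", 1, 8), ("linear", 5, 2), ("median", 5, 8),
    ])
    def test_invalid_config_rejected(self, variant, window, n_orient):
        with pytest.raises(ValueError):
            KuwaharaConfig(variant, window, n_orient).validate()


# ---------------------------------------------------------------------------
# Sobel


class TestSobel:
    def test_constant_image_gives_zero(self):
        assert np.all(sobel_magnitude(np.full((10, 10), 99, dtype=np.uint8)) == 0)

    def test_step_magnitude_is_4x_contrast_at_flanking_columns(self):
        # hand convolution: smoothing [1,2,1] x derivative [-1,0,1] on a step
        # a->b gives 4|b-a| in the two columns next to the edge
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 50
        out = sobel_magnitude(img)
        assert np.all(out[:, 4] == 200) and np.all(out[:, 5] == 200)
        assert np.all(out[:, :4] == 0) and np.all(out[:, 6:] == 0)

    def test_rotation_equivariance(self, rng):
        img = rng.integers(0, 60, (16, 16), dtype=np.uint8)  # low contrast: no clipping
        assert np.array_equal(sobel_magnitude(np.rot90(img)), np.rot90(sobel_magnitude(img)))

    def test_intensity_offset_invariance(self, rng):
        img = rng.integers(0, 50, (16, 16), dtype=np.uint8)
        assert np.array_equal(sobel_magnitude(img), sobel_magnitude(img + 20))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            sobel_magnitude(np.zeros((2, 5), dtype=np.uint8))


# ---------------------------------------------------------------------------
# thresholds


class TestThresholds:
    def test_fixed_value_passthrough(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        assert compute_threshold(img, ThresholdMethod("fixed", 128)) == 128

    def test_otsu_on_two_valued_image_matches_brute_force(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:, 5:] = 255
        t = compute_threshold(img, ThresholdMethod("otsu"))
        hist = np.bincount(img.ravel(), minlength=256).tolist()
        assert t == _otsu_reference(hist)
        mask = binarize(img, t)
        assert mask.sum() == 50  # separates the classes

    def test_huang_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(200):
            hist = np.zeros(256)
            n_modes = rng.integers(1, 4)
            for _ in range(n_modes):
                c = rng.integers(10, 246)
                w = rng.integers(3, 30)
                g = np.arange(256)
                hist += rng.integers(50, 500) * np.exp(-0.5 * ((g - c) / w) ** 2)
            hist = np.floor(hist)
            if np.count_nonzero(hist) < 2:
                continue
            assert huang_threshold(hist) == _huang_reference(hist)

    def test_huang_on_image_equals_histogram_result(self, rng):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        hist = np.bincount(img.ravel(), minlength=256)
        assert compute_threshold(img, ThresholdMethod("huang")) == huang_threshold(hist)

    @pytest.mark.parametrize("name", ["isodata", "otsu", "huang"])
    def test_constant_image_rejected_for_automatic_methods(self, name):
        img = np.full((10, 10), 42, dtype=np.uint8)
        with pytest.raises(ValueError, match="degenerate histogram"):
            compute_threshold(img, ThresholdMethod(name))

    def test_fixed_requires_value(self):
        with pytest.raises(ValueError, match="fixed_value"):
            ThresholdMethod("fixed").validate()


class TestBinarize:
    def test_threshold_255_gives_empty_mask(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        assert not binarize(img, 255).any()

    def test_threshold_0_on_positive_image_gives_full_mask(self):
        img = np.full((8, 8), 1, dtype=np.uint8)
        assert binarize(img, 0).all()

    def test_ramp_at_127_selects_upper_half(self):
        ramp = np.arange(256, dtype=np.uint8).reshape(16, 16)
        mask = binarize(ramp, 127)
        assert mask.sum() == 128
        assert np.array_equal(np.sort(ramp[mask]), np.arange(128, 256))

    def test_below_is_fg_is_complement(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        assert np.array_equal(binarize(img, 100, "below_is_fg"), ~binarize(img, 100))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 255))
    def test_partition_property(self, t):
        ramp = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert binarize(ramp, t).sum() == 255 - t
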