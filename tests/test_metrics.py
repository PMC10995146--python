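"""Tests for the four fusion-quality indexes and phase congruency."""

import numpy as np
import pytest

from dmif.metrics import (
    HistogramSpec,
    entropy,
    log_gabor_bank,
    metric_report,
    mutual_information,
    phase_congruency,
    q_mi,
    q_pc,
    std_dev,
)


def brute_force_mi(a, b, bins=256, lo=0.0, hi=255.0):
    """Joint-histogram mutual information via explicit binning loops."""
    scale = bins / (hi - lo)
    joint = np.zeros((bins, bins))
    for x, y in zip(a.ravel(), b.ravel()):
        i = min(int((x - lo) * scale), bins - 1)
        j = min(int((y - lo) * scale), bins - 1)
        joint[i, j] += 1
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if pxy[i, j] > 0:
                mi += pxy[i, j] * np.log2(pxy[i, j] / (px[i] * py[j]))
    return mi


class TestStdDev:
    def test_constant_image_has_zero_sd(self):
        assert std_dev(np.full((16, 16), 42.0)) == 0.0

    def test_two_point_distribution(self):
        img = np.zeros((16, 16))
        img[:8] = 255.0
        assert std_dev(img) == pytest.approx(127.5)

    def test_matches_two_pass_formula(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        mean = img.sum() / img.size
        var = ((img - mean) ** 2).sum() / img.size
        assert std_dev(img) == pytest.approx(np.sqrt(var), rel=1e-12)


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert entropy(np.full((16, 16), 7.0)) == 0.0

    def test_uniform_256_levels_is_8_bits(self):
        img = np.tile(np.arange(256.0), (256, 1))
        assert entropy(img) == pytest.approx(8.0)

    def test_two_equal_levels_is_1_bit(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        assert entropy(img) == pytest.approx(1.0)

    def test_bounded_by_log2_bins(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        assert 0.0 <= entropy(img) <= 8.0


class TestMutualInformation:
    def test_self_information_equals_entropy(self, rng):
        a = rng.uniform(0, 255, (32, 32))
        assert mutual_information(a, a) == pytest.approx(entropy(a), rel=1e-10)

    def test_degenerate_marginal_gives_zero(self, rng):
        a = np.full((16, 16), 100.0)
        b = rng.uniform(0, 255, (16, 16))
        assert mutual_information(a, b) == 0.0

    def test_symmetric_and_nonnegative(self, rng):
        a = rng.uniform(0, 255, (16, 16))
        b = rng.uniform(0, 255, (16, 16))
        mab = mutual_information(a, b)
        assert mab == pytest.approx(mutual_information(b, a), rel=1e-12)
        assert mab >= 0.0

    def test_matches_brute_force_oracle_small_bins(self, rng):
        spec = HistogramSpec(bins=16)
        a = rng.uniform(0, 255, (12, 12))
        b = rng.uniform(0, 255, (12, 12))
        assert mutual_information(a, b, spec) == pytest.approx(
            brute_force_mi(a, b, bins=16), rel=1e-9
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros((8, 8)), np.zeros((8, 9)))


class TestQMI:
    def test_perfect_transfer_scores_two(self, rng):
        a = rng.uniform(0, 255, (32, 32))
        assert q_mi(a, a, a) == pytest.approx(2.0, abs=1e-9)

    def test_independent_noise_scores_at_bias_floor(self):
        # With a 256x256-bin joint histogram and 256*256 samples, MI of
        # independent images does not vanish: the Miller-Madow
        # finite-sample bias is ~ (bins-1)^2 / (2 N ln 2) bits.  Q_MI of
        # unrelated noise must sit at this floor, far below fused-image
        # scores, and must shrink when the bias does (coarser bins).
        gen = np.random.default_rng(99)
        a = gen.uniform(0, 255, (256, 256))
        b = gen.uniform(0, 255, (256, 256))
        f = gen.uniform(0, 255, (256, 256))
        bias = 255**2 / (2 * a.size * np.log(2))
        floor = 2 * (bias / (entropy(a) + entropy(f)) + bias / (entropy(b) + entropy(f)))
        assert q_mi(a, b, f) <= 1.5 * floor
        coarse = HistogramSpec(bins=16)
        assert q_mi(a, b, f, coarse) <= 0.05

    def test_source_order_symmetry(self, rng):
        a = rng.uniform(0, 255, (16, 16))
        b = rng.uniform(0, 255, (16, 16))
        f = 0.5 * a + 0.5 * b
        assert q_mi(a, b, f) == pytest.approx(q_mi(b, a, f), rel=1e-12)

    def test_matches_own_component_composition(self, rng):
        a = rng.uniform(0, 255, (16, 16))
        b = rng.uniform(0, 255, (16, 16))
        f = np.maximum(a, b)
        expect = 2.0 * (
            mutual_information(a, f) / (entropy(a) + entropy(f))
            + mutual_information(b, f) / (entropy(b) + entropy(f))
        )
        assert q_mi(a, b, f) == pytest.approx(expect, rel=1e-12)

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 255, (24, 24))
            b = rng.uniform(0, 255, (24, 24))
            f = 0.5 * a + 0.5 * b
            assert 0.0 <= q_mi(a, b, f) <= 2.0


class TestPhaseCongruency:
    def test_constant_image_has_no_congruency(self):
        maps = phase_congruency(np.full((64, 64), 120.0))
        assert maps.pc.max() <= 1e-3

    def test_step_edge_peaks_at_edge_column(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 200.0
        maps = phase_congruency(img)
        # away from the wrap-around border, each row peaks at the edge
        for row in range(8, 56):
            assert abs(int(np.argmax(maps.pc[row])) - 32) <= 1

    def test_maps_bounded_and_moments_ordered(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        maps = phase_congruency(img)
        assert np.all(maps.pc >= 0.0) and np.all(maps.pc <= 1.0)
        assert np.all(maps.min_moment >= 0.0)
        assert np.all(maps.min_moment <= maps.max_moment + 1e-12)

    def test_frequency_filtering_matches_spatial_convolution(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        bank = log_gabor_bank((64, 64))
        filt = bank[2, 1]
        freq_resp = np.fft.ifft2(np.fft.fft2(img) * filt)
        kernel = np.fft.ifft2(filt)
        spatial = np.zeros((64, 64), dtype=complex)
        for u in range(64):
            for v in range(64):
                spatial += img[u, v] * np.roll(np.roll(kernel, u, axis=0), v, axis=1)
        assert np.abs(freq_resp - spatial).max() <= 1e-6

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            phase_congruency(np.zeros((8, 64)))


class TestQPC:
    def test_identical_triple_scores_one(self, rng):
        a = rng.uniform(0, 255, (64, 64))
        assert q_pc(a, a, a) == pytest.approx(1.0, abs=1e-9)

    def test_constant_fused_scores_zero_with_warning(self, rng):
        a = rng.uniform(0, 255, (64, 64))
        b = rng.uniform(0, 255, (64, 64))
        f = np.full((64, 64), 100.0)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            assert q_pc(a, b, f) == 0.0

    def test_source_order_symmetry(self, rng):
        a = rng.uniform(0, 255, (64, 64))
        b = rng.uniform(0, 255, (64, 64))
        f = 0.5 * a + 0.5 * b
        assert q_pc(a, b, f) == pytest.approx(q_pc(b, a, f), rel=1e-12)

    def test_noise_monotonically_degrades_score(self, ct_mri_64):
        a, b = ct_mri_64
        f = 0.5 * a + 0.5 * b
        means = []
        for amplitude in (0.0, 8.0, 25.0):
            scores = []
            for seed in range(10):
                noise = amplitude * np.random.default_rng(seed).standard_normal(f.shape)
                scores.append(q_pc(a, b, np.clip(f + noise, 0, 255)))
            means.append(np.mean(scores))
        assert means[0] > means[1] > means[2]


class TestMetricReport:
    def test_report_on_color_inputs_uses_luma(self, rng):
        a = rng.uniform(0, 255, (64, 64))
        f_rgb = np.repeat(rng.uniform(0, 255, (64, 64))[..., None], 3, axis=2)
        rep = metric_report(a, a, f_rgb)
        assert set(rep.as_dict()) == {"SD", "EN", "Q_MI", "Q_PC"}
        assert rep.sd == pytest.approx(std_dev(f_rgb[..., 0]), rel=1e-9)
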