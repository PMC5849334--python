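import numpy as np
import pytest

from nmrpeaks.cwt_peaks import (
    CWTConfigError,
    CWTParams,
    cwt_transform,
    detect_peaks_vector,
    find_ridges,
    ricker_kernel,
)


def gaussian_bump(p=512, center=256, sigma=4.0, height=1.0):
    x = np.arange(p)
    return height * np.exp(-((x - center) ** 2) / (2 * sigma**2))


class TestTransform:
    def test_zero_signal_gives_zero_coefficients(self):
        coefs = cwt_transform(np.zeros(256), scales=(1, 2, 4))
        np.testing.assert_array_equal(coefs, 0.0)

    def test_linearity_in_signal_amplitude(self):
        x = gaussian_bump()
        a = cwt_transform(x, scales=(2, 4, 8))
        b = cwt_transform(3.5 * x, scales=(2, 4, 8))
        np.testing.assert_allclose(b, 3.5 * a, rtol=1e-12, atol=1e-300)

    def test_matches_direct_convolution_oracle(self):
        """Each row equals a brute-force reflect-padded convolution."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        scales = (2, 5, 9)
        coefs = cwt_transform(x, scales)
        for k, s in enumerate(scales):
            kern = ricker_kernel(s, max_len=x.size)
            half = (kern.size - 1) // 2
            # edge-repeating reflection: (c b a | a b c ... | c b a)
            padded = np.concatenate([x[half - 1 :: -1], x, x[-1 : -half - 1 : -1]])
            expect = np.convolve(padded, kern[::-1], mode="valid")
            np.testing.assert_allclose(coefs[k], expect, atol=1e-10)

    def test_gaussian_bump_maximum_at_apex_and_matching_scale(self):
        sigma = 4.0
        x = gaussian_bump(sigma=sigma)
        scales = tuple(range(1, 13))
        coefs = cwt_transform(x, scales)
        srow, col = np.unravel_index(coefs.argmax(), coefs.shape)
        assert abs(col - 256) <= 1
        # for a unit-L2 Mexican hat the response to a Gaussian of width sigma
        # is ~ a^(5/2) / (a^2 + sigma^2)^(3/2), maximal at a = sqrt(5)*sigma
        assert abs(scales[srow] - np.sqrt(5) * sigma) <= 2

    def test_too_short_signal_rejected(self):
        with pytest.raises(CWTConfigError, match="scale"):
            cwt_transform(np.zeros(10), scales=(8,))

    def test_empty_scales_rejected(self):
        with pytest.raises(CWTConfigError):
            cwt_transform(np.zeros(100), scales=())


def brute_force_ridges(coefs, scales, window_factor=2.0):
    """Independent chain search: from each global-to-local maximum at the
    largest scale, follow the nearest local maximum down the scales."""
    chains = []
    rows = []
    for k in range(len(scales)):
        r = coefs[k]
        rows.append(
            [i for i in range(1, len(r) - 1) if r[i] > r[i - 1] and r[i] >= r[i + 1] and r[i] > 0]
        )
    top = len(scales) - 1
    for start in rows[top]:
        chain = {top: start}
        col = start
        for k in range(top - 1, -1, -1):
            cands = [c for c in rows[k] if abs(c - col) <= max(2, window_factor * scales[k])]
            if not cands:
                break
            col = min(cands, key=lambda c: abs(c - col))
            chain[k] = col
        chains.append(chain)
    return chains


class TestRidges:
    def test_zero_matrix_gives_no_ridges(self):
        assert find_ridges(np.zeros((4, 100)), scales=(1, 2, 3, 4)) == []

    def test_single_peak_single_ridge_matches_chain_oracle(self):
        x = gaussian_bump(p=256, center=128, sigma=3)
        scales = tuple(range(1, 9))
        coefs = cwt_transform(x, scales)
        ridges = find_ridges(coefs, scales, ridge_length_min=4)
        assert len(ridges) == 1
        assert abs(ridges[0].max_col - 128) <= 1
        oracle = brute_force_ridges(coefs, scales)
        assert len(oracle) == 1
        best = max(oracle[0].items(), key=lambda kv: coefs[kv[0], kv[1]])
        assert abs(best[1] - ridges[0].max_col) <= 1

    def test_two_separated_peaks_two_ridges(self):
        sigma = 3
        x = gaussian_bump(p=512, center=150, sigma=sigma) + gaussian_bump(
            p=512, center=150 + 25 * sigma, sigma=sigma
        )
        scales = tuple(range(1, 9))
        ridges = find_ridges(cwt_transform(x, scales), scales, ridge_length_min=4)
        assert sorted(abs(r.max_col - c) <= 1 for r in ridges for c in (150, 225)).count(True) == 2
        assert len(ridges) == 2


class TestDetect:
    def test_flat_spectrum_no_peaks(self):
        assert detect_peaks_vector(np.zeros(2048), CWTParams(baseline_threshold=0)) == []

    def test_planted_peaks_recovered_without_extras(self, rng):
        """10 peaks >= 10x noise sigma: all found within +-2, nothing else."""
        p = 4096
        noise_sd = 50.0
        centers = np.arange(300, 4000, 380)[:10]
        x = rng.normal(0, noise_sd, p)
        for c in centers:
            x += gaussian_bump(p, c, sigma=4.0, height=5000.0)
        params = CWTParams(baseline_threshold=1000.0)
        peaks = detect_peaks_vector(x, params)
        found = np.array([pk.peak_index for pk in peaks])
        for c in centers:
            assert np.abs(found - c).min() <= 2
        for pk in peaks:
            assert np.abs(centers - pk.peak_index).min() <= 3 * pk.scale

    def test_baseline_threshold_filters_small_apexes(self, rng):
        p = 4096
        heights = np.array([200, 300, 400, 500, 600, 5000, 6000, 7000, 8000, 9000.0])
        centers = np.arange(300, 4000, 380)[:10]
        x = rng.normal(0, 10.0, p)
        for c, h in zip(centers, heights):
            x += gaussian_bump(p, c, sigma=4.0, height=h)
        peaks = detect_peaks_vector(x, CWTParams(baseline_threshold=1000.0))
        found = np.array([pk.peak_index for pk in peaks])
        tall = centers[heights > 1000]
        assert len(found) == len(tall)
        for c in tall:
            assert np.abs(found - c).min() <= 2

    def test_smooth_baseline_barely_perturbs_detection(self, rng):
        """A slowly varying baseline moves no index by more than 1 and no
        peak value by more than 5 %."""
        p = 4096
        centers = np.arange(400, 3900, 500)
        x = rng.normal(0, 20.0, p)
        for c in centers:
            x += gaussian_bump(p, c, sigma=4.0, height=5000.0)
        t = np.linspace(-1, 1, p)
        baseline = 2000.0 * (0.5 + 0.3 * t + 0.4 * t**2)
        params = CWTParams(baseline_threshold=0.0)
        a = {pk.peak_index: pk.peak_value for pk in detect_peaks_vector(x, params)}
        b = {pk.peak_index: pk.peak_value for pk in detect_peaks_vector(x + baseline, params)}
        for c in centers:
            ia = min(a, key=lambda i: abs(i - c))
            ib = min(b, key=lambda i: abs(i - c))
            assert abs(ia - ib) <= 1
            assert abs(a[ia] - b[ib]) <= 0.05 * a[ia]

    @pytest.mark.parametrize("knob", ["baseline_threshold", "snr_threshold"])
    def test_detection_count_non_increasing_in_thresholds(self, rng, knob):
        p = 4096
        x = rng.normal(0, 50.0, p)
        for c in np.arange(300, 4000, 380):
            x += gaussian_bump(p, c, sigma=4.0, height=rng.uniform(500, 8000))
        counts = [
            len(detect_peaks_vector(x, CWTParams(**{knob: v})))
            for v in (0.0, 1.0, 3.0, 10.0, 1e6)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_pure_noise_yields_no_detections(self, rng):
        x = rng.normal(0, 100.0, 10000)
        peaks = detect_peaks_vector(x, CWTParams(baseline_threshold=0.0, snr_threshold=3.0))
        assert len(peaks) < 1 + 10000 // 10000  # < 1 per 10k points, i.e. none here
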