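"""Feature extractors vs. independent brute-force oracles, and the
1044-feature count contract."""

import numpy as np
import pytest

import seedxray as sx
from seedxray.features import (
    FeatureBankConfig,
    extract_all,
    extract_contrast,
    extract_gabor,
    extract_haralick,
    extract_intensity,
    extract_local_fft,
    extract_lbp,
)
from seedxray.features.config import FAMILY_COUNTS, ConfigurationError
from seedxray.features.gabor import gabor_responses
from seedxray.features.haralick import haralick_statistics, masked_glcm, quantize_masked
from seedxray.features.lbp import LBP_EPS, lbp_histogram
from seedxray.preprocess import compute_mask, enhance_sets


# ---------------------------------------------------------------- oracles
def brute_force_lbp_histogram(image, radius):
    """Independent per-pixel LBP: explicit neighbor loop, manual bilinear
    interpolation, explicit uniform-pattern ranking."""
    h, w = image.shape

    def interp(y, x):
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        wy, wx = y - y0, x - x0
        y0 = min(max(y0, 0), h - 1)
        x0 = min(max(x0, 0), w - 1)
        y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
        return ((1 - wy) * (1 - wx) * image[y0, x0] + (1 - wy) * wx * image[y0, x1]
                + wy * (1 - wx) * image[y1, x0] + wy * wx * image[y1, x1])

    uniform = []
    for p in range(256):
        bits = [(p >> k) & 1 for k in range(8)]
        if sum(bits[k] != bits[(k + 1) % 8] for k in range(8)) <= 2:
            uniform.append(p)
    rank = {p: i for i, p in enumerate(uniform)}

    counts = np.zeros(59)
    for i in range(radius, h - radius):
        for j in range(radius, w - radius):
            pattern = 0
            for k in range(8):
                ang = 2 * np.pi * k / 8
                val = interp(i - radius * np.sin(ang), j + radius * np.cos(ang))
                if val - image[i, j] > LBP_EPS:
                    pattern |= 1 << k
            counts[rank.get(pattern, 58)] += 1
    return counts / counts.sum()


def brute_force_glcm(quantized, offset):
    """Co-occurrence counts by explicit loops; symmetric; background (0)
    pairs excluded; normalized."""
    dy, dx = offset
    levels = quantized.max()
    counts = np.zeros((levels, levels))
    h, w = quantized.shape
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dy, j + dx
            if 0 <= i2 < h and 0 <= j2 < w:
                a, b = quantized[i, j], quantized[i2, j2]
                if a > 0 and b > 0:
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    return counts / counts.sum()


def brute_force_moments(pixels):
    n = len(pixels)
    mean = sum(pixels) / n
    var = sum((p - mean) ** 2 for p in pixels) / n
    sd = var**0.5
    skew = sum((p - mean) ** 3 for p in pixels) / n / sd**3 if sd > 0 else 0.0
    kurt = sum((p - mean) ** 4 for p in pixels) / n / sd**4 - 3 if sd > 0 else 0.0
    return mean, sd, skew, kurt, min(pixels), max(pixels)


# ------------------------------------------------------------- intensity
class TestIntensity:
    def test_constant_region(self):
        img = np.full((20, 20), 0.4)
        mask = np.ones((20, 20), bool)
        vals = extract_intensity(img, mask)
        assert vals == pytest.approx([0.4, 0.0, 0.0, 0.0, 0.4, 0.4])

    def test_symmetric_binary_region(self):
        img = np.array([[0.0, 1.0] * 5] * 4)
        vals = extract_intensity(img, np.ones_like(img, bool))
        assert vals[0] == pytest.approx(0.5)
        assert vals[2] == pytest.approx(0.0)  # skewness of a symmetric set

    def test_matches_brute_force_on_synthetic_seed(self, single_seed):
        rad, truth = single_seed
        vals = extract_intensity(rad.pixels, truth.seed_mask)
        expected = brute_force_moments(list(rad.pixels[truth.seed_mask]))
        assert vals == pytest.approx(expected, rel=1e-9)


# ------------------------------------------------------------------- lbp
class TestLBP:
    def test_constant_image_all_zero_code(self):
        img = np.full((16, 16), 0.5)
        vals = extract_lbp(img, np.ones_like(img, bool))
        assert vals[0] == pytest.approx(1.0)  # radius-1 all-zeros uniform bin
        assert vals[-2] == pytest.approx(1.0)  # pooled energy
        assert vals[-1] == pytest.approx(0.0)  # pooled entropy

    @pytest.mark.parametrize("radius", [1, 2, 3, 4])
    def test_histograms_normalized(self, single_seed, radius):
        rad, truth = single_seed
        hist = lbp_histogram(rad.pixels, truth.seed_mask, radius)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 10, (8, 8)) / 10.0
        got = lbp_histogram(img, np.ones_like(img, bool), radius=1)
        expected = brute_force_lbp_histogram(img, radius=1)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_larger_radius_matches_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 8, (12, 12)) / 8.0
        got = lbp_histogram(img, np.ones_like(img, bool), radius=2)
        expected = brute_force_lbp_histogram(img, radius=2)
        assert got == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------------- gabor
class TestGabor:
    def test_zero_image_all_zero(self):
        img = np.zeros((64, 64))
        vals = extract_gabor(img, np.ones_like(img, bool))
        assert vals.shape == (67,)
        assert np.allclose(vals, 0.0)

    def test_grating_peaks_at_matching_orientation(self):
        config = FeatureBankConfig()
        freq = config.gabor_frequencies[1]
        target = 3  # bank orientation index
        theta = np.pi * target / config.gabor_n_orientations
        yy, xx = np.mgrid[0:96, 0:96]
        # grating with wavevector along the filter's modulation direction
        phase = 2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta))
        img = 0.5 + 0.5 * np.cos(phase)
        responses = gabor_responses(img, config.gabor_frequencies, 8)
        interior = np.zeros((96, 96), bool)
        interior[24:-24, 24:-24] = True
        energies = [np.abs(r[interior]).mean() for r in responses]
        best = int(np.argmax(energies))
        assert best == 1 * 8 + target  # frequency row 1, orientation column 3

    def test_output_length(self, single_seed):
        rad, truth = single_seed
        assert extract_gabor(rad.pixels, truth.seed_mask).shape == (67,)


# -------------------------------------------------------------- contrast
class TestContrast:
    def test_flat_image_all_zero(self):
        img = np.full((30, 30), 0.4)
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        assert extract_contrast(img, mask) == pytest.approx([0.0] * 5)

    def test_full_range_region(self):
        img = np.zeros((10, 10))
        img[0, 0] = 1.0
        vals = extract_contrast(img, np.ones_like(img, bool))
        assert vals[0] == pytest.approx(1.0)  # Michelson
        assert vals[3] == pytest.approx(1.0)  # range

    def test_rms_equals_sd_oracle(self, single_seed):
        rad, truth = single_seed
        vals = extract_contrast(rad.pixels, truth.seed_mask)
        _, sd, *_ = brute_force_moments(list(rad.pixels[truth.seed_mask]))
        assert vals[1] == pytest.approx(sd, rel=1e-9)


# -------------------------------------------------------------- haralick
class TestHaralick:
    def test_constant_region(self):
        img = np.full((20, 20), 0.6)
        vals = extract_haralick(img, np.ones_like(img, bool))
        names_idx = {"ASM": 0, "Contrast": 1}
        assert vals[names_idx["Contrast"]] == pytest.approx(0.0)
        assert vals[names_idx["ASM"]] == pytest.approx(1.0)

    def test_stripe_contrast_matches_hand_enumeration(self):
        img = np.tile([0.0, 1.0], (6, 3))  # 6x6 vertical stripes
        mask = np.ones_like(img, bool)
        glcm = masked_glcm(img, mask, levels=32)
        # offset 0 degrees = horizontal neighbors: every pair spans the two
        # extreme quantization levels (1 and 32), so contrast = (32-1)^2
        stats = haralick_statistics(glcm[:, :, 0])
        assert stats[1] == pytest.approx(31.0**2)

    def test_glcm_matches_brute_force_counts(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(size=(6, 6))
        mask = rng.uniform(size=(6, 6)) > 0.2
        q = quantize_masked(img, mask, levels=4)
        got = masked_glcm(img, mask, levels=4)
        # angle a pairs (r, c) with (r + round(d sin a), c + round(d cos a))
        offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
        for a, off in offsets.items():
            expected = brute_force_glcm(q, off)
            assert got[:, :, a] == pytest.approx(expected, abs=1e-12)

    def test_rotation_permutes_offset_statistics(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(size=(16, 16))
        mask = np.ones((16, 16), bool)
        orig = masked_glcm(img, mask)
        rot = masked_glcm(np.rot90(img), mask)
        orig_stats = np.stack([haralick_statistics(orig[:, :, a]) for a in range(4)])
        rot_stats = np.stack([haralick_statistics(rot[:, :, a]) for a in range(4)])
        assert np.allclose(np.sort(orig_stats, axis=0), np.sort(rot_stats, axis=0), atol=1e-9)

    def test_output_length(self, single_seed):
        rad, truth = single_seed
        assert extract_haralick(rad.pixels, truth.seed_mask).shape == (28,)


# ------------------------------------------------------------------- fft
class TestLocalFFT:
    def test_constant_image_no_off_dc_energy(self):
        img = np.full((64, 64), 0.7)
        vals = extract_local_fft(img, np.ones_like(img, bool))
        assert np.allclose(vals[:4], 0.0)

    def test_grating_energy_in_matching_band(self):
        freq = 0.2  # cycles/pixel -> second band (0.125, 0.25]
        xx = np.arange(128)
        img = 0.5 + 0.4 * np.cos(2 * np.pi * freq * xx)[None, :] * np.ones((128, 1))
        vals = extract_local_fft(img, np.ones((128, 128), bool))
        assert int(np.argmax(vals[:4])) == 1
        assert vals[1] > 0.9

    def test_output_length(self, single_seed):
        rad, truth = single_seed
        assert extract_local_fft(rad.pixels, truth.seed_mask).shape == (8,)


# ----------------------------------------------------------- full vector
class TestExtractAll:
    def test_count_contract(self, single_seed):
        rad, _ = single_seed
        triplet = enhance_sets(rad)
        mask = compute_mask(triplet.set_A)
        fv = extract_all(triplet, mask, seed_id=rad.seed_id)
        assert len(fv.names) == len(fv.values) == 1044
        for letter in "ABC":
            assert sum(n.endswith(f"[{letter}]") for n in fv.names) == 348
        config = FeatureBankConfig()
        assert config.family_counts() == FAMILY_COUNTS

    def test_names_unique_and_parseable(self, single_seed):
        rad, _ = single_seed
        triplet = enhance_sets(rad)
        mask = compute_mask(triplet.set_A)
        fv = extract_all(triplet, mask)
        assert len(set(fv.names)) == 1044
        families = [sx.parse_feature_name(n)[0] for n in fv.names]
        for family, count in FAMILY_COUNTS.items():
            assert families.count(family) == 3 * count

    def test_reextraction_bit_identical(self, single_seed):
        rad, _ = single_seed
        triplet = enhance_sets(rad)
        mask = compute_mask(triplet.set_A)
        a = extract_all(triplet, mask)
        b = extract_all(triplet, mask)
        assert np.array_equal(a.values, b.values)
        assert a.names == b.names

    def test_bad_family_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            FeatureBankConfig(lbp_radii=(1, 2, 3))
        with pytest.raises(ConfigurationError):
            FeatureBankConfig(gabor_frequencies=(0.1, 0.2))
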