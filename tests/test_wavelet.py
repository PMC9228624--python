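"""Multiresolution decomposition, band reconstruction, scale selection."""

import math
import warnings

import numpy as np
import pytest

from dwdc import (BandSelection, WaveletBandExtractor,
                  characteristic_band_for_width, decompose, reconstruct,
                  reconstruct_band)
from dwdc.errors import ParameterError


def _rel_err(a, b):
    return np.abs(a - b).max() / max(np.abs(b).max(), 1e-300)


class TestDecompose:
    @pytest.mark.parametrize("wavelet", ["coif3", "db4", "haar", "sym5"])
    def test_perfect_reconstruction_round_trip(self, rng, wavelet):
        img = rng.uniform(0, 255, (128, 128))
        dec = decompose(img, wavelet, max_level=4)
        assert _rel_err(reconstruct(dec), img) < 1e-8

    def test_constant_image_lives_in_approximation(self):
        img = np.full((64, 64), 37.0)
        dec = decompose(img, "coif3", max_level=3)
        for trio in dec.details.values():
            for coeff in trio:
                assert np.abs(coeff).max() < 1e-9 * 37.0
        assert dec.approximation.mean() == pytest.approx(8 * 37.0, rel=1e-6)

    def test_pyramid_shapes_at_level_six(self):
        img = np.zeros((2048, 2048))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = decompose(img, "coif3", max_level=6)
        side = dec.details[6][0].shape[0]
        # ~2048 / 2^6 = 32 plus the symmetric-extension filter margin
        assert 32 <= side <= 32 + 2 * 18
        assert dec.details[1][0].shape[0] >= 1024

    def test_unknown_wavelet_lists_supported_families(self):
        with pytest.raises(ParameterError, match="supported families.*haar"):
            decompose(np.zeros((32, 32)), "not-a-wavelet", 2)

    def test_excessive_level_warns_but_proceeds(self):
        img = np.random.default_rng(0).uniform(0, 1, (64, 64))
        with pytest.warns(UserWarning, match="advisable"):
            dec = decompose(img, "coif3", max_level=6)
        assert _rel_err(reconstruct(dec), img) < 1e-8


class TestBandReconstruction:
    def test_band_plus_complement_equals_input(self, rng):
        img = rng.uniform(0, 255, (128, 128))
        dec = decompose(img, "coif3", max_level=4)
        band_img = reconstruct_band(dec, BandSelection(2, 3))
        complement = img - band_img
        # the complement is by construction the un-selected structure; the
        # sum of per-level reconstructions plus approximation re-creates it
        pieces = reconstruct_band(dec, BandSelection(1, 1)) + \
            reconstruct_band(dec, BandSelection(4, 4))
        approx_only = reconstruct(dec) - reconstruct_band(dec, BandSelection(1, 4))
        assert _rel_err(pieces + approx_only, complement) < 1e-6

    def test_sum_of_all_subband_reconstructions_equals_input(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        dec = decompose(img, "db4", max_level=3)
        total = reconstruct(dec) - reconstruct_band(dec, BandSelection(1, 3))
        for n in range(1, 4):
            total = total + reconstruct_band(dec, BandSelection(n, n))
        assert _rel_err(total, img) < 1e-6

    def test_full_band_with_approximation_is_identity(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        dec = decompose(img, "coif3", max_level=3)
        detail = reconstruct_band(dec, BandSelection(1, 3))
        approx = reconstruct(dec) - detail
        assert _rel_err(detail + approx, img) < 1e-8

    def test_white_noise_variance_suppressed_by_coarse_band(self):
        # levels 1-3 carry the high-frequency noise; keeping 4-6 drops it
        ratios = []
        for seed in range(5):
            img = np.random.default_rng(seed).normal(0, 10, (256, 256))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dec = decompose(img, "coif3", max_level=6)
                out = reconstruct_band(dec, BandSelection(4, 6))
            ratios.append(out.var() / img.var())
        assert max(ratios) < 0.2

    def test_clip_negative_floors_at_zero(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        dec = decompose(img, "coif3", max_level=3)
        out = reconstruct_band(dec, BandSelection(1, 2), clip_negative=True)
        assert out.min() == 0.0

    def test_band_beyond_levels_rejected(self):
        dec = decompose(np.zeros((64, 64)), "haar", 3)
        with pytest.raises(ParameterError):
            reconstruct_band(dec, BandSelection(2, 5))

    @pytest.mark.parametrize("width", [4, 16, 32])
    def test_bar_energy_concentrates_at_its_scale(self, width):
        # Haar localizes dyadic scales exactly: a bar of width w keeps most
        # of its detail energy in levels [floor(log2 w), ceil(log2 w)+1]
        img = np.zeros((256, 256))
        img[:, 128 - width // 2:128 - width // 2 + width] = 100.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = decompose(img, "haar", max_level=6)
            energy = {n: (reconstruct_band(dec, BandSelection(n, n)) ** 2).sum()
                      for n in range(1, 7)}
        lo = max(int(math.floor(math.log2(width))), 1)
        hi = min(int(math.ceil(math.log2(width))) + 1, 6)
        inside = sum(energy[n] for n in range(lo, hi + 1))
        assert inside / sum(energy.values()) >= 0.6


class TestCharacteristicBand:
    @pytest.mark.parametrize("wmin,wmax,expected", [
        (16, 64, (4, 6)),
        (20, 60, (4, 6)),
        (1, 1, (1, 1)),
        (2, 200, (1, 6)),  # clamped at the top by max_level
    ])
    def test_width_to_order_mapping(self, wmin, wmax, expected):
        band = characteristic_band_for_width(wmin, wmax, max_level=6)
        assert (band.n_low, band.n_high) == expected

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ParameterError):
            characteristic_band_for_width(0, 16)

    def test_inverted_band_rejected(self):
        with pytest.raises(ParameterError):
            BandSelection(4, 2)


class TestExtractorTransformer:
    def test_matches_function_path_and_handles_stacks(self, rng):
        img = rng.uniform(0, 255, (2, 64, 64))
        est = WaveletBandExtractor(wavelet="coif3", max_level=3, n_low=2,
                                   n_high=3)
        out = est.fit_transform(img)
        ref = reconstruct_band(decompose(img[0], "coif3", 3),
                               BandSelection(2, 3), clip_negative=True)
        assert np.allclose(out[0], ref)
        assert out.shape == img.shape
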