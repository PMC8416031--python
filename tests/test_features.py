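"""Feature extraction against direct-formula and periodogram oracles."""

import numpy as np
import pytest
import scipy.signal as sps
import scipy.stats as spstats
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from somnostage import features as F

RATE = 100.0


def sine(freq, n=3000, rate=RATE, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / rate + phase)


class TestSequenceBank:
    def test_exactly_ten_sequences(self):
        bank = F.build_sequence_bank(np.random.default_rng(0).normal(size=3000), RATE)
        assert set(bank.sequences) == set(F.SEQUENCE_NAMES)
        assert len(bank.sequences) == 10

    def test_zero_input_gives_zero_bands_and_diff(self):
        bank = F.build_sequence_bank(np.zeros(3000), RATE)
        np.testing.assert_array_equal(bank.sequences["diff1"], 0.0)
        for name in F.SEQUENCE_NAMES[2:]:
            np.testing.assert_array_equal(bank.sequences[name], 0.0)

    def test_diff1_length(self):
        bank = F.build_sequence_bank(np.arange(3000.0), RATE)
        assert bank.sequences["diff1"].size == 2999

    def test_alpha_sine_concentrates_welch_power(self):
        # 10 Hz sine: the alpha-band Welch bins must hold >= 90% of the total
        # 0.5-30 Hz Welch power (direct periodogram confirms the peak bin).
        x = sine(10.0)
        bank = F.build_sequence_bank(x, RATE)
        total = sum(bank.sequences[f"welch_{b}"].sum() for b in F.BANDS)
        assert bank.sequences["welch_alpha"].sum() / total >= 0.90
        f, p = sps.periodogram(x, fs=RATE)
        assert abs(f[np.argmax(p)] - 10.0) < 0.5

    def test_band_sequences_nonnegative(self):
        bank = F.build_sequence_bank(np.random.default_rng(1).normal(size=3000), RATE)
        for name in F.SEQUENCE_NAMES[2:]:
            assert np.all(bank.sequences[name] >= 0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            F.build_sequence_bank(np.zeros(30 * 50), 50.0)

    def test_fast_lomb_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=3000) + sine(7.0, amp=3.0)
        bank = F.build_sequence_bank(x, RATE)
        ref = sps.lombscargle(
            np.arange(3000) / RATE, x - x.mean(), 2 * np.pi * bank.lomb_freqs
        )
        np.testing.assert_allclose(bank.lomb_psd, ref, rtol=1e-9, atol=1e-12)


class TestDescriptiveStats:
    def test_simple_triplet(self):
        s = F.descriptive_stats([1.0, 2.0, 3.0])
        assert s[0] == 3.0 and s[1] == 1.0 and s[2] == 2.0  # max, min, mean
        assert s[10] == 2.0  # median
        assert s[11] == 0.0  # zero-crossing rate

    def test_constant_vector_degenerate_conventions(self):
        s = F.descriptive_stats(np.full(10, 3.7))
        var, std = s[3], s[4]
        skew, kurt = s[8], s[9]
        mobility, complexity = s[12], s[13]
        assert var == std == 0.0
        assert skew == kurt == 0.0
        assert mobility == complexity == 0.0

    def test_alternating_vector_brute_force(self):
        x = np.array([0.0, 1.0, 0.0, -1.0, 0.0, 1.0, 0.0, -1.0])
        s = F.descriptive_stats(x)
        mobility_ref = np.sqrt(np.var(np.diff(x)) / np.var(x))
        assert s[12] == pytest.approx(mobility_ref, abs=1e-12)
        sign_changes = sum(
            1 for a, b in zip(x[:-1], x[1:]) if a * b < 0
        )  # enumeration
        assert s[11] == pytest.approx(sign_changes / (len(x) - 1))

    @settings(max_examples=30, deadline=None)
    @given(
        hnp.arrays(
            np.float64,
            st.integers(5, 60),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_matches_naive_oracle(self, x):
        """Moments/percentiles/Hjorth agree with scipy/numpy direct formulas."""
        s = F.descriptive_stats(x)
        np.testing.assert_allclose(s[2], np.mean(x), atol=1e-9)
        np.testing.assert_allclose(s[3], np.var(x), atol=1e-6)
        if np.var(x) > 1e-12:
            np.testing.assert_allclose(s[8], spstats.skew(x), atol=1e-7)
            np.testing.assert_allclose(s[9], spstats.kurtosis(x), atol=1e-7)
        np.testing.assert_allclose(
            s[5:8], np.percentile(x, [25, 75, 95]), atol=1e-9
        )
        np.testing.assert_allclose(s[10], np.median(x), atol=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            F.descriptive_stats([1.0, 2.0])


class TestBandEnergy:
    def test_zero_signal(self):
        bank = F.build_sequence_bank(np.zeros(3000), RATE)
        np.testing.assert_array_equal(F.band_energy(bank), 0.0)

    def test_alpha_sine_dominates(self):
        bank = F.build_sequence_bank(sine(10.0), RATE)
        e = F.band_energy(bank)
        assert np.argmax(e) == 2  # delta, theta, [alpha], beta

    def test_white_noise_energy_tracks_bandwidth(self):
        rng = np.random.default_rng(3)
        e = np.zeros(4)
        for _ in range(20):  # average over epochs to tame periodogram variance
            bank = F.build_sequence_bank(rng.normal(size=3000), RATE)
            e += F.band_energy(bank)
        widths = np.array([high - low for low, high in F.BANDS.values()])
        ratio = (e / e.sum()) / (widths / widths.sum())
        np.testing.assert_allclose(ratio, 1.0, atol=0.25)


class TestEntropies:
    def test_permutation_entropy_of_monotone_is_zero(self):
        assert F.permutation_entropy(np.arange(100.0)) == 0.0

    def test_permutation_entropy_of_noise_near_one(self):
        x = np.random.default_rng(4).uniform(size=3000)
        assert F.permutation_entropy(x, order=3) >= 0.99

    @settings(max_examples=25, deadline=None)
    @given(
        hnp.arrays(
            np.float64, st.integers(10, 200), elements=st.floats(-10, 10, allow_nan=False)
        )
    )
    def test_permutation_entropy_bounded(self, x):
        assert 0.0 <= F.permutation_entropy(x) <= 1.0

    def test_sample_entropy_constant_is_zero(self):
        assert F.sample_entropy(np.full(30, 2.5)) == 0.0

    def test_sample_entropy_alternating_matches_exhaustive_oracle(self):
        x = np.array([0.0, 1.0] * 10)
        m, r = 2, 0.2 * np.std(x)

        def cheb(a, b):
            return np.max(np.abs(a - b))

        nt = len(x) - m
        A = B = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                if cheb(x[i : i + m], x[j : j + m]) <= r:
                    B += 1
                    if cheb(x[i : i + m + 1], x[j : j + m + 1]) <= r:
                        A += 1
        expected = -np.log(A / B)
        assert F.sample_entropy(x, m=2, r=0.2) == pytest.approx(expected, abs=1e-12)

    def test_sample_entropy_reversal_invariant(self):
        x = np.random.default_rng(5).normal(size=200)
        assert F.sample_entropy(x) == pytest.approx(F.sample_entropy(x[::-1]), abs=1e-12)

    def test_svd_entropy_ramp_near_zero(self):
        assert F.svd_entropy(np.arange(3000.0)) < 0.05

    def test_svd_entropy_noise_near_one(self):
        x = np.random.default_rng(6).normal(size=3000)
        assert F.svd_entropy(x, embed_dim=10) > 0.9

    def test_svd_entropy_bounds_and_zero_convention(self):
        assert F.svd_entropy(np.zeros(100)) == 0.0
        x = np.random.default_rng(7).normal(size=500)
        assert 0.0 <= F.svd_entropy(x) <= 1.0

    def test_svd_entropy_matches_full_svd_oracle(self):
        x = np.random.default_rng(8).normal(size=400)
        dim, delay = 10, 1
        n_rows = x.size - (dim - 1) * delay
        Y = np.array([x[i : i + dim] for i in range(n_rows)])
        s = np.linalg.svd(Y, compute_uv=False)
        p = s / s.sum()
        expected = -(p * np.log(p)).sum() / np.log(dim)
        assert F.svd_entropy(x, dim, delay) == pytest.approx(expected, abs=1e-9)


class TestChannelFeatures:
    @pytest.mark.parametrize("rate", [100.0, 250.0])
    def test_152_finite_features_any_rate(self, rate):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 10, int(30 * rate)) + sine(10, n=int(30 * rate), rate=rate)
        feats = F.extract_channel_features(x, rate)
        assert feats.shape == (152,)
        assert np.all(np.isfinite(feats))
        assert F.FEATURES_PER_CHANNEL == 152

    def test_zero_epoch_all_finite(self):
        feats = F.extract_channel_features(np.zeros(3000), RATE)
        assert np.all(np.isfinite(feats))
        # all descriptive statistics of the zero signal vanish
        assert np.all(feats[:140] == 0.0)

    def test_six_channels_give_912_in_canonical_order(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(2, 6, 3000))
        labels = ["O2", "C4", "F4", "EMG", "REOG", "LEOG"]  # scrambled input
        fm = F.extract_features(data, labels, RATE)
        assert fm.n_features == 912
        assert fm.channel_order == list(F.CANONICAL_CHANNEL_ORDER)
        assert fm.feature_names[0].startswith("C4|")
        assert fm.feature_names[-1].startswith("O2|")

    def test_channel_block_matches_single_channel_extraction(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=(1, 2, 3000))
        fm = F.extract_features(data, ["EMG", "C4"], RATE)
        direct = F.extract_channel_features(data[0, 1], RATE)  # C4 comes first
        np.testing.assert_allclose(fm.values[0, :152], direct, atol=1e-12)


class TestNormalizer:
    def test_fit_then_apply_zeroes_train_columns(self):
        rng = np.random.default_rng(12)
        X = rng.normal(5, 3, size=(50, 7))
        params = F.fit_normalizer(X)
        Z = F.apply_normalizer(X, params)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_identical_rows_map_to_zero(self):
        X = np.tile([1.0, -2.0, 3.0], (10, 1))
        Z = F.apply_normalizer(X, F.fit_normalizer(X))
        np.testing.assert_array_equal(Z, 0.0)

    def test_shifted_test_set_not_centred(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 4))
        params = F.fit_normalizer(X)
        Z_test = F.apply_normalizer(X + 2.0, params)
        assert np.all(np.abs(Z_test.mean(axis=0)) > 0.5)
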