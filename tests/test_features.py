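"""Feature blocks: statistics, spectra, wavelet coefficients, complexity measures."""

import math

import numpy as np
import pytest
import pywt

from moodquant.errors import AggregationError, CatalogError, SchemaError
from moodquant.features import (
    ALIASES,
    BLOCK_SIZES,
    CATALOG,
    FEATURE_NAMES,
    N_FEATURES,
    FeatureVector,
    aggregate_session,
    approximate_entropy,
    c0_complexity,
    extract_segment_features,
    freq_features,
    resolve_feature_name,
    time_features,
    vectors_to_wide,
    wavelet_entropy,
    wavelet_features,
    welch_psd,
    wide_to_vectors,
)
from moodquant.preprocess import SubbandSet, decompose_subbands, denoise
from tests.conftest import FS, SEG_LEN, tone


class TestCatalog:
    def test_exact_block_sizes(self):
        from collections import Counter

        counts = Counter(e.block for e in CATALOG.values())
        assert dict(counts) == BLOCK_SIZES
        assert len(FEATURE_NAMES) == N_FEATURES == 176

    @pytest.mark.parametrize(
        "name", ["theta_mean", "alpha_psd", "denoised_sum_CD4", "original_min_CD6"]
    )
    def test_named_features_resolve(self, name):
        assert resolve_feature_name(name) in CATALOG

    def test_unknown_name_rejected(self):
        with pytest.raises(CatalogError):
            resolve_feature_name("no_such_feature")

    def test_aliases_cover_all_coefficient_features(self):
        assert len(ALIASES) == 55
        assert all(v in CATALOG for v in ALIASES.values())


class TestTimeFeatures:
    def test_hand_arithmetic(self):
        f = time_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["mean"] == 2.5
        assert f["median"] == 2.5
        assert f["min"] == 1.0 and f["max"] == 4.0

    def test_translation_shifts_location_only(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1000)
        a, b = time_features(x), time_features(x + 5.0)
        for stat in ("mean", "min", "max", "p25", "median", "p75"):
            assert b[stat] == pytest.approx(a[stat] + 5.0)
        for stat in ("std", "kurtosis", "skewness"):
            assert b[stat] == pytest.approx(a[stat], abs=1e-9)

    def test_normal_sample_moments(self):
        rng = np.random.default_rng(1)
        f = time_features(rng.standard_normal(100_000))
        assert abs(f["kurtosis"]) < 0.05  # excess convention
        assert abs(f["skewness"]) < 0.05

    def test_constant_series_higher_moments_zero(self):
        f = time_features(np.full(100, 3.0))
        assert f["kurtosis"] == 0.0 and f["skewness"] == 0.0


class TestWelch:
    def test_peak_at_tone_frequency(self):
        freqs, psd = welch_psd(tone(10.0, amp=1.0))
        assert abs(freqs[np.argmax(psd)] - 10.0) <= freqs[1] - freqs[0]

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2.0, SEG_LEN)
        freqs, psd = welch_psd(x)
        assert np.trapezoid(psd, freqs) == pytest.approx(np.var(x), rel=0.05)

    def test_zero_input_zero_psd(self):
        _, psd = welch_psd(np.zeros(SEG_LEN))
        assert np.allclose(psd, 0.0)


@pytest.fixture(scope="module")
def band_sum_subbands():
    sig = sum(tone(f) for f in (3.0, 6.0, 12.0, 24.0, 48.0))
    return decompose_subbands(sig)


class TestFreqFeatures:
    def test_relative_powers_sum_to_one(self, band_sum_subbands):
        f = freq_features(band_sum_subbands)
        total = sum(f[f"{b}_rel_power"] for b in ("delta", "theta", "alpha", "beta", "gamma"))
        assert total == pytest.approx(1.0, rel=0.05)

    def test_pure_beta_tone_maximizes_beta_relative_power(self):
        f = freq_features(decompose_subbands(tone(24.0)))
        rels = {b: f[f"{b}_rel_power"] for b in ("delta", "theta", "alpha", "beta", "gamma")}
        assert max(rels, key=rels.get) == "beta"

    def test_equal_band_powers_give_unit_ratio(self):
        # matched-power theta and beta tones
        sig = tone(6.0, amp=4.0) + tone(24.0, amp=4.0)
        f = freq_features(decompose_subbands(sig))
        assert f["beta_theta_abs_ratio"] == pytest.approx(1.0, abs=0.1)
        assert f["beta_theta_rel_ratio"] == pytest.approx(1.0, abs=0.1)

    def test_count_is_54(self, band_sum_subbands):
        assert len(freq_features(band_sum_subbands)) == 54


class TestWaveletFeatures:
    def _dummy_subbands(self, layer_coeffs):
        z = np.zeros(256)
        return SubbandSet(
            denoised=z, delta=z, theta=z, alpha=z, beta=z, gamma=z,
            layer_coefficients=layer_coeffs,
        )

    def test_constant_layer_statistics(self):
        n = 64
        coeffs = {j: np.zeros(8) for j in range(1, 9)}
        coeffs[4] = np.ones(n)
        f = wavelet_features(self._dummy_subbands(coeffs))
        assert f["denoised_sum_CD4"] == n
        assert f["denoised_energy_CD4"] == n
        assert f["denoised_std_CD4"] == 0.0

    def test_energy_shares_at_most_one(self):
        rng = np.random.default_rng(3)
        coeffs = {j: rng.normal(size=32) for j in range(1, 9)}
        f = wavelet_features(self._dummy_subbands(coeffs))
        share = sum(f[f"denoised_rel_energy_CD{j}"] for j in range(3, 8))
        assert 0.0 < share <= 1.0 + 1e-12

    def test_missing_layer_rejected(self):
        coeffs = {j: np.ones(8) for j in (1, 2, 3)}
        with pytest.raises(SchemaError):
            wavelet_features(self._dummy_subbands(coeffs))

    def test_sum_cd4_matches_independent_decomposition(self, eeg_segment):
        fv = extract_segment_features(eeg_segment)
        # independent oracle: direct pywt decomposition of the denoised segment
        den = denoise(eeg_segment)
        coeffs = pywt.wavedec(den, "db5", mode="periodization", level=8)
        d4 = coeffs[5]  # [A8, D8, D7, D6, D5, D4, D3, D2, D1]
        assert fv["denoised_sum_CD4"] == pytest.approx(float(np.sum(d4)), rel=1e-10)


class TestWaveletEntropy:
    def test_single_layer_degenerate(self):
        coeffs = {j: np.zeros(4) for j in range(1, 9)}
        coeffs[5] = np.ones(4)
        assert wavelet_entropy(coeffs) == 0.0

    def test_uniform_maximum(self):
        coeffs = {j: np.ones(4) for j in range(1, 9)}
        assert wavelet_entropy(coeffs) == pytest.approx(math.log(8), rel=1e-12)

    def test_hand_computed_distribution(self):
        # energies (1, 1, 2, 0, ..., 0) -> -(0.25 ln .25)*2 - 0.5 ln .5
        coeffs = {j: np.zeros(2) for j in range(1, 9)}
        coeffs[1] = np.array([1.0, 0.0])
        coeffs[2] = np.array([1.0, 0.0])
        coeffs[3] = np.array([np.sqrt(2.0), 0.0])
        expected = -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))
        assert wavelet_entropy(coeffs) == pytest.approx(expected, rel=1e-12)


class TestC0Complexity:
    def test_pure_sinusoid_is_regular(self):
        x = tone(8.0, n=4096)  # integer number of cycles in 8 s
        assert c0_complexity(x) < 0.05

    def test_white_noise_is_irregular(self):
        values = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values.append(c0_complexity(rng.standard_normal(4096)))
        assert np.mean(values) > 0.5

    def test_mixture_lies_between(self):
        rng = np.random.default_rng(7)
        regular = tone(8.0, n=4096, amp=5.0)
        noise = rng.normal(0, 1.0, 4096)
        c_reg = c0_complexity(regular)
        c_noise = c0_complexity(noise)
        c_mix = c0_complexity(regular + noise)
        assert c_reg < c_mix < c_noise


class TestApproximateEntropy:
    def test_constant_series_zero(self):
        assert approximate_entropy(np.full(100, 2.0)) == 0.0

    def test_matches_brute_force_template_count(self):
        rng = np.random.default_rng(1)
        x = np.tile([1.0, 2.0], 30) + rng.normal(0, 0.1, 60)
        m, r = 2, 0.5 * np.std(x)

        def brute(x, m, r):
            n = len(x)

            def phi(mm):
                vecs = [x[i : i + mm] for i in range(n - mm + 1)]
                tot = 0.0
                for v in vecs:
                    c = sum(
                        1 for w in vecs if max(abs(a - b) for a, b in zip(v, w)) <= r
                    )
                    tot += math.log(c / len(vecs))
                return tot / len(vecs)

            return phi(m) - phi(m + 1)

        assert approximate_entropy(x, m=2, r_frac=0.5, max_len=None) == pytest.approx(
            brute(list(x), m, r), rel=1e-12
        )

    def test_noise_more_entropic_than_sinusoid(self):
        rng = np.random.default_rng(2)
        sine = tone(10.0, n=1024, amp=1.0)
        noise = rng.normal(0, np.std(sine), 1024)
        assert approximate_entropy(noise) > approximate_entropy(sine)


class TestExtraction:
    def test_vector_has_all_catalog_features(self, eeg_segment):
        fv = extract_segment_features(eeg_segment)
        assert tuple(fv.values) == FEATURE_NAMES
        assert np.all(np.isfinite(fv.as_array()))

    def test_extraction_deterministic(self, eeg_segment):
        a = extract_segment_features(eeg_segment)
        b = extract_segment_features(eeg_segment)
        assert np.array_equal(a.as_array(), b.as_array())

    def test_alpha_psd_consistent_with_direct_welch(self, eeg_segment):
        fv = extract_segment_features(eeg_segment)
        sb = decompose_subbands(denoise(eeg_segment))
        freqs, psd = welch_psd(sb.alpha)
        assert fv["alpha_psd"] == pytest.approx(np.trapezoid(psd, freqs), rel=1e-10)


class TestAggregation:
    def _vec(self, fill, channel="Fp1"):
        values = {n: float(fill) for n in FEATURE_NAMES}
        return FeatureVector("S01", None, channel, values)

    def test_single_segment_identity(self):
        v = self._vec(1.5)
        agg = aggregate_session([v])
        assert np.array_equal(agg.as_array(), v.as_array())
        assert agg.level == "session"

    def test_mean_of_two(self):
        agg = aggregate_session([self._vec(1.0), self._vec(3.0)])
        assert np.all(agg.as_array() == 2.0)

    def test_permutation_invariant(self):
        vs = [self._vec(v) for v in (1.0, 2.0, 7.0)]
        a = aggregate_session(vs).as_array()
        b = aggregate_session(vs[::-1]).as_array()
        assert np.array_equal(a, b)

    def test_empty_list_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_session([])

    def test_mixed_channels_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_session([self._vec(1.0, "Fp1"), self._vec(1.0, "Fp2")])


def test_wide_table_round_trip(eeg_segment):
    fv = extract_segment_features(eeg_segment, subject_id="S01")
    df = vectors_to_wide([fv])
    assert df.shape == (1, 5 + 176)
    back = wide_to_vectors(df)[0]
    assert np.allclose(back.as_array(), fv.as_array())
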