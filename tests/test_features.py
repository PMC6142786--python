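"""Feature extraction: moments, spectra, entropies, nonlinear estimators,
normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepforest.errors import DegenerateInputError, FeatureComputationError
from sleepforest.features import (
    FEATURE_NAMES,
    EmbeddingConfig,
    SpectralDensity,
    band_features,
    c0_complexity,
    extract_features,
    hjorth_parameters,
    kolmogorov_entropy,
    kurtosis,
    max_lyapunov,
    minmax_apply,
    minmax_fit,
    power_spectral_density,
    shannon_entropy,
    skewness,
    spectral_entropy,
)
from sleepforest.synthetic import BANDS, generate_epoch

from conftest import logistic_map

FS = 100.0
T = np.arange(3000) / FS


class TestHjorth:
    def test_sine_closed_form(self):
        # unit sine at 1 Hz: mobility = 2 sin(pi/100), complexity = 1
        x = np.sin(2 * np.pi * 1.0 * T)
        _, mob, cpx = hjorth_parameters(x)
        assert mob == pytest.approx(2 * np.sin(np.pi / 100), rel=0.02)
        assert cpx == pytest.approx(1.0, rel=0.02)

    def test_white_noise_complexity_above_one(self):
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(3000)
            assert hjorth_parameters(x)[2] > 1.0

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateInputError):
            hjorth_parameters(np.full(100, 3.0))

    def test_brute_force_moment_oracle(self, rng):
        """Direct-summation formulas on short random vectors."""
        for _ in range(20):
            x = rng.standard_normal(20)
            n, mu = len(x), x.mean()
            act = sum((v - mu) ** 2 for v in x) / (n - 1)
            xd = x[1:] - x[:-1]
            mud = xd.mean()
            v1 = sum((v - mud) ** 2 for v in xd) / (n - 2)
            xdd = xd[1:] - xd[:-1]
            mudd = xdd.mean()
            v2 = sum((v - mudd) ** 2 for v in xdd) / (n - 3)
            a, m, c = hjorth_parameters(x)
            assert a == pytest.approx(act, abs=1e-12)
            assert m == pytest.approx(np.sqrt(v1 / act), abs=1e-12)
            assert c == pytest.approx(np.sqrt(v2 / v1) / np.sqrt(v1 / act), abs=1e-12)


class TestMoments:
    def test_symmetric_skew_zero(self):
        assert skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)

    def test_kurtosis_hand_value(self):
        # m2 = 2, m4 = 6.8 -> 6.8 / 4 = 1.7
        assert kurtosis([1, 2, 3, 4, 5]) == pytest.approx(1.7, abs=1e-12)

    def test_gaussian_kurtosis_three(self, rng):
        assert kurtosis(rng.standard_normal(200_000)) == pytest.approx(3.0, abs=0.1)

    def test_population_moment_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal(20)
            mu = x.mean()
            m2 = sum((v - mu) ** 2 for v in x) / len(x)
            m3 = sum((v - mu) ** 3 for v in x) / len(x)
            m4 = sum((v - mu) ** 4 for v in x) / len(x)
            assert skewness(x) == pytest.approx(m3 / m2 ** 1.5, abs=1e-12)
            assert kurtosis(x) == pytest.approx(m4 / m2 ** 2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            skewness(np.ones(10))


class TestSpectral:
    def test_sine_peak_location(self):
        sd = power_spectral_density(np.sin(2 * np.pi * 10 * T), FS)
        df = sd.freqs[1] - sd.freqs[0]
        assert abs(sd.freqs[np.argmax(sd.psd)] - 10.0) <= df

    def test_parseval_within_ten_percent(self, rng):
        x = rng.standard_normal(3000)
        sd = power_spectral_density(x, FS)
        df = sd.freqs[1] - sd.freqs[0]
        assert sd.psd.sum() * df == pytest.approx(x.var(), rel=0.10)

    def test_zeros_give_zero_psd(self):
        sd = power_spectral_density(np.zeros(3000), FS)
        assert np.all(sd.psd == 0)

    def test_band_features_pure_alpha_tone(self):
        sd = power_spectral_density(np.sin(2 * np.pi * 10 * T), FS)
        absolute, relative, center, peak = band_features(sd, ("alpha", 8, 13))
        df = sd.freqs[1] - sd.freqs[0]
        assert relative > 0.95
        assert abs(center - 10.0) <= df
        assert band_features(sd, ("delta", 0.5, 2))[1] < 0.02
        assert peak == sd.psd.max()

    def test_two_equal_tones_balance_bands(self):
        x = np.sin(2 * np.pi * 3 * T) + np.sin(2 * np.pi * 20 * T)
        sd = power_spectral_density(x, FS)
        saw = band_features(sd, ("sawtooth", 2, 4))[1]
        beta = band_features(sd, ("beta", 13, 30))[1]
        assert saw == pytest.approx(beta, rel=0.10)

    def test_relative_powers_tile_full_range(self, one_epoch_per_stage):
        for ep in one_epoch_per_stage.values():
            sd = power_spectral_density(ep.samples[0], FS)
            total = sum(band_features(sd, b)[1] for b in BANDS)
            assert 0.98 <= total <= 1.02

    def test_zero_power_rejected(self):
        sd = power_spectral_density(np.zeros(3000), FS)
        with pytest.raises(DegenerateInputError):
            band_features(sd, ("alpha", 8, 13))


class TestEntropies:
    def test_shannon_constant_zero(self):
        assert shannon_entropy(np.full(100, 2.0)) == 0.0

    def test_shannon_uniform_16_bins_is_4_bits(self):
        x = np.repeat(np.arange(16.0), 10)
        assert shannon_entropy(x, n_bins=16) == pytest.approx(4.0, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_shannon_max_entropy_bound(self, seed):
        x = np.random.default_rng(seed).standard_normal(500)
        assert 0.0 <= shannon_entropy(x, 16) <= 4.0 + 1e-12

    def test_spectral_entropy_two_equal_bins(self):
        sd = SpectralDensity(
            freqs=np.array([1.0, 2.0, 3.0]), psd=np.array([1.0, 1.0, 0.0]), fs=FS
        )
        assert spectral_entropy(sd) == pytest.approx(1.0, abs=1e-12)

    def test_spectral_entropy_sine_near_minimal(self):
        # Hamming-window leakage spreads a pure tone over a few bins, so
        # the floor is ~1 bit, far below the log2(60)=5.9 flat-spectrum cap
        sd = power_spectral_density(np.sin(2 * np.pi * 10 * T), FS)
        assert spectral_entropy(sd) < 1.5

    def test_spectral_entropy_white_noise_near_maximal(self, rng):
        x = rng.standard_normal(60_000)
        sd = power_spectral_density(x, FS)
        n_bins = ((sd.freqs >= 0.5) & (sd.freqs <= 30)).sum()
        assert spectral_entropy(sd) == pytest.approx(np.log2(n_bins), rel=0.10)

    def test_entropies_amplitude_invariant(self, rng):
        x = rng.standard_normal(3000)
        assert shannon_entropy(3.7 * x) == pytest.approx(shannon_entropy(x), abs=1e-9)
        a = spectral_entropy(power_spectral_density(3.7 * x, FS))
        b = spectral_entropy(power_spectral_density(x, FS))
        assert a == pytest.approx(b, abs=1e-9)


LOGISTIC_CFG = EmbeddingConfig(
    dimension=2, delay=1, eps_factors=(0.1, 0.15, 0.2), theiler=2, max_points=800
)


class TestKolmogorovEntropy:
    def test_periodic_signal_near_zero(self):
        x = np.sin(2 * np.pi * 10 * T)
        assert kolmogorov_entropy(x, EmbeddingConfig(), FS) < 0.05

    def test_logistic_map_bracket(self):
        # fully chaotic logistic map: KS entropy = ln 2 = 0.693 nats/iter
        x = logistic_map(3000)
        k2 = kolmogorov_entropy(x, LOGISTIC_CFG, fs=1.0)
        assert 0.5 <= k2 <= 0.9

    def test_iid_noise_exceeds_chaotic_map(self, rng):
        noise = rng.uniform(0, 1, 3000)
        k2_noise = kolmogorov_entropy(noise, LOGISTIC_CFG, fs=1.0)
        k2_map = kolmogorov_entropy(logistic_map(3000), LOGISTIC_CFG, fs=1.0)
        assert k2_noise > k2_map

    def test_tiny_radius_rejected(self):
        x = logistic_map(600)
        cfg = EmbeddingConfig(dimension=2, delay=1, eps_factors=(1e-9,), theiler=2)
        with pytest.raises(DegenerateInputError, match="radius"):
            kolmogorov_entropy(x, cfg, fs=1.0)


WOLF_CFG = EmbeddingConfig(dimension=2, delay=1, theiler=5, evolve_steps=1,
                           max_steps=1000)


class TestMaxLyapunov:
    def test_logistic_map_ln2(self):
        lam = max_lyapunov(logistic_map(3000), WOLF_CFG, fs=1.0)
        assert lam == pytest.approx(np.log(2), rel=0.15)

    def test_pure_sine_near_zero(self):
        lam = max_lyapunov(np.sin(2 * np.pi * 10 * T),
                           EmbeddingConfig(dimension=5), FS)
        assert lam <= 0.05

    def test_scale_invariance(self):
        x = logistic_map(3000)
        a = max_lyapunov(x, WOLF_CFG, fs=1.0)
        b = max_lyapunov(2.0 * x, WOLF_CFG, fs=1.0)
        assert b == pytest.approx(a, rel=0.05)


class TestC0Complexity:
    def test_pure_sine_near_zero(self):
        assert c0_complexity(np.sin(2 * np.pi * 10 * T)) < 0.05

    def test_white_noise_above_06(self, rng):
        assert c0_complexity(rng.standard_normal(3000), r=3.0) > 0.6

    def test_retained_peak_signal_exactly_regular(self):
        # bin-aligned strong tones are fully retained -> residual ~ 0
        x = 5 * np.sin(2 * np.pi * 10 * T) + 4 * np.cos(2 * np.pi * 5 * T)
        assert c0_complexity(x) < 1e-10

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            c0_complexity(np.zeros(3000))


class TestExtractFeatures:
    def test_sixty_finite_named_values(self, one_epoch_per_stage):
        values = extract_features(one_epoch_per_stage["NREM2"])
        assert list(values) == FEATURE_NAMES
        assert all(np.isfinite(v) for v in values.values())

    def test_channel_duplication_duplicates_block(self, one_epoch_per_stage):
        from dataclasses import replace

        ep = one_epoch_per_stage["WA"]
        dup = replace(ep, samples=np.vstack([ep.samples[0], ep.samples[0]]))
        values = extract_features(dup)
        for name in FEATURE_NAMES:
            if name.startswith("Fpz-Cz"):
                mirror = name.replace("Fpz-Cz", "Pz-Oz")
                assert values[name] == values[mirror]

    def test_sws_epoch_delta_dominates(self, one_epoch_per_stage):
        values = extract_features(one_epoch_per_stage["NREM4"])
        rels = [values[f"Fpz-Cz.relative_power.{b}"]
                for b in ("delta", "sawtooth", "theta", "alpha", "beta")]
        assert np.argmax(rels) == 0

    def test_pure_function_bit_identical(self, one_epoch_per_stage):
        ep = one_epoch_per_stage["REM"]
        assert extract_features(ep) == extract_features(ep)

    def test_error_carries_feature_name(self):
        from sleepforest.epoch_io import Epoch

        flat = Epoch(samples=np.zeros((2, 3000)), stage="WA",
                     subject_id="s", epoch_id="s:0")
        with pytest.raises(FeatureComputationError, match="Fpz-Cz"):
            extract_features(flat)

    def test_manifest_matches_feature_names(self):
        import json
        from importlib import resources

        doc = json.loads(
            resources.files("sleepforest").joinpath("feature_manifest.json").read_text()
        )
        assert doc["names"] == FEATURE_NAMES


class TestMinMax:
    def test_direct_mapping(self):
        m = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out = minmax_apply(m, minmax_fit(m, ["a"]))
        assert out["a"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_warns_and_zeroes(self):
        m = pd.DataFrame({"a": [3.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_apply(m, minmax_fit(m, ["a"]))
        assert (out["a"] == 0.0).all()

    def test_fit_apply_hits_unit_bounds(self, rng):
        m = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        out = minmax_apply(m, minmax_fit(m, list("abc")))
        assert np.allclose(out.min(), 0.0) and np.allclose(out.max(), 1.0)

    def test_unseen_data_clipped(self):
        train = pd.DataFrame({"a": [0.0, 1.0]})
        params = minmax_fit(train, ["a"])
        test = pd.DataFrame({"a": [-1.0, 2.0]})
        clipped = minmax_apply(test, params)
        assert clipped["a"].tolist() == [0.0, 1.0]
        raw = minmax_apply(test, params, clip=False)
        assert raw["a"].tolist() == [-1.0, 2.0]
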