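"""Statistical descriptors: entropy oracles, manifest sanity, selection."""

import numpy as np
import pytest

from microfuse.records import EEGRecord
from microfuse.stats_features import (
    EntropyParams, FeatureConfig, FEATURE_NAMES, INFO_THEORETIC_FEATURES,
    sample_entropy, app_entropy, svd_entropy, svd_fisher_info,
    extract_features, extract_channel_features, gini_select,
)
from conftest import make_record


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_sampen(x, m, r_frac):
    """O(n²) template-pair counting with Chebyshev distance <= r."""
    x = np.asarray(x, dtype=float)
    tol = r_frac * x.std()

    def count(order):
        n = len(x) - m  # same template population at both lengths
        emb = np.stack([x[i:i + order] for i in range(len(x) - order + 1)])[:n]
        c = 0
        for i in range(len(emb)):
            for j in range(i + 1, len(emb)):
                if np.max(np.abs(emb[i] - emb[j])) <= tol:
                    c += 1
        return c

    B = count(m)
    A = count(m + 1)
    if A == 0 or B == 0:
        return np.inf
    return -np.log(A / B)


def gram_svd_probs(x, order, delay):
    """Singular values via eigen-decomposition of the Gram matrix."""
    n = len(x) - (order - 1) * delay
    emb = np.stack([x[i * delay: i * delay + n] for i in range(order)], axis=1)
    eig = np.linalg.eigvalsh(emb.T @ emb)
    s = np.sqrt(np.maximum(eig, 0))[::-1]
    return s / s.sum()


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(50, 3.14), 2, 0.2) == 0.0

    @pytest.mark.parametrize("seed,n", [(0, 80), (1, 120), (2, 60)])
    def test_matches_brute_force_on_random_series(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        assert sample_entropy(x, 2, 0.2) == pytest.approx(
            brute_force_sampen(x, 2, 0.2), abs=1e-12)

    def test_periodic_series_matches_brute_force(self):
        x = np.array([1.0, 2.0, 3.0] * 10)
        assert sample_entropy(x, 2, 0.2) == pytest.approx(
            brute_force_sampen(x, 2, 0.2), abs=1e-12)

    def test_monotone_ramp_has_no_matches(self):
        x = np.arange(50, dtype=float)
        assert np.isinf(sample_entropy(x, 2, 0.01))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), 2, 0.2)


class TestSVDFeatures:
    def test_rank_one_embedding_zero_entropy(self):
        x = np.ones(30)  # constant series -> exactly rank-1 embedding
        assert svd_entropy(x, 3, 1) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_gram_matrix_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(300)
        p = gram_svd_probs(x, 3, 1)
        expect_h = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert svd_entropy(x, 3, 1) == pytest.approx(expect_h, abs=1e-10)
        expect_fi = ((np.diff(p) ** 2) / (p[1:] + 1e-8)).sum()
        assert svd_fisher_info(x, 3, 1) == pytest.approx(expect_fi, abs=1e-10)

    def test_entropy_bounded_by_log_order(self, rng):
        for order in (2, 3, 5):
            x = rng.standard_normal(200)
            assert svd_entropy(x, order, 1) <= np.log(order) + 1e-12

    def test_fisher_hand_arithmetic_on_injected_spectrum(self):
        val = svd_fisher_info(None, probs=np.array([0.7, 0.2, 0.1]))
        assert val == pytest.approx(1.35, abs=1e-6)

    def test_fisher_uniform_spectrum_zero(self):
        assert svd_fisher_info(None, probs=np.full(4, 0.25)) == 0.0

    def test_fisher_nonnegative(self, rng):
        for _ in range(5):
            assert svd_fisher_info(rng.standard_normal(100), 4, 2) >= 0


class TestExtractFeatures:
    def test_manifest_is_40_named_dims(self, rng):
        rec = make_record(rng.standard_normal((3, 2000)))
        fv = extract_features(rec)
        assert len(fv.values) == 40
        assert fv.names == list(FEATURE_NAMES)
        assert np.isfinite(fv.values).all()

    def test_gaussian_noise_unit_std(self, rng):
        rec = make_record(rng.standard_normal((2, 10_000)))
        fv = extract_features(rec)
        std = fv.values[fv.names.index("std")]
        assert std == pytest.approx(1.0, rel=0.05)

    def test_sinusoid_zero_crossing_rate(self):
        fs = 128.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        rec = make_record(np.stack([x, -x]), fs)
        fv = extract_features(rec)
        zcr = fv.values[fv.names.index("zero_crossing_rate")]
        assert zcr == pytest.approx(20.0, rel=0.02)

    def test_degenerate_constant_channel(self):
        feats = extract_channel_features(np.full(1000, 2.0), 128.0)
        assert feats["std"] == 0.0
        assert feats["line_length"] == 0.0
        assert feats["samp_entropy"] == 0.0

    def test_too_short_record_lists_offenders(self, rng):
        rec = make_record(rng.standard_normal((2, 16)))
        with pytest.raises(ValueError, match="wavelet"):
            extract_features(rec)

    def test_channel_order_invariance(self, rng):
        data = rng.standard_normal((4, 1500))
        a = extract_features(make_record(data))
        b = extract_features(make_record(data[::-1]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestGiniSelect:
    def _data(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 10))
        X[:, 0] = y * 4.0 + rng.standard_normal(n) * 0.1  # fully informative
        return X, y, [f"f{i}" for i in range(10)]

    def test_informative_feature_retained(self):
        X, y, names = self._data()
        sel = gini_select(X, y, names, threshold=0.002, seed=0, always_keep=())
        assert "f0" in sel.names
        assert sel.importances[0] == sel.importances.max()

    def test_zero_threshold_keeps_all(self):
        X, y, names = self._data()
        sel = gini_select(X, y, names, threshold=0.0, seed=0)
        assert sel.names == names

    def test_importances_sum_to_one(self):
        X, y, names = self._data()
        sel = gini_select(X, y, names, seed=0)
        assert sel.importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_info_theoretic_features_always_kept(self):
        X, y, _ = self._data()
        names = list(INFO_THEORETIC_FEATURES) + [f"f{i}" for i in range(7)]
        sel = gini_select(X, y, names, threshold=0.5, seed=0)
        assert set(INFO_THEORETIC_FEATURES) <= set(sel.names)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 3))
        with pytest.raises(ValueError):
            gini_select(X, np.zeros(20), ["a", "b", "c"])

    def test_deterministic(self):
        X, y, names = self._data()
        a = gini_select(X, y, names, seed=3)
        b = gini_select(X, y, names, seed=3)
        np.testing.assert_array_equal(a.mask, b.mask)


def test_app_entropy_finite_on_noise(rng):
    assert np.isfinite(app_entropy(rng.standard_normal(500)))


def test_entropy_params_validation():
    with pytest.raises(ValueError):
        EntropyParams(m=0)
    with pytest.raises(ValueError):
        EntropyParams(r=-1.0)
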