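"""Microstate pipeline: GFP, peaks, polarity-invariant clustering,
alignment, backfitting, temporal statistics and GEV."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microfuse import synth
from microfuse import microstate as ms
from conftest import make_record


class TestGFP:
    def test_equal_channels_zero(self):
        rec = make_record(np.ones((4, 10)))
        assert np.all(ms.compute_gfp(rec).values == 0)

    def test_two_channel_hand_value(self):
        rec = make_record(np.array([[1.0], [-1.0]]))
        assert ms.compute_gfp(rec).values[0] == pytest.approx(1.0)

    def test_homogeneity(self, rng):
        data = rng.standard_normal((5, 100))
        g1 = ms.compute_gfp(make_record(data)).values
        g3 = ms.compute_gfp(make_record(3.0 * data)).values
        np.testing.assert_allclose(g3, 3.0 * g1, atol=1e-12)


class TestPeaks:
    def test_single_bump(self):
        v = np.concatenate([np.arange(10.0), np.arange(10.0)[::-1]])
        peaks = ms.detect_gfp_peaks(ms.GFPSeries(v, 1000.0), min_separation_ms=1)
        assert list(peaks) == [9]

    def test_close_equal_peaks_keep_earlier(self):
        v = np.array([0, 5, 0, 5, 0], dtype=float)
        peaks = ms.detect_gfp_peaks(ms.GFPSeries(v, 1000.0), min_separation_ms=3)
        assert list(peaks) == [1]

    def test_modulated_signal_peak_count(self):
        fs = 128.0
        t = np.arange(int(10 * fs)) / fs
        v = np.abs(np.sin(2 * np.pi * 5 * t))  # 10 GFP bumps per second
        peaks = ms.detect_gfp_peaks(ms.GFPSeries(v, fs), min_separation_ms=10)
        assert abs(len(peaks) - 100) <= 10


class TestClustering:
    def test_exact_recovery_from_clean_maps(self, ground_truth, rng):
        T = ground_truth.templates
        idx = rng.integers(0, 4, 200)
        signs = rng.choice([-1.0, 1.0], 200)
        amps = rng.uniform(0.5, 2.0, 200)
        maps = T[idx] * (signs * amps)[:, None]
        est = ms.cluster_templates(maps, K=4, n_init=5, seed=0)
        corr = np.abs(est @ T.T)
        assert corr.max(axis=1).min() > 0.999
        # one-to-one matching
        assert sorted(corr.argmax(axis=1)) == [0, 1, 2, 3]

    def test_polarity_invariance(self, ground_truth, rng):
        T = ground_truth.templates
        maps = T[rng.integers(0, 4, 100)] * rng.uniform(0.5, 2, 100)[:, None]
        a = ms.cluster_templates(maps, K=4, n_init=3, seed=1)
        b = ms.cluster_templates(np.vstack([maps, -maps]), K=4, n_init=3, seed=1)
        corr = np.abs(a @ b.T)
        assert corr.max(axis=1).min() > 0.999

    def test_noisy_recovery(self, ground_truth, rng):
        T = ground_truth.templates
        maps = T[rng.integers(0, 4, 400)] + rng.standard_normal((400, 19)) * 0.1
        est = ms.cluster_templates(maps, K=4, n_init=5, seed=2)
        assert np.abs(est @ T.T).max(axis=1).mean() > 0.9

    def test_too_few_maps(self, ground_truth):
        with pytest.raises(ValueError):
            ms.cluster_templates(ground_truth.templates[:2], K=4)

    def test_two_level_identical_subjects(self, ground_truth):
        sets = [ground_truth.templates] * 5
        glob = ms.two_level_cluster(sets, K=4, seed=0)
        corr = np.abs(glob @ ground_truth.templates.T)
        assert corr.max(axis=1).min() > 0.999

    def test_two_level_empty(self):
        with pytest.raises(ValueError):
            ms.two_level_cluster([])


class TestAlignment:
    def test_recovers_shuffle(self, ground_truth):
        T = ground_truth.templates
        perm = np.array([2, 0, 3, 1])
        aligned, p, signs = ms.align_to_reference(T[perm], T)
        np.testing.assert_allclose(np.abs(aligned @ T.T).diagonal(), 1.0, atol=1e-9)
        np.testing.assert_array_equal(perm[p], [0, 1, 2, 3])

    def test_sign_flips_corrected(self, ground_truth):
        T = ground_truth.templates
        aligned, p, signs = ms.align_to_reference(-T, T)
        np.testing.assert_array_equal(p, [0, 1, 2, 3])
        np.testing.assert_allclose((aligned @ T.T).diagonal(), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = synth.generate_templates(19, 4, seed=seed)
        B = synth.generate_templates(19, 4, seed=seed + 100)
        aligned, perm, signs = ms.align_to_reference(A, B)
        got = np.abs((A[perm] * signs[:, None] * B).sum(axis=1)).sum()
        corr = A @ B.T
        best = max(
            sum(abs(corr[p[j], j]) for j in range(4))
            for p in itertools.permutations(range(4))
        )
        assert got == pytest.approx(best, abs=1e-9)

    def test_channel_mismatch(self, ground_truth):
        with pytest.raises(ValueError):
            ms.align_to_reference(ground_truth.templates[:, :10], ground_truth.templates)


class TestBackfit:
    def test_scale_invariance(self, noiseless_record, noiseless_ground_truth):
        rec, labels = noiseless_record
        big = rec.with_data(rec.data * 10.0)
        np.testing.assert_array_equal(
            ms.backfit(big, noiseless_ground_truth.templates), labels)

    def test_negated_template_sample(self, ground_truth):
        T = ground_truth.templates
        rec = make_record(np.stack([-T[2], T[0]], axis=1))
        labels = ms.backfit(rec, T)
        assert labels[0] == 2 and labels[1] == 0

    def test_whole_record_polarity_invariance(self, noiseless_record,
                                              noiseless_ground_truth):
        rec, labels = noiseless_record
        neg = rec.with_data(-rec.data)
        np.testing.assert_array_equal(
            ms.backfit(neg, noiseless_ground_truth.templates), labels)


class TestSummarize:
    def test_hand_counted_example(self):
        labels = np.array([0, 0, 1, 1, 1, 2])
        s = ms.summarize(labels, fs_hz=1000.0)
        np.testing.assert_allclose(s.coverage, [2 / 6, 3 / 6, 1 / 6, 0])
        assert s.duration_ms[0] == pytest.approx(2.0)
        assert s.transition_matrix[0, 1] == 1.0
        assert s.transition_matrix[1, 2] == 1.0
        assert not s.occurred[3]

    def test_constant_labels(self):
        s = ms.summarize(np.full(100, 2), fs_hz=128.0)
        np.testing.assert_allclose(s.coverage, [0, 0, 1, 0])
        assert s.transition_matrix.sum() == 0
        assert list(s.occurred) == [False, False, True, False]

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=200))
    def test_normalization_invariants(self, labels):
        s = ms.summarize(np.array(labels), fs_hz=128.0)
        assert s.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        for k in range(4):
            row = s.transition_matrix[k].sum()
            assert row == pytest.approx(1.0, abs=1e-9) or row == 0.0


class TestGEV:
    def test_zero_noise_total_gev_is_one(self, noiseless_record, noiseless_ground_truth):
        rec, labels = noiseless_record
        gev = ms.compute_gev(rec, labels, noiseless_ground_truth.templates)
        assert gev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_random_labels_on_noise_below_one(self, rng, ground_truth):
        rec = make_record(rng.standard_normal((19, 2000)))
        labels = rng.integers(0, 4, 2000)
        gev = ms.compute_gev(rec, labels, ground_truth.templates)
        assert 0 < gev.sum() < 1.0

    def test_single_state_perfect_fit(self, ground_truth):
        T = ground_truth.templates
        data = np.tile(T[0][:, None], (1, 50)) * np.linspace(0.5, 2, 50)
        rec = make_record(data)
        gev = ms.compute_gev(rec, np.zeros(50, dtype=int), T)
        np.testing.assert_allclose(gev, [1.0, 0, 0, 0], atol=1e-9)

    def test_zero_gfp_rejected(self, ground_truth):
        rec = make_record(np.ones((19, 10)))
        with pytest.raises(ValueError):
            ms.compute_gev(rec, np.zeros(10, dtype=int), ground_truth.templates)


class TestFeatureVector:
    def test_length_and_block_structure(self):
        labels = np.array([0, 1, 2, 3] * 25)
        s = ms.summarize(labels, 128.0)
        fv = ms.feature_vector(s, np.full(4, 0.2))
        assert len(fv) == 28
        assert fv.names[0] == "duration_A"
        assert len([n for n in fv.names if n.startswith("trans_")]) == 12
        assert len([n for n in fv.names if n.startswith("gev_")]) == 4

    def test_absent_state_zeros(self):
        s = ms.summarize(np.array([0, 1, 0, 1]), 128.0)
        fv = ms.feature_vector(s, np.zeros(4))
        idx = {n: i for i, n in enumerate(fv.names)}
        for name in ("duration_D", "coverage_D", "occurrence_D"):
            assert fv.values[idx[name]] == 0.0
        assert not fv.occurred[3]


def test_smooth_labels_removes_short_runs():
    labels = np.array([0, 0, 0, 1, 0, 0, 2, 2, 2, 2])
    out = ms.smooth_labels(labels, fs_hz=1000.0, min_duration_ms=2.0)
    assert np.array_equal(out, [0, 0, 0, 0, 0, 0, 2, 2, 2, 2])


def test_canonical_reference_templates_roundtrip():
    maps, chans = ms.canonical_reference_templates()
    assert maps.shape == (4, 19)
    np.testing.assert_allclose(maps.mean(axis=1), 0, atol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(maps, axis=1), 1, atol=1e-9)
    # reordering channels permutes map columns consistently
    sub, _ = ms.canonical_reference_templates(list(reversed(chans)))
    np.testing.assert_allclose(sub, ms._normalize_maps(maps[:, ::-1]), atol=1e-12)
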