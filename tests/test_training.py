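"""Feedback-loop rules (reward, loss weight, stagnation, resampling) and
feature-level augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microfuse.network import ConvGRUNet, NetworkConfig
from microfuse.training import (
    DROPOUT_GRID, LR_GRID, L2_GRID,
    AugmentationConfig, FeedbackConfig, FeedbackController, TrainerConfig,
    compute_reward, update_loss_weight, weighted_bce, check_stagnation,
    resample_hparams, perturb_weight, augment_noise, augment_cutout,
    build_augmented_set, train_model, FeedbackState,
)


class TestRewardRules:
    @pytest.mark.parametrize("acc,loss,expected", [
        (0.9, 0.2, 0.7), (0.4, 0.4, 0.0), (0.5, 2.5, -2.0),
    ])
    def test_reward_arithmetic(self, acc, loss, expected):
        assert compute_reward(acc, loss) == pytest.approx(expected)

    def test_weight_update_arithmetic(self):
        assert update_loss_weight(1.0, 0.7, eta=0.1) == pytest.approx(1.07)

    def test_weight_clipped_above(self):
        assert update_loss_weight(1.9, 0.7, eta=1.0) == 2.0

    def test_weight_clipped_below(self):
        assert update_loss_weight(0.5, -3.0, eta=1.0) == 0.5

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=50))
    def test_weight_always_in_bounds(self, rewards):
        w = 1.0
        for R in rewards:
            w = update_loss_weight(w, R)
            assert 0.5 <= w <= 2.0

    def test_weighted_bce_closed_forms(self):
        y = np.array([1.0])
        assert weighted_bce(y, np.array([0.5]), 1.0) == pytest.approx(np.log(2))
        assert weighted_bce(y, np.array([0.5]), 2.0) == pytest.approx(2 * np.log(2))
        assert weighted_bce(y, np.array([1.0 - 1e-7]), 1.7) < 1e-6

    def test_weighted_bce_clamps_extreme_probs(self):
        assert np.isfinite(weighted_bce(np.array([1.0]), np.array([0.0]), 1.0))


class TestStagnation:
    def test_trace_triggers_at_T_nonimproving(self):
        ctrl = FeedbackController(FeedbackConfig(epsilon=0.001, t_stag=3), seed=0)
        actions = [ctrl.epoch_feedback(0.8, 0.1)["action"] for _ in range(4)]
        # epoch 0 improves (best -inf -> 0.8); epochs 1..3 stagnate; trigger at 3
        assert actions == ["none", "none", "none", "perturb"]

    def test_never_triggers_on_improvement(self):
        ctrl = FeedbackController(FeedbackConfig(epsilon=0.001, t_stag=3), seed=0)
        for i, acc in enumerate(np.linspace(0.5, 0.9, 10)):
            assert ctrl.epoch_feedback(acc, 0.1)["action"] == "none"

    def test_counter_resets_on_midway_improvement(self):
        ctrl = FeedbackController(FeedbackConfig(epsilon=0.001, t_stag=3), seed=0)
        accs = [0.8, 0.8, 0.85, 0.85, 0.85]  # improvement at index 2 resets
        actions = [ctrl.epoch_feedback(a, 0.1)["action"] for a in accs]
        assert "perturb" not in actions

    def test_flat_curve_alternates_perturb_then_reinit(self):
        ctrl = FeedbackController(FeedbackConfig(t_stag=5), seed=0)
        actions = [ctrl.epoch_feedback(0.7, 0.3)["action"] for _ in range(21)]
        # improvement at epoch 0; perturb after 5 stagnant epochs, reinit
        # after 5 more, then the cycle repeats
        assert actions[5] == "perturb"
        assert actions[10] == "reinit"
        assert actions[15] == "perturb"  # counter restarted after the reinit
        assert actions[20] == "reinit"
        assert actions.count("reinit") == 2

    def test_check_stagnation_updates_best(self):
        st_ = FeedbackState(w=1.0)
        assert not check_stagnation(st_, 0.8, 0.001)
        assert st_.best_val_acc == 0.8
        assert check_stagnation(st_, 0.8, 0.001)
        assert st_.stagnation_count == 1


class TestSampling:
    def test_hparams_in_grids(self):
        for seed in range(50):
            hp = resample_hparams(seed)
            assert hp["dropout"] in DROPOUT_GRID
            assert hp["lr"] in LR_GRID
            assert hp["l2"] in L2_GRID

    def test_hparams_uniform(self):
        draws = [resample_hparams(s)["dropout"] for s in range(10_000)]
        for v in DROPOUT_GRID:
            assert np.mean(np.array(draws) == v) == pytest.approx(0.25, abs=0.02)

    def test_hparams_deterministic(self):
        assert resample_hparams(7) == resample_hparams(7)

    def test_perturb_bounds_and_mean(self):
        draws = np.array([perturb_weight(s) for s in range(10_000)])
        assert draws.min() >= 0.7 and draws.max() <= 1.3
        assert draws.mean() == pytest.approx(1.0, abs=0.01)
        assert perturb_weight(3) == perturb_weight(3)


class TestAugmentation:
    def test_zero_sigma_identity(self, rng):
        X = rng.standard_normal((5, 10))
        np.testing.assert_array_equal(augment_noise(X, 0.0, 1), X)

    def test_noise_sd_matches_sigma(self, rng):
        X = np.zeros((200, 500))
        noisy = augment_noise(X, 0.05, seed=2)
        assert noisy.std() == pytest.approx(0.05, rel=0.02)

    def test_noise_seeds_differ(self):
        X = np.zeros((2, 10))
        assert not np.array_equal(augment_noise(X, 0.1, 1), augment_noise(X, 0.1, 2))

    def test_cutout_exact_length(self):
        X = np.ones((20, 50))
        cut = augment_cutout(X, 0.1, seed=0)
        for row in cut:
            zeros = np.nonzero(row == 0)[0]
            assert len(zeros) == 5
            assert zeros[-1] - zeros[0] == 4  # contiguous

    def test_cutout_zero_fraction_identity(self, rng):
        X = rng.standard_normal((4, 30))
        np.testing.assert_array_equal(augment_cutout(X, 0.0, 1), X)

    def test_cutout_sum_drop(self):
        X = np.ones((10, 40))
        assert augment_cutout(X, 0.1, seed=1).sum() == X.sum() - 10 * 4

    def test_triples_dataset(self, rng):
        X = rng.standard_normal((10, 20))
        y = rng.integers(0, 2, 10)
        Xa, ya = build_augmented_set(X, y, AugmentationConfig(), seed=5)
        assert Xa.shape == (30, 20) and ya.shape == (30,)
        np.testing.assert_array_equal(Xa[:10], X)
        np.testing.assert_array_equal(ya, np.concatenate([y, y, y]))

    def test_class_proportions_preserved(self, rng):
        y = np.array([0, 0, 0, 1])
        X = rng.standard_normal((4, 8))
        _, ya = build_augmented_set(X, y, AugmentationConfig(), seed=0)
        assert ya.mean() == y.mean()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_augmented_set(np.zeros((0, 5)), np.zeros(0), AugmentationConfig(), 0)


class TestControllerTrajectory:
    def test_w_trajectory_matches_hand_trace(self):
        """Scripted validation curve reproduces the closed-loop arithmetic."""
        cfg = FeedbackConfig(eta=0.1, epsilon=0.001, t_stag=100)
        ctrl = FeedbackController(cfg, seed=0)
        curve = [(0.6, 0.5), (0.7, 0.4), (0.7, 0.45), (0.9, 0.1)]
        expected_w = []
        w = 1.0
        for acc, loss in curve:
            w = float(np.clip(w + 0.1 * (acc - loss), 0.5, 2.0))
            expected_w.append(w)
        got = [ctrl.epoch_feedback(a, l)["w"] for a, l in curve]
        np.testing.assert_allclose(got, expected_w, atol=1e-12)


class TestTrainModel:
    def _data(self, rng):
        y = rng.integers(0, 2, 40).astype(float)
        X = rng.standard_normal((40, 8)) * 0.5 + (2 * y - 1)[:, None]
        return X, y

    def _model(self, seed=0):
        return ConvGRUNet(NetworkConfig(input_steps=8, conv_filters_1=2, conv_filters_2=4,
                               gru_units=4, dense_units=4, dropout_rate=0.1), seed=seed)

    def test_reproducible_logs(self, rng):
        X, y = self._data(rng)
        logs = []
        for _ in range(2):
            res = train_model(self._model(1), X[:30], y[:30], X[30:], y[30:],
                              trainer=TrainerConfig(max_epochs=8, batch_size=8, seed=3))
            logs.append(res.log)
        assert logs[0] == logs[1]

    def test_single_class_split_rejected(self, rng):
        X, _ = self._data(rng)
        with pytest.raises(ValueError):
            train_model(self._model(), X[:10], np.zeros(10), X[10:15], np.ones(5),
                        trainer=TrainerConfig(max_epochs=1))

    def test_log_contains_feedback_fields(self, rng):
        X, y = self._data(rng)
        res = train_model(self._model(), X[:30], y[:30], X[30:], y[30:],
                          trainer=TrainerConfig(max_epochs=3, batch_size=8, seed=0))
        assert {"epoch", "val_acc", "val_loss", "R", "w", "action"} <= set(res.log[0])
        assert all(0.5 <= e["w"] <= 2.0 for e in res.log)

    def test_reinit_changes_weights_and_resamples(self, rng):
        X, y = self._data(rng)
        # flat validation performance forces reinit quickly with tiny T
        res = train_model(
            self._model(), X[:30], y[:30], X[30:], y[30:],
            trainer=TrainerConfig(max_epochs=12, batch_size=8, seed=0,
                                  early_stop_patience=100, lr=0.0),
            feedback=FeedbackConfig(t_stag=2),
        )
        actions = [e["action"] for e in res.log]
        assert "perturb" in actions and "reinit" in actions
        reinit_entry = res.log[actions.index("reinit")]
        assert "reinit_seed" in reinit_entry
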