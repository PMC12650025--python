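"""Feedback-driven training loop and feature-level augmentation.

Performance-feedback parameter optimisation (closed loop)
---------------------------------------------------------
After each epoch a reward ``R = val_acc - val_loss`` is computed from the
validation split; the loss weight follows ``w ← clip(w + η·R, 0.5, 2.0)``
and scales the binary cross-entropy used for optimisation.  Stagnation —
``val_acc ≤ best + ε`` for ``T`` consecutive epochs — triggers escalating
interventions: first a perturbation reset of the loss weight
(``w ~ U(0.7, 1.3)``), then, if stagnation persists another ``T`` epochs,
hyperparameter resampling from the preset grids

    dropout ∈ {0.4, 0.5, 0.6, 0.7}
    learning rate ∈ {1e-3, 1e-4, 5e-5}
    L2 ∈ {1e-3, 5e-4, 1e-4}

together with a full network re-initialisation (fresh derived seed, fresh
optimiser — clean-restart semantics; the early-stopping patience counter
also resets, since a reinitialised network is a new trajectory).  The
validation loss entering the reward is the *unweighted* BCE so rewards are
comparable across loss-weight values.

Feature-level augmentation
--------------------------
The training split (never validation/test) is tripled: the original rows,
a Gaussian-noise copy (σ = 0.05 on the standardised features) and a cutout
copy (a random contiguous 10% of each vector zeroed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .network import ConvGRUNet, NetworkConfig, Adam, binary_cross_entropy

__all__ = [
    "AugmentationConfig",
    "FeedbackConfig",
    "FeedbackState",
    "FeedbackController",
    "TrainerConfig",
    "TrainResult",
    "compute_reward",
    "update_loss_weight",
    "weighted_bce",
    "check_stagnation",
    "resample_hparams",
    "perturb_weight",
    "augment_noise",
    "augment_cutout",
    "build_augmented_set",
    "train_model",
]

DROPOUT_GRID = (0.4, 0.5, 0.6, 0.7)
LR_GRID = (1e-3, 1e-4, 5e-5)
L2_GRID = (1e-3, 5e-4, 1e-4)


# ---------------------------------------------------------------------------
# feedback rules (each exposed as a pure function, then composed)
# ---------------------------------------------------------------------------

def compute_reward(val_acc: float, val_loss: float) -> float:
    """Reward ``R = val_acc - val_loss`` (can be negative, unbounded below)."""
    if not 0 <= val_acc <= 1:
        raise ValueError("val_acc must be in [0, 1]")
    if val_loss < 0:
        raise ValueError("val_loss must be nonnegative")
    return val_acc - val_loss


def update_loss_weight(w: float, R: float, eta: float = 0.1,
                       w_min: float = 0.5, w_max: float = 2.0) -> float:
    """``w ← clip(w + η·R, w_min, w_max)``."""
    return float(np.clip(w + eta * R, w_min, w_max))


def weighted_bce(y_true: np.ndarray, y_pred: np.ndarray, w: float) -> float:
    """``w`` times the mean binary cross-entropy (probabilities clamped)."""
    return w * binary_cross_entropy(y_true, y_pred)


def resample_hparams(seed: int) -> dict[str, float]:
    """Uniform draw from the preset dropout / learning-rate / L2 grids."""
    rng = np.random.default_rng(seed)
    return {
        "dropout": float(rng.choice(DROPOUT_GRID)),
        "lr": float(rng.choice(LR_GRID)),
        "l2": float(rng.choice(L2_GRID)),
    }


def perturb_weight(seed: int) -> float:
    """Perturbation reset of the loss weight: ``w ~ U(0.7, 1.3)``."""
    return float(np.random.default_rng(seed).uniform(0.7, 1.3))


@dataclass
class FeedbackConfig:
    eta: float = 0.1
    epsilon: float = 1e-3
    t_stag: int = 10
    w_init: float = 1.0
    w_min: float = 0.5
    w_max: float = 2.0


@dataclass
class FeedbackState:
    """Mutable state of the feedback loop."""

    w: float = 1.0
    best_val_acc: float = -np.inf
    stagnation_count: int = 0
    escalation_stage: int = 0        # 0: next trigger perturbs w; 1: next reinitialises
    hparam_sample: dict = field(default_factory=dict)
    reward_history: list = field(default_factory=list)


def check_stagnation(state: FeedbackState, val_acc: float, epsilon: float) -> bool:
    """Update the stagnation counter; True if this epoch did *not* improve.

    Improvement (``val_acc > best + ε``) resets the counter and the
    escalation stage and records the new best.
    """
    if val_acc > state.best_val_acc + epsilon:
        state.best_val_acc = val_acc
        state.stagnation_count = 0
        state.escalation_stage = 0
        return False
    state.stagnation_count += 1
    return True


class FeedbackController:
    """Composes the feedback rules into the per-epoch closed loop.

    :meth:`epoch_feedback` returns the action to take this epoch:
    ``"none"``, ``"perturb"`` (loss weight was resampled in [0.7, 1.3]) or
    ``"reinit"`` (fresh hyperparameters in ``hparam_sample``; the caller
    must reinitialise the network and optimiser).
    """

    def __init__(self, config: FeedbackConfig | None = None, seed: int = 0) -> None:
        self.config = config or FeedbackConfig()
        self.state = FeedbackState(w=self.config.w_init)
        self._seeds = np.random.SeedSequence(seed)

    def _next_seed(self) -> int:
        child = self._seeds.spawn(1)[0]
        return int(child.generate_state(1)[0] % (2 ** 31))

    def epoch_feedback(self, val_acc: float, val_loss: float) -> dict:
        cfg, st = self.config, self.state
        R = compute_reward(val_acc, val_loss)
        st.reward_history.append(R)
        st.w = update_loss_weight(st.w, R, cfg.eta, cfg.w_min, cfg.w_max)
        action = "none"
        check_stagnation(st, val_acc, cfg.epsilon)
        if st.stagnation_count > 0 and st.stagnation_count % cfg.t_stag == 0:
            if st.escalation_stage == 0:
                st.w = perturb_weight(self._next_seed())
                st.escalation_stage = 1
                action = "perturb"
            else:
                st.hparam_sample = resample_hparams(self._next_seed())
                st.stagnation_count = 0
                st.escalation_stage = 0
                action = "reinit"
        return {"R": R, "w": st.w, "action": action,
                "best_val_acc": st.best_val_acc,
                "stagnation_count": st.stagnation_count}


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationConfig:
    noise_sd: float = 0.05
    cutout_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.cutout_fraction < 1:
            raise ValueError("cutout_fraction must be in [0, 1)")


def augment_noise(X: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. Gaussian noise ``N(0, σ²)`` elementwise."""
    X = np.asarray(X, dtype=float)
    if sigma == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X + rng.normal(0.0, sigma, size=X.shape)


def augment_cutout(X: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Zero a random contiguous segment of length ``round(fraction·T)``
    (at least 1 when the fraction is positive) in each row."""
    X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
    if fraction == 0:
        return X
    T = X.shape[1]
    L = max(1, int(round(fraction * T)))
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, T - L + 1, size=X.shape[0])
    for i, s in enumerate(starts):
        X[i, s:s + L] = 0.0
    return X


def build_augmented_set(
    X: np.ndarray, y: np.ndarray, config: AugmentationConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """``[X, X+noise, cutout(X)]`` with labels replicated: N → 3N rows.

    The first N rows are the originals, unchanged.  Apply to the training
    split only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if len(X) == 0:
        raise ValueError("empty training set")
    ss = np.random.SeedSequence(seed).spawn(2)
    s_noise, s_cut = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss]
    X_aug = np.concatenate(
        [X, augment_noise(X, config.noise_sd, s_noise),
         augment_cutout(X, config.cutout_fraction, s_cut)], axis=0
    )
    y_aug = np.concatenate([y, y, y])
    return X_aug, y_aug


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainerConfig:
    lr: float = 1e-4
    l2: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 500
    early_stop_patience: int = 50
    use_feedback: bool = True
    use_augmentation: bool = True
    seed: int = 0


@dataclass
class TrainResult:
    model: ConvGRUNet
    log: list[dict]
    best_val_acc: float
    best_epoch: int


def _accuracy(y_true: np.ndarray, probs: np.ndarray) -> float:
    return float(((probs >= 0.5).astype(int) == np.asarray(y_true).astype(int)).mean())


def train_model(
    model: ConvGRUNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    trainer: TrainerConfig | None = None,
    feedback: FeedbackConfig | None = None,
    augmentation: AugmentationConfig | None = None,
) -> TrainResult:
    """Closed-loop training of a ConvGRUNet on fused feature vectors.

    Per epoch: minibatch Adam on the (augmented) training split with the
    reward-weighted BCE, then validation evaluation, reward computation,
    loss-weight update and stagnation checking.  A ``reinit`` action swaps
    in the resampled dropout / learning rate / L2, reinitialises all
    weights with a fresh derived seed and restarts the optimiser.  The
    best-validation-accuracy weights are restored at the end.  Fully
    reproducible for a fixed ``(seed, data)``.
    """
    tcfg = trainer or TrainerConfig()
    y_train = np.asarray(y_train).astype(float)
    y_val = np.asarray(y_val).astype(float)
    for name, yy in (("train", y_train), ("val", y_val)):
        if len(np.unique(yy)) < 2:
            raise ValueError(f"{name} split contains a single class")

    ss = np.random.SeedSequence(tcfg.seed)
    s_aug, s_ctrl, s_loop = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3)]
    rng = np.random.default_rng(s_loop)

    if tcfg.use_augmentation:
        X_fit, y_fit = build_augmented_set(
            X_train, y_train, augmentation or AugmentationConfig(), s_aug
        )
    else:
        X_fit, y_fit = np.asarray(X_train, dtype=float), y_train

    controller = FeedbackController(feedback, seed=s_ctrl)
    opt = Adam(model.params, lr=tcfg.lr, l2=tcfg.l2)
    log: list[dict] = []
    best_acc, best_epoch, patience = -np.inf, -1, 0
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_bn = _bn_snapshot(model)
    n = len(X_fit)

    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs >1 sample
            _, grads, _ = model.loss_and_grads(
                X_fit[idx], y_fit[idx],
                loss_weight=controller.state.w if tcfg.use_feedback else 1.0,
                rng=rng, training=True,
            )
            opt.step(model.params, grads)

        val_probs = model.predict_proba(X_val)
        val_acc = _accuracy(y_val, val_probs)
        val_loss = binary_cross_entropy(y_val, val_probs)  # unweighted
        entry = {"epoch": epoch, "val_acc": val_acc, "val_loss": val_loss}

        if tcfg.use_feedback:
            fb = controller.epoch_feedback(val_acc, val_loss)
            entry.update(fb)
            if fb["action"] == "reinit":
                hp = controller.state.hparam_sample
                model.config.dropout_rate = hp["dropout"]
                reinit_seed = int(rng.integers(2 ** 31))
                model.init_params(reinit_seed)
                opt = Adam(model.params, lr=hp["lr"], l2=hp["l2"])
                patience = 0
                entry["reinit_seed"] = reinit_seed
        log.append(entry)

        if val_acc > best_acc:
            best_acc, best_epoch, patience = val_acc, epoch, 0
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_bn = _bn_snapshot(model)
        else:
            patience += 1
            if patience >= tcfg.early_stop_patience:
                break

    model.params = best_params
    _bn_restore(model, best_bn)
    return TrainResult(model=model, log=log, best_val_acc=best_acc, best_epoch=best_epoch)


def _bn_snapshot(model: ConvGRUNet) -> tuple:
    return (model.bn1.running_mean.copy(), model.bn1.running_var.copy(),
            model.bn2.running_mean.copy(), model.bn2.running_var.copy())


def _bn_restore(model: ConvGRUNet, snap: tuple) -> None:
    model.bn1.running_mean, model.bn1.running_var = snap[0].copy(), snap[1].copy()
    model.bn2.running_mean, model.bn2.running_var = snap[2].copy(), snap[3].copy()
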