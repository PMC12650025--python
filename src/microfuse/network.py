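"""CNN-GRU parallel classifier, implemented in NumPy.

Architecture
------------
The fused feature vector enters as a length-T sequence with D=1 channels.
Two branches process it in parallel:

* convolutional branch: SeparableConv1D(k=3) → BatchNorm → ReLU →
  SeparableConv1D(k=5) → BatchNorm, plus a 1×1-convolution residual
  shortcut from the input added before the final ReLU; then max pooling,
  flattening and dropout;
* recurrent branch: a standard GRU
  (``z_t = σ(W_z x_t + U_z h_{t-1} + b_z)`` etc., ``h_0 = 0``) whose last
  hidden state is taken, with dropout.

The branch outputs are concatenated and passed through a ReLU dense layer
with dropout and a single sigmoid output neuron giving the case-class
probability.

Forward, backward (including batch-norm and backprop-through-time) and the
Adam optimiser are written directly in NumPy; the gradients are verified
against central finite differences in the test suite.  Inference is
deterministic (dropout disabled, running batch-norm statistics); training
stochasticity is fully controlled by seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkConfig", "ConvGRUNet", "Adam", "count_params", "sigmoid", "binary_cross_entropy"]

PROB_CLIP = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Mean BCE with probabilities clamped away from exactly 0/1."""
    p = np.clip(np.asarray(y_prob, dtype=float), PROB_CLIP, 1.0 - PROB_CLIP)
    y = np.asarray(y_true, dtype=float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    Kernel sizes are fixed (3, 5 and a 1×1 residual); widths are
    configurable — the defaults put the trainable-parameter count in the
    low-hundreds-of-thousands range for a ~70-step input.
    """

    input_steps: int = 68
    input_dim: int = 1
    conv_filters_1: int = 32
    conv_filters_2: int = 64
    pool_size: int = 2
    gru_units: int = 64
    dense_units: int = 64
    dropout_rate: float = 0.5
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3

    def __post_init__(self) -> None:
        if self.input_steps < 5:
            raise ValueError("input_steps must be >= 5 (largest kernel)")
        for w in (self.conv_filters_1, self.conv_filters_2, self.pool_size,
                  self.gru_units, self.dense_units, self.input_dim):
            if w < 1:
                raise ValueError("all widths must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def flat_dim(self) -> int:
        return (self.input_steps // self.pool_size) * self.conv_filters_2

    @property
    def concat_dim(self) -> int:
        return self.flat_dim + self.gru_units


def count_params(config: NetworkConfig) -> int:
    """Exact trainable-parameter count from shape arithmetic."""
    c = config
    D, f1, f2, U, dd = c.input_dim, c.conv_filters_1, c.conv_filters_2, c.gru_units, c.dense_units
    sep3 = 3 * D + D * f1 + f1
    bn1 = 2 * f1
    sep5 = 5 * f1 + f1 * f2 + f2
    bn2 = 2 * f2
    res = D * f2 + f2
    gru = 3 * (D * U + U * U + U)
    fc1 = (c.flat_dim + U) * dd + dd
    fc2 = dd + 1
    return sep3 + bn1 + sep5 + bn2 + res + gru + fc1 + fc2


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------

def _depthwise(x: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Same-padded depthwise 1-D convolution; x (B,T,C), K (k,C)."""
    k = K.shape[0]
    pad = k // 2
    T = x.shape[1]
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    out = np.zeros_like(x, shape=(x.shape[0], T, x.shape[2]))
    for j in range(k):
        out += xp[:, j:j + T, :] * K[j]
    return out


def _depthwise_backward(dout: np.ndarray, x: np.ndarray, K: np.ndarray):
    k = K.shape[0]
    pad = k // 2
    T = x.shape[1]
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    dK = np.zeros_like(K)
    dxp = np.zeros_like(xp)
    for j in range(k):
        dK[j] = (dout * xp[:, j:j + T, :]).sum(axis=(0, 1))
        dxp[:, j:j + T, :] += dout * K[j]
    return dK, dxp[:, pad:pad + T, :]


class _BatchNorm:
    """Per-channel batch normalisation over the (batch, time) axes."""

    def __init__(self, n_ch: int, momentum: float, eps: float) -> None:
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x, gamma, beta, training):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        cache = (x, xhat, mu, inv, gamma, training)
        return gamma * xhat + beta, cache

    @staticmethod
    def backward(dy, cache):
        x, xhat, mu, inv, gamma, training = cache
        dgamma = (dy * xhat).sum(axis=(0, 1))
        dbeta = dy.sum(axis=(0, 1))
        dxhat = dy * gamma
        if not training:
            return dxhat * inv, dgamma, dbeta
        N = x.shape[0] * x.shape[1]
        dvar = (dxhat * (x - mu)).sum(axis=(0, 1)) * (-0.5) * inv ** 3
        dmu = -(dxhat.sum(axis=(0, 1))) * inv
        dx = dxhat * inv + dvar * 2.0 * (x - mu) / N + dmu / N
        return dx, dgamma, dbeta


def _dropout_mask(shape, rate, rng):
    if rate <= 0 or rng is None:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _apply_mask(x, mask):
    return x if mask is None else x * mask


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ConvGRUNet:
    """Two-branch separable-convolution / GRU classifier."""

    def __init__(self, config: NetworkConfig, seed: int = 0) -> None:
        self.config = config
        self.bn1 = _BatchNorm(config.conv_filters_1, config.bn_momentum, config.bn_eps)
        self.bn2 = _BatchNorm(config.conv_filters_2, config.bn_momentum, config.bn_eps)
        self.params: dict[str, np.ndarray] = {}
        self.init_params(seed)

    # -- initialisation ----------------------------------------------------

    def init_params(self, seed: int) -> None:
        """(Re-)initialise all weights: Glorot-uniform kernels/dense,
        orthogonal GRU recurrence, zero biases, unit batch-norm scale."""
        c = self.config
        rng = np.random.default_rng(seed)

        def glorot(shape, fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        def orthogonal(n):
            q, r = np.linalg.qr(rng.standard_normal((n, n)))
            return q * np.sign(np.diag(r))

        D, f1, f2, U, dd = c.input_dim, c.conv_filters_1, c.conv_filters_2, c.gru_units, c.dense_units
        p = {
            "dw1": glorot((3, D), 3, 1),
            "pw1": glorot((D, f1), D, f1),
            "pw1_b": np.zeros(f1),
            "bn1_gamma": np.ones(f1), "bn1_beta": np.zeros(f1),
            "dw2": glorot((5, f1), 5, 1),
            "pw2": glorot((f1, f2), f1, f2),
            "pw2_b": np.zeros(f2),
            "bn2_gamma": np.ones(f2), "bn2_beta": np.zeros(f2),
            "res_w": glorot((D, f2), D, f2),
            "res_b": np.zeros(f2),
            "fc1_w": glorot((c.concat_dim, dd), c.concat_dim, dd),
            "fc1_b": np.zeros(dd),
            "fc2_w": glorot((dd, 1), dd, 1),
            "fc2_b": np.zeros(1),
        }
        for gate in ("z", "r", "h"):
            p[f"W{gate}"] = glorot((D, U), D, U)
            p[f"U{gate}"] = orthogonal(U)
            p[f"b{gate}"] = np.zeros(U)
        self.params = p
        self.bn1 = _BatchNorm(f1, c.bn_momentum, c.bn_eps)
        self.bn2 = _BatchNorm(f2, c.bn_momentum, c.bn_eps)

    @property
    def num_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward -----------------------------------------------------------

    def _as_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        if X.shape[1] != self.config.input_steps or X.shape[2] != self.config.input_dim:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match config "
                f"({self.config.input_steps}, {self.config.input_dim})"
            )
        if not np.isfinite(X).all():
            raise ValueError("non-finite network input")
        return X

    def _check_state(self) -> None:
        for k, v in self.params.items():
            if not np.isfinite(v).all():
                raise FloatingPointError(f"non-finite weights in {k}")

    def _cnn_forward(self, X, training, rng, cache):
        p = self.params
        c = self.config
        a1 = _depthwise(X, p["dw1"])
        c1 = a1 @ p["pw1"] + p["pw1_b"]
        bn1_out, bn1_cache = self.bn1.forward(c1, p["bn1_gamma"], p["bn1_beta"], training)
        H1 = np.maximum(bn1_out, 0.0)
        a2 = _depthwise(H1, p["dw2"])
        c2 = a2 @ p["pw2"] + p["pw2_b"]
        H2, bn2_cache = self.bn2.forward(c2, p["bn2_gamma"], p["bn2_beta"], training)
        Hres = X @ p["res_w"] + p["res_b"]
        S = H2 + Hres
        Hcnn = np.maximum(S, 0.0)
        # max pooling (truncating the tail that does not fill a window)
        ps = c.pool_size
        Tp = Hcnn.shape[1] // ps
        pooled_in = Hcnn[:, :Tp * ps, :].reshape(Hcnn.shape[0], Tp, ps, -1)
        arg = pooled_in.argmax(axis=2)
        pooled = np.take_along_axis(pooled_in, arg[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(pooled.shape[0], -1)
        mask = _dropout_mask(flat.shape, c.dropout_rate if training else 0.0, rng)
        F_cnn = _apply_mask(flat, mask)
        cache.update(
            X=X, a1=a1, bn1_cache=bn1_cache, bn1_out=bn1_out, H1=H1, a2=a2,
            bn2_cache=bn2_cache, S=S, Hcnn_shape=Hcnn.shape, pool_arg=arg,
            Tp=Tp, cnn_mask=mask,
        )
        return F_cnn

    def _gru_forward(self, X, training, rng, cache):
        p = self.params
        B, T, _ = X.shape
        U = self.config.gru_units
        h = np.zeros((B, U))
        steps = []
        for t in range(T):
            x_t = X[:, t, :]
            z = sigmoid(x_t @ p["Wz"] + h @ p["Uz"] + p["bz"])
            r = sigmoid(x_t @ p["Wr"] + h @ p["Ur"] + p["br"])
            hh = np.tanh(x_t @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
            h_new = (1 - z) * h + z * hh
            steps.append((x_t, h, z, r, hh))
            h = h_new
        mask = _dropout_mask(h.shape, self.config.dropout_rate if training else 0.0, rng)
        F_gru = _apply_mask(h, mask)
        cache.update(gru_steps=steps, gru_mask=mask)
        return F_gru

    def forward(self, X, training: bool = False, rng: np.random.Generator | None = None):
        """Full forward pass; returns ``(probabilities, cache)``.

        ``training=True`` activates dropout (requires ``rng``) and batch
        statistics in the normalisation layers; inference uses running
        statistics and is fully deterministic.
        """
        self._check_state()
        X = self._as_input(X)
        p = self.params
        cache: dict = {}
        F_cnn = self._cnn_forward(X, training, rng, cache)
        F_gru = self._gru_forward(X, training, rng, cache)
        F = np.concatenate([F_cnn, F_gru], axis=1)
        z1 = F @ p["fc1_w"] + p["fc1_b"]
        a = np.maximum(z1, 0.0)
        mask = _dropout_mask(a.shape, self.config.dropout_rate if training else 0.0, rng)
        ad = _apply_mask(a, mask)
        logit = ad @ p["fc2_w"] + p["fc2_b"]
        # clamp away from exactly 0/1 (saturated sigmoid in float arithmetic)
        prob = np.clip(sigmoid(logit[:, 0]), PROB_CLIP, 1.0 - PROB_CLIP)
        cache.update(F=F, z1=z1, ad=ad, head_mask=mask, prob=prob)
        return prob, cache

    def cnn_branch(self, X, training: bool = False, rng=None) -> np.ndarray:
        """Local convolutional representation F_cnn (flattened, pooled)."""
        return self._cnn_forward(self._as_input(X), training, rng, {})

    def gru_branch(self, X, training: bool = False, rng=None) -> np.ndarray:
        """Last GRU hidden state (dropout in training mode)."""
        return self._gru_forward(self._as_input(X), training, rng, {})

    def predict_proba(self, X) -> np.ndarray:
        return self.forward(X, training=False)[0]

    # -- backward ----------------------------------------------------------

    def backward(self, cache, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter.

        ``dlogit`` is the loss gradient at the pre-sigmoid output, shape
        ``(B, 1)``.
        """
        p = self.params
        g = {k: np.zeros_like(v) for k, v in p.items()}

        # head
        g["fc2_w"] = cache["ad"].T @ dlogit
        g["fc2_b"] = dlogit.sum(axis=0)
        d_ad = dlogit @ p["fc2_w"].T
        da = _apply_mask(d_ad, cache["head_mask"])
        dz1 = da * (cache["z1"] > 0)
        g["fc1_w"] = cache["F"].T @ dz1
        g["fc1_b"] = dz1.sum(axis=0)
        dF = dz1 @ p["fc1_w"].T
        flat_dim = self.config.flat_dim
        dF_cnn = dF[:, :flat_dim]
        dF_gru = dF[:, flat_dim:]

        # cnn branch
        dflat = _apply_mask(dF_cnn, cache["cnn_mask"])
        B, T, f2 = cache["Hcnn_shape"]
        Tp, ps = cache["Tp"], self.config.pool_size
        dpooled = dflat.reshape(B, Tp, f2)
        dpool_in = np.zeros((B, Tp, ps, f2))
        np.put_along_axis(dpool_in, cache["pool_arg"][:, :, None, :],
                          dpooled[:, :, None, :], axis=2)
        dHcnn = np.zeros((B, T, f2))
        dHcnn[:, :Tp * ps, :] = dpool_in.reshape(B, Tp * ps, f2)
        dS = dHcnn * (cache["S"] > 0)
        # residual path
        X = cache["X"]
        g["res_w"] = np.tensordot(X, dS, axes=([0, 1], [0, 1]))
        g["res_b"] = dS.sum(axis=(0, 1))
        # second separable conv
        dc2, g["bn2_gamma"], g["bn2_beta"] = _BatchNorm.backward(dS, cache["bn2_cache"])
        g["pw2"] = np.tensordot(cache["a2"], dc2, axes=([0, 1], [0, 1]))
        g["pw2_b"] = dc2.sum(axis=(0, 1))
        da2 = dc2 @ p["pw2"].T
        g["dw2"], dH1 = _depthwise_backward(da2, cache["H1"], p["dw2"])
        dbn1 = dH1 * (cache["bn1_out"] > 0)
        dc1, g["bn1_gamma"], g["bn1_beta"] = _BatchNorm.backward(dbn1, cache["bn1_cache"])
        g["pw1"] = np.tensordot(cache["a1"], dc1, axes=([0, 1], [0, 1]))
        g["pw1_b"] = dc1.sum(axis=(0, 1))
        da1 = dc1 @ p["pw1"].T
        g["dw1"], _ = _depthwise_backward(da1, X, p["dw1"])

        # gru branch (backprop through time)
        dh = _apply_mask(dF_gru, cache["gru_mask"])
        for x_t, h_prev, z, r, hh in reversed(cache["gru_steps"]):
            dz = dh * (hh - h_prev)
            dhh = dh * z
            dh_prev = dh * (1 - z)
            dhh_pre = dhh * (1 - hh ** 2)
            g["Wh"] += x_t.T @ dhh_pre
            g["bh"] += dhh_pre.sum(axis=0)
            g["Uh"] += (r * h_prev).T @ dhh_pre
            drh = dhh_pre @ p["Uh"].T
            dr = drh * h_prev
            dh_prev += drh * r
            dz_pre = dz * z * (1 - z)
            dr_pre = dr * r * (1 - r)
            g["Wz"] += x_t.T @ dz_pre
            g["bz"] += dz_pre.sum(axis=0)
            g["Uz"] += h_prev.T @ dz_pre
            g["Wr"] += x_t.T @ dr_pre
            g["br"] += dr_pre.sum(axis=0)
            g["Ur"] += h_prev.T @ dr_pre
            dh = dh_prev + dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
        return g

    def loss_and_grads(self, X, y, loss_weight: float = 1.0,
                       rng: np.random.Generator | None = None,
                       training: bool = True):
        """Weighted BCE loss, its parameter gradients and the probabilities."""
        y = np.asarray(y, dtype=float)
        prob, cache = self.forward(X, training=training, rng=rng)
        loss = loss_weight * binary_cross_entropy(y, prob)
        dlogit = (loss_weight * (prob - y) / len(y))[:, None]
        grads = self.backward(cache, dlogit)
        return loss, grads, prob


class Adam:
    """Adam with optional decoupled-from-biases L2 regularisation.

    The L2 term ``l2 * ||W||²/2`` is applied to matrix/kernel parameters
    only (not biases or batch-norm scale/shift), added to the gradient as
    ``l2 * W``.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 l2: float = 0.0, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.l2, self.beta1, self.beta2, self.eps = lr, l2, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, w in params.items():
            gk = grads[k]
            if self.l2 > 0 and w.ndim >= 2 and not k.startswith("bn"):
                gk = gk + self.l2 * w
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
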