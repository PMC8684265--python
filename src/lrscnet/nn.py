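"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the pieces the similarity encoder needs — 3x3
same-padded convolution, per-channel batch normalization, ReLU, 2x2 max
pooling, global average pooling, fully connected layers, a 2-way
softmax/cross-entropy head, and SGD with momentum and L2 weight decay.
Parameters default to float32 (``DTYPE``) — the training loop is
memory-bandwidth bound, so halving the element size roughly halves the
epoch time — but every layer follows its input dtype, so the same code
paths run in float64 for finite-difference gradient checks.

Layout conventions: activations are ``(N, C, H, W)``; convolution
weights are stored as ``(C_in * 9, C_out)`` matrices acting on im2col
patches; fully connected weights are ``(in, out)``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

DTYPE = np.float32  # training/inference dtype; layers follow their input dtype
BN_EPS = 1e-5
BN_MOMENTUM = 0.1  # fraction of the batch statistic blended into the running stat


# ---------------------------------------------------------------------------
# 3x3 same-padded convolution as nine offset-accumulated BLAS products
# (avoids materializing im2col neighborhoods, which dominates runtime
# for these small feature maps)
# ---------------------------------------------------------------------------

def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution.  W: (C_in*9, C_out), b: (C_out,).

    The weight row ordering is c*9 + di*3 + dj for input channel c and
    kernel offset (di, dj).
    """
    N, C, H, Wd = x.shape
    F = W.shape[1]
    Wk = W.reshape(C, 3, 3, F)
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((N, H, Wd, F), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            # (N, C, H, W) shifted view x (C, F) -> (N, H, W, F)
            out += np.tensordot(
                xp[:, :, di : di + H, dj : dj + Wd], Wk[:, di, dj, :], axes=([1], [0])
            )
    out += b
    out = out.transpose(0, 3, 1, 2)
    return out, (xp, x.shape, W)


def conv3x3_backward(dout: np.ndarray, cache):
    xp, xshape, W = cache
    N, C, H, Wd = xshape
    F = W.shape[1]
    Wk = W.reshape(C, 3, 3, F)
    dW = np.empty((C, 3, 3, F), dtype=dout.dtype)
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    dout_nhwf = dout.transpose(0, 2, 3, 1)
    for di in range(3):
        for dj in range(3):
            xs = xp[:, :, di : di + H, dj : dj + Wd]
            dW[:, di, dj, :] = np.tensordot(xs, dout, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, di : di + H, dj : dj + Wd] += np.tensordot(
                dout_nhwf, Wk[:, di, dj, :], axes=([3], [1])
            ).transpose(0, 3, 1, 2)
    dx = dxp[:, :, 1 : 1 + H, 1 : 1 + Wd]
    return dx, dW.reshape(C * 9, F), db


# ---------------------------------------------------------------------------
# Batch normalization (per channel over N, H, W)
# ---------------------------------------------------------------------------

def bn_forward(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
):
    """Returns (out, cache, new_running_mean, new_running_var).

    Train mode normalizes with batch statistics and blends them into the
    running estimates; eval mode uses the running estimates, making
    inference deterministic.
    """
    g = gamma.reshape(1, -1, 1, 1)
    be = beta.reshape(1, -1, 1, 1)
    if train:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        new_rm = (1 - BN_MOMENTUM) * running_mean + BN_MOMENTUM * mean
        new_rv = (1 - BN_MOMENTUM) * running_var + BN_MOMENTUM * var
    else:
        mean, var = running_mean, running_var
        new_rm, new_rv = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mean.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
    out = g * xhat + be
    cache = (xhat, inv_std, gamma, train)
    return out, cache, new_rm, new_rv


def bn_backward(dout: np.ndarray, cache):
    xhat, inv_std, gamma, train = cache
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    g = gamma.reshape(1, -1, 1, 1)
    if not train:
        dx = dout * g * inv_std.reshape(1, -1, 1, 1)
        return dx, dgamma, dbeta
    N, C, H, W = dout.shape
    nb = N * H * W
    dxhat = dout * g
    mean_dxhat = dxhat.mean(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
    mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
    dx = inv_std.reshape(1, -1, 1, 1) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# Elementwise / pooling layers
# ---------------------------------------------------------------------------

def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""
    N, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    xt = x[:, :, : 2 * H2, : 2 * W2]
    win = xt.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H2, W2, 4)
    am = win.argmax(axis=-1)
    out = np.take_along_axis(win, am[..., None], axis=-1)[..., 0]
    return out, (am, x.shape)


def maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    am, xshape = cache
    N, C, H, W = xshape
    H2, W2 = H // 2, W // 2
    dwin = np.zeros((N, C, H2, W2, 4), dtype=dout.dtype)
    np.put_along_axis(dwin, am[..., None], dout[..., None], axis=-1)
    dx = np.zeros(xshape, dtype=dout.dtype)
    dx[:, :, : 2 * H2, : 2 * W2] = (
        dwin.reshape(N, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, 2 * H2, 2 * W2)
    )
    return dx


def gap_forward(x: np.ndarray):
    """Global average pooling: (N, C, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3)), x.shape


def gap_backward(dout: np.ndarray, xshape) -> np.ndarray:
    N, C, H, W = xshape
    return np.broadcast_to(dout[:, :, None, None], xshape) / (H * W)


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, (x, W)


def linear_backward(dout: np.ndarray, cache):
    x, W = cache
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


# ---------------------------------------------------------------------------
# Softmax / cross-entropy and the optimizer
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    probs = softmax(logits)
    N = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(N), labels], 1e-300, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(N), labels] -= 1.0
    return loss, dlogits / N


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    Weight decay is applied only to the parameter names listed in
    ``decay_params`` (convolution and fully connected weight matrices);
    biases and batch-norm affine parameters are not decayed.
    """

    def __init__(self, lr: float, momentum: float, weight_decay: float, decay_params: set[str]):
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.decay_params = decay_params
        self.velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for name, g in grads.items():
            if name in self.decay_params and self.weight_decay > 0:
                g = g + self.weight_decay * params[name]
            v = self.velocity.get(name)
            v = g if v is None else self.momentum * v + g
            self.velocity[name] = v
            params[name] -= self.lr * v
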