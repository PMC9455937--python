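"""Low-level numpy operators for the temporal convolutional autoencoder.

The network is a single temporal convolution (stride 1, zero same-padding)
with bias, factor-2 temporal max-pooling and ReLU; the decoder applies the
exact adjoint of the convolution after inverse pooling.  Because every
stage is either linear or piecewise linear, all gradients are closed-form
adjoints; they are validated against central-difference numerical gradients
in the test suite.

Shapes: inputs are (..., M, D) with M frames and D channels; weights are
(F, D, w) with F filters of odd width w; feature maps are (..., M, F).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _pad_time(x: np.ndarray, c: int) -> np.ndarray:
    pad = [(0, 0)] * x.ndim
    pad[-2] = (c, c)
    return np.pad(x, pad)


def conv_same(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Same-padded temporal convolution: (..., M, D) x (F, D, w) -> (..., M, F).

    ``out[t, f] = sum_{d, tau} W[f, d, tau] * x[t + tau - w//2, d]`` with
    zeros outside the sequence.
    """
    F, D, w = W.shape
    c = w // 2
    xp = _pad_time(x, c)
    win = sliding_window_view(xp, w, axis=-2)  # (..., M, D, w)
    return np.tensordot(win, W, axes=([-2, -1], [1, 2]))


def conv_adjoint(z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`conv_same` in the frame/channel axes.

    Equals convolution with the weight tensor reflected along the frame
    axis and transposed in the filter/channel axes — the decoder's
    "inverse convolution".
    """
    return conv_same(z, W[:, :, ::-1].transpose(1, 0, 2))


def conv_grad_w(x: np.ndarray, u: np.ndarray, w: int) -> np.ndarray:
    """Gradient of ``sum(u * conv_same(x, W))`` with respect to W.

    ``x`` is (..., M, D), ``u`` is (..., M, F); leading axes are summed.
    By symmetry of the trilinear form, this same primitive also yields the
    decoder's weight gradient with ``x = dXhat`` and ``u = G - b``.
    """
    c = w // 2
    xp = _pad_time(x, c)
    win = sliding_window_view(xp, w, axis=-2)  # (..., M, D, w)
    n_lead = u.ndim - 1
    axes_win = list(range(n_lead))
    out = np.tensordot(u, win, axes=(axes_win, axes_win))  # (F, D, w)
    return out


def maxpool2(z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Factor-2 max-pool along the frame axis (-2); odd tails keep the lone frame.

    Returns the pooled array (..., ceil(M/2), F) and the argmax offsets
    (0 or 1) needed to route gradients back.
    """
    m = z.shape[-2]
    u = (m + 1) // 2
    if m % 2:
        pad = [(0, 0)] * z.ndim
        pad[-2] = (0, 1)
        z = np.pad(z, pad, constant_values=-np.inf)
    pairs = z.reshape(z.shape[:-2] + (u, 2, z.shape[-1]))
    arg = np.argmax(pairs, axis=-2)
    pooled = np.take_along_axis(pairs, arg[..., None, :], axis=-2)[..., 0, :]
    return pooled, arg


def maxpool2_grad(dp: np.ndarray, arg: np.ndarray, m: int) -> np.ndarray:
    """Route pooled-gradients back to the argmax frame of each pair."""
    u = dp.shape[-2]
    full = np.zeros(dp.shape[:-2] + (u, 2, dp.shape[-1]), dtype=dp.dtype)
    np.put_along_axis(full, arg[..., None, :], dp[..., None, :], axis=-2)
    full = full.reshape(dp.shape[:-2] + (2 * u, dp.shape[-1]))
    return full[..., :m, :]


def unpool2(h: np.ndarray, m: int) -> np.ndarray:
    """Inverse max-pool: repeat each pooled value into two adjacent frames,
    truncated to ``m`` frames for odd-length sequences."""
    return np.repeat(h, 2, axis=-2)[..., :m, :]


def unpool2_adjoint(g: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`unpool2`: sum each adjacent pair of frame gradients."""
    m = g.shape[-2]
    u = (m + 1) // 2
    if m % 2:
        pad = [(0, 0)] * g.ndim
        pad[-2] = (0, 1)
        g = np.pad(g, pad)
    pairs = g.reshape(g.shape[:-2] + (u, 2, g.shape[-1]))
    return pairs.sum(axis=-2)


class Adam:
    """Adaptive moment estimation (Kingma & Ba) over a list of arrays."""

    def __init__(self, shapes, learning_rate=0.001, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.lr = learning_rate
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads):
        """Update parameter arrays in place from matching gradient arrays."""
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
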