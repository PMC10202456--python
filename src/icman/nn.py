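"""Minimal NumPy building blocks for the convolutional encoder.

Hand-written forward/backward passes for the handful of operations the
encoder needs: strided 1-D convolution with "same"-style padding, per-channel
PReLU, the symmetric log activation, learnable sinc (bandpass) kernels, and
an Adam optimizer. Everything runs in single precision; im2col views feed
BLAS matmuls so a scaled-down model trains in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


def pad_amounts(kernel: int, stride: int) -> tuple[int, int]:
    """Left/right padding so that out_len = in_len // stride (kernel >= stride)."""
    total = kernel - stride
    left = total // 2
    return left, total - left


def _im2col(xp: np.ndarray, kernel: int, stride: int, out_len: int) -> np.ndarray:
    """Strided view (B, C, out_len, kernel) of a padded (B, C, Tp) array."""
    sB, sC, sT = xp.strides
    return as_strided(xp, shape=(xp.shape[0], xp.shape[1], out_len, kernel),
                      strides=(sB, sC, sT * stride, sT), writeable=False)


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                   stride: int) -> tuple[np.ndarray, tuple]:
    """y[B,F,To] = conv(x[B,C,T], w[F,C,K]) + b, with To = T // stride."""
    B, C, T = x.shape
    F, _, K = w.shape
    if T % stride:
        raise ValueError("input length must be divisible by the stride")
    out_len = T // stride
    lp, rp = pad_amounts(K, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (lp, rp)))
    cols = _im2col(xp, K, stride, out_len)                    # B,C,To,K
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3))  # B,To,C,K
    cols2 = cols2.reshape(B, out_len, C * K)
    y = cols2 @ w.reshape(F, C * K).T + b
    cache = (cols2, x.shape, w.shape, stride, lp)
    return np.ascontiguousarray(y.transpose(0, 2, 1)), cache


def conv1d_backward(dy: np.ndarray, cache: tuple):
    """Gradients (dx, dw, db) of conv1d_forward."""
    cols2, x_shape, w_shape, stride, lp = cache
    B, C, T = x_shape
    F, _, K = w_shape
    out_len = T // stride
    dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1))     # B,To,F
    flat_dy = dy2.reshape(B * out_len, F)
    flat_cols = cols2.reshape(B * out_len, C * K)
    dw = (flat_dy.T @ flat_cols).reshape(F, C, K)
    db = flat_dy.sum(axis=0)
    return None, dw, db, (flat_dy, stride, lp, x_shape, K)


def conv1d_backward_input(w: np.ndarray, bwd_cache: tuple) -> np.ndarray:
    """Input gradient, split out so frozen front layers can skip it."""
    flat_dy, stride, lp, x_shape, K = bwd_cache
    B, C, T = x_shape
    F = w.shape[0]
    out_len = T // stride
    dcols = (flat_dy @ w.reshape(F, C * K)).reshape(B, out_len, C, K)
    dcols = dcols.transpose(0, 2, 1, 3)                  # B,C,To,K
    rp = (K - stride) - lp
    dxp = np.zeros((B, C, T + lp + rp), dtype=flat_dy.dtype)
    for k in range(K):
        dxp[:, :, k:k + out_len * stride:stride] += dcols[:, :, :, k]
    return dxp[:, :, lp:lp + T]


# -- activations ------------------------------------------------------------

def prelu_forward(x: np.ndarray, a: np.ndarray):
    """Per-channel PReLU; a has shape (C,) broadcast over (B, C, T)."""
    neg = x < 0
    y = np.where(neg, a[None, :, None] * x, x)
    return y, (x, neg)

def prelu_backward(dy: np.ndarray, a: np.ndarray, cache):
    x, neg = cache
    dx = np.where(neg, a[None, :, None], 1.0).astype(dy.dtype) * dy
    da = np.sum(dy * x * neg, axis=(0, 2))
    return dx, da


def symlog_forward(x: np.ndarray):
    """y = sign(x) * log(1 + |x|): odd, monotone, compresses dynamic range."""
    y = np.sign(x) * np.log1p(np.abs(x))
    return y, x

def symlog_backward(dy: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dy / (1.0 + np.abs(x))


# -- sinc (learnable bandpass) kernels --------------------------------------

MIN_LOW_HZ = 50.0
MIN_BAND_HZ = 50.0


def sinc_kernels(p_low: np.ndarray, p_band: np.ndarray, kernel: int,
                 rate_hz: float):
    """Bandpass FIR kernels from learnable edge parameters (SincNet style).

    Band edges: f1 = MIN_LOW + |p_low|, f2 = f1 + MIN_BAND + |p_band| (Hz),
    f2 capped at Nyquist. Kernels are the ideal bandpass impulse response on
    a half-integer-centered grid (even length, so no zero sample), under a
    Hamming window. Returns (kernels[F,1,K], cache for gradients).
    """
    nyq = rate_hz / 2.0
    f1 = MIN_LOW_HZ + np.abs(p_low)
    f2 = np.minimum(f1 + MIN_BAND_HZ + np.abs(p_band), 0.99 * nyq)
    n = (np.arange(kernel) - (kernel - 1) / 2.0) / rate_hz   # seconds
    win = np.hamming(kernel)
    arg2 = 2.0 * np.pi * np.outer(f2, n)
    arg1 = 2.0 * np.pi * np.outer(f1, n)
    base = (np.sin(arg2) - np.sin(arg1)) / (np.pi * n)[None, :]
    kernels = (base * win[None, :] / (2.0 * f2[:, None])).astype(np.float32)
    cache = (p_low, p_band, f1, f2, n, win, arg1, arg2, base, nyq)
    return kernels[:, None, :], cache


def sinc_kernel_grads(dkern: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray]:
    """Gradients w.r.t. (p_low, p_band) given dL/dkernels."""
    p_low, p_band, f1, f2, n, win, arg1, arg2, base, nyq = cache
    dk = dkern[:, 0, :].astype(np.float64)
    inv2f2 = 1.0 / (2.0 * f2[:, None])
    # d kernel / d f2 and / d f1 (kernel = base * win / (2 f2))
    dbase_df2 = 2.0 * np.cos(arg2)
    dbase_df1 = -2.0 * np.cos(arg1)
    dk_df2 = (dbase_df2 * win[None, :]) * inv2f2 - base * win[None, :] * (inv2f2 ** 2) * 2.0
    dk_df1 = (dbase_df1 * win[None, :]) * inv2f2
    g_f2 = np.sum(dk * dk_df2, axis=1)
    g_f1 = np.sum(dk * dk_df1, axis=1)
    capped = f2 >= 0.99 * nyq
    g_f2 = np.where(capped, 0.0, g_f2)
    # f1 = MIN_LOW + |p_low|; f2 = f1 + MIN_BAND + |p_band|
    g_plow = (g_f1 + g_f2) * np.sign(p_low)
    g_pband = g_f2 * np.sign(p_band)
    return g_plow.astype(np.float32), g_pband.astype(np.float32)


def mel_spaced_edges(n_filters: int, f_lo: float = 50.0, f_hi: float = 12000.0,
                     rate_hz: float = 24414.0625):
    """Mel-spaced initial (p_low, p_band) parameter values."""
    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    pts = imel(np.linspace(mel(f_lo), mel(min(f_hi, 0.95 * rate_hz / 2)),
                           n_filters + 2))
    lows, highs = pts[:-2], pts[2:]
    p_low = np.maximum(lows - MIN_LOW_HZ, 1.0)
    p_band = np.maximum(highs - lows - MIN_BAND_HZ, 1.0)
    return p_low.astype(np.float32), p_band.astype(np.float32)


# -- optimizer --------------------------------------------------------------

class Adam:
    """Adam over a dict of named parameter arrays (updated in place)."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.params:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
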