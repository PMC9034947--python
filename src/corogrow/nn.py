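"""A small NumPy convolutional encoder-decoder with manual backprop.

Sized to train on CPU in minutes on phantom axial slices: per encoder level a
single 3x3 convolution + ReLU followed by 2x2 average pooling; the decoder
mirrors it with nearest-neighbor upsampling and skip concatenation; a final
1x1 convolution + sigmoid yields per-pixel probabilities.  Trained with Adam
under the smoothed Dice loss.  All randomness flows from one integer seed, so
training is bit-reproducible.

Arrays are NCHW float32; input height/width must be divisible by
2**(depth-1).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded 3x3 (or 1x1) convolution; returns (output, cached patches)."""
    k = w.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    patches = sliding_window_view(xp, (k, k), axis=(2, 3))
    y = np.einsum("nchwij,ocij->nohw", patches, w, optimize=True) + b[None, :, None, None]
    return y.astype(np.float32), patches


def conv2d_backward(
    patches: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of a same-padded convolution."""
    k = w.shape[2]
    pad = k // 2
    dw = np.einsum("nchwij,nohw->ocij", patches, dy, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dyp = np.pad(dy, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else dy
    dy_patches = sliding_window_view(dyp, (k, k), axis=(2, 3))
    wflip = w[:, :, ::-1, ::-1]
    dx = np.einsum("nohwij,ocij->nchw", dy_patches, wflip, optimize=True)
    return dx.astype(np.float32), dw.astype(np.float32), db.astype(np.float32)


def avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


def upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def dice_loss_value_grad(
    pre: np.ndarray, lab: np.ndarray, smooth: float
) -> tuple[float, np.ndarray]:
    """Smoothed Dice loss over all pixels of the batch and its gradient w.r.t. pre."""
    num = 2.0 * float((lab * pre).sum()) + smooth
    den = float(pre.sum()) + float(lab.sum()) + smooth
    loss = 1.0 - num / den
    grad = -(2.0 * lab * den - num) / den**2
    return loss, grad.astype(np.float32)


class EncoderDecoder:
    """Encoder-decoder with skip connections; see module docstring."""

    def __init__(self, depth: int = 3, base_channels: int = 8, rng_seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        self.depth = depth
        self.base_channels = base_channels
        rng = np.random.default_rng(rng_seed)
        self.params: dict[str, np.ndarray] = {}
        chans = [base_channels * 2**i for i in range(depth)]
        in_c = 1
        for i, out_c in enumerate(chans):  # encoder (last level = bottleneck)
            self._init_conv(rng, f"enc{i}", in_c, out_c, 3)
            in_c = out_c
        for i in range(depth - 2, -1, -1):  # decoder
            self._init_conv(rng, f"dec{i}", in_c + chans[i], chans[i], 3)
            in_c = chans[i]
        self._init_conv(rng, "out", in_c, 1, 1)

    def _init_conv(self, rng, name: str, in_c: int, out_c: int, k: int) -> None:
        # He initialization for ReLU layers
        std = np.sqrt(2.0 / (in_c * k * k))
        self.params[f"{name}_w"] = rng.normal(0, std, (out_c, in_c, k, k)).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(out_c, dtype=np.float32)

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        p = self.params
        skips: list[np.ndarray] = []
        acts: dict[str, np.ndarray] = {}
        patches: dict[str, np.ndarray] = {}
        h = x.astype(np.float32)
        for i in range(self.depth):
            z, pt = conv2d(h, p[f"enc{i}_w"], p[f"enc{i}_b"])
            a = np.maximum(z, 0.0)
            patches[f"enc{i}"] = pt
            acts[f"enc{i}"] = a
            if i < self.depth - 1:
                skips.append(a)
                h = avgpool2(a)
            else:
                h = a
        for i in range(self.depth - 2, -1, -1):
            h = np.concatenate([upsample2(h), skips[i]], axis=1)
            acts[f"cat{i}"] = h
            z, pt = conv2d(h, p[f"dec{i}_w"], p[f"dec{i}_b"])
            a = np.maximum(z, 0.0)
            patches[f"dec{i}"] = pt
            acts[f"dec{i}"] = a
            h = a
        z, pt = conv2d(h, p["out_w"], p["out_b"])
        patches["out"] = pt
        prob = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
        if cache is not None:
            cache["acts"] = acts
            cache["patches"] = patches
            cache["prob"] = prob
        return prob.astype(np.float32)

    def backward(self, cache: dict, dprob: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        acts, patches, prob = cache["acts"], cache["patches"], cache["prob"]
        grads: dict[str, np.ndarray] = {}
        dz = dprob * prob * (1.0 - prob)  # through sigmoid
        dh, grads["out_w"], grads["out_b"] = conv2d_backward(patches["out"], p["out_w"], dz)
        dskips: dict[int, np.ndarray] = {}
        for i in range(0, self.depth - 1):  # decoder levels, reverse of forward
            dz = dh * (acts[f"dec{i}"] > 0)
            dcat, grads[f"dec{i}_w"], grads[f"dec{i}_b"] = conv2d_backward(
                patches[f"dec{i}"], p[f"dec{i}_w"], dz
            )
            c_up = acts[f"cat{i}"].shape[1] - acts[f"enc{i}"].shape[1]
            dup, dskip = dcat[:, :c_up], dcat[:, c_up:]
            dskips[i] = dskip
            dh = upsample2_backward(dup)
        for i in range(self.depth - 1, -1, -1):  # encoder levels
            if i < self.depth - 1:
                dh = avgpool2_backward(dh) + dskips[i]
            dz = dh * (acts[f"enc{i}"] > 0)
            dh, grads[f"enc{i}_w"], grads[f"enc{i}_b"] = conv2d_backward(
                patches[f"enc{i}"], p[f"enc{i}_w"], dz
            )
        return grads


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
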