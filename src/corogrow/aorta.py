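"""Ascending-aorta localization and coronary-root seed derivation.

The ascending aorta is the largest, brightest, most circular structure on
axial CTA slices, which makes it the natural anchor for automatic seeding:
segment the aorta per slice (a small Dice-loss-trained encoder-decoder, or a
deterministic circularity-based fallback), then place the coronary seed at the
most vessel-like voxel just outside the aorta surface — the aorta-coronary
junction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .errors import InputError, LocalizationError, ParameterError, TrainingError
from .nn import Adam, EncoderDecoder, dice_loss_value_grad

Coord = tuple[int, int, int]

#: affine normalization from the 0-600 HU working range to roughly [-1, 1]
_HU_CENTER, _HU_SCALE = 300.0, 300.0


@dataclass(frozen=True)
class DiceLossSpec:
    """Smoothing constant that keeps the Dice ratio defined for empty masks."""

    smooth: float = 1.0

    def validate(self) -> None:
        if self.smooth <= 0:
            raise ParameterError("smooth must be > 0")


@dataclass(frozen=True)
class SegmenterSpec:
    input_size: tuple[int, int] = (64, 64)
    depth: int = 3
    base_channels: int = 8
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-2
    rng_seed: int = 0

    def validate(self) -> None:
        if self.depth < 2:
            raise ParameterError("depth must be >= 2")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        div = 2 ** (self.depth - 1)
        if any(s % div for s in self.input_size):
            raise ParameterError(
                f"input_size {self.input_size} must be divisible by {div} for depth {self.depth}"
            )


def dice_loss(
    pre: np.ndarray, lab: np.ndarray, spec: DiceLossSpec | None = None
) -> float:
    """Smoothed Dice loss 1 - (2*sum(lab*pre)+smooth)/(sum(pre)+sum(lab)+smooth).

    ``pre`` holds per-pixel predictions in [0, 1]; ``lab`` is binary.  The
    value lies in [0, 1): 0 for a perfect prediction, and also 0 for the
    doubly-empty case, which the smoothing constant rescues from 0/0.
    """
    if spec is None:
        spec = DiceLossSpec()
    spec.validate()
    pre = np.asarray(pre, dtype=np.float64)
    lab = np.asarray(lab, dtype=np.float64)
    if pre.shape != lab.shape:
        raise InputError(f"shape mismatch: pre {pre.shape} vs lab {lab.shape}")
    if pre.min() < 0 or pre.max() > 1:
        raise InputError("predictions must lie in [0, 1]")
    if not np.isin(lab, (0.0, 1.0)).all():
        raise InputError("labels must be binary")
    num = 2.0 * float((lab * pre).sum()) + spec.smooth
    den = float(pre.sum()) + float(lab.sum()) + spec.smooth
    return 1.0 - num / den


class AortaSegmenter:
    """A trained encoder-decoder plus its spec; thresholds probabilities at 0.5."""

    FORMAT_VERSION = 1

    def __init__(self, net: EncoderDecoder, spec: SegmenterSpec, loss_history: list[float]):
        self.net = net
        self.spec = spec
        self.loss_history = loss_history

    def predict_proba(self, slices: list[np.ndarray] | np.ndarray) -> np.ndarray:
        x = _to_batch(slices, self.spec.input_size)
        return self.net.forward(x)[:, 0]

    def predict(self, slices: list[np.ndarray] | np.ndarray) -> list[np.ndarray]:
        return [(p >= 0.5).astype(np.uint8) for p in self.predict_proba(slices)]

    def save(self, path: str) -> None:
        meta = dict(
            format_version=self.FORMAT_VERSION,
            depth=self.spec.depth,
            base_channels=self.spec.base_channels,
            input_h=self.spec.input_size[0],
            input_w=self.spec.input_size[1],
            rng_seed=self.spec.rng_seed,
            loss_history=np.asarray(self.loss_history),
        )
        np.savez(path, **meta, **{f"param_{k}": v for k, v in self.net.params.items()})

    @classmethod
    def load(cls, path: str) -> "AortaSegmenter":
        data = np.load(path)
        if int(data["format_version"]) != cls.FORMAT_VERSION:
            raise InputError(f"unsupported segmenter file version in {path}")
        spec = SegmenterSpec(
            input_size=(int(data["input_h"]), int(data["input_w"])),
            depth=int(data["depth"]),
            base_channels=int(data["base_channels"]),
            rng_seed=int(data["rng_seed"]),
        )
        net = EncoderDecoder(spec.depth, spec.base_channels, spec.rng_seed)
        for k in net.params:
            net.params[k] = data[f"param_{k}"]
        return cls(net, spec, list(data["loss_history"]))


def _to_batch(slices: list[np.ndarray] | np.ndarray, input_size: tuple[int, int]) -> np.ndarray:
    arr = np.asarray(slices, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != tuple(input_size):
        raise InputError(f"slices of shape {arr.shape[1:]} do not match spec {input_size}")
    return ((arr - _HU_CENTER) / _HU_SCALE)[:, None]


def train_aorta_segmenter(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    spec: SegmenterSpec | None = None,
    loss: DiceLossSpec | None = None,
) -> AortaSegmenter:
    """Train the encoder-decoder on (slice, aorta mask) pairs under Dice loss.

    Training is full-epoch minibatch Adam, bit-reproducible under
    ``spec.rng_seed``.  Emits a convergence warning (not an error) if the
    epoch loss did not decrease from first to last epoch.
    """
    if spec is None:
        spec = SegmenterSpec()
    if loss is None:
        loss = DiceLossSpec()
    spec.validate()
    loss.validate()
    if len(pairs) < 8:
        raise TrainingError(f"need >= 8 training pairs, got {len(pairs)}")
    x = _to_batch([p[0] for p in pairs], spec.input_size)
    y = np.asarray([p[1] for p in pairs], dtype=np.float32)[:, None]
    if y.shape[2:] != tuple(spec.input_size):
        raise TrainingError("labels do not match spec input_size")

    net = EncoderDecoder(spec.depth, spec.base_channels, spec.rng_seed)
    opt = Adam(net.params, lr=spec.learning_rate)
    rng = np.random.default_rng(spec.rng_seed + 1)
    n = len(pairs)
    history: list[float] = []
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            cache: dict = {}
            prob = net.forward(x[idx], cache)
            lval, dprob = dice_loss_value_grad(prob, y[idx], loss.smooth)
            grads = net.backward(cache, dprob)
            opt.step(net.params, grads)
            epoch_losses.append(lval)
        history.append(float(np.mean(epoch_losses)))
    if len(history) > 1 and history[-1] >= history[0]:
        warnings.warn("training loss did not decrease from first to last epoch")
    return AortaSegmenter(net, spec, history)


def segment_aorta(
    segmenter: AortaSegmenter, slices: list[np.ndarray] | np.ndarray
) -> list[np.ndarray]:
    """Per-slice binary aorta masks (probabilities thresholded at 0.5)."""
    return segmenter.predict(slices)


def fallback_aorta_detect(slice_2d: np.ndarray, circularity_min: float = 0.7) -> np.ndarray:
    """Deterministic non-learned aorta detector.

    Returns the largest bright connected component whose isoperimetric
    circularity 4*pi*A/P**2 is at least ``circularity_min``; an empty mask if
    no component qualifies.  Works on HU or window-enhanced slices.
    """
    img = np.asarray(slice_2d, dtype=np.float64)
    if img.ndim != 2:
        raise InputError("expected a 2D slice")
    empty = np.zeros(img.shape, dtype=np.uint8)
    if float(img.max() - img.min()) < 1e-9:
        return empty
    thresh = filters.threshold_otsu(img)
    bright = img > thresh
    labeled = measure.label(bright, connectivity=1)
    best_area, best_label = 0, 0
    for region in measure.regionprops(labeled):
        if region.area < 9 or region.perimeter == 0:
            continue
        circularity = 4.0 * np.pi * region.area / region.perimeter**2
        if circularity >= circularity_min and region.area > best_area:
            best_area, best_label = region.area, region.label
    if best_label == 0:
        return empty
    return (labeled == best_label).astype(np.uint8)


def locate_seed(
    aorta_masks: list[np.ndarray] | np.ndarray,
    vesselness: np.ndarray,
    search_radius: float = 5.0,
) -> Coord:
    """Coronary-root seed: the max-vesselness voxel just outside the aorta.

    Candidates are voxels outside the stacked aorta mask within
    ``search_radius`` voxels of its surface; ties break toward the
    lexicographically smallest (z, y, x).
    """
    aorta = np.asarray(aorta_masks).astype(bool)
    vesselness = np.asarray(vesselness, dtype=np.float64)
    if aorta.shape != vesselness.shape:
        raise InputError("aorta masks and vesselness volume are misaligned")
    if not aorta.any():
        raise LocalizationError("all aorta masks are empty")
    dist = ndimage.distance_transform_edt(~aorta)
    candidates = (dist > 0) & (dist <= search_radius)
    if not candidates.any():
        raise LocalizationError("no candidate voxels near the aorta surface")
    scores = np.where(candidates, vesselness, -1.0)
    flat = int(np.argmax(scores))  # first occurrence = lexicographically smallest
    if scores.flat[flat] <= 0.0:
        raise LocalizationError("all candidate voxels have zero vesselness")
    return tuple(int(v) for v in np.unravel_index(flat, aorta.shape))
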