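"""CT intensity windowing.

Coronary CTA working intensities live roughly in 0–600 HU.  A piecewise-linear
window/level transform maps that range onto a display/feature range so that
lumen voxels occupy the upper part of the output scale and soft tissue is
compressed toward zero:

    y = 0                         for x in [0, wl - ww/2)
    y = 128 + 256 * (x - wl)/ww   for x in [wl - ww/2, wl + ww/2)
    y = 255                       for x in [wl + ww/2, hu_max]

with window level ``wl`` (the center of the window) and window width ``ww``
(its span), both in HU.  Inputs outside [0, hu_max] are clamped to the nearest
bound first, and the output is clamped to [0, clamp_max].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError

#: upper bound of the HU working range the transform is defined on
HU_MAX = 600.0


@dataclass(frozen=True)
class WindowParams:
    """Window level / width and the output clamp bound.

    Defaults are the coronary-CTA setting: level 300 HU, width 600 HU, so the
    whole 0–600 HU working range maps linearly onto [0, 255].
    """

    wl: float = 300.0
    ww: float = 600.0
    clamp_max: float = 255.0

    def validate(self) -> None:
        if self.ww <= 0:
            raise ParameterError(f"window width must be > 0, got {self.ww}")
        if self.clamp_max <= 0:
            raise ParameterError(f"clamp_max must be > 0, got {self.clamp_max}")


def apply_window(
    volume: np.ndarray,
    params: WindowParams | None = None,
    *,
    quantize: bool = False,
) -> np.ndarray:
    """Apply the piecewise window/level transform voxelwise.

    Parameters
    ----------
    volume
        HU-valued array of any shape.  Must be finite.
    params
        Window level/width; defaults to wl=300, ww=600, clamp 255.
    quantize
        If True, round the output to unsigned 8-bit integers (for export).
        By default values are kept as floats so downstream filtering loses
        no precision.
    """
    if params is None:
        params = WindowParams()
    params.validate()
    x = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise InputError("volume contains non-finite voxel values")

    x = np.clip(x, 0.0, HU_MAX)
    lo = params.wl - params.ww / 2.0
    hi = params.wl + params.ww / 2.0

    y = 128.0 + 256.0 * (x - params.wl) / params.ww
    y = np.where(x < lo, 0.0, y)
    y = np.where(x >= hi, 255.0, y)
    y = np.clip(y, 0.0, params.clamp_max)
    if quantize:
        return np.rint(y).astype(np.uint8)
    return y
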