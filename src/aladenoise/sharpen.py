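"""Unsharp-mask sharpening, the second pipeline stage.

Local averaging trades a little sharpness for noise removal; the unsharp
mask buys the sharpness back by mixing each RGB channel with its
Gaussian-blurred counterpart:

    out = clamp(channel * gain - blur(channel) * amount, 0, 255)

with the default gain 1.6 and amount 0.6, so gain - amount = 1 and flat
regions (and the image mean, absent clamping) are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SharpenParams", "gaussian_blur", "unsharp_mask"]


@dataclass(frozen=True)
class SharpenParams:
    """Unsharp-mask configuration.

    blur_radius — Gaussian blur radius in pixels (default 5); mapped to a
    standard deviation of ``radius / 2`` with the kernel truncated at 3
    standard deviations.  amount/gain — mixing weights (defaults 0.6/1.6,
    a brightness-preserving pair since gain - amount = 1).
    """

    blur_radius: float = 5.0
    amount: float = 0.6
    gain: float = 1.6

    def __post_init__(self):
        if self.blur_radius <= 0:
            raise ValueError("blur_radius must be positive")


def gaussian_blur(plane, radius: float) -> np.ndarray:
    """Separable Gaussian blur with sigma = radius/2, reflective borders."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    arr = np.asarray(plane, dtype=np.float64)
    return gaussian_filter(arr, sigma=radius / 2.0, mode="reflect", truncate=3.0)


def unsharp_mask(img, params: SharpenParams = SharpenParams()) -> np.ndarray:
    """Sharpen each channel against its blurred counterpart; clamped output."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        channels = [arr]
    elif arr.ndim == 3:
        channels = [arr[..., k] for k in range(arr.shape[2])]
    else:
        raise ValueError(f"expected a 2-D plane or HxWxC image, got {arr.shape}")
    sharpened = [
        c * params.gain - gaussian_blur(c, params.blur_radius) * params.amount
        for c in channels
    ]
    out = sharpened[0] if arr.ndim == 2 else np.stack(sharpened, axis=-1)
    return np.clip(out, 0.0, 255.0)
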