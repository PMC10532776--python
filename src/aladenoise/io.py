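"""8-bit image decode/encode (PNG, TIFF, JPEG) via imageio.

Grayscale inputs are promoted to three identical channels at load; alpha
channels are dropped.  Planes processed at floating precision are rounded
and clamped to uint8 only here, at encode time.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["load_image", "save_image", "to_uint8"]


def load_image(path) -> np.ndarray:
    """Read an image as an HxWx3 uint8 array."""
    arr = iio.imread(Path(path))
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"unsupported image shape {arr.shape} in {path}")
    return arr


def to_uint8(arr) -> np.ndarray:
    """Quantize a floating [0, 255] array to uint8 (round half to even)."""
    return np.clip(np.round(np.asarray(arr, dtype=np.float64)), 0, 255).astype(np.uint8)


def save_image(path, arr) -> None:
    """Encode an array (float or uint8) as an 8-bit image file."""
    iio.imwrite(Path(path), to_uint8(arr))
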