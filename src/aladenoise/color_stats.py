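"""Color-space decomposition and the global statistics behind the ALA threshold.

The denoiser operates only on the luminance (Y) plane of a YUV-decomposed
image; chroma passes through untouched.  Its single tuning parameter, the
variability threshold ``Th``, is derived from two global statistics of Y:
the median brightness ``mu`` and a Laplacian-based noise estimate ``sigma``,

    Th = 2 * sigma + mu / 60.

All planes are carried at floating precision in the [0, 255] gray domain;
quantization to 8-bit integers happens only when an image is encoded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "YuvImage",
    "NoiseStats",
    "CHROMA_NEUTRAL",
    "rgb_to_yuv",
    "yuv_to_rgb",
    "rgb_to_gray",
    "estimate_noise_sigma",
    "median_brightness",
    "image_noise_stats",
    "ala_threshold",
]

#: Neutral chroma offset: achromatic pixels map to U = V = 128.
CHROMA_NEUTRAL = 128.0

# Full-range BT.601 forward matrix (rows: Y, U, V; columns: R, G, B).
_FWD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_INV = np.linalg.inv(_FWD)

# 3x3 discrete Laplacian (4-neighbour stencil).
_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])

# mean(|Laplacian * N(0, s)|) = s * sqrt(20) * sqrt(2/pi); dividing by that
# gain turns the raw mean absolute response into an estimate of s itself.
_LAPLACIAN_NOISE_GAIN = np.sqrt(20.0) * np.sqrt(2.0 / np.pi)


def _as_color(img) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 color image, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    return arr


def _as_plane(y) -> np.ndarray:
    arr = np.asarray(y, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D gray plane, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class YuvImage:
    """A luminance plane plus two chroma planes of identical shape."""

    y: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        y, u, v = (_as_plane(p) for p in (self.y, self.u, self.v))
        if not (y.shape == u.shape == v.shape):
            raise ValueError(
                f"Y/U/V plane shapes differ: {y.shape}, {u.shape}, {v.shape}"
            )
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.shape


@dataclass(frozen=True)
class NoiseStats:
    """Global Y-plane statistics feeding the threshold formula.

    mu_median
        Median gray value of the plane, in [0, 255].
    sigma_laplacian
        Non-negative noise estimate from the absolute Laplacian response.
    """

    mu_median: float
    sigma_laplacian: float


def rgb_to_yuv(img) -> YuvImage:
    """Decompose an RGB image into full-range BT.601 Y, U, V planes.

    Y = 0.299 R + 0.587 G + 0.114 B carries brightness; U and V carry
    chroma, offset so that achromatic pixels sit at ``CHROMA_NEUTRAL``.
    """
    arr = _as_color(img)
    yuv = arr @ _FWD.T
    return YuvImage(
        y=yuv[..., 0],
        u=yuv[..., 1] + CHROMA_NEUTRAL,
        v=yuv[..., 2] + CHROMA_NEUTRAL,
    )


def yuv_to_rgb(img: YuvImage) -> np.ndarray:
    """Invert :func:`rgb_to_yuv`; samples are clamped to [0, 255]."""
    if not isinstance(img, YuvImage):
        img = YuvImage(*img)
    yuv = np.stack(
        [img.y, img.u - CHROMA_NEUTRAL, img.v - CHROMA_NEUTRAL], axis=-1
    )
    rgb = yuv @ _INV.T
    return np.clip(rgb, 0.0, 255.0)


def rgb_to_gray(img) -> np.ndarray:
    """Unweighted channel mean (R + G + B) / 3, the gray transform the
    quality metrics operate on."""
    return _as_color(img).mean(axis=2)


def estimate_noise_sigma(y, calibrated: bool = True) -> float:
    """Noise estimate from the mean absolute 3x3-Laplacian response.

    The Laplacian annihilates constants and linear ramps, so its response
    on a mostly smooth image is dominated by pixel noise.  The mean is
    taken over the valid interior only (no padding contribution).

    With ``calibrated=True`` (default) the raw mean absolute response is
    divided by sqrt(20 * 2/pi), the gain of the stencil on white Gaussian
    noise, so the returned value estimates the noise standard deviation on
    the gray-value scale.  ``calibrated=False`` returns the raw mean
    absolute response.
    """
    arr = _as_plane(y)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("plane must be at least 3x3 for the Laplacian estimate")
    raw = float(np.mean(np.abs(convolve2d(arr, _LAPLACIAN, mode="valid"))))
    return raw / _LAPLACIAN_NOISE_GAIN if calibrated else raw


def median_brightness(y) -> float:
    """Median gray value; the midpoint convention for even sample counts."""
    return float(np.median(_as_plane(y)))


def image_noise_stats(y, calibrated: bool = True) -> NoiseStats:
    """Convenience bundle of the two global statistics of a Y plane."""
    return NoiseStats(
        mu_median=median_brightness(y),
        sigma_laplacian=estimate_noise_sigma(y, calibrated=calibrated),
    )


def ala_threshold(stats: NoiseStats) -> float:
    """Variability threshold Th = 2*sigma + mu/60, with no clamping."""
    if stats.sigma_laplacian < 0:
        raise ValueError("sigma_laplacian must be non-negative")
    return 2.0 * stats.sigma_laplacian + stats.mu_median / 60.0
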