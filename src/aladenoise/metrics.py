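"""Image-quality metrics: two PSNR formulations, SSIM, and brightness.

All metrics operate on gray planes in the [0, 255] domain; color images
are first reduced with the unweighted channel mean
(:func:`aladenoise.color_stats.rgb_to_gray`).

Two PSNR variants are used side by side.  The pairwise form,
``20 log10(255 / RMSE)``, quantifies the difference between two images and
is infinite for identical ones — which also means a weak denoiser whose
output barely differs from its noisy input scores deceptively high.  The
single-image form, ``20 log10(255 / mean_gray)``, is therefore reported as
a complementary check that needs no reference image (brighter images score
lower).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["QualityReport", "psnr_pair", "psnr_single", "ssim", "brightness"]

_PEAK = 255.0


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"plane shapes differ: {x.shape} vs {y.shape}")
    return x, y


@dataclass(frozen=True)
class QualityReport:
    """Quality measurements for one image (or image pair)."""

    psnr_pair_db: float
    psnr_single_db: float
    ssim: float
    mean_brightness: float


def psnr_pair(a, b) -> float:
    """Pairwise PSNR in dB: 20*log10(255/sqrt(MSE)); +inf if identical."""
    x, y = _pair(a, b)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(_PEAK / np.sqrt(mse)))


def psnr_single(a) -> float:
    """Reference-free PSNR in dB: 20*log10(255/mean); +inf for an all-zero
    plane (flagged by convention rather than raising)."""
    mu = float(np.mean(np.asarray(a, dtype=np.float64)))
    if mu == 0.0:
        return float("inf")
    return float(20.0 * np.log10(_PEAK / mu))


def ssim(a, b, win_size: int = 7, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity index with a uniform window.

    Local means, variances and covariance are estimated in sliding
    ``win_size x win_size`` windows (unbiased normalization), combined with
    the standard stabilizing constants C1 = (k1*255)^2 and C2 = (k2*255)^2,
    and averaged over window centers that see a full window.  Symmetric in
    its arguments; exactly 1 for identical planes.
    """
    x, y = _pair(a, b)
    if min(x.shape) < win_size:
        raise ValueError(f"planes must be at least {win_size} pixels on a side")
    if x.ndim != 2:
        raise ValueError("ssim operates on 2-D gray planes")

    c1 = (k1 * _PEAK) ** 2
    c2 = (k2 * _PEAK) ** 2
    np_win = win_size * win_size
    cov_norm = np_win / (np_win - 1)

    def f(p):
        return uniform_filter(p, size=win_size, mode="reflect")

    ux, uy = f(x), f(y)
    vx = cov_norm * (f(x * x) - ux * ux)
    vy = cov_norm * (f(y * y) - uy * uy)
    cxy = cov_norm * (f(x * y) - ux * uy)

    num = (2 * ux * uy + c1) * (2 * cxy + c2)
    den = (ux * ux + uy * uy + c1) * (vx + vy + c2)
    s = num / den
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def brightness(a) -> float:
    """Arithmetic mean gray value, the brightness-conservation check."""
    arr = np.asarray(a, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty plane")
    return float(arr.mean())
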