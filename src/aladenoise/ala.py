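"""Adaptive local averaging (ALA), the core edge-preserving denoising filter.

For every pixel a square patch grows outward until the brightness
variability inside it exceeds the threshold ``Th``; the pixel is replaced
by the mean of the largest patch that stayed below the threshold.  Near
contours the variability rises immediately, so patches stay small (or the
pixel is left untouched); in homogeneous regions patches grow large and
average away noise — the spatial-pooling strategy of nocturnal insect
vision, where lamina neurons trade resolution for signal-to-noise ratio.

The production filter evaluates all window statistics through summed-area
tables (integral images) of Y and Y^2, so each of the ~20 radius passes is
O(H*W).  For 8-bit-valued planes every window sum is an exactly
representable integer in double precision, which makes the accelerated
filter bit-identical to a naive per-pixel loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter

__all__ = ["AlaParams", "patch_variability", "ala_pixel", "ala_filter"]

_STATISTICS = ("stddev", "range")


@dataclass(frozen=True)
class AlaParams:
    """Configuration of the adaptive local averaging filter.

    threshold
        Variability threshold Th on the gray-value scale (see
        :func:`aladenoise.color_stats.ala_threshold`).
    min_extent, max_extent
        Patch side bounds in pixels.  Patches are centered odd-sided
        windows of side ``2r + 1``; the stated extents map to radii
        ``r_min = max(1, min_extent // 2)`` and ``r_max = max_extent // 2``
        (defaults 2 and 40 give r in [1, 20]).
    variability_statistic
        ``"stddev"`` — population standard deviation of the window
        (default); ``"range"`` — max minus min.
    """

    threshold: float
    min_extent: int = 2
    max_extent: int = 40
    variability_statistic: str = "stddev"

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if not (1 <= self.min_extent < self.max_extent):
            raise ValueError("require 1 <= min_extent < max_extent")
        if self.variability_statistic not in _STATISTICS:
            raise ValueError(
                f"variability_statistic must be one of {_STATISTICS}"
            )

    @property
    def r_min(self) -> int:
        return max(1, self.min_extent // 2)

    @property
    def r_max(self) -> int:
        return self.max_extent // 2

    @property
    def halo(self) -> int:
        """Overlap (in pixels) tiled processing needs to match full-frame
        output exactly: the maximum patch radius."""
        return self.r_max


def _as_plane(y) -> np.ndarray:
    arr = np.asarray(y, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D gray plane, got shape {arr.shape}")
    return arr


def _window(y: np.ndarray, row: int, col: int, r: int) -> np.ndarray:
    h, w = y.shape
    return y[max(row - r, 0) : min(row + r + 1, h), max(col - r, 0) : min(col + r + 1, w)]


def _check_center(y: np.ndarray, center) -> tuple[int, int]:
    row, col = center
    h, w = y.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"center {center} outside plane of shape {y.shape}")
    return int(row), int(col)


def patch_variability(y, center, half_width: int, statistic: str = "stddev") -> float:
    """Brightness variability inside the window of side ``2*half_width + 1``
    centered on ``center``, clipped to the image bounds."""
    arr = _as_plane(y)
    row, col = _check_center(arr, center)
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    win = _window(arr, row, col, half_width)
    if statistic == "stddev":
        return float(win.std())
    return float(win.max() - win.min())


def ala_pixel(y, center, params: AlaParams) -> float:
    """ALA output for a single pixel (the reference per-pixel procedure).

    The patch grows from ``r_min`` to ``r_max``; growth stops at the first
    radius whose variability exceeds the threshold and the mean of the last
    passing window is returned.  If already the smallest window fails, the
    pixel keeps its original value; if no window fails, the ``r_max``
    window is averaged.
    """
    arr = _as_plane(y)
    row, col = _check_center(arr, center)
    value = float(arr[row, col])
    for r in range(params.r_min, params.r_max + 1):
        win = _window(arr, row, col, r)
        if params.variability_statistic == "stddev":
            var = float(win.std())
        else:
            var = float(win.max() - win.min())
        if var > params.threshold:
            break
        value = float(win.mean())
    return value


def _clipped_window_sums(cum: np.ndarray, r: int, h: int, w: int):
    """Window sums over clipped [i-r, i+r] x [j-r, j+r] from a padded
    2-D cumulative sum table of shape (h+1, w+1)."""
    i0 = np.clip(np.arange(h) - r, 0, None)
    i1 = np.clip(np.arange(h) + r + 1, None, h)
    j0 = np.clip(np.arange(w) - r, 0, None)
    j1 = np.clip(np.arange(w) + r + 1, None, w)
    s = (
        cum[i1[:, None], j1[None, :]]
        - cum[i0[:, None], j1[None, :]]
        - cum[i1[:, None], j0[None, :]]
        + cum[i0[:, None], j0[None, :]]
    )
    n = (i1 - i0)[:, None] * (j1 - j0)[None, :]
    return s, n


def ala_filter(y, params: AlaParams) -> np.ndarray:
    """Apply adaptive local averaging to a whole plane.

    Equivalent pixel-for-pixel to calling :func:`ala_pixel` everywhere, but
    vectorized: one pass per radius, window sums in O(1) via summed-area
    tables (or sliding min/max filters for the range statistic).  Window
    clipping at the plane border uses only the in-bounds samples, which is
    what lets tiled processing with a sufficient halo reproduce full-frame
    output exactly.
    """
    arr = _as_plane(y)
    h, w = arr.shape
    if h < params.min_extent or w < params.min_extent:
        raise ValueError(
            f"plane {arr.shape} smaller than min_extent {params.min_extent}"
        )
    th = float(params.threshold)

    use_std = params.variability_statistic == "stddev"
    cum1 = np.zeros((h + 1, w + 1))
    cum1[1:, 1:] = arr.cumsum(axis=0).cumsum(axis=1)
    if use_std:
        cum2 = np.zeros((h + 1, w + 1))
        cum2[1:, 1:] = (arr * arr).cumsum(axis=0).cumsum(axis=1)

    out = arr.copy()
    active = np.ones((h, w), dtype=bool)
    for r in range(params.r_min, params.r_max + 1):
        if not active.any():
            break
        s1, n = _clipped_window_sums(cum1, r, h, w)
        if use_std:
            s2, _ = _clipped_window_sums(cum2, r, h, w)
            # population variance <= th^2  <=>  n*S2 - S1^2 <= (th*n)^2;
            # the left side is an exact integer for 8-bit-valued input
            passed = n * s2 - s1 * s1 <= (th * th) * (n * n).astype(np.float64)
        else:
            hi = maximum_filter(arr, size=2 * r + 1, mode="constant", cval=-np.inf)
            lo = minimum_filter(arr, size=2 * r + 1, mode="constant", cval=np.inf)
            passed = hi - lo <= th
        update = active & passed
        out[update] = s1[update] / n[update]
        active &= passed
    return out
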