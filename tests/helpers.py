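"""Independent brute-force oracles used to cross-check the fast paths."""

import numpy as np


def naive_ala(y, threshold, r_min=1, r_max=20, statistic="stddev"):
    """Reference ALA: explicit per-pixel loop with direct window slices.

    Grows the window radius until the variability exceeds the threshold
    and returns the mean of the last passing window (the original value if
    the smallest window already fails).  Deliberately unoptimized and
    independent of the summed-area-table implementation.
    """
    arr = np.asarray(y, dtype=np.float64)
    h, w = arr.shape
    out = arr.copy()
    for i in range(h):
        for j in range(w):
            value = arr[i, j]
            for r in range(r_min, r_max + 1):
                win = arr[max(i - r, 0): i + r + 1, max(j - r, 0): j + r + 1]
                if statistic == "stddev":
                    var = win.std()
                else:
                    var = win.max() - win.min()
                if var > threshold:
                    break
                value = win.mean()
            out[i, j] = value
    return out


def random_plane(rng, h, w, lo=0, hi=256):
    """8-bit-valued float plane, the domain the filter operates on."""
    return rng.integers(lo, hi, size=(h, w)).astype(np.float64)
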