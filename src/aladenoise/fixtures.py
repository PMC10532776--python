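"""Synthetic scenes, camera-noise models and averaged ground truth.

The generator stands in for the real-world noisy image pairs the pipeline
is meant for: structured clean scenes (flat fields, step edges, ramps,
checkerboards, blob layouts with homogeneous regions and sharp contours),
sensor noise as a Poisson-Gaussian composite (photon shot noise plus
read-out noise, quantized to 8 bits), and "ground truth" obtained the way
real-world benchmark datasets obtain it — by averaging many noisy captures
of a static scene.

Default noise levels model a high-ISO consumer camera in 8-bit gray units:
shot-noise variance ``signal / poisson_scale`` with ``poisson_scale = 8``
(standard deviation about 3.5 at mid-gray) plus Gaussian read noise of 2.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SceneSpec",
    "NoiseSpec",
    "SCENE_KINDS",
    "make_scene",
    "add_noise",
    "make_ground_truth",
    "write_fixture_set",
]

SCENE_KINDS = ("flat", "two_region_step", "gradient_ramp", "checker", "blobs_texture")

_DEFAULT_LEVELS = {
    "flat": (96.0,),
    "two_region_step": (50.0, 200.0),
    "gradient_ramp": (30.0, 220.0),
    "checker": (60.0, 190.0),
    "blobs_texture": (70.0, 180.0, 140.0, 220.0),
}


@dataclass(frozen=True)
class SceneSpec:
    """A deterministic clean test scene."""

    kind: str
    size: tuple[int, int] = (96, 96)
    levels: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SCENE_KINDS:
            raise ValueError(f"kind must be one of {SCENE_KINDS}")
        h, w = self.size
        if h < 8 or w < 8:
            raise ValueError("scene must be at least 8x8")

    @property
    def gray_levels(self) -> tuple[float, ...]:
        return self.levels if self.levels is not None else _DEFAULT_LEVELS[self.kind]


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor-noise model.

    ``gaussian``: out = clamp(round(in + N(0, gaussian_sigma))).
    ``poisson_gaussian``: out = clamp(round(Poisson(in*s)/s + N(0, sigma)))
    with s = ``poisson_scale``, giving signal-dependent variance in/s.
    ``per_channel_sigmas`` optionally replaces the Gaussian sigma with one
    value per color channel (real cameras show different noise levels in
    the three channels).
    """

    model: str = "poisson_gaussian"
    gaussian_sigma: float = 2.0
    poisson_scale: float = 8.0
    per_channel_sigmas: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("gaussian", "poisson_gaussian"):
            raise ValueError("model must be 'gaussian' or 'poisson_gaussian'")
        if self.gaussian_sigma < 0 or self.poisson_scale <= 0:
            raise ValueError("gaussian_sigma must be >= 0 and poisson_scale > 0")


def make_scene(spec: SceneSpec) -> np.ndarray:
    """Render the clean scene as an HxWx3 uint8 image."""
    h, w = spec.size
    lv = spec.gray_levels
    yy, xx = np.mgrid[0:h, 0:w]
    if spec.kind == "flat":
        plane = np.full((h, w), lv[0])
    elif spec.kind == "two_region_step":
        plane = np.full((h, w), lv[0])
        plane[:, w // 2 :] = lv[1]
    elif spec.kind == "gradient_ramp":
        plane = lv[0] + (xx / (w - 1)) * (lv[1] - lv[0])
    elif spec.kind == "checker":
        block = max(4, min(h, w) // 8)
        plane = np.where((xx // block + yy // block) % 2 == 0, lv[0], lv[1])
    else:  # blobs_texture: homogeneous background, disk blobs, mild ramp
        rng = np.random.default_rng(spec.seed)
        plane = np.full((h, w), lv[0]) + (xx / (w - 1)) * 10.0
        n_blobs = 3 + int(rng.integers(0, 3))
        for k in range(n_blobs):
            cy = int(rng.integers(h // 6, 5 * h // 6))
            cx = int(rng.integers(w // 6, 5 * w // 6))
            rad = int(rng.integers(min(h, w) // 16, min(h, w) // 6))
            level = float(lv[1 + k % (len(lv) - 1)]) if len(lv) > 1 else 180.0
            plane[(yy - cy) ** 2 + (xx - cx) ** 2 <= rad * rad] = level
    plane = np.clip(plane, 0.0, 255.0)
    return np.round(np.stack([plane] * 3, axis=-1)).astype(np.uint8)


def _add_noise_rng(img: np.ndarray, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if spec.model == "poisson_gaussian":
        s = spec.poisson_scale
        signal = rng.poisson(np.clip(arr, 0, None) * s) / s
    else:
        signal = arr
    if spec.per_channel_sigmas is not None and arr.ndim == 3:
        sig = np.asarray(spec.per_channel_sigmas, dtype=np.float64)
        noise = rng.normal(0.0, 1.0, arr.shape) * sig
    else:
        noise = rng.normal(0.0, spec.gaussian_sigma, arr.shape)
    return np.clip(np.round(signal + noise), 0, 255).astype(np.uint8)


def add_noise(img, spec: NoiseSpec) -> np.ndarray:
    """One noisy 8-bit capture of ``img`` under the given noise model."""
    return _add_noise_rng(img, spec, np.random.default_rng(spec.seed))


def make_ground_truth(clean, noise: NoiseSpec, n_frames: int) -> np.ndarray:
    """Per-pixel mean of ``n_frames`` independent noisy captures.

    Emulates the frame-averaging protocol real-world denoising benchmarks
    use to approximate a noise-free reference (~500 captures of a static
    scene).  Returned at floating precision; the residual standard
    deviation against the clean scene shrinks as 1/sqrt(n_frames).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rngs = np.random.default_rng(noise.seed).spawn(n_frames)
    acc = np.zeros(np.asarray(clean).shape, dtype=np.float64)
    for rng in rngs:
        acc += _add_noise_rng(np.asarray(clean), noise, rng)
    return acc / n_frames


def write_fixture_set(
    out_dir,
    kinds=SCENE_KINDS,
    size=(96, 96),
    noise: NoiseSpec = NoiseSpec(),
    n_truth_frames: int = 100,
    seed: int = 0,
) -> list[dict]:
    """Write clean/noisy/ground-truth PNG triplets plus a TSV manifest.

    Files follow the ``<id>_real.png`` / ``<id>_mean.png`` pairing
    convention of real-world noisy-image datasets so the batch evaluator
    can pair them; the clean scene is kept as ``<id>_clean.png``.
    """
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, kind in enumerate(kinds):
        scene_spec = SceneSpec(kind=kind, size=size, seed=seed + i)
        nspec = replace(noise, seed=seed + 1000 + i)
        clean = make_scene(scene_spec)
        noisy = add_noise(clean, nspec)
        truth = make_ground_truth(clean, nspec, n_truth_frames)
        stem = f"{kind}_{i}"
        _io.save_image(out / f"{stem}_clean.png", clean)
        _io.save_image(out / f"{stem}_real.png", noisy)
        _io.save_image(out / f"{stem}_mean.png", truth)
        rows.append(
            {
                "id": stem,
                "kind": kind,
                "noise_model": nspec.model,
                "gaussian_sigma": nspec.gaussian_sigma,
                "poisson_scale": nspec.poisson_scale,
                "seed": nspec.seed,
            }
        )
    with open(out / "manifest.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    return rows
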