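# Methods

## The model

ALA assumes that luminance variability is high near object contours and
low inside homogeneous regions, and that moderate sensor noise can be
removed by averaging over the largest neighborhood that is still
"homogeneous enough". Formally, for pixel *p* and radius *r* ∈
[r_min, r_max], let W_r(p) be the (2r+1)×(2r+1) window centered on *p*,
clipped to the image bounds, and v(W) its variability. The filter output
is the mean of W_R(p) where R is the largest radius reached by growing
*r* from r_min before v first exceeds the threshold *Th*; if
v(W_{r_min}) > *Th* the pixel is returned unchanged (this is what
preserves contours exactly), and if no window exceeds *Th* the r_max
window is averaged. Growth stops at the **first** failing radius — the
variability profile is not scanned for later re-entries below the
threshold, matching the "expanding patch" procedure.

The stated patch extents 2–40 px are mapped to centered odd-sided windows
with radii 1–20: an expanding patch centered on a pixel needs an odd
side, and the 20-px tiling halo equals exactly this maximum radius.

Only the Y plane of a full-range BT.601 YUV decomposition is filtered.
Chroma noise is deliberately untouched: luminance noise dominates
perceived noise, and skipping two of three channels saves two thirds of
the filter cost.

## The threshold and the noise estimate

*Th* = 2σ + µ/60 with µ the median Y value (midpoint convention for even
counts) and σ a noise estimate from the 3×3 Laplacian
`[[0,1,0],[1,−4,1],[0,1,0]]`, whose response annihilates constants and
linear ramps and therefore isolates high-frequency content. σ is the
mean of |L∗Y| over the valid interior (no padding contribution), divided
by the stencil's white-noise gain √(20·2/π) ≈ 3.568 so that on a pure
Gaussian noise field the estimate equals the noise standard deviation
itself (`estimate_noise_sigma(..., calibrated=False)` returns the raw
mean absolute response). This calibration was a genuinely open design
point; it was resolved in favor of the calibrated form because *Th* is
compared against window standard deviations on the gray-value scale, so
σ must live on that same scale: with the raw (uncalibrated) amplitude a
σ=10 noise field yields *Th* ≈ 75, which admits windows spanning
moderate contours and turns the filter into near-uniform 41×41 box
blurring, while the calibrated form stops patch growth at contours at
every noise level tested. On low-noise photographic input both variants
behave similarly because the raw estimate is then dominated by edge
response rather than noise.

The µ/60 term raises the threshold slightly for bright images, whose
shot noise is larger in absolute gray levels.

## Variability statistic

Population standard deviation by default (commensurate with *Th*'s
gray-value scale); window range (max − min) is available as a
configuration alternative. The stddev decision `var ≤ Th²` is evaluated
in the integer-exact form `n·Σx² − (Σx)² ≤ Th²·n²`, which avoids the
catastrophic cancellation of the naive `E[x²] − E[x]²` path.

## Exactness of the accelerated filter and of tiling

Window sums of Y and Y² come from summed-area tables. For 8-bit-valued
planes every partial sum is an integer below 2⁵³ and hence exactly
representable in double precision, so window means (sum/count) are
bit-identical to those of the brute-force per-pixel loop — the oracle
equivalence asserted in the tests is exact equality, not a tolerance.

Tiling splits the plane into core rectangles that partition it (2×2
quadrants for 4 tiles, row strips otherwise) and filters each core with
a halo of surplus pixels. Because no window statistic reaches farther
than r_max from its center, a halo ≥ r_max gives every core pixel
exactly the neighborhood it sees in full-frame processing — including
border clipping, since tiles at true image borders clip exactly as the
full frame does. Stitching is therefore bit-identical for any tile
count, serial or process-parallel; with halo 0 the tile-edge clipping
differs and horizontal/vertical seam lines appear, which the tests
reproduce as a negative control.

## Sharpening

Unsharp mask per RGB channel: `out = clamp(c·gain − blur(c)·amount)`
with gain 1.6, amount 0.6, Gaussian blur of radius 5. The printed form
of the mixing equation is self-referential (the sharpened channel
appears on its own right-hand side); it is implemented as the standard
unsharp mask of the original channel against its blurred counterpart,
which is the operation the accompanying description states. The
radius→σ mapping is σ = radius/2 with truncation at 3σ and reflective
borders — the blur kernel's effective extent is then the stated radius.
Defaults satisfy gain − amount = 1, so constants are fixed points and
mean brightness is preserved wherever no clamping occurs.

Note that on synthetic piecewise-constant scenes with mathematically
sharp contours, sharpening *lowers* fidelity to the clean reference
(overshoot at ideal step edges), even though it raises perceived
sharpness; real photographic references have optically soft edges and do
not show this effect to the same degree. The efficacy guarantee in the
tests is therefore asserted on the denoising stage, and the two-step
clean-reference gain is reported by the acceptance script without a
pass bound.

## Metrics

- Pairwise PSNR `20·log10(255/√MSE)` in dB, +∞ for identical planes.
  The RMSE reading of the printed formula is used: it is the standard
  definition and the only reading consistent with reported dB ranges for
  8-bit photographic content. Log base 10 throughout.
- Reference-free PSNR `20·log10(255/µ)` with µ the mean gray value —
  a brightness-anchored check that needs no reference and decreases for
  brighter images.
- SSIM with the standard constants K1 = 0.01, K2 = 0.03, L = 255 and a
  uniform 7×7 window, unbiased covariance normalization, averaged over
  window centers with full support. The test suite cross-checks this
  implementation against scikit-image's independent one to 10⁻⁶.
- All metrics operate on gray-transformed images using the unweighted
  channel mean (R+G+B)/3 — the arithmetic-mean convention, isolated in
  `rgb_to_gray` so a luma-weighted transform can be swapped in.
- Evaluation quantizes the denoised output to 8 bits first (metrics see
  the image as written to disk), so identical image pairs report +∞
  pairwise PSNR exactly.

## Synthetic data

The generator emulates the structure of real-world noisy/ground-truth
image datasets without any download:

- **Scenes**: flat fields, two-region steps, linear ramps,
  checkerboards, and blob layouts (disks of distinct levels over a
  homogeneous background with a mild gradient) — each deterministic
  given its seed, each non-flat kind containing at least one sharp
  contour and one homogeneous region.
- **Noise**: `gaussian` (additive, constant σ) or `poisson_gaussian`
  (shot noise `Poisson(in·s)/s`, variance in/s, plus Gaussian read
  noise), rounded and clamped to 8 bits per capture — rounding models
  quantization noise and clamping matches camera saturation, at the cost
  of a slight mean bias near 0/255. Defaults are `poisson_scale` s = 8
  (shot-noise SD ≈ 3.5 at mid-gray) and read noise σ = 2: a high-ISO
  consumer camera in 8-bit units, chosen to mirror the mild noise of
  real-world benchmark photographs. Per-channel σ triples model the
  different noise levels of the three color channels.
- **Ground truth**: the per-pixel mean of n independent captures, the
  frame-averaging protocol of real-world datasets (~500 captures of a
  static scene); the residual SD against the clean scene shrinks as
  1/√n (σ=10, n=500 → ≈ 0.45), which the tests verify.

What passing on these fixtures does *not* show: performance on spatially
correlated noise, fixed-pattern noise, demosaicing artifacts, or
compression noise — none of which the generator emulates — nor exact
replication of published benchmark figures, which additionally depend on
the camera content of the benchmark photographs. The batch evaluator and
CLI accept any directory of `*_real`/`*_mean` 8-bit image pairs, so a
downloaded real-world dataset can be scored with the identical protocol.

## Problem sizes and numerical choices

Tests and the acceptance script use 64–256 px planes and batches of ~10
scenes with 100–500 noise frames, sizes at which every statistical
assertion has comfortable margins while the whole suite runs in seconds.
All intermediate planes are double precision; quantization to uint8
happens once, at encode time. Degenerate inputs (planes smaller than the
kernel or patch, non-3-channel images, negative noise parameters,
out-of-bounds centers) raise `ValueError`/`IndexError` rather than being
silently clipped.

## Known limitations

- ALA is O(H·W·r_max) even with summed-area tables; very large images
  should use tiling (the CLI default) for parallelism.
- Neighborhoods are isotropic squares; no anisotropic or multi-scale
  adaptation.
- Chroma noise passes through by design; strongly chroma-noisy input
  will retain color speckle.
- The threshold formula is a heuristic calibrated on 8-bit gray scales;
  16-bit/HDR input is out of scope.
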