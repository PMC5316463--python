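# Methods

## Model and assumptions

A retinal vessel seen through a small window is modeled as a straight
tube: intensity constant along the vessel axis with a Gaussian
cross-section, i.e. a line-spread function (LSF). Two consequences are
exploited:

1. **Detection.** The normalized dot product between a window and an
   oriented LSF kernel is a matched-filter response; maximizing it over a
   bank of orientations and scales estimates the local vessel direction
   and width. Both kernel and window are made zero-mean and
   unit-Euclidean-norm first, so the response is invariant to local
   brightness and contrast and lies in [−1, 1].
2. **Filtering.** The bilateral filter's isotropic spatial kernel is
   replaced by the winning LSF profile: weight 1 along the detected
   center line, Gaussian decay with the perpendicular distance. Averaging
   therefore runs along the vessel; the range kernel continues to reject
   pixels of dissimilar intensity. The filter is single-pass and
   non-iterative.

The model assumes locally straight vessels (small curvature relative to
the window), a roughly Gaussian cross-section, and one dominant
orientation per window. Junctions violate the last assumption: at a
bifurcation the best single-orientation kernel is a compromise, and the
filter's advantage there is smaller than on straight segments (see
Limitations).

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `k` | window side (px), odd | 9 | used by both detection and filtering; should exceed the widest vessel of interest |
| `sigmas_px` | LSF cross-section scales (px) | 0.4, 0.8, 1.2, 1.6 | the scale grid; `m = len(sigmas_px)` |
| `sigma_r` | range-kernel scale on [0, 1] | 0.04 | ≈ 10 of 255 gray levels; set near the noise standard deviation |
| `n` | orientation count | 12 | uniform grid θ_i = i·180°/n (15° steps); a line at θ and θ+180° is the same line, so a half turn suffices |
| `polarity` | dark or bright vessels | dark | fundus green-channel vessels are dark; synthetic phantoms here are bright. Flips the sign of detection kernels only |
| `border` | window padding | reflect | mirror padding avoids fabricating dark borders that would look like vessels |
| `L` | line-support length (px) | = k | detection kernels are zero where the along-line coordinate exceeds L/2 |

Intensities are always mapped to [0, 1] on load (8-bit /255, 16-bit
/65535); `sigma_r` is interpreted on that scale.

## Numerical and design choices

- **Rotation convention.** Window offsets are (x, y) = (column, row,
  downward positive); the rotated coordinates are u = x cosθ − y sinθ,
  v = x sinθ + y cosθ. θ = 0 is a vertical line (u = x). Rotated kernels
  are evaluated analytically at (u, v), never resampled from the θ = 0
  matrix, so there are no interpolation artifacts at k = 9.
- **Support condition.** Detection kernels apply |v| ≤ L/2 (with L = k the
  cut removes only far corners of oblique kernels). The spatial *weights*
  use the plain profile exp(−u²/2σ²) with no cut, so every weight is
  strictly positive, the center weight is 1, and the normalizer k_p ≥ 1 —
  outputs are always well-defined convex combinations of window values.
- **Degenerate windows.** A constant window has an undefined normalized
  response (0/0). Such pixels are flagged, assigned response 0 and indices
  (0, 0); downstream, the σ = 0.4 spatial kernel is nearly an impulse and
  the range kernel dominates, so the choice is inconsequential.
- **Tie-breaking.** All kernels within 1e−9 of the maximum response count
  as tied and the lowest (orientation, scale) index wins. Exact ties are
  real, not hypothetical: reflect padding makes border windows
  mirror-symmetric, so mirror-pair orientations respond identically and
  float summation order would otherwise pick the winner.
- **Binarization.** Otsu's threshold is estimated on pixels more than one
  8-bit quantization step away from 0 and 1, then applied to all pixels.
  Salt-and-pepper impulses survive any bilateral-family filter essentially
  unchanged (the center weight is 1 while every neighbor's range weight is
  ~exp(−200)), and the resulting endpoint classes can otherwise out-vote
  the vessel/background split in Otsu's between-class variance. A fixed
  threshold is available for two-level synthetic images. Constant images
  yield an empty mask plus a warning.
- **Metrics.** Acc is the correctly-labeled fraction (tp+tn)/N; AUC is
  defined as (Se+Sp)/2 (balanced accuracy), not a ROC area; DC is the
  Dice overlap 2tp/(2tp+fp+fn). Empty denominators give NaN plus a flag,
  never a silent 0.

## Synthetic phantoms

The generator renders straight segments (vessel 180, background 125 on
the 8-bit scale — a 55-level contrast), optional Y-junctions and gaps,
and corrupts with Gaussian noise (default variance 0.0016 on [0, 1], i.e.
σ ≈ 10 gray levels, matching the σ_r operating point) and salt-and-pepper
impulses (default density 0.01). At these defaults a thresholded *noisy
input* already scores Se/Sp ≈ 0.98–0.99 — the regime in which
edge-preserving filters are meaningfully compared; much stronger noise
makes every global threshold collapse and measures the thresholder, not
the filter.

Rasterization is binary: a pixel is vessel iff its center is within
thickness/2 of the segment axis with the axial projection inside the
segment span (butt ends), so axis-aligned segments contain exactly
thickness × length pixels. Gaps ("broken vessels") are cut from the image
but kept in the truth mask, so a filter that reconnects a broken vessel is
rewarded. The thin-vessel phantom uses three 1-px strokes rather than one
so that the vessel class is a real histogram mode (~4% of pixels); a
single stroke (~1%) defeats global thresholding on some noise draws.

What the phantoms do **not** emulate: curvature and tortuosity, fundus
background texture and illumination gradients, the optic disc, vessel
cross-sections that are genuinely Gaussian rather than two-level, and
field-of-view borders. Passing phantom tests therefore demonstrates the
geometric behavior of the filter (orientation adaptivity, vessel
preservation, reconnection), not end-to-end performance on clinical
images.

## Problem sizes

Phantoms are 64 × 64 (orientation-recovery lines 49 × 49); the
replicated comparisons use 25 seeded noise draws per phantom. These sizes
give stable means (standard error of the Dice difference ≈ 7e−4) while
keeping the whole suite fast; all quantities scale per-pixel, and the
filter runs unchanged on full 768 × 584 fundus frames.

## Known limitations

- Salt-and-pepper impulses are preserved, not removed, by the range
  kernel (as with any bilateral filter); a median prefilter would be
  needed for heavy impulse noise.
- At Y-junctions the single-orientation LSF model is a compromise; the
  measured Dice advantage over an optimally tuned fixed-σ_s bilateral
  baseline on the bifurcation phantom is positive but small
  (vessel-pixel recall is strictly better; background smoothing is
  slightly weaker because background windows pick arbitrary orientations
  and often small scales).
- Orientation is quantized to the 15° grid; no sub-grid interpolation.
- Dark and bright vessels are handled by a sign flip; mixed-polarity
  images (e.g. central light reflex) are not modeled.
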