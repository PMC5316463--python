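# oolsf — retinal image denoising with an optimally oriented line-spread-function bilateral filter

Thin retinal vessels are easily destroyed by denoising: they occupy a few
pixels of any local window and their contrast against the background is
weak, so both the spatial and the range kernel of a classic bilateral
filter average them away. `oolsf` implements an edge-preserving filter
specialized for tubular structures: the bilateral range kernel is kept,
but the isotropic spatial kernel is replaced, per pixel, by a line-spread
function (LSF) — constant along the locally detected vessel direction and
Gaussian across it — so that averaging runs *along* the vessel instead of
over it.

The package is for researchers working on fundus-image preprocessing and
vessel segmentation: it provides the filter, the classic bilateral and
Gaussian baselines, segmentation metrics, a synthetic vessel-phantom
generator with ground truth, and a CLI.

## Method

The output at pixel `p` is a normalized weighted mean over its `k × k`
window `R_p`:

    D(p) = k_p^{-1} Σ_{q ∈ R_p} W'_s(p, q) · W_r(p, q) · I(q)
    k_p  = Σ_{q ∈ R_p} W'_s(p, q) · W_r(p, q)

with the usual range kernel `W_r = exp(−(I(q) − I(p))² / 2σ_r²)` and the
adaptive spatial kernel

    W'_s(q) = exp(−u² / 2σ_s²),   u = x cos θ_t − y sin θ_t,

where `(x, y)` is `q`'s offset in the window and `(θ_t, σ_s)` are chosen
per pixel by matched-filter detection: the window is compared (zero-mean,
unit-norm dot product) against a bank of `m · n` oriented LSF kernels

    K'_{i,j}(x, y) = ±exp(−u² / 2σ_j²)  for |v| ≤ L/2,

over `n = 12` orientations spanning a half turn and `m = 4` scales
`σ ∈ {0.4, 0.8, 1.2, 1.6}` px; the maximum-response kernel wins (sign `−`
for vessels darker than background, `+` for brighter ones). Defaults:
`k = 9`, `σ_r = 0.04` on the [0, 1] intensity scale.

## Worked example

Generate the eight standard vessel phantoms, denoise the noisy thin-vessel
image, and score it against its ground-truth mask (phantoms are bright
vessels, intensity 180 on a 125 background, with Gaussian plus
salt-and-pepper noise):

```sh
$ oolsf fixtures fx --seed 7
$ oolsf denoise fx/thin_noisy.png fx/thin_denoised.png --polarity bright
$ oolsf evaluate fx/thin_denoised.png fx/thin_noisy.mask.png --polarity bright
thin_denoised.png: tp=178 tn=3893 fp=24 fn=1 | Se=0.9944 Sp=0.9939 Acc=0.9939 AUC=0.9941 DC=0.9344
```

Reading the output: of the 179 true vessel pixels, 178 survive denoising
and Otsu binarization (sensitivity 0.994 — one vessel pixel lost), 24
background pixels are misclassified (mostly surviving salt impulses), and
the Dice overlap with the unbroken ground truth is 0.93. The same command
with `--filter blf --sigma-s 1.6` runs the classic bilateral baseline for
comparison.

The same pipeline is available as a library:

```python
from oolsf import FilterParams, phantom_suite, oolsf_filter, binarize, evaluate

params = FilterParams(polarity="bright")
fx = {f.name: f for f in phantom_suite(seed=7)}["thin_noisy"]
out = oolsf_filter(fx.image, params)
print(evaluate(binarize(out), fx.truth).dc)
```

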