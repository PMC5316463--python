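"""Per-pixel vessel orientation and scale by matched-filter argmax.

For each pixel the k-by-k window is compared against every kernel of the
bank by a normalized dot product: both the kernel and the window are made
zero-mean and unit-Euclidean-norm first, which makes the response invariant
to local brightness (additive) and contrast (positive multiplicative)
changes and bounds it in [-1, 1] by Cauchy-Schwarz.  The kernel with the
maximum response wins; its (orientation, scale) indices parameterize the
adaptive spatial kernel downstream, and the winning response field is,
as a byproduct, a matched-filter vessel-enhancement map.

Constant windows have an undefined normalized response (0/0); they are
flagged degenerate and assigned response 0 and indices (0, 0).

Tie-breaking: all kernels whose response lies within ``TIE_TOL`` of the
per-pixel maximum count as tied, and the lowest (theta_index, scale_index)
pair wins.  Exact ties are common — a reflect-padded border patch is
mirror-symmetric, so mirror-pair orientations respond identically — and
without the tolerance the winner would be decided by float summation
order, which is not reproducible across implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import GrayImage, as_gray
from .kernel_bank import EPS_NORM, KernelBank, matching_normalize

__all__ = ["OrientationScaleMap", "normalize_patch", "detect",
           "export_maps", "TIE_TOL"]

#: responses within this distance of the per-pixel maximum are tied;
#: far above float summation noise (~1e-16), far below genuine response
#: gaps between distinct orientations on real structure.
TIE_TOL = 1e-9


@dataclass
class OrientationScaleMap:
    """Per-pixel winning kernel indices and response.

    theta_index, scale_index : int arrays, shape of the image
    response : float array, the winning normalized dot product
    degenerate : bool array, True where the window was constant
    """

    theta_index: np.ndarray
    scale_index: np.ndarray
    response: np.ndarray
    degenerate: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta_index.shape  # type: ignore[return-value]


def normalize_patch(patch: np.ndarray,
                    eps: float = EPS_NORM) -> tuple[np.ndarray, bool]:
    """Zero-mean, unit-norm copy of a square window.

    Returns ``(normalized, degenerate)``.  A constant patch (centered norm
    < eps) yields the all-zeros window with ``degenerate=True`` — this is a
    flag, not an error.  Idempotent on already-normalized input.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"expected a square window, got shape {patch.shape}")
    return matching_normalize(patch, eps)


def detect(image: GrayImage | np.ndarray, bank: KernelBank,
           border: str = "reflect", chunk_rows: int = 64) -> OrientationScaleMap:
    """Select the maximum-response kernel at every pixel.

    Windows are extracted with ``border`` padding (numpy.pad mode).  Ties
    are broken toward the lowest theta_index, then the lowest scale_index
    (first maximum in the bank's orientation-major order).  If ``image`` is
    a GrayImage its polarity must match the bank's.

    ``chunk_rows`` only bounds the memory of the vectorized sweep; the
    result is independent of it.
    """
    img = as_gray(image, bank.polarity)
    vals = img.values
    k, r = bank.k, bank.k // 2
    H, W = vals.shape
    if min(H, W) < k:
        raise ValueError(f"image {vals.shape} smaller than the {k}x{k} window")

    padded = np.pad(vals, r, mode=border)
    windows = sliding_window_view(padded, (k, k))  # (H, W, k, k), a view
    kmat = bank.matched_stack()                    # (n*m, k*k)

    theta_idx = np.empty((H, W), dtype=np.int32)
    scale_idx = np.empty((H, W), dtype=np.int32)
    response = np.empty((H, W), dtype=np.float64)
    degenerate = np.empty((H, W), dtype=bool)

    for i0 in range(0, H, chunk_rows):
        i1 = min(i0 + chunk_rows, H)
        w = windows[i0:i1].reshape(i1 - i0, W, k * k).astype(np.float64)
        w = w - w.mean(axis=-1, keepdims=True)
        norm = np.sqrt(np.einsum("rwc,rwc->rw", w, w))
        deg = norm < EPS_NORM
        w /= np.where(deg, 1.0, norm)[..., None]
        resp = w @ kmat.T                          # (rows, W, n*m)
        mx = resp.max(axis=-1, keepdims=True)
        # first index within TIE_TOL of the max = lowest tied (t, s)
        best = (resp >= mx - TIE_TOL).argmax(axis=-1)
        best_val = np.take_along_axis(resp, best[..., None], axis=-1)[..., 0]
        theta_idx[i0:i1] = best // bank.m
        scale_idx[i0:i1] = best % bank.m
        response[i0:i1] = np.where(deg, 0.0, best_val)
        degenerate[i0:i1] = deg

    theta_idx[degenerate] = 0
    scale_idx[degenerate] = 0
    return OrientationScaleMap(theta_index=theta_idx, scale_index=scale_idx,
                               response=response, degenerate=degenerate)


def export_maps(osmap: OrientationScaleMap, prefix: str | Path) -> None:
    """Write debug/visualization maps next to ``prefix``.

    theta/scale indices go to 16-bit single-channel PNGs, the response to a
    32-bit float TIFF.
    """
    import imageio.v3 as iio

    prefix = Path(prefix)
    iio.imwrite(prefix.with_suffix(".theta.png"),
                osmap.theta_index.astype(np.uint16))
    iio.imwrite(prefix.with_suffix(".scale.png"),
                osmap.scale_index.astype(np.uint16))
    iio.imwrite(prefix.with_suffix(".response.tiff"),
                osmap.response.astype(np.float32))
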