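"""The oriented-LSF bilateral filter and its baselines.

The output at pixel p is a normalized weighted mean over its k-by-k window,

    D(p) = k_p^{-1} * sum_q W_s(p, q) * W_r(p, q) * I(q),
    k_p  = sum_q W_s(p, q) * W_r(p, q),

with a range kernel W_r = exp(-(I(q) - I(p))^2 / (2 sigma_r^2)) shared by
all variants.  The variants differ in the spatial kernel W_s:

* oolsf_filter — W_s = exp(-u^2 / (2 sigma_s^2)) where u is the distance of
  q from the line through p oriented along the locally detected vessel
  direction, and (theta, sigma_s) are the per-pixel winners of the
  matched-filter detection.  Weights are constant along the vessel and
  Gaussian across it, so averaging runs along the vessel, not over it.
* bilateral_filter — classic isotropic W_s = exp(-d_pq^2 / (2 sigma_s^2))
  with d_pq the Euclidean pixel distance.
* gaussian_filter — isotropic W_s with the range kernel removed
  (a windowed, renormalized Gaussian mean).

All filters are single-pass and non-iterative; outputs are convex
combinations of window intensities, hence stay in [window min, window max].
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import GrayImage, as_gray
from .kernel_bank import KernelBank, build_bank, _offsets
from .orientation_detection import OrientationScaleMap, detect
from .params import FilterParams

__all__ = ["spatial_weights", "spatial_weight_table", "range_weights",
           "oolsf_filter", "bilateral_filter", "gaussian_filter"]

#: defensive floor for the normalizer k_p; with full-window Gaussian spatial
#: weights k_p >= 1 (the center pixel has weight 1), so this never triggers.
_KP_FLOOR = 1e-12


def _spatial_matrix(theta_deg: float, sigma_px: float, k: int) -> np.ndarray:
    """exp(-(x cos(theta) - y sin(theta))^2 / (2 sigma^2)) over the window.

    This is the magnitude of the LSF profile: no polarity sign and no line
    support cut, so every entry is in (0, 1] and the center entry is 1.
    """
    x, y = _offsets(k)
    th = np.deg2rad(theta_deg)
    u = x * np.cos(th) - y * np.sin(th)
    return np.exp(-u * u / (2.0 * sigma_px * sigma_px))


def spatial_weights(theta_index: int, scale_index: int,
                    params: FilterParams) -> np.ndarray:
    """Adaptive spatial weight window for one (orientation, scale) choice."""
    if not (0 <= theta_index < params.n):
        raise ValueError(f"theta_index {theta_index} outside [0, {params.n})")
    if not (0 <= scale_index < params.m):
        raise ValueError(f"scale_index {scale_index} outside [0, {params.m})")
    return _spatial_matrix(params.thetas_deg[theta_index],
                           params.sigmas_px[scale_index], params.k)


def spatial_weight_table(params: FilterParams) -> np.ndarray:
    """All n*m spatial weight windows, shape (n, m, k, k)."""
    table = np.empty((params.n, params.m, params.k, params.k))
    for t, theta in enumerate(params.thetas_deg):
        for s, sigma in enumerate(params.sigmas_px):
            table[t, s] = _spatial_matrix(theta, sigma, params.k)
    return table


def range_weights(window: np.ndarray, center_value: float,
                  sigma_r: float) -> np.ndarray:
    """Intensity-similarity weights exp(-(I(q) - I(p))^2 / (2 sigma_r^2))."""
    if sigma_r <= 0:
        raise ValueError(f"sigma_r must be positive, got {sigma_r}")
    diff = np.asarray(window, dtype=np.float64) - float(center_value)
    return np.exp(-diff * diff / (2.0 * sigma_r * sigma_r))


def _windows(vals: np.ndarray, k: int, border: str) -> np.ndarray:
    H, W = vals.shape
    if min(H, W) < k:
        raise ValueError(f"image {vals.shape} smaller than the {k}x{k} window")
    padded = np.pad(vals, k // 2, mode=border)
    return sliding_window_view(padded, (k, k))


def _weighted_mean_pass(vals: np.ndarray, k: int, border: str,
                        spatial_of_chunk, sigma_r: float | None,
                        chunk_rows: int = 32) -> np.ndarray:
    """Shared normalized weighted-mean sweep.

    ``spatial_of_chunk(i0, i1)`` returns the spatial weights for rows
    [i0, i1) as an array broadcastable to (i1-i0, W, k, k).  ``sigma_r``
    None drops the range kernel (plain weighted mean).
    """
    windows = _windows(vals, k, border)
    H, W = vals.shape
    out = np.empty_like(vals)
    for i0 in range(0, H, chunk_rows):
        i1 = min(i0 + chunk_rows, H)
        win = windows[i0:i1].astype(np.float64)
        wgt = np.broadcast_to(spatial_of_chunk(i0, i1),
                              win.shape).copy()
        if sigma_r is not None:
            diff = win - vals[i0:i1, :, None, None]
            wgt *= np.exp(-diff * diff / (2.0 * sigma_r * sigma_r))
        kp = wgt.sum(axis=(-1, -2))
        num = (wgt * win).sum(axis=(-1, -2))
        safe = kp > _KP_FLOOR
        out[i0:i1] = np.where(safe, num / np.where(safe, kp, 1.0),
                              vals[i0:i1])
    return np.clip(out, 0.0, 1.0)


def oolsf_filter(image: GrayImage | np.ndarray,
                 params: FilterParams | None = None, *,
                 bank: KernelBank | None = None,
                 detection: OrientationScaleMap | None = None) -> GrayImage:
    """Bilateral filter with the per-pixel optimally oriented LSF kernel.

    Runs in two stages: kernel determination (matched-filter detection of
    each pixel's vessel orientation and scale, unless a precomputed
    ``detection`` is supplied) and filtering (the normalized weighted mean
    with the adaptive spatial kernel).
    """
    params = params or FilterParams()
    img = as_gray(image, params.polarity)
    if bank is None:
        bank = build_bank(params)
    if detection is None:
        detection = detect(img, bank, params.border)
    if detection.shape != img.shape:
        raise ValueError("detection map shape does not match the image")
    table = spatial_weight_table(params)
    t_idx, s_idx = detection.theta_index, detection.scale_index

    def spatial_of_chunk(i0: int, i1: int) -> np.ndarray:
        return table[t_idx[i0:i1], s_idx[i0:i1]]  # (rows, W, k, k)

    out = _weighted_mean_pass(img.values, params.k, params.border,
                              spatial_of_chunk, params.sigma_r)
    return GrayImage(out, img.polarity)


def bilateral_filter(image: GrayImage | np.ndarray, sigma_s: float,
                     sigma_r: float, k: int = 9,
                     border: str = "reflect") -> GrayImage:
    """Classic bilateral filter with an isotropic Gaussian spatial kernel."""
    if sigma_s <= 0 or sigma_r <= 0:
        raise ValueError("sigma_s and sigma_r must be positive")
    img = image if isinstance(image, GrayImage) else GrayImage(image, "dark")
    x, y = _offsets(k)
    ws = np.exp(-(x * x + y * y) / (2.0 * sigma_s * sigma_s))
    out = _weighted_mean_pass(img.values, k, border,
                              lambda i0, i1: ws, sigma_r)
    return GrayImage(out, img.polarity)


def gaussian_filter(image: GrayImage | np.ndarray, sigma_s: float,
                    k: int = 9, border: str = "reflect") -> GrayImage:
    """Windowed Gaussian mean (weights renormalized over the k-by-k window)."""
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    img = image if isinstance(image, GrayImage) else GrayImage(image, "dark")
    x, y = _offsets(k)
    ws = np.exp(-(x * x + y * y) / (2.0 * sigma_s * sigma_s))
    out = _weighted_mean_pass(img.values, k, border,
                              lambda i0, i1: ws, None)
    return GrayImage(out, img.polarity)
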