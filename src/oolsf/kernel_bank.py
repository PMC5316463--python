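"""Multiscale oriented line-spread-function (LSF) kernels.

A retinal vessel seen in a small window is well modeled by a line-spread
function: intensity constant along the vessel direction and spreading as a
Gaussian across it.  The kernel matched to a vessel at angle theta with
cross-section scale sigma is

    K(x, y) = s * exp(-u^2 / (2 sigma^2))   for |v| <= L/2, else 0,

where (u, v) = (x cos(theta) - y sin(theta), x sin(theta) + y cos(theta))
are the window coordinates rotated by theta, L is the line-support length,
and s = -1 for dark-on-bright vessels (fundus green channel) or +1 for
bright-on-dark ones.  At theta = 0 the vessel is aligned with the image
y-axis (a vertical line) and u = x.

A bank holds all m * n kernels on a uniform half-turn orientation grid
theta_i = i * 180 / n and a scale grid sigma_j; it is computed once,
independently of any image.  Each kernel also carries a matching-normalized
copy (zero mean, unit Euclidean norm) used for matched-filter detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import FilterParams

#: slack on the |v| <= L/2 support test, so lattice points on the exact
#: boundary are kept regardless of float rounding in the rotation.
_SUPPORT_TOL = 1e-9

#: centered-norm threshold below which a kernel/patch counts as constant
EPS_NORM = 1e-12


def _offsets(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Window coordinates (x, y) of each cell relative to the center.

    x is the column offset (rightward positive), y the row offset
    (downward positive); both run over -(k//2) .. k//2.
    """
    r = k // 2
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    return x.astype(np.float64), y.astype(np.float64)


def _validate(k: int, sigma_px: float, L: float | None) -> float:
    if k < 3 or k % 2 == 0:
        raise ValueError(f"window side k must be odd and >= 3, got {k}")
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be positive, got {sigma_px}")
    L_eff = float(k) if L is None else float(L)
    if not (0 < L_eff <= k):
        raise ValueError(f"support length L must lie in (0, k], got {L}")
    return L_eff


def matching_normalize(values: np.ndarray,
                       eps: float = EPS_NORM) -> tuple[np.ndarray, bool]:
    """Zero-mean, unit-Euclidean-norm copy of a matrix.

    Returns ``(normalized, degenerate)``; a constant input (centered norm
    below ``eps``) yields an all-zeros matrix and ``degenerate=True``.
    """
    centered = values - values.mean()
    norm = float(np.sqrt(np.sum(centered * centered)))
    if norm < eps:
        return np.zeros_like(values), True
    return centered / norm, False


@dataclass(frozen=True)
class KernelMatrix:
    """One oriented/scaled LSF kernel.

    ``values`` are the raw signed entries of the defining equation;
    ``matched`` is the zero-mean unit-norm copy used only by detection.
    """

    values: np.ndarray
    matched: np.ndarray
    theta_index: int
    scale_index: int
    theta_deg: float
    sigma_px: float

    @property
    def k(self) -> int:
        return self.values.shape[0]


def rotate_kernel(k: int, sigma_px: float, theta_deg: float,
                  polarity: str = "dark", L: float | None = None,
                  theta_index: int = 0, scale_index: int = 0) -> KernelMatrix:
    """Evaluate the LSF kernel at angle ``theta_deg`` analytically.

    The kernel is evaluated at rotated coordinates (u, v), not resampled
    from the axis-aligned kernel, so there are no interpolation artifacts
    at small k.  Entries with |v| > L/2 fall outside the line support and
    are zero.
    """
    L_eff = _validate(k, sigma_px, L)
    if polarity not in ("dark", "bright"):
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")
    x, y = _offsets(k)
    th = np.deg2rad(theta_deg)
    u = x * np.cos(th) - y * np.sin(th)
    v = x * np.sin(th) + y * np.cos(th)
    vals = np.exp(-u * u / (2.0 * sigma_px * sigma_px))
    vals[np.abs(v) > L_eff / 2.0 + _SUPPORT_TOL] = 0.0
    if polarity == "dark":
        vals = -vals
    matched, _ = matching_normalize(vals)
    return KernelMatrix(values=vals, matched=matched,
                        theta_index=theta_index, scale_index=scale_index,
                        theta_deg=float(theta_deg), sigma_px=float(sigma_px))


def make_base_kernel(k: int, sigma_px: float, polarity: str = "dark",
                     L: float | None = None) -> KernelMatrix:
    """Kernel for a vessel aligned with the y-axis (theta = 0, u = x)."""
    return rotate_kernel(k, sigma_px, 0.0, polarity, L)


@dataclass(frozen=True)
class KernelBank:
    """All m*n oriented/scaled kernels, ordered orientation-major.

    ``kernels[t * m + s]`` is the kernel at orientation index ``t`` and
    scale index ``s``; this ordering makes a first-maximum argmax break
    ties by lowest theta_index, then lowest scale_index.
    """

    kernels: tuple[KernelMatrix, ...]
    thetas_deg: tuple[float, ...]
    sigmas_px: tuple[float, ...]
    k: int
    polarity: str

    @property
    def n(self) -> int:
        return len(self.thetas_deg)

    @property
    def m(self) -> int:
        return len(self.sigmas_px)

    def kernel(self, theta_index: int, scale_index: int) -> KernelMatrix:
        return self.kernels[theta_index * self.m + scale_index]

    def matched_stack(self) -> np.ndarray:
        """(n*m, k*k) matrix of flattened matching-normalized kernels."""
        return np.stack([km.matched.ravel() for km in self.kernels])


def build_bank(params: FilterParams) -> KernelBank:
    """Construct the full m*n bank for the given parameters.

    Deterministic: two banks built from equal params are bit-identical.
    """
    kernels = []
    for t, theta in enumerate(params.thetas_deg):
        for s, sigma in enumerate(params.sigmas_px):
            kernels.append(rotate_kernel(params.k, sigma, theta,
                                         params.polarity, params.support_length,
                                         theta_index=t, scale_index=s))
    return KernelBank(kernels=tuple(kernels),
                      thetas_deg=params.thetas_deg,
                      sigmas_px=params.sigmas_px,
                      k=params.k, polarity=params.polarity)


def save_bank_txt(bank: KernelBank, path: str | Path) -> None:
    """Dump raw kernel matrices to a plain-text file, one block per kernel.

    Each block starts with a header line ``theta_deg sigma_px`` followed by
    the k rows of the raw matrix.
    """
    path = Path(path)
    with path.open("w") as fh:
        for km in bank.kernels:
            fh.write(f"{km.theta_deg:.6f} {km.sigma_px:.6f}\n")
            for row in km.values:
                fh.write(" ".join(f"{v:.12e}" for v in row) + "\n")
            fh.write("\n")
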