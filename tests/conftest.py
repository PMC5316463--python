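"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain Python loops and direct formula
evaluation so they share no code path with the vectorized implementation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from oolsf import FilterParams, build_bank


@pytest.fixture(scope="session")
def default_params():
    return FilterParams()


@pytest.fixture(scope="session")
def bright_params():
    return FilterParams(polarity="bright")


@pytest.fixture(scope="session")
def default_bank(default_params):
    return build_bank(default_params)


@pytest.fixture(scope="session")
def bright_bank(bright_params):
    return build_bank(bright_params)


# ---------------------------------------------------------------- oracles

def naive_detect(vals, bank, border="reflect"):
    """Triple-loop matched-filter argmax (pixels x kernels x window)."""
    k = bank.k
    r = k // 2
    H, W = vals.shape
    padded = np.pad(vals, r, mode=border)
    t_map = np.zeros((H, W), dtype=int)
    s_map = np.zeros((H, W), dtype=int)
    resp = np.zeros((H, W))
    deg = np.zeros((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            patch = padded[i:i + k, j:j + k]
            c = patch - patch.mean()
            norm = math.sqrt(float((c * c).sum()))
            if norm < 1e-12:
                deg[i, j] = True
                continue
            c = c / norm
            responses = [float(np.sum(km.matched * c))
                         for km in bank.kernels]
            # tie rule: lowest index within 1e-9 of the maximum wins
            mx = max(responses)
            best_idx = next(idx for idx, rv in enumerate(responses)
                            if rv >= mx - 1e-9)
            t_map[i, j] = best_idx // bank.m
            s_map[i, j] = best_idx % bank.m
            resp[i, j] = responses[best_idx]
    return t_map, s_map, resp, deg


def _lsf_weight_window(theta_deg, sigma, k):
    """Direct evaluation of the oriented spatial weight formula."""
    r = k // 2
    w = np.empty((k, k))
    th = math.radians(theta_deg)
    for row in range(k):
        for col in range(k):
            x, y = col - r, row - r
            u = x * math.cos(th) - y * math.sin(th)
            w[row, col] = math.exp(-u * u / (2.0 * sigma * sigma))
    return w


def naive_oolsf(vals, params, t_map, s_map, border="reflect"):
    """Per-pixel double-loop weighted mean with the adaptive LSF kernel."""
    k, r = params.k, params.k // 2
    H, W = vals.shape
    padded = np.pad(vals, r, mode=border)
    tables = {(t, s): _lsf_weight_window(params.thetas_deg[t],
                                         params.sigmas_px[s], k)
              for t in range(params.n) for s in range(params.m)}
    out = np.empty((H, W))
    two_sr2 = 2.0 * params.sigma_r ** 2
    for i in range(H):
        for j in range(W):
            ws = tables[(t_map[i, j], s_map[i, j])]
            win = padded[i:i + k, j:j + k]
            num = den = 0.0
            for a in range(k):
                for b in range(k):
                    wr = math.exp(-(win[a, b] - vals[i, j]) ** 2 / two_sr2)
                    w = ws[a, b] * wr
                    num += w * win[a, b]
                    den += w
            out[i, j] = num / den
    return out


def naive_bilateral(vals, sigma_s, sigma_r, k, border="reflect"):
    """Per-pixel double-loop classic bilateral filter."""
    r = k // 2
    H, W = vals.shape
    padded = np.pad(vals, r, mode=border)
    out = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            win = padded[i:i + k, j:j + k]
            num = den = 0.0
            for a in range(k):
                for b in range(k):
                    d2 = (a - r) ** 2 + (b - r) ** 2
                    ws = math.exp(-d2 / (2.0 * sigma_s ** 2))
                    wr = math.exp(-(win[a, b] - vals[i, j]) ** 2
                                  / (2.0 * sigma_r ** 2))
                    num += ws * wr * win[a, b]
                    den += ws * wr
            out[i, j] = num / den
    return out
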