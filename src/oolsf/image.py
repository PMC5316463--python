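"""Normalized grayscale image container.

All pipeline stages operate on 2-D float64 intensity fields on the [0, 1]
scale, tagged with a vessel polarity: "dark" for fundus images (vessels darker
than background) and "bright" for inverted or synthetic bright-vessel images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import POLARITIES

_RANGE_TOL = 1e-9


@dataclass
class GrayImage:
    """A 2-D intensity field on [0, 1] with a vessel-polarity flag."""

    values: np.ndarray
    polarity: str = "dark"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, "
                             f"got {self.polarity!r}")
        lo, hi = float(arr.min(initial=0.0)), float(arr.max(initial=0.0))
        if lo < -_RANGE_TOL or hi > 1.0 + _RANGE_TOL:
            raise ValueError(
                f"intensities must lie in [0, 1]; got range [{lo}, {hi}]")
        # tolerate float round-off just outside [0, 1]
        self.values = np.clip(arr, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def as_gray(image: "GrayImage | np.ndarray", polarity: str) -> GrayImage:
    """Coerce an array or GrayImage to a GrayImage with the given polarity.

    A plain array is wrapped with ``polarity``; a GrayImage must already
    agree with it (a mismatch is a configuration error, since detection
    kernels are polarity-signed).
    """
    if isinstance(image, GrayImage):
        if image.polarity != polarity:
            raise ValueError(
                f"image polarity {image.polarity!r} does not match the "
                f"configured polarity {polarity!r}")
        return image
    return GrayImage(np.asarray(image, dtype=np.float64), polarity)
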