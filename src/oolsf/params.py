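"""Parameter container shared by kernel construction, detection and filtering.

The filter has five tunable parameters: the window side ``k`` (pixels, odd),
the spatial-scale grid ``sigmas_px`` (Gaussian cross-section widths of the
line-spread function, pixels), the range-kernel scale ``sigma_r`` (on the
normalized [0, 1] intensity axis), and the orientation/scale counts ``n`` and
``m``.  Defaults are the values used throughout: k=9, sigmas=(0.4, 0.8, 1.2,
1.6), sigma_r=0.04, n=12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

POLARITIES = ("dark", "bright")

#: numpy.pad modes accepted as window border policy.  "reflect" mirrors the
#: image about its edge pixel (no edge duplication) and is the default.
BORDER_MODES = ("reflect", "symmetric", "edge", "wrap")


@dataclass(frozen=True)
class FilterParams:
    """Configuration of the oriented-LSF bilateral filter.

    Attributes
    ----------
    k : int
        Side of the square detection/filtering window, odd, >= 3.
    sigmas_px : tuple of float
        Spatial scales (Gaussian sigma of the vessel cross-section profile,
        in pixels).  Its length is the scale count ``m``.
    sigma_r : float
        Range-kernel scale on the normalized [0, 1] intensity axis.
    n : int
        Number of kernel orientations, uniformly covering a half turn.
    polarity : {"dark", "bright"}
        Whether vessels are darker or brighter than the background.
    border : str
        numpy.pad mode used for window extraction at image borders.
    L : float or None
        Line-support length in pixels (half-width L/2 of the kernel along
        the line direction).  ``None`` means L = k.
    """

    k: int = 9
    sigmas_px: tuple[float, ...] = (0.4, 0.8, 1.2, 1.6)
    sigma_r: float = 0.04
    n: int = 12
    polarity: str = "dark"
    border: str = "reflect"
    L: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigmas_px",
                           tuple(float(s) for s in self.sigmas_px))
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if not self.sigmas_px:
            raise ValueError("sigmas_px must contain at least one scale")
        if any(s <= 0 for s in self.sigmas_px):
            raise ValueError(f"spatial scales must be positive: {self.sigmas_px}")
        if self.sigma_r <= 0:
            raise ValueError(f"sigma_r must be positive, got {self.sigma_r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, "
                             f"got {self.polarity!r}")
        if self.border not in BORDER_MODES:
            raise ValueError(f"border must be one of {BORDER_MODES}, "
                             f"got {self.border!r}")
        if self.L is not None and not (0 < self.L <= self.k):
            raise ValueError(f"L must lie in (0, k], got {self.L}")

    @property
    def m(self) -> int:
        """Number of spatial scales."""
        return len(self.sigmas_px)

    @property
    def support_length(self) -> float:
        """Effective line-support length L (defaults to the window side k)."""
        return float(self.k) if self.L is None else float(self.L)

    @property
    def thetas_deg(self) -> tuple[float, ...]:
        """Orientation grid theta_i = i * 180 / n degrees, i = 0..n-1."""
        return tuple(i * 180.0 / self.n for i in range(self.n))
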