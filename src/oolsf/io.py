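"""Image loading/saving with green-channel extraction and [0, 1] scaling.

RGB fundus photographs are reduced to a single channel before filtering;
the green channel is the default because it carries the largest
vessel-background contrast.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .image import GrayImage

__all__ = ["load_image", "save_image"]

SAVE_EXTENSIONS = (".png", ".tif", ".tiff")
LOAD_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


def _rescale(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype == np.uint16:
        return arr / 65535.0
    if arr.dtype == bool:
        return arr.astype(np.float64)
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(np.float64), 0.0, 1.0)
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")


def load_image(path: str | Path, channel: str | int = "green",
               polarity: str = "dark") -> GrayImage:
    """Read a PNG/TIFF/JPEG image as a normalized GrayImage.

    ``channel`` applies to color inputs: "green" (default), "red", "blue",
    "gray" (luminance), or an explicit channel index.  8-/16-bit integer
    data are rescaled to [0, 1].
    """
    path = Path(path)
    if path.suffix.lower() not in LOAD_EXTENSIONS:
        raise ValueError(f"unsupported image format {path.suffix!r}: {path}")
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 3:
        if arr.shape[2] > 3:            # drop alpha
            arr = arr[..., :3]
        if channel == "gray":
            from skimage.color import rgb2gray
            return GrayImage(rgb2gray(_rescale(arr, path)), polarity)
        idx = _CHANNELS.get(channel, channel)
        if not isinstance(idx, int) or not (0 <= idx < arr.shape[2]):
            raise ValueError(f"invalid channel {channel!r} for {path}")
        arr = arr[..., idx]
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality "
                         f"{arr.ndim} in {path}")
    return GrayImage(_rescale(arr, path), polarity)


def save_image(image: GrayImage | np.ndarray, path: str | Path) -> None:
    """Quantize a [0, 1] image to 8 bits and write it as PNG or TIFF.

    Quantization is round-half-away-from-zero, so a save/load round trip
    changes each pixel by at most 1/255.
    """
    path = Path(path)
    if path.suffix.lower() not in SAVE_EXTENSIONS:
        raise ValueError(f"unsupported output format {path.suffix!r}: {path} "
                         f"(use one of {SAVE_EXTENSIONS})")
    vals = image.values if isinstance(image, GrayImage) else np.asarray(image)
    q = np.floor(np.clip(vals, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(path, q)
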