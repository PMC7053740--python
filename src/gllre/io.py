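"""Image reading/writing and histogram export.

Accepts single-channel PNG/TIFF/PGM.  8-bit images pass through unchanged;
16-bit images are rescaled to [0, 255] by the fixed-range map
round(v * 255 / 65535) (absolute intensity semantics, not per-image
min-max).  RGB inputs are rejected unless luma conversion is requested, in
which case the ITU-R BT.601 weights (0.299, 0.587, 0.114) are applied.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import InvalidInputError

__all__ = ["read_gray", "write_mask", "write_gray", "export_histogram_csv"]

_LUMA = np.array([0.299, 0.587, 0.114])


def read_gray(path, to_gray: bool = False) -> np.ndarray:
    """Read an image file as an 8-bit gray-level array.

    Parameters
    ----------
    path : str or Path
        PNG, TIFF or PGM file.
    to_gray : bool
        Convert RGB(A) input with BT.601 luma weights instead of rejecting it.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 3:
        if not to_gray:
            raise InvalidInputError(
                f"{path.name} has {arr.shape[2]} channels; pass to_gray=True "
                "(--to-gray) for BT.601 luma conversion"
            )
        arr = arr[..., :3] @ _LUMA
        arr = np.round(arr)
    if arr.ndim != 2:
        raise InvalidInputError(f"unsupported image layout {arr.shape} in {path.name}")

    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) * 255.0 / 65535.0)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    out = arr.astype(np.int64)
    if out.min() < 0 or out.max() > 255:
        raise InvalidInputError(f"{path.name}: gray levels outside [0, 255] after conversion")
    return out


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255, background 0)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InvalidInputError(f"mask must be 2-D, got shape {mask.shape}")
    iio.imwrite(Path(path), (mask.astype(bool).astype(np.uint8) * 255))


def write_gray(image: np.ndarray, path) -> None:
    """Write an 8-bit gray image (e.g. a phantom) as PNG/PGM/TIFF."""
    image = np.asarray(image)
    if image.ndim != 2 or image.min() < 0 or image.max() > 255:
        raise InvalidInputError("expected a 2-D image with values in [0, 255]")
    iio.imwrite(Path(path), image.astype(np.uint8))


def export_histogram_csv(hist, path) -> None:
    """Dump an L x L histogram as CSV: row = gray level i, column = LRE bin j."""
    p = hist.p if hasattr(hist, "p") else np.asarray(hist)
    np.savetxt(Path(path), p, delimiter=",", fmt="%.12g")
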