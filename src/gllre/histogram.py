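"""Gray-level / local-relative-entropy (GLLRE) two-dimensional histogram.

A pixel's local relative entropy (LRE) scores how strongly its n x n
neighborhood deviates from the neighborhood mean brightness:

    J(x, y) = sum_w I_w * |log(I_w / Ibar(x, y))|

where the sum runs over the window centered at (x, y) and Ibar is the window
mean.  The LRE is near zero inside homogeneous object or background regions
and large at edges and on noise pixels.  After min-max normalization of J to
the integer range [0, L-1], the joint frequencies of (gray level, normalized
LRE) pairs over all pixels form an L x L histogram whose low-LRE strip holds
the class mass used for threshold selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "LREImage",
    "GLLREHistogram",
    "compute_lre",
    "normalize_lre",
    "build_histogram",
    "gllre_histogram",
]

# numpy pad modes implementing each border policy
_PAD_MODES = {"replicate": "edge", "mirror": "reflect"}


@dataclass(frozen=True)
class LREImage:
    """Local-relative-entropy map of an image.

    Attributes
    ----------
    raw : ndarray of float, shape (M, N)
        Unnormalized LRE values in nats; nonnegative.
    normalized : ndarray of int, shape (M, N)
        Raw values min-max scaled to the integer range [0, L-1].
    j_min, j_max : float
        Observed extremes of the raw map.
    """

    raw: np.ndarray
    normalized: np.ndarray
    j_min: float
    j_max: float


@dataclass(frozen=True)
class GLLREHistogram:
    """Joint (gray level, normalized LRE) frequency matrix.

    ``p[i, j]`` is the fraction of pixels with gray level ``i`` and
    normalized LRE ``j``; ``counts`` holds the raw pair counts and
    ``total`` the number of pixels, so ``p = counts / total`` exactly.
    """

    p: np.ndarray
    counts: np.ndarray
    total: int

    @property
    def levels(self) -> int:
        return self.p.shape[0]

    def gray_marginal(self) -> np.ndarray:
        """Marginal over the LRE axis: the ordinary 1-D gray-level histogram."""
        return self.counts.sum(axis=1)


def _validate_image(image: np.ndarray, levels: int) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise InvalidInputError(
            f"expected a non-empty 2-D gray image, got shape {image.shape}"
        )
    if not np.issubdtype(image.dtype, np.integer):
        if not np.allclose(image, np.round(image)):
            raise InvalidInputError("gray image must hold integer gray levels")
        image = np.round(image).astype(np.int64)
    if image.min() < 0 or image.max() > levels - 1:
        raise InvalidInputError(
            f"gray levels must lie in [0, {levels - 1}], "
            f"got range [{image.min()}, {image.max()}]"
        )
    return image.astype(np.int64, copy=False)


def compute_lre(
    image: np.ndarray,
    window: int = 3,
    border: str = "replicate",
    levels: int = 256,
) -> LREImage:
    """Compute the local-relative-entropy map of a gray image.

    Parameters
    ----------
    image : ndarray of int, shape (M, N)
        Gray levels in [0, levels-1].
    window : odd int >= 3
        Side length n of the square neighborhood.
    border : {'replicate', 'mirror'}
        How windows extending past the image border are filled.
    levels : int
        Number of gray levels L; sets the normalized range [0, L-1].

    Notes
    -----
    Terms with a zero pixel value contribute 0 (the 0*|log 0| := 0 entropy
    convention), and an all-zero window has mean 0 and LRE 0.  Natural
    logarithms are used; the choice of base is cancelled by the min-max
    normalization, so the normalized map is base-invariant.
    """
    image = _validate_image(image, levels)
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError(f"window must be an odd integer >= 3, got {window}")
    if border not in _PAD_MODES:
        raise InvalidParameterError(
            f"border must be one of {sorted(_PAD_MODES)}, got {border!r}"
        )

    r = (window - 1) // 2
    padded = np.pad(image.astype(np.float64), r, mode=_PAD_MODES[border])
    win = sliding_window_view(padded, (window, window))  # (M, N, n, n) view
    mean = win.mean(axis=(2, 3))

    with np.errstate(divide="ignore", invalid="ignore"):
        term = win * np.abs(np.log(win) - np.log(mean)[..., None, None])
    # zero pixels contribute 0; an all-zero window (mean 0) is all zeros too
    term = np.where(win > 0, term, 0.0)
    raw = term.sum(axis=(2, 3))

    normalized = normalize_lre(raw, levels)
    return LREImage(
        raw=raw,
        normalized=normalized,
        j_min=float(raw.min()),
        j_max=float(raw.max()),
    )


def normalize_lre(raw: np.ndarray, levels: int = 256) -> np.ndarray:
    """Min-max scale a raw LRE map to integers in [0, levels-1].

    Values are rounded half-up; a constant map (j_max == j_min) maps to all
    zeros.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)) or raw.size == 0:
        raise InvalidInputError("raw LRE map must be non-empty and finite")
    j_min = raw.min()
    j_max = raw.max()
    if j_max == j_min:
        return np.zeros(raw.shape, dtype=np.int64)
    scaled = (raw - j_min) / (j_max - j_min) * (levels - 1)
    return np.floor(scaled + 0.5).astype(np.int64)  # round half up


def build_histogram(
    image: np.ndarray, lre: np.ndarray, levels: int = 256
) -> GLLREHistogram:
    """Count (gray level, normalized LRE) pairs into an L x L histogram."""
    image = _validate_image(image, levels)
    lre = np.asarray(lre)
    if lre.shape != image.shape:
        raise InvalidInputError(
            f"LRE shape {lre.shape} does not match image shape {image.shape}"
        )
    lre = _validate_image(lre, levels)
    flat = image.ravel() * levels + lre.ravel()
    counts = np.bincount(flat, minlength=levels * levels).reshape(levels, levels)
    total = image.size
    return GLLREHistogram(p=counts / total, counts=counts, total=total)


def gllre_histogram(
    image: np.ndarray,
    window: int = 3,
    border: str = "replicate",
    levels: int = 256,
) -> GLLREHistogram:
    """Full pipeline: LRE map -> normalization -> joint histogram."""
    lre = compute_lre(image, window=window, border=border, levels=levels)
    return build_histogram(image, lre.normalized, levels=levels)
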