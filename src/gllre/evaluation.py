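"""Segmentation evaluation: the misclassification error (ME).

ME is the fraction of pixels whose binary label disagrees with the ground
truth:

    ME = 1 - (|B_o ∩ B_T| + |F_o ∩ F_T|) / (|B_o| + |F_o|)

with B/F the background/foreground pixel sets of the ground-truth (o) and
thresholded (T) masks; the denominator is the pixel count M*N.  ME = 0 is a
perfect segmentation, ME = 1 a completely wrong one.

Because bi-level thresholding cannot know which side of the cut is the
"object", :func:`best_polarity_me` also reports the ME of the complemented
mask and keeps the better orientation.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["misclassification_error", "best_polarity_me"]


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise InvalidInputError(f"expected a non-empty 2-D mask, got shape {mask.shape}")
    if mask.dtype == bool:
        return mask
    u = np.unique(mask)
    if not np.isin(u, (0, 1)).all():
        raise InvalidInputError(f"mask values must be binary {{0, 1}}, got {u}")
    return mask.astype(bool)


def misclassification_error(truth: np.ndarray, test: np.ndarray) -> float:
    """Fraction of pixels misclassified relative to the ground truth."""
    truth = _as_mask(truth)
    test = _as_mask(test)
    if truth.shape != test.shape:
        raise InvalidInputError(
            f"mask shapes differ: {truth.shape} vs {test.shape}"
        )
    return float(np.mean(truth != test))


def best_polarity_me(truth: np.ndarray, test: np.ndarray) -> tuple[float, bool]:
    """ME minimized over the two polarities of ``test``.

    Returns ``(me, flipped)``; ties prefer the unflipped orientation.
    """
    plain = misclassification_error(truth, test)
    flipped = misclassification_error(truth, 1 - _as_mask(test).astype(np.uint8))
    if flipped < plain:
        return flipped, True
    return plain, False
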