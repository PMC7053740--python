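"""Scikit-learn style thresholder estimators.

`fit(X)` takes a single 2-D gray image, selects the threshold, and exposes
it as fitted attributes; `predict(X)` (alias `transform`) labels the pixels
of any image of the same gray range with that threshold.  Both estimators
follow the sklearn contract (``get_params``/``set_params``, clonable
constructors, trailing-underscore fitted attributes) so they compose with
``sklearn.base.clone`` and pipeline tooling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import thresholding as th
from .exceptions import InvalidParameterError
from .histogram import build_histogram, compute_lre

__all__ = ["GLLREThresholder", "HistogramThresholder", "threshold_image"]

_2D_METHODS = ("mre", "otsu", "kapur")


class GLLREThresholder(BaseEstimator):
    """Bi-level thresholding on the gray-level / local-relative-entropy histogram.

    Parameters
    ----------
    method : {'mre', 'otsu', 'kapur'}
        Selection criterion on the 2-D histogram: minimum relative entropy
        (the method of interest), or the Otsu / Kapur criteria restricted to
        the same class regions.
    window : odd int >= 3
        Neighborhood side length for the LRE map.
    border : {'replicate', 'mirror'}
        Border fill for windows leaving the image.
    levels : int
        Number of gray levels L.
    invert : bool
        Flip the foreground/background polarity of predicted masks.

    Attributes
    ----------
    threshold_ : ThresholdVector
        Selected (s, t).
    criterion_ : float
        Criterion value at the selected vector (D for 'mre', the
        between-class / entropy score otherwise).
    lre_ : LREImage
        The LRE map of the fitted image.
    histogram_ : GLLREHistogram
        The joint histogram of the fitted image.

    Examples
    --------
    >>> from gllre import GLLREThresholder, generate_phantom, PhantomSpec
    >>> img, truth = generate_phantom(PhantomSpec(seed=1))
    >>> est = GLLREThresholder().fit(img)
    >>> 60 < est.threshold_.s <= 180
    True
    """

    def __init__(
        self,
        method: str = "mre",
        window: int = 3,
        border: str = "replicate",
        levels: int = 256,
        invert: bool = False,
    ):
        self.method = method
        self.window = window
        self.border = border
        self.levels = levels
        self.invert = invert

    def fit(self, X, y=None):
        if self.method not in _2D_METHODS:
            raise InvalidParameterError(
                f"method must be one of {_2D_METHODS}, got {self.method!r}"
            )
        X = np.asarray(X)
        self.lre_ = compute_lre(
            X, window=self.window, border=self.border, levels=self.levels
        )
        self.histogram_ = build_histogram(X, self.lre_.normalized, levels=self.levels)
        selector = {
            "mre": th.select_threshold_min_re,
            "otsu": th.otsu_gllre,
            "kapur": th.kapur_gllre,
        }[self.method]
        self.threshold_ = selector(self.histogram_)
        if self.method == "mre":
            self.criterion_ = th.relative_entropy_criterion(
                self.histogram_, self.threshold_
            ).D
        else:
            self.criterion_ = float("nan")
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        return th.apply_threshold(X, self.threshold_, invert=self.invert)

    def transform(self, X):
        return self.predict(X)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)


class HistogramThresholder(BaseEstimator):
    """Classical 1-D thresholding on the gray-level histogram.

    Parameters
    ----------
    method : {'otsu', 'kapur'}
        Between-class variance (Otsu) or maximum class entropy (Kapur).
    levels, invert : see :class:`GLLREThresholder`.

    Attributes
    ----------
    threshold_ : int
        Selected gray-level cut s; foreground is ``I < s``.
    """

    def __init__(self, method: str = "otsu", levels: int = 256, invert: bool = False):
        self.method = method
        self.levels = levels
        self.invert = invert

    def fit(self, X, y=None):
        if self.method not in ("otsu", "kapur"):
            raise InvalidParameterError(
                f"method must be 'otsu' or 'kapur', got {self.method!r}"
            )
        X = np.asarray(X)
        hist = np.bincount(X.ravel().astype(np.int64), minlength=self.levels)
        selector = th.otsu_1d if self.method == "otsu" else th.kapur_1d
        self.threshold_ = selector(hist)
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        return th.apply_threshold(X, self.threshold_, invert=self.invert)

    def transform(self, X):
        return self.predict(X)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)


_METHOD_MAP = {
    "gllre-mre": (GLLREThresholder, "mre"),
    "gllre-otsu": (GLLREThresholder, "otsu"),
    "gllre-kapur": (GLLREThresholder, "kapur"),
    "otsu": (HistogramThresholder, "otsu"),
    "kapur": (HistogramThresholder, "kapur"),
}


def threshold_image(
    image: np.ndarray,
    method: str = "gllre-mre",
    window: int = 3,
    border: str = "replicate",
    levels: int = 256,
    invert: bool = False,
):
    """Thin functional wrapper: fit the named thresholder, return (mask, estimator).

    ``method`` is one of 'gllre-mre', 'gllre-otsu', 'gllre-kapur' (2-D) or
    'otsu', 'kapur' (1-D baselines).
    """
    if method not in _METHOD_MAP:
        raise InvalidParameterError(
            f"method must be one of {sorted(_METHOD_MAP)}, got {method!r}"
        )
    cls, inner = _METHOD_MAP[method]
    if cls is GLLREThresholder:
        est = cls(method=inner, window=window, border=border, levels=levels, invert=invert)
    else:
        est = cls(method=inner, levels=levels, invert=invert)
    est.fit(image)
    return est.predict(image), est
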