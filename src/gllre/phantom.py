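"""Synthetic two-class phantoms with exact ground truth.

The generator emulates the bimodal-with-valley regime that bi-level
thresholding assumes: a background at one gray mode, foreground objects at
another, optionally corrupted by additive Gaussian noise (rounded and
clipped to the gray range).  The rasterized geometry is returned as the
ground-truth mask, so every pipeline stage is testable without external
images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import InvalidParameterError

__all__ = ["PhantomSpec", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a two-class phantom image.

    Defaults match the regime exercised throughout the test suite: a
    128 x 128 image, background mode 60, foreground mode 180 (a 120-level
    gap, comfortably bimodal), three disks covering roughly 20% of the
    area, and noiseless rendering; ``noise_sigma`` adds rounded, clipped
    additive Gaussian noise in gray levels.
    """

    shape: tuple[int, int] = (128, 128)
    bg_level: int = 60
    fg_level: int = 180
    geometry: str = "disks"
    n_objects: int = 3
    area_fraction: float = 0.2
    noise_sigma: float = 0.0
    levels: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.bg_level == self.fg_level:
            raise InvalidParameterError("bg_level and fg_level must differ")
        for name in ("bg_level", "fg_level"):
            v = getattr(self, name)
            if not 0 <= v <= self.levels - 1:
                raise InvalidParameterError(f"{name}={v} outside [0, {self.levels - 1}]")
        if self.geometry not in ("disks", "rectangles", "blobs"):
            raise InvalidParameterError(f"unknown geometry {self.geometry!r}")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if not 0 < self.area_fraction < 1:
            raise InvalidParameterError("area_fraction must lie in (0, 1)")
        if self.n_objects < 1:
            raise InvalidParameterError("n_objects must be >= 1")


def _disk_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    M, N = spec.shape
    mask = np.zeros((M, N), dtype=bool)
    # equal-area disks summing to the requested fraction (overlap avoided
    # by rejection sampling on the centers, best effort)
    r = np.sqrt(spec.area_fraction * M * N / (np.pi * spec.n_objects))
    yy, xx = np.mgrid[0:M, 0:N]
    centers: list[tuple[float, float]] = []
    for _ in range(spec.n_objects):
        lo_y, hi_y = (r, M - r) if M > 2 * r else (M / 2, M / 2 + 1e-9)
        lo_x, hi_x = (r, N - r) if N > 2 * r else (N / 2, N / 2 + 1e-9)
        for _attempt in range(200):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 > (2 * r) ** 2 for oy, ox in centers):
                break
        centers.append((cy, cx))
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def _rect_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    M, N = spec.shape
    mask = np.zeros((M, N), dtype=bool)
    side = np.sqrt(spec.area_fraction * M * N / spec.n_objects)
    for _ in range(spec.n_objects):
        h = max(1, int(round(side * rng.uniform(0.7, 1.4))))
        w = max(1, int(round(spec.area_fraction * M * N / spec.n_objects / h)))
        h, w = min(h, M), min(w, N)
        y0 = rng.integers(0, M - h + 1)
        x0 = rng.integers(0, N - w + 1)
        mask[y0 : y0 + h, x0 : x0 + w] = True
    return mask


def _blob_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    # smoothed Gaussian field thresholded at the quantile that yields the
    # requested foreground fraction; n_objects sets the correlation length
    M, N = spec.shape
    scale = max(2.0, min(M, N) / (4.0 * spec.n_objects))
    field = ndimage.gaussian_filter(rng.standard_normal((M, N)), sigma=scale)
    cut = np.quantile(field, 1.0 - spec.area_fraction)
    return field > cut


_GEOMETRIES = {"disks": _disk_mask, "rectangles": _rect_mask, "blobs": _blob_mask}


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a phantom image and its exact ground-truth mask.

    Returns
    -------
    image : ndarray of int64, shape ``spec.shape``
        Gray levels in [0, levels-1]; exactly ``{bg_level, fg_level}`` when
        ``noise_sigma == 0``.
    mask : ndarray of uint8
        1 on foreground (``fg_level``) pixels, 0 elsewhere.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _GEOMETRIES[spec.geometry](spec, rng)
    image = np.where(mask, spec.fg_level, spec.bg_level).astype(np.float64)
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    image = np.clip(np.round(image), 0, spec.levels - 1).astype(np.int64)
    return image, mask.astype(np.uint8)
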