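"""Slice conditioning ahead of segmentation: crop, contrast, denoise.

All operations act on 8-bit gray slices (``uint8`` arrays, row index top to
bottom, column index left to right).  Real CT data stored in Hounsfield
units is first mapped onto this scale with :func:`window_to_uint8`; the
segmentation and classification stages all assume 0-255 grays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GaussianSpec",
    "DEFAULT_GAUSS_SIGMA",
    "PreprocessError",
    "window_to_uint8",
    "body_bbox",
    "crop_to_body",
    "equalize_histogram",
    "gaussian_denoise",
    "preprocess_slice",
]

DEFAULT_AIR_CUTOFF = 15
DEFAULT_CROP_MARGIN = 10
DEFAULT_WINDOW = (-1000.0, 400.0)
DEFAULT_GAUSS_SIGMA = 0.7


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class GaussianSpec:
    """Truncated Gaussian smoothing kernel.

    The kernel's total width is 6 sigma, rounded up to the next odd integer
    so the kernel has a well-defined center; it is normalized to sum 1.
    """

    sigma: float = DEFAULT_GAUSS_SIGMA

    def __post_init__(self):
        if self.sigma <= 0:
            raise PreprocessError("Gaussian sigma must be > 0")

    @property
    def width(self) -> int:
        w = int(np.ceil(6.0 * self.sigma))
        return w + 1 if w % 2 == 0 else w

    @property
    def radius(self) -> int:
        return (self.width - 1) // 2

    def kernel(self) -> np.ndarray:
        t = np.arange(-self.radius, self.radius + 1, dtype=float)
        k = np.exp(-0.5 * (t / self.sigma) ** 2)
        return k / k.sum()


def window_to_uint8(hu: np.ndarray, window=DEFAULT_WINDOW) -> np.ndarray:
    """Linearly map a HU image onto [0, 255], clipping outside the window."""
    lo, hi = window
    if hi <= lo:
        raise PreprocessError("window_high must exceed window_low")
    scaled = (np.asarray(hu, float) - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def body_bbox(image: np.ndarray, cutoff: int = DEFAULT_AIR_CUTOFF,
              margin: int = DEFAULT_CROP_MARGIN):
    """Half-open bounding box (r0, r1, c0, c1) of pixels above ``cutoff``,
    expanded by ``margin`` and clipped to the frame; None if all-dark."""
    img = np.asarray(image)
    rows, cols = np.nonzero(img > cutoff)
    if rows.size == 0:
        return None
    r0 = max(int(rows.min()) - margin, 0)
    r1 = min(int(rows.max()) + 1 + margin, img.shape[0])
    c0 = max(int(cols.min()) - margin, 0)
    c1 = min(int(cols.max()) + 1 + margin, img.shape[1])
    return (r0, r1, c0, c1)


def crop_to_body(image: np.ndarray, margin: int = DEFAULT_CROP_MARGIN,
                 cutoff: int = DEFAULT_AIR_CUTOFF) -> np.ndarray:
    """Crop to the bounding box of non-air pixels (gray > ``cutoff``).

    An image with no pixel above the cutoff is returned unchanged.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise PreprocessError("empty image")
    box = body_bbox(img, cutoff=cutoff, margin=margin)
    if box is None:
        return img.copy()
    r0, r1, c0, c1 = box
    return img[r0:r1, c0:c1].copy()


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Global 256-bin histogram equalization, ``T(k) = round(255 * cdf(k))``.

    The mapping is monotone non-decreasing, so pixel order relations are
    preserved; applying it twice equals applying it once up to the discrete
    CDF mapping.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise PreprocessError("empty image")
    img = img.astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist) / img.size
    lut = np.rint(255.0 * cdf).astype(np.uint8)
    return lut[img]


def gaussian_denoise(image: np.ndarray,
                     spec: GaussianSpec | float = DEFAULT_GAUSS_SIGMA
                     ) -> np.ndarray:
    """Convolve with the normalized truncated Gaussian (reflective border)."""
    if not isinstance(spec, GaussianSpec):
        spec = GaussianSpec(float(spec))
    img = np.asarray(image, dtype=float)
    k = spec.kernel()
    out = ndimage.convolve1d(img, k, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, k, axis=1, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess_slice(image: np.ndarray, *, crop: bool = False,
                     margin: int = DEFAULT_CROP_MARGIN,
                     equalize: bool = False,
                     gauss_sigma: float = DEFAULT_GAUSS_SIGMA) -> np.ndarray:
    """Default conditioning chain: (crop) -> (equalize) -> denoise.

    Cropping and equalization are off by default: cropping changes the
    coordinate frame (the pipeline tracks the offset explicitly via
    :func:`body_bbox` when it is wanted), and equalization is a contrast aid
    for real scans whose gray scale does not already match the 0-255
    classification scale.
    """
    out = np.asarray(image).astype(np.uint8)
    if crop:
        out = crop_to_body(out, margin=margin)
    if equalize:
        out = equalize_histogram(out)
    if gauss_sigma and gauss_sigma > 0:
        out = gaussian_denoise(out, GaussianSpec(gauss_sigma))
    return out
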