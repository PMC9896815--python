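"""Lung parenchyma segmentation on a preprocessed axial slice.

The stages follow the classical adaptive-threshold pipeline for chest CT:

1. iterative (ISODATA-style) gray threshold between the dark classes
   (outside field, air, parenchyma) and the bright ones (soft tissue, bone);
2. binarization — parenchyma candidates are the pixels *below* threshold;
3. 4-connected component screening by area: the largest component is the
   surrounding air and is discarded; the next two large components are the
   lungs; tiny components (trachea, noise) are dropped.  A scale factor
   ``lambda`` guards the degenerate cases (fused lungs, single lung);
4. hole filling (vessels and nodules appear as holes in the binary lungs);
5. morphological boundary repair and smoothing per lung;
6. multiplication of the repaired mask with the gray slice.

Quality versus a reference mask is measured with the Dice similarity
coefficient ``2|A∩B| / (|A|+|B|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, closing, opening, erosion

__all__ = [
    "SegmentationError",
    "ComponentTable",
    "SegmentationResult",
    "SegmentConfig",
    "iterative_threshold",
    "binarize_parenchyma",
    "screen_components",
    "fill_holes",
    "repair_boundary",
    "split_left_right",
    "apply_mask",
    "dice_coefficient",
    "segment_slice",
]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


class SegmentationError(ValueError):
    pass


@dataclass
class ComponentTable:
    """4-connected components of a binary slice with areas sorted descending."""

    labels: np.ndarray              # label image, 0 = background
    areas: np.ndarray               # area per label, index 0 = label 1
    order: np.ndarray               # label ids sorted by descending area
    lam: float                      # scale factor used for screening

    @property
    def sorted_areas(self) -> np.ndarray:
        """The descending area vector S with S1 >= S2 >= ..."""
        return self.areas[self.order - 1]


@dataclass
class SegmentationResult:
    mask: np.ndarray                # combined parenchyma mask
    left: np.ndarray
    right: np.ndarray
    masked_image: np.ndarray        # gray slice * mask
    threshold: float
    fused: bool = False             # single connected lung region
    components: ComponentTable | None = None


@dataclass(frozen=True)
class SegmentConfig:
    epsilon: float = 1e-3
    lam: float = 50.0
    open_radius: int = 9
    erode_radius: int = 1
    repair_ops: tuple[str, ...] = ("close", "open", "erode")


def iterative_threshold(image: np.ndarray, epsilon: float = 1e-3) -> float:
    """Adaptive gray threshold by fixed-point iteration.

    Starting from ``T0 = (g_max + g_min) / 2``, the threshold is repeatedly
    replaced by the average of the mean gray below and the mean gray at or
    above it, until the update falls below ``epsilon`` (gray levels).
    """
    g = np.asarray(image, dtype=float).ravel()
    if g.size == 0:
        raise SegmentationError("empty image")
    gmax, gmin = g.max(), g.min()
    if gmax == gmin:
        raise SegmentationError("constant image: threshold undefined")
    t = (gmax + gmin) / 2.0
    for _ in range(500):
        lo, hi = g[g < t], g[g >= t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = (lo.mean() + hi.mean()) / 2.0
        if abs(t_new - t) < epsilon:
            return float(t_new)
        t = t_new
    return float(t)


def binarize_parenchyma(image: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground = pixels strictly darker than the threshold."""
    return np.asarray(image, dtype=float) < threshold


def screen_components(mask: np.ndarray, lam: float = 50.0,
                      border_guard: bool = True
                      ) -> tuple[np.ndarray, ComponentTable]:
    """Area-based screening of 4-connected components.

    The largest component is the surrounding air and is always discarded;
    components touching the image border are likewise ineligible as lung
    when ``border_guard`` is set.  Among the remaining candidates with
    leading areas S2 >= S3: if ``S2/S3 <= lam`` every component with area in
    ``[S3, S2]`` is kept (left and right lung), otherwise — fused lungs or a
    single lung in view — only the S2 component survives.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_CROSS)
    if n == 0:
        raise SegmentationError("no foreground components")
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    order = np.arange(1, n + 1)[np.argsort(-areas, kind="stable")]
    table = ComponentTable(labels=labels, areas=areas, order=order, lam=lam)

    air_label = int(order[0])
    eligible = [int(l) for l in order if l != air_label]
    if border_guard:
        border = np.zeros_like(mask)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        border_labels = set(np.unique(labels[border & mask]).tolist()) - {0}
        eligible = [l for l in eligible if l not in border_labels]
    if not eligible:
        raise SegmentationError("no lung candidate found after screening")

    s2 = areas[eligible[0] - 1]
    if len(eligible) >= 2:
        s3 = areas[eligible[1] - 1]
        if s3 > 0 and s2 / s3 <= lam:
            keep = [l for l in eligible if s3 <= areas[l - 1] <= s2]
        else:
            keep = [eligible[0]]
    else:
        keep = [eligible[0]]
    out = np.isin(labels, keep)
    return out, table


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    return ndimage.binary_fill_holes(np.asarray(mask, bool), structure=_CROSS)


def repair_boundary(left: np.ndarray, right: np.ndarray,
                    open_radius: int = 9, erode_radius: int = 1,
                    ops: tuple[str, ...] = ("close", "open", "erode")
                    ) -> np.ndarray:
    """Morphological boundary repair, each lung processed independently.

    Default sequence per lung: closing with a disk (re-incorporates
    juxta-pleural notches), opening with the same disk (removes spurs), and
    a light erosion that smooths the contour.  Radius 0 disables a step.
    """
    left = np.asarray(left, bool)
    right = np.asarray(right, bool)
    if (left & right).any():
        raise SegmentationError("left and right masks overlap")

    def _repair(m: np.ndarray) -> np.ndarray:
        if not m.any():
            return m
        for op in ops:
            if op == "close" and open_radius > 0:
                m = closing(m, disk(open_radius)).astype(bool)
            elif op == "open" and open_radius > 0:
                m = opening(m, disk(open_radius)).astype(bool)
            elif op == "erode" and erode_radius > 0:
                m = erosion(m, disk(erode_radius)).astype(bool)
        return m

    return _repair(left) | _repair(right)


@dataclass
class LungSplit:
    left: np.ndarray
    right: np.ndarray
    fused: bool = False


def split_left_right(mask: np.ndarray) -> LungSplit:
    """Assign the component with smaller mean column index as (image-) left.

    A single connected region — fused lungs — is returned in both slots
    with ``fused=True``.  More than two components is an error: screen
    first.
    """
    mask = np.asarray(mask, bool)
    labels, n = ndimage.label(mask, structure=_CROSS)
    if n == 0:
        raise SegmentationError("empty mask")
    if n > 2:
        raise SegmentationError(f"{n} components; screen before splitting")
    if n == 1:
        return LungSplit(left=mask.copy(), right=mask.copy(), fused=True)
    mean_cols = [np.nonzero(labels == l)[1].mean() for l in (1, 2)]
    left_label = 1 if mean_cols[0] <= mean_cols[1] else 2
    return LungSplit(left=labels == left_label, right=labels == (3 - left_label))


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise product of gray slice and binary mask (background 0)."""
    image = np.asarray(image)
    mask = np.asarray(mask, bool)
    if image.shape != mask.shape:
        raise SegmentationError("image and mask shapes differ")
    return (image * mask).astype(image.dtype)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise SegmentationError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise SegmentationError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / denom


def segment_slice(image: np.ndarray, config: SegmentConfig | None = None
                  ) -> SegmentationResult:
    """Full single-slice parenchyma segmentation.

    threshold -> binarize -> screen -> split -> fill -> repair -> combine ->
    apply mask.  Stage errors propagate as :class:`SegmentationError` with
    the stage name prefixed.
    """
    cfg = config or SegmentConfig()
    image = np.asarray(image)

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except SegmentationError as e:
            raise SegmentationError(f"{name}: {e}") from e

    t = _stage("threshold", iterative_threshold, image, cfg.epsilon)
    binary = binarize_parenchyma(image, t)
    screened, table = _stage("screen", screen_components, binary, cfg.lam)
    split = _stage("split", split_left_right, screened)
    if split.fused:
        filled = fill_holes(split.left)
        repaired = _stage("repair", repair_boundary, filled,
                          np.zeros_like(filled),
                          cfg.open_radius, cfg.erode_radius, cfg.repair_ops)
        left = right = repaired
    else:
        left_f = fill_holes(split.left)
        right_f = fill_holes(split.right)
        repaired = _stage("repair", repair_boundary, left_f, right_f,
                          cfg.open_radius, cfg.erode_radius, cfg.repair_ops)
        _, n = ndimage.label(repaired, structure=_CROSS)
        if n >= 2:
            resplit = split_left_right(screened_two_largest(repaired))
            left, right = resplit.left, resplit.right
        else:
            left = right = repaired
    if not repaired.any():
        raise SegmentationError("repair: empty parenchyma mask")
    masked = apply_mask(image, repaired)
    return SegmentationResult(mask=repaired, left=left, right=right,
                              masked_image=masked, threshold=t,
                              fused=split.fused, components=table)


def screened_two_largest(mask: np.ndarray) -> np.ndarray:
    """Keep the two largest 4-connected components (helper after repair)."""
    labels, n = ndimage.label(np.asarray(mask, bool), structure=_CROSS)
    if n <= 2:
        return np.asarray(mask, bool)
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.arange(1, n + 1)[np.argsort(-areas)][:2]
    return np.isin(labels, keep)
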