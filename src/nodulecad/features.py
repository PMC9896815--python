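"""Candidate nodule regions and their hand-crafted shape/gray descriptors.

A candidate region is a bright 8-connected blob inside the masked
parenchyma image (nodules and vessels are brighter than the surrounding
parenchyma).  Each region is described by seven features:

* area ``S_R`` — pixel count;
* perimeter ``P_R`` — length of the closed outer boundary chain, diagonal
  steps weighted sqrt(2);
* quasi-roundness ``C_R = 4 pi S_R / P_R^2`` — near 1 for compact round
  regions, small for elongated vessels (digitization can push it above 1
  for tiny regions);
* marginal burr rate ``MBR = n_b / n`` — fraction of boundary points that
  are burrs (spiculation spikes);
* marginal burr magnitude ``MBM`` — mean excess of the normalized radial
  distance at the burr points over the boundary average;
* gray mean ``GM``, population gray variance ``GV``, and gray entropy
  ``GE`` (natural log over the 256-level histogram of the region).

A boundary point is classified as a burr when its normalized radial
distance from the region centroid is a strict local maximum within a small
window of boundary neighbors and exceeds the boundary mean by a margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .parenchyma import iterative_threshold, SegmentationError

__all__ = [
    "FeatureError",
    "Region",
    "RadialProfile",
    "RegionFeatures",
    "trace_boundary",
    "chain_perimeter",
    "candidate_regions",
    "refine_region",
    "radial_profile",
    "shape_features",
    "gray_features",
    "compute_features",
    "features_table",
    "DEFAULT_BURR_WINDOW",
    "DEFAULT_BURR_MARGIN",
]

DEFAULT_BURR_WINDOW = 5
DEFAULT_BURR_MARGIN = 0.05

_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighborhood in clockwise order on screen coordinates (row down)
_DIRS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_DIR_INDEX = {d: i for i, d in enumerate(_DIRS)}


class FeatureError(ValueError):
    pass


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Closed outer boundary chain of an 8-connected region.

    Moore-neighbor tracing with Jacob's stopping criterion, starting at the
    topmost-leftmost pixel.  Pixels on one-pixel-wide protrusions appear
    twice in the chain (the walk goes out and back), so the chain length is
    a faithful perimeter even for spikes and line-like regions.  Returns an
    (n, 2) array of (row, col) points; a single isolated pixel gives n = 1.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if pts.size == 0:
        raise FeatureError("trace_boundary: empty mask")
    start = tuple(pts[np.lexsort((pts[:, 1], pts[:, 0]))][0])
    nrows, ncols = mask.shape

    def fg(p):
        return 0 <= p[0] < nrows and 0 <= p[1] < ncols and mask[p]

    chain = [start]
    cur = start
    prev_bg = (start[0], start[1] - 1)  # west of start is background
    first_transition = None
    for _ in range(8 * mask.size + 8):
        d0 = _DIR_INDEX[(prev_bg[0] - cur[0], prev_bg[1] - cur[1])]
        nxt = None
        last_bg = prev_bg
        for i in range(1, 9):
            d = _DIRS[(d0 + i) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if fg(cand):
                nxt = cand
                break
            last_bg = cand
        if nxt is None:
            break  # isolated pixel
        if first_transition is None:
            first_transition = (cur, nxt)
        elif (cur, nxt) == first_transition:
            break
        chain.append(nxt)
        prev_bg = last_bg
        cur = nxt
    if len(chain) > 1 and chain[-1] == start:
        chain.pop()
    return np.asarray(chain, dtype=int)


def chain_perimeter(chain: np.ndarray) -> float:
    """Length of the closed chain; diagonal steps count sqrt(2)."""
    chain = np.asarray(chain)
    if len(chain) < 2:
        return 0.0
    steps = np.diff(np.vstack([chain, chain[:1]]), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


@dataclass
class Region:
    """A candidate region: pixel set, outer boundary, per-region gray range."""

    coords: np.ndarray          # (N, 2) array of (row, col)
    boundary: np.ndarray        # (n, 2) closed outer chain
    shape: tuple[int, int]      # source image shape
    g_max: float
    g_min: float
    label: int = 0
    slice_index: int | None = None

    @property
    def area(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) mean of the region's pixel coordinates."""
        return tuple(self.coords.mean(axis=0))

    def to_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m

    def grays(self, image: np.ndarray) -> np.ndarray:
        return np.asarray(image)[self.coords[:, 0], self.coords[:, 1]]


def _region_from_mask(mask: np.ndarray, image: np.ndarray, label: int = 0,
                      slice_index: int | None = None) -> Region:
    coords = np.argwhere(mask)
    grays = np.asarray(image, float)[mask]
    return Region(coords=coords, boundary=trace_boundary(mask),
                  shape=mask.shape, g_max=float(grays.max()),
                  g_min=float(grays.min()), label=label,
                  slice_index=slice_index)


def candidate_regions(parenchyma_image: np.ndarray,
                      slice_index: int | None = None) -> list[Region]:
    """Bright 8-connected blobs inside the masked parenchyma image.

    The adaptive threshold is computed over the nonzero (in-lung) pixels
    only; candidate foreground is gray >= threshold.  Returns an empty list
    when the parenchyma is empty or uniformly gray (no bright object).
    """
    img = np.asarray(parenchyma_image, dtype=float)
    inside = img > 0
    if not inside.any():
        return []
    try:
        t = iterative_threshold(img[inside])
    except SegmentationError:
        return []
    fg = inside & (img >= t)
    labels, n = ndimage.label(fg, structure=_EIGHT)
    regions = []
    for l in range(1, n + 1):
        regions.append(_region_from_mask(labels == l, img, label=l,
                                         slice_index=slice_index))
    return regions


def refine_region(region: Region, image: np.ndarray, tau: float = 0.5
                  ) -> Region:
    """Gray-judgment refinement of a candidate region.

    Pixels with ``g >= (1 - tau) * (g_max + g_min) / 2`` are retained; the
    cutoffs come from the input region once (no re-iteration), so the
    operation is idempotent at fixed ``tau``.
    """
    if not (0.0 <= tau <= 1.0):
        raise FeatureError("tau must lie in [0, 1]")
    if region.area == 0:
        raise FeatureError("empty region")
    cutoff = (1.0 - tau) * (region.g_max + region.g_min) / 2.0
    grays = region.grays(image)
    keep = grays >= cutoff
    coords = region.coords[keep]
    mask = np.zeros(region.shape, dtype=bool)
    mask[coords[:, 0], coords[:, 1]] = True
    # boundary from the largest 8-connected piece of what remains
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n > 1:
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        biggest = labels == (1 + int(np.argmax(areas)))
    else:
        biggest = mask
    return Region(coords=coords, boundary=trace_boundary(biggest),
                  shape=region.shape, g_max=region.g_max, g_min=region.g_min,
                  label=region.label, slice_index=region.slice_index)


@dataclass
class RadialProfile:
    rd_raw: np.ndarray          # unnormalized boundary-to-centroid distances
    rd: np.ndarray              # normalized so max == 1
    rd_ave: float
    burr_idx: np.ndarray        # indices of burr points in the chain
    window: int
    margin: float

    @property
    def n_burrs(self) -> int:
        return len(self.burr_idx)


def radial_profile(region: Region, w: int = DEFAULT_BURR_WINDOW,
                   delta_burr: float = DEFAULT_BURR_MARGIN) -> RadialProfile:
    """Normalized radial-distance profile of the boundary plus burr points.

    ``rd[i]`` is the Euclidean distance from boundary point ``i`` to the
    region centroid, normalized by the maximum distance.  A burr point is a
    strict local maximum of ``rd`` over a cyclic window of ``w`` chain
    neighbors whose excess over the mean exceeds ``delta_burr``.
    """
    chain = region.boundary
    if len(chain) < 3:
        raise FeatureError("radial profile needs >= 3 boundary points")
    cy, cx = region.centroid
    raw = np.hypot(chain[:, 0] - cy, chain[:, 1] - cx)
    rmax = raw.max()
    if rmax == 0:
        raise FeatureError("degenerate boundary: all points at the centroid")
    rd = raw / rmax
    rd_ave = float(rd.mean())
    half = max(w // 2, 1)
    n = len(rd)
    is_burr = rd - rd_ave > delta_burr
    for off in range(1, half + 1):
        is_burr &= rd > np.roll(rd, off)
        is_burr &= rd > np.roll(rd, -off)
    return RadialProfile(rd_raw=raw, rd=rd, rd_ave=rd_ave,
                         burr_idx=np.nonzero(is_burr)[0], window=w,
                         margin=delta_burr)


@dataclass
class RegionFeatures:
    s_r: float                  # area (pixel count)
    p_r: float                  # perimeter (chain length)
    c_r: float                  # quasi-roundness
    mbr: float                  # marginal burr rate
    mbm: float                  # marginal burr magnitude
    gm: float                   # gray mean
    gv: float                   # gray variance (population)
    ge: float                   # gray entropy (natural log)
    hist: np.ndarray            # A(k), k = 0..255
    centroid: tuple[float, float]
    label: int = 0
    slice_index: int | None = None


def shape_features(region: Region, profile: RadialProfile
                   ) -> tuple[float, float, float, float, float]:
    """(S_R, P_R, C_R, MBR, MBM) from the region and its radial profile."""
    s_r = float(region.area)
    p_r = chain_perimeter(region.boundary)
    c_r = 4.0 * np.pi * s_r / p_r**2 if p_r > 0 else np.inf
    n = len(region.boundary)
    n_b = profile.n_burrs
    mbr = n_b / n if n else 0.0
    if n_b:
        mbm = float((profile.rd[profile.burr_idx] - profile.rd_ave).sum() / n_b)
    else:
        mbm = 0.0
    return s_r, p_r, c_r, mbr, mbm


def gray_features(region: Region, image: np.ndarray
                  ) -> tuple[float, float, float, np.ndarray]:
    """(GM, GV, GE, A) over the region's pixels in ``image``."""
    g = region.grays(image).astype(float)
    if g.size == 0:
        raise FeatureError("empty region")
    gm = float(g.mean())
    gv = float(((g - gm) ** 2).mean())
    hist = np.bincount(np.clip(np.rint(g), 0, 255).astype(int), minlength=256)
    p = hist[hist > 0] / g.size
    ge = float(-(p * np.log(p)).sum())
    return gm, gv, ge, hist


def compute_features(region: Region, image: np.ndarray,
                     w: int = DEFAULT_BURR_WINDOW,
                     delta_burr: float = DEFAULT_BURR_MARGIN) -> RegionFeatures:
    """All seven descriptors for one region.

    Regions too small to carry a radial profile (< 3 boundary points) get
    zero burr features and an undefined (infinite) quasi-roundness; they are
    rejected by the area gate downstream anyway.
    """
    try:
        profile = radial_profile(region, w=w, delta_burr=delta_burr)
        s_r, p_r, c_r, mbr, mbm = shape_features(region, profile)
    except FeatureError:
        s_r, p_r, c_r, mbr, mbm = float(region.area), 0.0, np.inf, 0.0, 0.0
    gm, gv, ge, hist = gray_features(region, image)
    return RegionFeatures(s_r=s_r, p_r=p_r, c_r=c_r, mbr=mbr, mbm=mbm,
                          gm=gm, gv=gv, ge=ge, hist=hist,
                          centroid=region.centroid, label=region.label,
                          slice_index=region.slice_index)


def features_table(feature_list: list[RegionFeatures]) -> pd.DataFrame:
    """One row per region, ready for CSV/TSV export."""
    rows = [{
        "slice": f.slice_index, "label": f.label, "S_R": f.s_r, "P_R": f.p_r,
        "C_R": f.c_r, "MBR": f.mbr, "MBM": f.mbm, "GM": f.gm, "GV": f.gv,
        "GE": f.ge, "centroid_row": f.centroid[0], "centroid_col": f.centroid[1],
    } for f in feature_list]
    return pd.DataFrame(rows)
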