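"""Straight-needle biopsy insertion-path planning.

Given a target nodule centroid and the external chest surface, the planner
enumerates every surface point, keeps the k nearest as candidate entry
points (shortest-puncture-distance principle), ranks the candidates by the
cumulative gray value of the voxels their straight path traverses (soft,
dark tissue is preferred), and returns the lowest-gray-sum candidate whose
path avoids every obstacle mask (bone, key vessels).  Ties in distance or
gray sum are broken lexicographically on the (z, y, x) entry index so the
plan is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume3d import GrayVolume

__all__ = ["PlanningError", "SurfaceSet", "InsertionPath", "body_surface",
           "candidate_paths", "bresenham_3d", "path_gray_sum",
           "check_obstacles", "plan_insertion"]


class PlanningError(ValueError):
    pass


@dataclass
class SurfaceSet:
    """Boundary points of the external chest surface."""

    points_vox: np.ndarray        # (n_c, 3) integer (z, y, x)
    points_mm: np.ndarray         # (n_c, 3) mm

    @property
    def n_c(self) -> int:
        return len(self.points_vox)


@dataclass
class InsertionPath:
    entry_vox: tuple[int, int, int]
    entry_mm: tuple[float, float, float]
    target_vox: tuple[int, int, int]
    target_mm: tuple[float, float, float]
    length_mm: float
    voxels: np.ndarray | None = None      # (m, 3) traversed voxels
    gray_sum: float | None = None
    feasible: bool | None = None
    rejection_reason: str | None = None
    slice_index: int | None = None


def body_surface(volume: GrayVolume, body_mask: np.ndarray,
                 exclude_border: bool = True) -> SurfaceSet:
    """Body voxels with at least one background 6-neighbor.

    Voxels on the volume border are excluded by default (the body is cut by
    the field of view there, not by skin).
    """
    body = np.asarray(body_mask, bool)
    if not body.any():
        raise PlanningError("empty body mask")
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(body, structure=struct,
                                      border_value=not exclude_border)
    surface = body & ~interior
    pts = np.argwhere(surface)
    if exclude_border:
        shp = np.asarray(body.shape)
        on_border = ((pts == 0) | (pts == shp - 1)).any(axis=1)
        pts = pts[~on_border]
    if len(pts) == 0:
        raise PlanningError("no surface points (body fills the volume?)")
    mm = pts * np.asarray(volume.spacing) + np.asarray(volume.origin)
    return SurfaceSet(points_vox=pts, points_mm=mm)


def candidate_paths(target_mm, surface: SurfaceSet, k: int = 4
                    ) -> list[InsertionPath]:
    """The k entry points nearest to the target, ascending by distance.

    Exhaustive evaluation over all surface points; distance ties are broken
    lexicographically on the (z, y, x) entry index.
    """
    if surface.n_c == 0:
        raise PlanningError("empty surface")
    if k < 1:
        raise PlanningError("k must be >= 1")
    target_mm = np.asarray(target_mm, float)
    d = np.linalg.norm(surface.points_mm - target_mm, axis=1)
    p = surface.points_vox
    order = np.lexsort((p[:, 2], p[:, 1], p[:, 0], d))
    picked = order[:min(k, surface.n_c)]
    return [
        InsertionPath(
            entry_vox=tuple(int(c) for c in surface.points_vox[i]),
            entry_mm=tuple(float(c) for c in surface.points_mm[i]),
            target_vox=(0, 0, 0),
            target_mm=tuple(target_mm),
            length_mm=float(d[i]),
        )
        for i in picked
    ]


def bresenham_3d(p0, p1) -> np.ndarray:
    """Integer voxel traversal of the segment p0 -> p1, each voxel once.

    Steps along the driving (longest) axis; the other coordinates follow
    the rounded linear interpolation, ties rounded toward +inf.  Endpoints
    are included; p0 == p1 yields a single voxel.
    """
    p0 = np.asarray(p0, int)
    p1 = np.asarray(p1, int)
    delta = p1 - p0
    steps = int(np.abs(delta).max())
    if steps == 0:
        return p0[None, :].copy()
    out = np.empty((steps + 1, 3), dtype=int)
    for ax in range(3):
        d = int(delta[ax])
        # floor((2*j*d + steps) / (2*steps)) == round(j*d/steps), half up
        j = np.arange(steps + 1)
        out[:, ax] = p0[ax] + np.floor_divide(2 * j * d + steps, 2 * steps)
    return out


def path_gray_sum(volume: GrayVolume, path: InsertionPath) -> float:
    """Sum of voxel grays along the straight entry-target segment."""
    shp = volume.shape
    for pt in (path.entry_vox, path.target_vox):
        if any(not (0 <= pt[i] < shp[i]) for i in range(3)):
            raise PlanningError(f"path endpoint {pt} outside the volume")
    vox = bresenham_3d(path.entry_vox, path.target_vox)
    total = float(volume.data[vox[:, 0], vox[:, 1], vox[:, 2]].astype(float).sum())
    path.voxels = vox
    path.gray_sum = total
    return total


def check_obstacles(path: InsertionPath, obstacle_masks: dict) -> bool:
    """Feasible iff no traversed voxel lies in any obstacle mask."""
    vox = path.voxels
    if vox is None:
        vox = bresenham_3d(path.entry_vox, path.target_vox)
        path.voxels = vox
    for name, mask in obstacle_masks.items():
        hit = np.asarray(mask, bool)[vox[:, 0], vox[:, 1], vox[:, 2]]
        if hit.any():
            path.feasible = False
            path.rejection_reason = name
            return False
    path.feasible = True
    path.rejection_reason = None
    return True


def largest_cross_section_slice(nodule_mask: np.ndarray) -> int:
    areas = np.asarray(nodule_mask, bool).sum(axis=(1, 2))
    return int(np.argmax(areas))


def plan_insertion(volume: GrayVolume, target_mm, body_mask: np.ndarray,
                   k: int = 4, obstacle_masks: dict | None = None,
                   nodule_mask: np.ndarray | None = None,
                   in_slice: bool = False) -> InsertionPath:
    """Pick the best feasible insertion path for one nodule.

    Generates the k shortest entry candidates, ranks them by path gray sum
    (ties lexicographic on entry index), and returns the first candidate
    that clears every obstacle mask.  If all k fail, the candidate pool is
    widened once to 2k before giving up.  ``in_slice`` restricts entry
    candidates to the axial slice of the target (the 2-D search mode).
    The chosen path also records the axial slice index showing the
    nodule's largest cross-section (``slice_index`` attribute).
    """
    obstacle_masks = obstacle_masks or {}
    target_mm = np.asarray(target_mm, float)
    target_vox = tuple(int(round(c)) for c in volume.mm_to_index(target_mm))
    surface = body_surface(volume, body_mask)
    if in_slice:
        sel = surface.points_vox[:, 0] == target_vox[0]
        if not sel.any():
            raise PlanningError("no surface point on the target slice")
        surface = SurfaceSet(points_vox=surface.points_vox[sel],
                             points_mm=surface.points_mm[sel])

    reasons = []
    for kk in (k, 2 * k):
        cands = candidate_paths(target_mm, surface, k=kk)
        for c in cands:
            c.target_vox = target_vox
            path_gray_sum(volume, c)
        order = sorted(range(len(cands)),
                       key=lambda i: (cands[i].gray_sum, cands[i].entry_vox))
        reasons = []
        for i in order:
            c = cands[i]
            if check_obstacles(c, obstacle_masks):
                if nodule_mask is not None:
                    c.slice_index = largest_cross_section_slice(nodule_mask)
                else:
                    c.slice_index = target_vox[0]
                return c
            reasons.append((c.entry_vox, c.rejection_reason))
    raise PlanningError(
        "no feasible path among the widened candidate set; rejections: "
        + ", ".join(f"{e}:{r}" for e, r in reasons))
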