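"""Voxel volumes from slice stacks and triangulated tissue surfaces.

Convention: volumes are indexed (slice z, row y, col x) with per-axis
spacing in mm; a voxel's patient-space position is ``origin + index *
spacing`` (origin defaults to 0).  Meshes are in mm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

__all__ = ["VolumeError", "GrayVolume", "TriMesh", "build_volume",
           "resample_isotropic", "extract_surface"]


class VolumeError(ValueError):
    pass


@dataclass
class GrayVolume:
    data: np.ndarray                      # (z, y, x) uint8
    spacing: tuple[float, float, float]   # (sz, sy, sx) mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise VolumeError("voxel spacing must be positive on every axis")

    @property
    def shape(self):
        return self.data.shape

    def index_to_mm(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, float) * self.spacing

    def mm_to_index(self, mm) -> np.ndarray:
        return (np.asarray(mm, float) - self.origin) / np.asarray(self.spacing)


@dataclass
class TriMesh:
    vertices: np.ndarray                  # (V, 3) mm
    faces: np.ndarray                     # (F, 3) vertex indices
    iso: float

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)

    @property
    def area(self) -> float:
        return 0.0 if self.is_empty else float(self.to_trimesh().area)

    @property
    def watertight(self) -> bool:
        return (not self.is_empty) and bool(self.to_trimesh().is_watertight)


def build_volume(slices, spacing=None, z_positions=None) -> GrayVolume:
    """Stack congruent 2-D slices into a volume.

    Either pass ``spacing = (sz, sy, sx)`` directly, or per-slice
    ``z_positions`` (mm) plus in-plane spacing in ``spacing = (sy, sx)``;
    slices are then sorted by position and the slice pitch inferred from
    the (required uniform) position differences.
    """
    slices = [np.asarray(s) for s in slices]
    if len(slices) < 2:
        raise VolumeError("need at least 2 slices")
    shape0 = slices[0].shape
    if any(s.shape != shape0 for s in slices):
        raise VolumeError("slices are not congruent")
    if z_positions is not None:
        z = np.asarray(z_positions, float)
        if len(z) != len(slices):
            raise VolumeError("one z position per slice required")
        order = np.argsort(z)
        z = z[order]
        slices = [slices[i] for i in order]
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise VolumeError("z positions must be strictly monotone")
        if not np.allclose(dz, dz[0], rtol=1e-3, atol=1e-6):
            raise VolumeError("non-uniform slice pitch")
        if spacing is None or len(spacing) != 2:
            raise VolumeError("in-plane spacing (sy, sx) required")
        spacing3 = (float(dz[0]), float(spacing[0]), float(spacing[1]))
        origin = (float(z[0]), 0.0, 0.0)
    else:
        if spacing is None or len(spacing) != 3:
            raise VolumeError("spacing (sz, sy, sx) required")
        spacing3 = tuple(float(s) for s in spacing)
        origin = (0.0, 0.0, 0.0)
    return GrayVolume(data=np.stack(slices, axis=0), spacing=spacing3,
                      origin=origin)


def resample_isotropic(v: GrayVolume, target_spacing: float) -> GrayVolume:
    """Trilinear resampling onto an isotropic grid of ``target_spacing`` mm.

    Grid points are laid at multiples of the target spacing across the
    original physical extent; when the target equals the current spacing on
    every axis the data is returned unchanged.
    """
    if target_spacing <= 0:
        raise VolumeError("target spacing must be positive")
    if np.allclose(v.spacing, target_spacing):
        return GrayVolume(v.data.copy(), v.spacing, v.origin)
    extent = (np.asarray(v.shape) - 1) * np.asarray(v.spacing)
    new_shape = np.floor(extent / target_spacing + 1e-9).astype(int) + 1
    coords = np.meshgrid(*(np.arange(n) * target_spacing / s
                           for n, s in zip(new_shape, v.spacing)),
                         indexing="ij")
    data = ndimage.map_coordinates(v.data.astype(float), np.array(coords),
                                   order=1, mode="nearest")
    data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    return GrayVolume(data=data, spacing=(target_spacing,) * 3, origin=v.origin)


def extract_surface(v: GrayVolume, iso: float, smooth_iters: int = 10,
                    smooth_factor: float = 0.5) -> TriMesh:
    """Marching-cubes isosurface at ``iso`` followed by Laplacian smoothing.

    The volume is zero-padded by one voxel so that objects touching the
    border still yield closed surfaces.  An iso value outside the data
    range yields an empty mesh.
    """
    data = v.data.astype(float)
    if not (data.min() < iso < data.max()):
        return TriMesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int),
                       iso=iso)
    padded = np.pad(data, 1, mode="constant", constant_values=data.min())
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso,
                                                spacing=v.spacing)
    verts -= np.asarray(v.spacing)          # undo the pad offset
    verts += np.asarray(v.origin)
    if smooth_iters > 0 and len(faces):
        tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        trimesh.smoothing.filter_laplacian(tm, lamb=smooth_factor,
                                           iterations=smooth_iters)
        verts, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    return TriMesh(vertices=verts, faces=faces, iso=iso)
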