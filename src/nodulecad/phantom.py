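"""Synthetic thorax phantom generator.

Builds a deterministic 3-D chest-CT look-alike volume from analytic solids
(ellipsoids, cylinders, spheres with optional spiculated margins) rasterized
by center-of-voxel membership, together with exact ground-truth masks for
every structure.  The gray-level layout reproduces the peak-valley histogram
of a real chest slice: outside-of-field and air are dark, lung parenchyma is
slightly brighter, soft tissue occupies the mid range, and bone is bright.

The phantom is the test substrate for the whole pre-diagnosis pipeline:
segmentation quality, nodule detection and path planning are all measured
against the truth masks returned here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ClassGrays",
    "NoduleSpec",
    "VesselSpec",
    "RibSpec",
    "LungSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PhantomError",
    "generate_phantom",
    "spiculate",
    "default_spec",
]


class PhantomError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass(frozen=True)
class ClassGrays:
    """Mean gray level per tissue class on the 8-bit scale.

    Ordering must be outside ≈ air < parenchyma < soft tissue < bone so the
    volume histogram shows the familiar peak-valley structure.
    """

    outside: float = 0.0
    air: float = 10.0
    parenchyma: float = 40.0
    soft_tissue: float = 120.0
    bone: float = 250.0

    def validate(self) -> None:
        vals = [self.outside, self.air, self.parenchyma, self.soft_tissue, self.bone]
        if any(not (0 <= v <= 255) for v in vals):
            raise PhantomError("class gray levels must lie in [0, 255]")
        if not (max(self.outside, self.air) < self.parenchyma
                < self.soft_tissue < self.bone):
            raise PhantomError(
                "class grays must be ordered outside/air < parenchyma "
                "< soft tissue < bone")


@dataclass(frozen=True)
class NoduleSpec:
    """A roughly spherical lesion with an optionally spiculated margin.

    ``spikes`` > 0 modulates the in-plane radius as
    ``r(theta) = r0 * (1 + spike_amp * cos(spikes * theta + phase))``, i.e. a
    petal-shaped ("burred") axial cross-section — the hallmark of a
    suspicious nodule.  ``gray_sigma`` adds internal gray texture (a Gaussian
    random field with correlation length ``texture_corr_mm``) so the lesion's
    gray entropy matches the heterogeneous interior of real nodules without
    the salt-and-pepper look of independent per-voxel noise.
    """

    center_mm: tuple[float, float, float]  # (z, y, x)
    radius_mm: float
    gray: float = 170.0
    spikes: int = 9
    spike_amp: float = 0.13
    gray_sigma: float = 16.0
    texture_corr_mm: float = 1.7


@dataclass(frozen=True)
class VesselSpec:
    """A cylindrical vessel segment.

    ``axis='z'`` gives a vessel perpendicular to the axial plane (circular,
    bright cross-section — the classic nodule mimic), ``axis='x'`` a vessel
    lying in-plane (elongated cross-section).
    """

    axis: str  # 'z' or 'x'
    center_mm: tuple[float, float, float]  # (z, y, x) midpoint of the axis
    radius_mm: float
    length_mm: float
    gray: float = 180.0


@dataclass(frozen=True)
class RibSpec:
    """An arc-shaped band of bone in the outer body shell."""

    theta_deg: tuple[float, float]   # polar angle range, 0 = +x, CCW
    z_mm: tuple[float, float]        # axial slab
    inner_scale: float = 0.88        # fractions of the body ellipse
    outer_scale: float = 0.96


@dataclass(frozen=True)
class LungSpec:
    """An ellipsoidal lung cavity filled with parenchyma gray."""

    center_mm: tuple[float, float, float]  # (z, y, x)
    semi_mm: tuple[float, float, float]    # (z, y, x) semi-axes


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]            # (slices, rows, cols)
    spacing_mm: tuple[float, float, float]  # (sz, sy, sx)
    fov_radius_mm: float
    body_semi_mm: tuple[float, float]      # (y, x) in-plane semi-axes
    lungs: tuple[LungSpec, LungSpec]
    nodules: tuple[NoduleSpec, ...] = ()
    vessels: tuple[VesselSpec, ...] = ()
    ribs: tuple[RibSpec, ...] = ()
    trachea_radius_mm: float = 0.0
    trachea_offset_mm: tuple[float, float] = (0.0, 0.0)  # (y, x) from center
    grays: ClassGrays = field(default_factory=ClassGrays)
    noise_sigma: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        self.grays.validate()
        if any(n <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing_mm):
            raise PhantomError("shape and spacing must be positive")
        if self.noise_sigma < 0:
            raise PhantomError("noise sigma must be non-negative")
        for structs, name in ((self.nodules, "nodule"), (self.vessels, "vessel")):
            for i, s in enumerate(structs):
                if not (0 <= s.gray <= 255):
                    raise PhantomError(f"{name} {i}: gray outside [0, 255]")


@dataclass
class PhantomTruth:
    """Ground-truth binary masks congruent with the generated volume."""

    body: np.ndarray
    lung_left: np.ndarray
    lung_right: np.ndarray
    nodules: list[np.ndarray]
    nodule_centroids_vox: list[tuple[float, float, float]]  # (z, y, x)
    vessels: np.ndarray
    bone: np.ndarray

    @property
    def parenchyma(self) -> np.ndarray:
        return self.lung_left | self.lung_right

    def nodule_centroids_mm(self, spacing_mm) -> list[tuple[float, float, float]]:
        s = np.asarray(spacing_mm, float)
        return [tuple(np.asarray(c) * s) for c in self.nodule_centroids_vox]


# ---------------------------------------------------------------------------
# rasterization helpers

def _grids_mm(shape, spacing):
    nz, ny, nx = shape
    sz, sy, sx = spacing
    z = np.arange(nz)[:, None, None] * sz
    y = np.arange(ny)[None, :, None] * sy
    x = np.arange(nx)[None, None, :] * sx
    return z, y, x


def _inplane_center_mm(shape, spacing):
    _, ny, nx = shape
    _, sy, sx = spacing
    return (ny - 1) / 2.0 * sy, (nx - 1) / 2.0 * sx


def _rasterize_nodule(nod: NoduleSpec, shape, spacing, phase: float) -> np.ndarray:
    """Center-of-voxel membership of a (possibly petal-margined) sphere."""
    cz, cy, cx = nod.center_mm
    z, y, x = _grids_mm(shape, spacing)
    dz = z - cz
    mask = np.zeros(shape, dtype=bool)
    inside_z = np.abs(dz[:, 0, 0]) <= nod.radius_mm
    dy = (y - cy)[0]
    dx = (x - cx)[0]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    for k in np.nonzero(inside_z)[0]:
        r_z = np.sqrt(max(nod.radius_mm**2 - dz[k, 0, 0] ** 2, 0.0))
        if nod.spikes > 0:
            limit = r_z * (1.0 + nod.spike_amp * np.cos(nod.spikes * theta + phase))
        else:
            limit = r_z
        mask[k] = rho <= limit
    return mask


def _rasterize_vessel(v: VesselSpec, shape, spacing) -> np.ndarray:
    cz, cy, cx = v.center_mm
    z, y, x = _grids_mm(shape, spacing)
    half = v.length_mm / 2.0
    if v.axis == "z":
        radial = np.hypot(y - cy, x - cx)
        along = np.abs(z - cz)
    elif v.axis == "x":
        radial = np.hypot(z - cz, y - cy)
        along = np.abs(x - cx)
    else:
        raise PhantomError(f"vessel axis must be 'z' or 'x', got {v.axis!r}")
    return (radial <= v.radius_mm) & (along <= half)


def _rasterize_rib(r: RibSpec, spec: PhantomSpec) -> np.ndarray:
    z, y, x = _grids_mm(spec.shape, spec.spacing_mm)
    cy, cx = _inplane_center_mm(spec.shape, spec.spacing_mm)
    by, bx = spec.body_semi_mm
    dy = (y - cy)[0]
    dx = (x - cx)[0]
    # normalized elliptical radius: 1.0 on the body surface
    rho = np.sqrt((dy / by) ** 2 + (dx / bx) ** 2)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    t0, t1 = (t % 360.0 for t in r.theta_deg)
    if t0 <= t1:
        ang = (theta >= t0) & (theta <= t1)
    else:
        ang = (theta >= t0) | (theta <= t1)
    band = (rho >= r.inner_scale) & (rho <= r.outer_scale) & ang
    zsel = (z[:, 0, 0] >= r.z_mm[0]) & (z[:, 0, 0] <= r.z_mm[1])
    out = np.zeros(spec.shape, dtype=bool)
    out[zsel] = band
    return out


def _correlated_texture(mask: np.ndarray, nod: NoduleSpec, spacing,
                        rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field with std ``gray_sigma`` on the mask."""
    from scipy import ndimage as _ndi
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    pad = 4
    lo = [max(l - pad, 0) for l in lo]
    hi = [min(h + pad, s) for h, s in zip(hi, mask.shape)]
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    field = rng.normal(size=tuple(h - l for l, h in zip(lo, hi)))
    sig_vox = [nod.texture_corr_mm / s for s in spacing]
    field = _ndi.gaussian_filter(field, sig_vox)
    sd = field.std()
    if sd > 0:
        field *= nod.gray_sigma / sd
    out = np.zeros(mask.shape, dtype=float)
    out[box] = field
    return out


# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Rasterize ``spec`` into an 8-bit volume plus ground-truth masks.

    The output is a pure function of the spec (including its seed): the same
    spec yields bit-identical volumes.  Raises :class:`PhantomError` if a
    nodule is not entirely contained in a lung.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing_mm
    g = spec.grays

    z, y, x = _grids_mm(shape, spacing)
    cy, cx = _inplane_center_mm(shape, spacing)

    fov = (np.hypot(y - cy, x - cx) <= spec.fov_radius_mm)
    fov = np.broadcast_to(fov, shape)
    by, bx = spec.body_semi_mm
    body2d = ((y - cy) / by) ** 2 + ((x - cx) / bx) ** 2 <= 1.0
    body = np.broadcast_to(body2d, shape).copy()

    lung_masks = []
    for lung in spec.lungs:
        lz, ly, lx = lung.center_mm
        az, ay, ax = lung.semi_mm
        m = (((z - lz) / az) ** 2 + ((y - ly) / ay) ** 2
             + ((x - lx) / ax) ** 2) <= 1.0
        lung_masks.append(m)
    # image-left lung = smaller mean column index
    order = np.argsort([np.nonzero(m)[2].mean() if m.any() else np.inf
                        for m in lung_masks])
    lung_left, lung_right = lung_masks[order[0]], lung_masks[order[1]]
    parenchyma = lung_left | lung_right

    nodule_masks = []
    for i, nod in enumerate(spec.nodules):
        phase = rng.uniform(0.0, 2 * np.pi)
        m = _rasterize_nodule(nod, shape, spacing, phase)
        if not m.any():
            raise PhantomError(f"nodule {i} rasterizes to no voxels")
        if (m & ~parenchyma).any():
            raise PhantomError(f"nodule {i} is not entirely inside a lung")
        nodule_masks.append(m)

    vessel_mask = np.zeros(shape, dtype=bool)
    vessel_grays = np.zeros(shape, dtype=float)
    for v in spec.vessels:
        m = _rasterize_vessel(v, shape, spacing)
        vessel_mask |= m
        vessel_grays[m] = v.gray

    bone = np.zeros(shape, dtype=bool)
    for rib in spec.ribs:
        bone |= _rasterize_rib(rib, spec)
    bone &= body & ~parenchyma  # ribs never intrude into the lungs

    vol = np.full(shape, g.outside, dtype=float)
    vol[fov] = g.air
    vol[body] = g.soft_tissue
    vol[parenchyma] = g.parenchyma
    if spec.trachea_radius_mm > 0:
        ty, tx = spec.trachea_offset_mm
        trachea2d = np.hypot(y - (cy + ty), x - (cx + tx))[0] <= spec.trachea_radius_mm
        trachea = np.broadcast_to(trachea2d, shape) & body & ~parenchyma
        vol[trachea] = g.air
    vol[vessel_mask] = vessel_grays[vessel_mask]
    for nod, m in zip(spec.nodules, nodule_masks):
        vol[m] = nod.gray
        if nod.gray_sigma > 0:
            vol[m] += _correlated_texture(m, nod, spacing, rng)[m]
    vol[bone] = g.bone

    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=shape)
    vol = np.clip(np.rint(vol), 0, 255).astype(np.uint8)

    centroids = [tuple(np.mean(np.nonzero(m), axis=1)) for m in nodule_masks]
    truth = PhantomTruth(
        body=body,
        lung_left=lung_left,
        lung_right=lung_right,
        nodules=nodule_masks,
        nodule_centroids_vox=centroids,
        vessels=vessel_mask,
        bone=bone,
    )
    return vol, truth


def spiculate(mask: np.ndarray, spikes: int, length: int = 4,
              seed: int = 0) -> np.ndarray:
    """Append ``spikes`` thin radial protrusions to a 2-D binary region.

    Spikes are 1-pixel-wide rays of ``length`` pixels attached at equally
    spaced boundary angles (phase fixed by ``seed``), emulating the burrs of
    a spiculated nodule margin.  ``spikes == 0`` returns the mask unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise PhantomError("spiculate expects a 2-D mask")
    if not mask.any():
        raise PhantomError("spiculate: empty mask")
    if spikes < 0:
        raise PhantomError("spike count must be >= 0")
    out = mask.copy()
    if spikes == 0:
        return out
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2 * np.pi)
    cy, cx = (np.mean(idx) for idx in np.nonzero(mask))
    nrows, ncols = mask.shape
    rmax = float(np.hypot(nrows, ncols))
    for j in range(spikes):
        theta = phase + 2 * np.pi * j / spikes
        dy, dx = np.sin(theta), np.cos(theta)
        # march outward to the last in-mask pixel along this ray
        base = None
        t = 0.0
        while t <= rmax:
            r_, c_ = int(round(cy + t * dy)), int(round(cx + t * dx))
            if 0 <= r_ < nrows and 0 <= c_ < ncols and mask[r_, c_]:
                base = (r_, c_, t)
            t += 0.5
        if base is None:
            continue
        r0, c0, t0 = base
        for step in np.arange(0.5, length + 0.25, 0.5):
            r_, c_ = int(round(cy + (t0 + step) * dy)), int(round(cx + (t0 + step) * dx))
            if 0 <= r_ < nrows and 0 <= c_ < ncols:
                out[r_, c_] = True
    return out


# ---------------------------------------------------------------------------
# default study geometry

def default_spec(seed: int = 0, *, noise_sigma: float = 3.0,
                 jitter: bool = True, **overrides) -> PhantomSpec:
    """The default thorax used throughout the test suite.

    A 40 x 256 x 256 grid at (2.0, 1.4, 1.4) mm spacing: elliptical body,
    two ellipsoidal lungs, a tracheal air column, one spiculated nodule per
    lung, one bright axial vessel and one in-plane vessel, and six rib arcs.
    ``seed`` jitters nodule/vessel placement (a few millimetres) and drives
    gray noise, so distinct seeds give distinct but statistically identical
    phantoms.
    """
    shape = (40, 256, 256)
    spacing = (2.0, 1.4, 1.4)
    cy = (shape[1] - 1) / 2.0 * spacing[1]   # 178.5 mm
    cx = (shape[2] - 1) / 2.0 * spacing[2]
    zc = 40.0                                 # lung mid-plane (slice 20)
    rng = np.random.default_rng(seed + 777)

    def jit(scale):
        return float(rng.uniform(-scale, scale)) if jitter else 0.0

    lung_dx = 72.8    # +-52 px
    lung_semi = (36.0, 112.0, 67.2)
    lungs = (
        LungSpec((zc, cy, cx - lung_dx), lung_semi),
        LungSpec((zc, cy, cx + lung_dx), lung_semi),
    )
    nodules = (
        NoduleSpec((zc, cy - 30.0 + jit(6), cx - lung_dx - 15.0 + jit(6)), 9.1),
        NoduleSpec((zc, cy + 35.0 + jit(6), cx + lung_dx + 12.0 + jit(6)), 9.1),
    )
    vessels = (
        # bright vessel perpendicular to the axial plane (nodule mimic)
        VesselSpec("z", (zc, cy - 25.0 + jit(4), cx + lung_dx - 20.0 + jit(4)),
                   4.9, 56.0, gray=235.0),
        # elongated in-plane vessel
        VesselSpec("x", (zc, cy + 40.0 + jit(4), cx - lung_dx + 10.0 + jit(4)),
                   2.8, 50.0, gray=180.0),
    )
    ribs = tuple(
        RibSpec((t0, t0 + 40.0), (z0, z0 + 10.0))
        for t0, z0 in [(250.0, 8.0), (290.0, 34.0), (70.0, 20.0),
                       (110.0, 50.0), (200.0, 56.0), (340.0, 62.0)]
    )
    spec = PhantomSpec(
        shape=shape,
        spacing_mm=spacing,
        fov_radius_mm=175.0,
        body_semi_mm=(140.0, 156.8),
        lungs=lungs,
        nodules=nodules,
        vessels=vessels,
        ribs=ribs,
        trachea_radius_mm=5.6,
        trachea_offset_mm=(-55.0, 0.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec
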