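"""Shared fixtures: phantoms and helper geometry used across the suite."""

from dataclasses import replace

import numpy as np
import pytest

from nodulecad.phantom import (LungSpec, NoduleSpec, RibSpec, default_spec,
                               generate_phantom)
from nodulecad.volume3d import GrayVolume

MID = 20          # default phantom lung mid-plane slice
CY = CX = 178.5   # in-plane center (mm) of the default phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom (deterministic geometry checks)."""
    spec = default_spec(seed=0, noise_sigma=0.0, jitter=False)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with the standard noise level."""
    spec = default_spec(seed=1)
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def fused_phantom():
    """Phantom whose lungs overlap across the midline (single region)."""
    spec = default_spec(seed=3, noise_sigma=0.0)
    spec = replace(spec, lungs=(
        LungSpec((40.0, CY, CX - 40.0), (36.0, 112.0, 67.2)),
        LungSpec((40.0, CY, CX + 40.0), (36.0, 112.0, 67.2))))
    vol, truth = generate_phantom(spec)
    return spec, vol, truth


def offset_nodule_spec():
    """Single nodule pushed toward the anterior chest wall; no clutter."""
    spec = default_spec(seed=0, noise_sigma=0.0, jitter=False)
    nod = NoduleSpec((40.0, CY - 95.0, CX - 72.8), 9.1)
    return replace(spec, nodules=(nod,), vessels=(), ribs=())


def rib_block_spec():
    """Offset nodule with a rib arc directly across its shortest path."""
    return replace(offset_nodule_spec(),
                   ribs=(RibSpec((220.0, 248.0), (30.0, 50.0)),))


def antialiased_sphere(radius: float = 10.0, n: int = 40,
                       gray: float = 200.0) -> GrayVolume:
    """Sphere rasterized with linear partial-volume shading at the shell."""
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = n // 2
    dist = np.sqrt((zz - c) ** 2.0 + (yy - c) ** 2 + (xx - c) ** 2)
    data = np.clip(radius - dist + 0.5, 0.0, 1.0) * gray
    return GrayVolume(np.clip(np.rint(data), 0, 255).astype(np.uint8),
                      (1.0, 1.0, 1.0))
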