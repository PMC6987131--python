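"""Cell-like refractive-index phantoms and the scattering potential.

Phantoms are built from geometric primitives (spheres, cylinders, shells,
boxes) with refractive indices in the cellular range 1.30-1.60 embedded in
a homogeneous medium n_m; they stand in for organelles of distinct optical
density (lipid droplets above the cytosol, dark vacuoles below it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fourier import space_axis
from .optics import OpticsConfig

RI_MIN, RI_MAX = 1.30, 1.60


@dataclass(frozen=True)
class Primitive:
    """One phantom building block; positions/lengths in nm from the volume center."""

    shape: str                          # sphere | cylinder | shell | box
    center: tuple[float, float, float]
    ri: float
    radius: float | None = None         # sphere / cylinder / shell (outer)
    length: float | None = None         # cylinder
    axis: int = 1                       # cylinder long axis (0=x, 1=y, 2=z)
    thickness: float | None = None      # shell
    size: tuple[float, float, float] | None = None   # box edge lengths

    def __post_init__(self):
        if self.shape not in ("sphere", "cylinder", "shell", "box"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if not (RI_MIN <= self.ri <= RI_MAX):
            raise ValueError(f"ri={self.ri} outside the cellular range [{RI_MIN}, {RI_MAX}]")
        needs = {"sphere": ("radius",), "cylinder": ("radius", "length"),
                 "shell": ("radius", "thickness"), "box": ("size",)}[self.shape]
        for name in needs:
            val = getattr(self, name)
            if val is None:
                raise ValueError(f"{self.shape} primitive requires {name}")
            if np.any(np.asarray(val, dtype=float) <= 0):
                raise ValueError(f"{self.shape} {name} must be positive")
        if self.shape == "shell" and self.thickness >= self.radius:
            raise ValueError("shell thickness must be smaller than its outer radius")


@dataclass(frozen=True)
class PhantomSpec:
    """Ordered primitives; later entries overwrite earlier ones where they overlap."""

    primitives: tuple[Primitive, ...] = ()

    @classmethod
    def of(cls, *primitives: Primitive) -> "PhantomSpec":
        return cls(primitives=tuple(primitives))


@dataclass
class RIVolume:
    """3D refractive-index map on the (x, y, z) voxel lattice."""

    data: np.ndarray                    # (nx, ny, nz) real
    voxel_size: tuple[float, float, float]
    medium_ri: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RI volume contains non-finite values")
        if self.data.min() < 1.0:
            raise ValueError("refractive index below 1.0 is unphysical here")


@dataclass
class PotentialVolume:
    """Scattering potential f(r) = k0**2 (n(r)**2 - n_m**2)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]


def _mask_for(prim: Primitive, X, Y, Z) -> np.ndarray:
    cx, cy, cz = prim.center
    dx, dy, dz = X - cx, Y - cy, Z - cz
    if prim.shape == "sphere":
        return dx * dx + dy * dy + dz * dz <= prim.radius ** 2
    if prim.shape == "cylinder":
        trans = [dx, dy, dz]
        along = trans.pop(prim.axis)
        r2 = trans[0] ** 2 + trans[1] ** 2
        return (r2 <= prim.radius ** 2) & (np.abs(along) <= prim.length / 2.0)
    if prim.shape == "shell":
        r2 = dx * dx + dy * dy + dz * dz
        inner = prim.radius - prim.thickness
        return (r2 <= prim.radius ** 2) & (r2 > inner ** 2)
    # box
    sx, sy, sz = prim.size
    return (np.abs(dx) <= sx / 2) & (np.abs(dy) <= sy / 2) & (np.abs(dz) <= sz / 2)


def _extent(prim: Primitive) -> np.ndarray:
    """Half-extent of the primitive's bounding box along (x, y, z)."""
    if prim.shape == "sphere" or prim.shape == "shell":
        return np.full(3, prim.radius)
    if prim.shape == "cylinder":
        ext = np.full(3, prim.radius)
        ext[prim.axis] = prim.length / 2.0
        return ext
    return np.asarray(prim.size, dtype=float) / 2.0


def build_phantom(spec: PhantomSpec, config: OpticsConfig,
                 supersample: int = 1) -> RIVolume:
    """Voxelize a phantom.

    With ``supersample=1`` (default) each voxel takes the RI of the last
    primitive containing its center, else the medium RI.  With
    ``supersample=s > 1`` each voxel is averaged over ``s**3`` sub-voxel
    sample points (partial-volume antialiasing), which suppresses the
    staircase error of binary rasterization -- useful when comparing
    simulated spectra against closed-form Fourier transforms.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    nx, ny, nz = config.volume_shape
    dx, dy, dz = config.voxel_size
    half = np.array([nx * dx, ny * dy, nz * dz]) / 2.0
    for prim in spec.primitives:
        if np.any(np.abs(np.asarray(prim.center)) + _extent(prim) > half + 1e-9):
            raise ValueError(
                f"{prim.shape} at {prim.center} extends outside the volume "
                f"(half-extent {half.tolist()} nm)")
    x = space_axis(nx, dx)
    y = space_axis(ny, dy)
    z = space_axis(nz, dz)
    s = supersample
    offsets = (np.arange(s) - (s - 1) / 2.0) / s
    n = np.full((nx, ny, nz), config.medium_ri, dtype=np.float64)
    for prim in spec.primitives:
        frac = np.zeros((nx, ny, nz), dtype=np.float64)
        for ox in offsets:
            for oy in offsets:
                for oz in offsets:
                    X, Y, Z = np.meshgrid(x + ox * dx, y + oy * dy,
                                          z + oz * dz, indexing="ij")
                    frac += _mask_for(prim, X, Y, Z)
        frac /= s ** 3
        n = n * (1.0 - frac) + prim.ri * frac   # later primitives win
    return RIVolume(data=n, voxel_size=config.voxel_size, medium_ri=config.medium_ri)


def scattering_potential(ri: RIVolume, config: OpticsConfig) -> PotentialVolume:
    """f(r) = k0**2 (n**2 - n_m**2), elementwise; zero in plain medium."""
    if tuple(ri.data.shape) != tuple(config.volume_shape):
        raise ValueError(
            f"RI volume shape {ri.data.shape} does not match config volume "
            f"shape {config.volume_shape}")
    f = config.k0 ** 2 * (ri.data.astype(np.float64) ** 2 - config.medium_ri ** 2)
    return PotentialVolume(data=f, voxel_size=ri.voxel_size)
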