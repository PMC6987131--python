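"""Optical configuration, frequency conventions, scan geometry, and the
modeled coherent transfer function (CTF).

Conventions (package-wide):

* angular spatial frequencies in rad/nm; lengths in nm;
* ``k0 = 2*pi/wavelength`` (vacuum), ``km = k0 * medium_ri``;
* spectra stored DC-centered (see :mod:`holotomo.fourier`);
* the scattering potential is ``f(r) = k0**2 * (n(r)**2 - n_m**2)`` and each
  tilted plane-wave illumination ``k_i`` samples its 3D spectrum on the
  translated Ewald cap ``K = k_s - k_i`` with ``|k_s| = km``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .fourier import freq_axis

#: default number of illumination angles per tomographic cycle
DEFAULT_N_ANGLES = 240

#: default ring radius as a fraction of the illumination band limit
DEFAULT_RING_FRACTION = 0.95


@dataclass(frozen=True)
class OpticsConfig:
    """Physical and sampling parameters of the off-axis ODT microscope.

    Defaults describe a 561-nm system with a water-immersion NA 1.0
    illumination objective and an oil NA 1.45 detection objective, 65-nm
    pixels at the sample plane.
    """

    wavelength: float = 561.0          # nm, vacuum
    medium_ri: float = 1.337           # immersion/mounting medium
    na_ill: float = 1.0                # illumination numerical aperture
    na_det: float = 1.45               # detection numerical aperture
    pixel_size: float = 65.0           # nm at the sample plane
    detector_shape: tuple[int, int] = (128, 128)   # (nx, ny); axis 0 is x
    voxel_size: tuple[float, float, float] = (65.0, 65.0, 150.0)   # nm
    volume_shape: tuple[int, int, int] = (128, 128, 64)

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0 < self.na_ill <= self.medium_ri):
            raise ValueError(
                f"na_ill must satisfy 0 < na_ill <= medium_ri "
                f"(got na_ill={self.na_ill}, medium_ri={self.medium_ri})")
        if self.na_det <= 0:
            raise ValueError("na_det must be positive")
        if np.pi / self.pixel_size <= self.q_det_max:
            raise ValueError(
                "pixel sampling violates Nyquist for the detection band: "
                f"pi/pixel_size = {np.pi / self.pixel_size:.3g} rad/nm must "
                f"exceed q_det_max = {self.q_det_max:.3g} rad/nm")
        for name in ("detector_shape", "volume_shape"):
            shape = getattr(self, name)
            if any(int(n) < 8 for n in shape):
                raise ValueError(f"all {name} axes must be >= 8, got {shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")

    # ---- derived quantities -------------------------------------------------
    @property
    def k0(self) -> float:
        """Vacuum angular wavenumber 2*pi/lambda (rad/nm)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def km(self) -> float:
        """Angular wavenumber in the medium (rad/nm)."""
        return self.k0 * self.medium_ri

    @property
    def q_ill_max(self) -> float:
        """Illumination transverse band limit 2*pi*NA_ill/lambda (rad/nm)."""
        return 2.0 * np.pi * self.na_ill / self.wavelength

    @property
    def q_det_max(self) -> float:
        """Detection transverse band limit 2*pi*NA_det/lambda (rad/nm)."""
        return 2.0 * np.pi * self.na_det / self.wavelength

    @property
    def q_det_eff(self) -> float:
        """Detection band limited to propagating waves: min(q_det_max, km)."""
        return min(self.q_det_max, self.km)

    @property
    def q_nyquist(self) -> float:
        """Per-axis detector Nyquist frequency pi/pixel_size (rad/nm)."""
        return np.pi / self.pixel_size

    def detector_freqs(self) -> tuple[np.ndarray, np.ndarray]:
        """DC-centered detector frequency axes (qx, qy) in rad/nm."""
        nx, ny = self.detector_shape
        return (freq_axis(nx, self.pixel_size), freq_axis(ny, self.pixel_size))

    def volume_freqs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """DC-centered volume frequency axes (qx, qy, qz) in rad/nm."""
        nx, ny, nz = self.volume_shape
        dx, dy, dz = self.voxel_size
        return (freq_axis(nx, dx), freq_axis(ny, dy), freq_axis(nz, dz))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detector_shape"] = list(self.detector_shape)
        d["voxel_size"] = list(self.voxel_size)
        d["volume_shape"] = list(self.volume_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        d = dict(d)
        for key in ("detector_shape", "voxel_size", "volume_shape"):
            if key in d:
                d[key] = tuple(d[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown OpticsConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class FrequencyGrid:
    """One-axis DC-centered frequency coordinate set (rad/unit)."""

    coords: np.ndarray
    spacing: float

    @property
    def step(self) -> float:
        return 2.0 * np.pi / (len(self.coords) * self.spacing)


def make_frequency_grid(n: int, spacing: float) -> FrequencyGrid:
    """DC-centered FFT frequency coordinates with step 2*pi/(n*spacing)."""
    return FrequencyGrid(coords=freq_axis(n, spacing), spacing=float(spacing))


@dataclass(frozen=True)
class ScanPattern:
    """Ordered designated transverse illumination wave vectors (rad/nm)."""

    vectors: np.ndarray            # (n, 2) -> (k_ix, k_iy)
    scheme: str = "ring"

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("scan vectors must have shape (n, 2)")
        object.__setattr__(self, "vectors", v)

    def __len__(self) -> int:
        return len(self.vectors)

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "vectors": self.vectors.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ScanPattern":
        return cls(vectors=np.asarray(d["vectors"], dtype=float),
                   scheme=d.get("scheme", "ring"))


_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def generate_scan_pattern(config: OpticsConfig,
                          n_angles: int = DEFAULT_N_ANGLES,
                          scheme: str = "ring",
                          ring_fraction: float = DEFAULT_RING_FRACTION) -> ScanPattern:
    """Deterministic tomographic scan geometry.

    ``ring`` places all vectors on one circle of radius
    ``ring_fraction * q_ill_max`` at uniform azimuths starting from 0;
    ``spiral`` distributes radii over (0, q_ill_max] with golden-angle
    azimuths (Fermat spiral), trading azimuthal density for radial coverage.
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    idx = np.arange(n_angles)
    if scheme == "ring":
        radius = ring_fraction * config.q_ill_max
        az = 2.0 * np.pi * idx / n_angles
        vec = radius * np.stack([np.cos(az), np.sin(az)], axis=1)
    elif scheme == "spiral":
        radius = config.q_ill_max * np.sqrt((idx + 1) / n_angles)
        az = idx * _GOLDEN_ANGLE
        vec = radius[:, None] * np.stack([np.cos(az), np.sin(az)], axis=1)
    else:
        raise ValueError(f"unknown scan scheme {scheme!r} (expected 'ring' or 'spiral')")
    norms = np.hypot(vec[:, 0], vec[:, 1])
    if np.any(norms > config.q_ill_max * (1 + 1e-12)):
        raise ValueError("scan vector exceeds the illumination band limit")
    return ScanPattern(vectors=vec, scheme=scheme)


def illumination_kz(k_perp: np.ndarray, config: OpticsConfig) -> float:
    """Axial component of an illumination wave vector on the Ewald sphere."""
    k_perp = np.asarray(k_perp, dtype=float)
    r2 = float(k_perp[0] ** 2 + k_perp[1] ** 2)
    if r2 > config.km ** 2:
        raise ValueError("transverse illumination frequency exceeds km (evanescent)")
    return float(np.sqrt(config.km ** 2 - r2))


@dataclass(frozen=True)
class CTFModel:
    """3D frequency-space weights of the tomographic system, in [0, 1].

    The weight at a lattice point is the fraction of scan angles whose
    translated Ewald cap deposits a sample into that voxel; support is the
    union of accessible cap translates (synthetic aperture).
    """

    weights: np.ndarray            # (nx, ny, nz) real, in [0, 1]
    provenance: str = "modeled"    # "modeled" | "loaded"

    def __post_init__(self):
        w = np.asarray(self.weights)
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("CTF weights must lie in [0, 1]")


def _cap_voxel_indices(k_perp: Sequence[float], config: OpticsConfig):
    """Lattice indices (ix, iy, iz) touched by the Ewald cap of one angle.

    Shared by the forward model, the Ewald stitcher and the modeled CTF so
    all three agree on exactly which voxels an illumination angle reaches.
    Returns (ix, iy, iz, k_sz, q_mask) where ``q_mask`` flags the detector
    frequency pairs (as a boolean (nx, ny) array) that survive the
    propagating/detection-band tests, and the index arrays are aligned with
    ``q_mask``'s True entries.
    """
    qx, qy = config.detector_freqs()
    nx_d, ny_d = len(qx), len(qy)
    nxv, nyv, nzv = config.volume_shape
    if (nx_d, ny_d) != (nxv, nyv) or not np.allclose(
            (config.voxel_size[0], config.voxel_size[1]),
            (config.pixel_size, config.pixel_size)):
        raise ValueError(
            "lateral volume sampling must match the detector grid "
            "(volume_shape[:2] == detector cols/rows and voxel_size xy == pixel_size)")
    km = config.km
    QX, QY = np.meshgrid(qx, qy, indexing="ij")
    ksx = QX + float(k_perp[0])
    ksy = QY + float(k_perp[1])
    ks_perp2 = ksx ** 2 + ksy ** 2
    # propagating, inside the detection aperture, and away from grazing
    # incidence where 1/k_sz diverges
    mask = (np.sqrt(ks_perp2) <= config.q_det_max) & (ks_perp2 <= (0.9995 * km) ** 2)
    k_sz = np.sqrt(np.maximum(km ** 2 - ks_perp2, 0.0))
    k_iz = illumination_kz(np.asarray(k_perp, dtype=float), config)
    Kz = k_sz - k_iz
    _, _, qz = config.volume_freqs()
    dqz = 2.0 * np.pi / (nzv * config.voxel_size[2])
    iz = np.rint(Kz / dqz).astype(int) + nzv // 2
    mask &= (iz >= 0) & (iz < nzv)
    ix, iy = np.meshgrid(np.arange(nxv), np.arange(nyv), indexing="ij")
    return ix[mask], iy[mask], iz[mask], k_sz[mask], mask


def model_ctf(config: OpticsConfig, scan: ScanPattern) -> CTFModel:
    """Coverage-count CTF of a scan, normalized to [0, 1].

    An empty scan yields all-zero weights.  For a full ring scan the lateral
    support radius approaches ``q_ill_max + q_det_eff`` (synthetic-aperture
    extension) and the axial ``missing cone`` around the q_z axis stays
    empty.
    """
    counts = np.zeros(config.volume_shape, dtype=np.float64)
    for k_perp in scan.vectors:
        ix, iy, iz, _, _ = _cap_voxel_indices(k_perp, config)
        np.add.at(counts, (ix, iy, iz), 1.0)
    peak = counts.max()
    if peak > 0:
        counts /= peak
    return CTFModel(weights=counts, provenance="modeled")
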