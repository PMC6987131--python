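"""Forward simulation: angle-scanned off-axis holograms of weak phantoms.

The scattered field is generated in the frequency domain by sampling the
phantom's potential spectrum on translated Ewald caps (the same mapping the
tomographic inversion uses, run in reverse), so forward and inverse are
mutually consistent by construction.  Under the first-order Rytov model the
total transmitted field is ``U = exp(s) * U0`` with ``U0`` the tilted
incident plane wave; interfering U with an off-axis reference plane wave
and (optionally) Poisson-sampling the intensity yields the raw hologram.

Per-frame illumination jitter emulates mechanical wobble of the scan
mirrors: the hologram is synthesized from the jittered ("true") wave
vector while the stack records only the designated one, exactly the
situation the VISA calibration must undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fourier import fft_centered, ifft_centered, space_axis
from .optics import OpticsConfig, ScanPattern, _cap_voxel_indices, illumination_kz
from .phantom import PotentialVolume, RIVolume, scattering_potential
from .holography import RytovField


def default_reference_carrier(config: OpticsConfig) -> np.ndarray:
    """Reference-beam carrier q_ref (rad/nm): 65% of Nyquist per axis along
    the detector diagonal.

    This keeps the sideband (radius q_det_max around -q_ref) inside the
    square Nyquist domain while clearing the weak-object DC term (radius
    q_det_eff + |k_i|) for every ring-scan angle.
    """
    q = 0.65 * config.q_nyquist
    return np.array([q, q])


@dataclass(frozen=True)
class NoiseModel:
    """Shot noise: expected photon count per pixel at the noiseless mean
    intensity of two unit-amplitude beams (I = 2)."""

    photons: float = 1e4
    seed: int = 0

    def __post_init__(self):
        if self.photons <= 0:
            raise ValueError("photons must be positive")


@dataclass(frozen=True)
class JitterModel:
    """I.i.d. zero-mean Gaussian perturbation of each transverse
    illumination wave-vector component, sd in rad/nm."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("jitter sigma must be >= 0")


@dataclass
class HologramFrame:
    """One raw off-axis intensity frame."""

    intensity: np.ndarray                 # (nx, ny) >= 0
    index: int
    k_designated: np.ndarray              # designated transverse illum. vector
    k_true: np.ndarray | None = None      # simulation metadata only
    exposure_tag: str = "simulated"

    def __post_init__(self):
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")


@dataclass
class HologramStack:
    """Ordered frames sharing one scan pattern and reference carrier."""

    frames: list
    scan: ScanPattern
    q_ref: np.ndarray
    config: OpticsConfig

    def __post_init__(self):
        if len(self.frames) != len(self.scan):
            raise ValueError(
                f"frame count {len(self.frames)} does not match scan length "
                f"{len(self.scan)}")

    def __len__(self):
        return len(self.frames)


@dataclass
class SimulationTruth:
    """Ground-truth record; never consumed by the reconstruction path."""

    true_vectors: np.ndarray              # (n, 2) rad/nm
    jitter: JitterModel
    noise: NoiseModel | None


class RytovSimulator:
    """Caches the 3D potential spectrum and samples Ewald caps per angle."""

    def __init__(self, potential: PotentialVolume, config: OpticsConfig):
        if tuple(potential.data.shape) != tuple(config.volume_shape):
            raise ValueError("potential shape does not match config volume shape")
        self.config = config
        self.spectrum = fft_centered(potential.data.astype(np.float64),
                                     config.voxel_size)

    def field(self, k_perp: Sequence[float], index: int = 0) -> RytovField:
        config = self.config
        k_perp = np.asarray(k_perp, dtype=float)
        if np.hypot(*k_perp) > config.km:
            raise ValueError("illumination wave vector is evanescent (|k_perp| > km)")
        ix, iy, iz, k_sz, mask = _cap_voxel_indices(k_perp, config)
        s_hat = np.zeros(config.detector_shape, dtype=np.complex128)
        s_hat[mask] = self.spectrum[ix, iy, iz] / (-2.0j * k_sz)
        s = ifft_centered(s_hat, config.pixel_size)
        return RytovField(data=s, k_perp=k_perp, spacing=config.pixel_size,
                          frame_index=index)


def simulate_rytov_field(potential: PotentialVolume, k_perp,
                         config: OpticsConfig) -> RytovField:
    """Complex Rytov phase s(rho) of one illumination angle (see
    :class:`RytovSimulator` for the cap-sampling model)."""
    return RytovSimulator(potential, config).field(k_perp)


class SidebandOverlapError(ValueError):
    """Reference carrier too close to the object band for clean demodulation."""


def check_sideband_separation(k_perp, q_ref, config: OpticsConfig,
                              index: int | None = None) -> None:
    """Require |q_ref - k_perp| > 2 * q_det_eff (sideband clears the
    weak-object DC term) and the sideband disk to fit inside Nyquist."""
    k_perp = np.asarray(k_perp, dtype=float)
    q_ref = np.asarray(q_ref, dtype=float)
    sep = float(np.hypot(*(q_ref - k_perp)))
    tag = "" if index is None else f" (frame {index})"
    if sep <= 2.0 * config.q_det_eff:
        raise SidebandOverlapError(
            f"carrier separation |q_ref - k_i| = {sep:.4g} rad/nm does not "
            f"exceed twice the object band radius {config.q_det_eff:.4g}{tag}")
    if np.any(np.abs(q_ref) + config.q_det_eff >= config.q_nyquist):
        raise SidebandOverlapError(
            f"sideband around q_ref = {q_ref.tolist()} exceeds the Nyquist "
            f"square (limit {config.q_nyquist:.4g} rad/nm){tag}")


def synthesize_hologram(field: RytovField, k_perp, q_ref,
                        noise: NoiseModel | None,
                        config: OpticsConfig, index: int = 0) -> HologramFrame:
    """Off-axis hologram I = |exp(s) exp(i k_i.rho) + exp(i q_ref.rho)|**2,
    optionally Poisson-sampled at the configured photon budget."""
    k_perp = np.asarray(k_perp, dtype=float)
    q_ref = np.asarray(q_ref, dtype=float)
    check_sideband_separation(k_perp, q_ref, config, index)
    nx, ny = config.detector_shape
    x = space_axis(nx, config.pixel_size)
    y = space_axis(ny, config.pixel_size)
    X, Y = np.meshgrid(x, y, indexing="ij")
    u = np.exp(field.data) * np.exp(1j * (k_perp[0] * X + k_perp[1] * Y))
    r = np.exp(1j * (q_ref[0] * X + q_ref[1] * Y))
    intensity = np.abs(u + r) ** 2
    if noise is not None:
        rng = np.random.default_rng(noise.seed + index)
        scale = noise.photons / 2.0   # photons per pixel at the I=2 mean
        intensity = rng.poisson(intensity * scale).astype(np.float64) / scale
    return HologramFrame(intensity=intensity, index=index,
                         k_designated=k_perp.copy(), k_true=None)


def simulate_stack(phantom: RIVolume, scan: ScanPattern,
                   jitter: JitterModel | None, noise: NoiseModel | None,
                   config: OpticsConfig,
                   q_ref: np.ndarray | None = None
                   ) -> tuple[HologramStack, SimulationTruth]:
    """Simulate a full tomographic cycle.

    Per frame the true illumination vector is the designated one plus a
    seeded jitter draw; the hologram is synthesized from the true vector
    while the stack stores the designated one.  Sideband separation is
    checked for every frame before any synthesis.
    """
    jitter = jitter or JitterModel()
    if q_ref is None:
        q_ref = default_reference_carrier(config)
    q_ref = np.asarray(q_ref, dtype=float)
    rng = np.random.default_rng(jitter.seed)
    true_vectors = scan.vectors + rng.normal(0.0, jitter.sigma,
                                             size=scan.vectors.shape)
    for i, k_true in enumerate(true_vectors):
        check_sideband_separation(k_true, q_ref, config, i)
        illumination_kz(k_true, config)   # raises if jitter made it evanescent

    potential = scattering_potential(phantom, config)
    sim = RytovSimulator(potential, config)
    frames = []
    for i, (k_des, k_true) in enumerate(zip(scan.vectors, true_vectors)):
        fld = sim.field(k_true, index=i)
        frame = synthesize_hologram(fld, k_true, q_ref, noise, config, index=i)
        frame.k_designated = np.asarray(k_des, dtype=float)
        frame.k_true = np.asarray(k_true, dtype=float)
        frames.append(frame)
    stack = HologramStack(frames=frames, scan=scan, q_ref=q_ref, config=config)
    truth = SimulationTruth(true_vectors=true_vectors, jitter=jitter, noise=noise)
    return stack, truth
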