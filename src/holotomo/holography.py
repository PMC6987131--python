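"""Complex-field recovery from off-axis holograms.

Three steps: sideband demodulation in the Fourier domain, deterministic 2D
phase unwrapping, and formation of the complex Rytov phase
``s = ln(|U|/|U0|) + i * unwrap(arg U - arg U0)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn, idctn

from .fourier import fft_centered, ifft_centered, space_axis
from .optics import OpticsConfig

AMPLITUDE_FLOOR = 1e-6
INCIDENT_MIN = 1e-12


@dataclass
class ComplexField2D:
    """2D complex field samples on the detector grid."""

    data: np.ndarray
    spacing: float
    normalization: str = "raw"       # "raw" | "incident-normalized"

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("complex field contains non-finite values")


@dataclass
class RytovField:
    """Complex Rytov phase of one frame: Re s = log-amplitude ratio,
    Im s = unwrapped phase difference."""

    data: np.ndarray
    k_perp: np.ndarray
    spacing: float
    frame_index: int = 0
    diagnostics: dict = None


def _intensity_of(frame) -> np.ndarray:
    return np.asarray(getattr(frame, "intensity", frame), dtype=np.float64)


def demodulate(frame, carrier, band_radius: float, config: OpticsConfig,
               band_center=None) -> ComplexField2D:
    """Extract the complex sideband field of an off-axis hologram.

    FFT -> hard circular mask of ``band_radius`` centered at ``band_center``
    (default: the carrier) -> recenter the carrier to DC -> inverse FFT.
    The mask must exclude the DC bin and fit inside the Nyquist square
    (both checked in the raw hologram's frequency coordinates).

    The recentering is applied as an exact real-space modulation *before*
    the transform: baseband-shifting first makes the object sideband
    lattice-periodic, so the hard mask passes it without spectral-leakage
    loss even when the carrier sits between frequency bins.
    """
    carrier = np.asarray(carrier, dtype=float)
    center = carrier if band_center is None else np.asarray(band_center, dtype=float)
    if band_radius <= 0:
        raise ValueError("band_radius must be positive")
    if np.hypot(*center) <= band_radius:
        raise ValueError(
            f"sideband mask (center {center.tolist()}, radius {band_radius:.4g}) "
            "touches DC")
    if np.any(np.abs(center) + band_radius >= config.q_nyquist):
        raise ValueError(
            f"sideband mask (center {center.tolist()}, radius {band_radius:.4g}) "
            f"touches the Nyquist limit {config.q_nyquist:.4g} rad/nm")
    intensity = _intensity_of(frame)
    nx, ny = intensity.shape
    x = space_axis(nx, config.pixel_size)
    y = space_axis(ny, config.pixel_size)
    ramp = np.exp(-1j * (carrier[0] * x[:, None] + carrier[1] * y[None, :]))
    spectrum = fft_centered(intensity * ramp, config.pixel_size)
    qx, qy = config.detector_freqs()
    QX, QY = np.meshgrid(qx, qy, indexing="ij")
    shifted_center = center - carrier
    mask = ((QX - shifted_center[0]) ** 2
            + (QY - shifted_center[1]) ** 2) <= band_radius ** 2
    field = ifft_centered(spectrum * mask, config.pixel_size)
    return ComplexField2D(data=field, spacing=config.pixel_size)


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - a, 2.0 * np.pi)


def unwrap_phase(wrapped: np.ndarray, method: str = "dct") -> np.ndarray:
    """Deterministic 2D phase unwrapping.

    ``dct`` (default) solves the weighted-free least-squares problem of
    Ghiglia & Romero with Neumann boundaries via DCT Poisson inversion and
    then forces congruence, so the output equals the input modulo 2*pi at
    every pixel.  ``quality`` delegates to scikit-image's reliability-guided
    unwrapper for noisy data.
    """
    wrapped = np.asarray(wrapped, dtype=np.float64)
    n_nan = int(np.count_nonzero(~np.isfinite(wrapped)))
    if n_nan:
        raise ValueError(f"phase map contains {n_nan} non-finite pixels")
    if method == "quality":
        from skimage.restoration import unwrap_phase as _sk_unwrap
        return np.asarray(_sk_unwrap(wrapped))
    if method != "dct":
        raise ValueError(f"unknown unwrap method {method!r}")

    gx = np.zeros_like(wrapped)
    gy = np.zeros_like(wrapped)
    gx[:-1, :] = _wrap(np.diff(wrapped, axis=0))
    gy[:, :-1] = _wrap(np.diff(wrapped, axis=1))
    rho = np.zeros_like(wrapped)
    rho += gx
    rho[1:, :] -= gx[:-1, :]
    rho += gy
    rho[:, 1:] -= gy[:, :-1]

    m, n = wrapped.shape
    wx = 2.0 * (np.cos(np.pi * np.arange(m) / m) - 1.0)
    wy = 2.0 * (np.cos(np.pi * np.arange(n) / n) - 1.0)
    denom = wx[:, None] + wy[None, :]
    denom[0, 0] = 1.0
    rho_hat = dctn(rho, type=2, norm="ortho")
    phi_hat = rho_hat / denom
    phi_hat[0, 0] = 0.0
    phi = idctn(phi_hat, type=2, norm="ortho")
    # The DCT solution carries an arbitrary constant; anchor the jump count
    # at the center pixel and snap to congruence (output = input mod 2*pi at
    # every pixel).  Anchoring pixelwise differences rather than a circular
    # mean keeps the rounding away from half-integer boundaries.
    resid = phi - wrapped
    resid -= resid[m // 2, n // 2]
    return wrapped + 2.0 * np.pi * np.round(resid / (2.0 * np.pi))


def unit_incident(shape, spacing: float) -> ComplexField2D:
    """Analytic incident field after carrier removal: unit plane wave."""
    return ComplexField2D(data=np.ones(shape, dtype=np.complex128),
                          spacing=spacing, normalization="incident-normalized")


def rytov_from_fields(sample: ComplexField2D, incident: ComplexField2D,
                      k_perp=(0.0, 0.0), frame_index: int = 0,
                      unwrap_method: str = "dct") -> RytovField:
    """Complex Rytov phase from sample and incident fields.

    Exact on multiplicative perturbations: if ``sample = incident * exp(c)``
    then ``s`` equals ``c`` (up to 2*pi phase branches resolved by
    unwrapping).  The amplitude ratio is floored at 1e-6 before the log;
    floored pixels are counted in ``diagnostics``.
    """
    if sample.data.shape != incident.data.shape:
        raise ValueError("sample and incident grids differ")
    mag0 = np.abs(incident.data)
    if mag0.min() < INCIDENT_MIN:
        raise ValueError("incident field magnitude below 1e-12 somewhere")
    ratio = np.abs(sample.data) / mag0
    n_floor = int(np.count_nonzero(ratio < AMPLITUDE_FLOOR))
    log_amp = np.log(np.maximum(ratio, AMPLITUDE_FLOOR))
    dphi = _wrap(np.angle(sample.data) - np.angle(incident.data))
    phase = unwrap_phase(dphi, method=unwrap_method)
    diag = {"amplitude_floor_pixels": n_floor,
            "amplitude_floor_fraction": n_floor / ratio.size}
    return RytovField(data=log_amp + 1j * phase,
                      k_perp=np.asarray(k_perp, dtype=float),
                      spacing=sample.spacing, frame_index=frame_index,
                      diagnostics=diag)
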