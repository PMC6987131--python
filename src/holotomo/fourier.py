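"""DC-centered Fourier transforms with physical (continuous-FT) scaling.

All spectra in this package are stored DC-centered: for an axis of length
``n`` with sample spacing ``d`` (nm), the angular spatial frequencies are
``q_k = 2*pi*(k - n//2) / (n*d)`` (rad/nm) and real-space coordinates are
``x_j = (j - n//2) * d``.  The forward kernel is ``exp(-i q.r)``, so the
discrete transforms below are Riemann approximations of the continuous
Fourier pair

    F(q) = int f(r) exp(-i q.r) dr,      f(r) = (2*pi)**-D int F(q) exp(+i q.r) dq.

``fftshift(fftn(ifftshift(x)))`` realizes the centered DFT exactly for any
``n``, which keeps forward simulation and tomographic inversion mutually
inverse to machine precision.
"""

from __future__ import annotations

import numpy as np


def freq_axis(n: int, spacing: float) -> np.ndarray:
    """DC-centered angular spatial frequencies (rad/unit) for one axis.

    Parameters
    ----------
    n : number of samples (>= 2).
    spacing : sample spacing (same length unit as 1/frequency).
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got n={n}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return 2.0 * np.pi * (np.arange(n) - n // 2) / (n * spacing)


def space_axis(n: int, spacing: float) -> np.ndarray:
    """Real-space coordinates with the origin at index ``n//2``."""
    if n < 2:
        raise ValueError(f"need at least 2 samples, got n={n}")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return (np.arange(n) - n // 2) * float(spacing)


def fft_centered(field: np.ndarray, spacing) -> np.ndarray:
    """Centered forward DFT scaled to approximate the continuous FT.

    ``spacing`` may be a scalar or one value per axis; the result is the
    plain centered DFT multiplied by the sample volume ``prod(spacing)``.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (field.ndim,))
    scale = float(np.prod(spacing))
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(field))) * scale


def ifft_centered(spectrum: np.ndarray, spacing) -> np.ndarray:
    """Inverse of :func:`fft_centered` (exact round trip)."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (spectrum.ndim,))
    scale = float(np.prod(spacing))
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spectrum))) / scale
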