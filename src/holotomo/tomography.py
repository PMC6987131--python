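"""Tomographic inversion: Ewald stitching, Wiener filtering, RI conversion.

Each calibrated frame contributes samples of the scattering-potential
spectrum on one translated Ewald cap,

    F(K) = -2j * k_sz * s_hat(q),   K = k_s - k_i,
    k_s = (q + k_i_perp, +sqrt(km**2 - |q + k_i_perp|**2)),

accumulated by nearest-voxel gridding into a complex numerator N(K) and a
count weight W(K).  Wiener filtering regularizes the uneven coverage,
``F_rec = N / (W + beta * W_max)``, and an inverse 3D FFT plus the algebraic
inverse of the scattering potential yields the refractive-index volume.
The unsampled axial "missing cone" is left untouched (no extrapolation),
which elongates reconstructions axially -- the standard transmission-ODT
signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .fourier import fft_centered, ifft_centered
from .optics import OpticsConfig, CTFModel, _cap_voxel_indices
from .phantom import PotentialVolume, RIVolume


@dataclass(frozen=True)
class ReconParams:
    """Reconstruction knobs.

    wiener_beta : Wiener regularizer relative to the peak coverage weight.
    gridding    : spectrum accumulation scheme ("nearest" only).
    nonneg_ri_contrast : clamp (n - n_m) below 0 (bright-object prior), off
        by default.
    unwrap_method : "dct" (deterministic least-squares) or "quality".
    calibrate   : run VISA; otherwise trust designated vectors.
    """

    wiener_beta: float = 1e-2
    gridding: str = "nearest"
    nonneg_ri_contrast: bool = False
    unwrap_method: str = "dct"
    calibrate: bool = True
    band_radius: float | None = None     # demodulation mask radius; default q_det_max
    background: str = "synthetic"        # incident-field model: synthetic | unit

    def __post_init__(self):
        if self.wiener_beta <= 0:
            raise ValueError("wiener_beta must be positive")
        if self.gridding != "nearest":
            raise ValueError(f"unsupported gridding scheme {self.gridding!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SpectrumAccumulator:
    """Numerator/weight grids on the potential-spectrum lattice."""

    numerator: np.ndarray         # (nx, ny, nz) complex
    weights: np.ndarray           # (nx, ny, nz) real counts
    config: OpticsConfig
    n_evanescent: int = 0         # samples skipped as non-propagating

    def __post_init__(self):
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any((self.weights == 0) & (self.numerator != 0)):
            raise ValueError("numerator nonzero where weight is zero")

    @property
    def coverage_fraction(self) -> float:
        return float(np.count_nonzero(self.weights)) / self.weights.size


@dataclass
class ReconstructionResult:
    ri: RIVolume
    diagnostics: dict
    calibration: object = None    # CalibratedScan when VISA ran


def map_to_ewald(fields, vectors, config: OpticsConfig) -> SpectrumAccumulator:
    """Stitch per-angle Rytov fields onto the 3D potential spectrum.

    ``fields`` are RytovFields (one per frame); ``vectors`` the matching
    calibrated transverse illumination vectors (rad/nm), or a
    CalibratedScan.  Evanescent samples are skipped and counted.
    """
    if hasattr(vectors, "refined_vectors"):
        vectors = vectors.refined_vectors
    vectors = np.asarray(vectors, dtype=float)
    fields = list(fields)
    if len(fields) != len(vectors):
        raise ValueError("one calibrated vector per field is required")
    num = np.zeros(config.volume_shape, dtype=np.complex128)
    wgt = np.zeros(config.volume_shape, dtype=np.float64)
    n_evan = 0
    for fld, k_perp in zip(fields, vectors):
        s_hat = fft_centered(np.asarray(fld.data, dtype=np.complex128),
                             config.pixel_size)
        ix, iy, iz, k_sz, mask = _cap_voxel_indices(k_perp, config)
        n_evan += int(mask.size - mask.sum())
        values = -2.0j * k_sz * s_hat[mask]
        np.add.at(num, (ix, iy, iz), values)
        np.add.at(wgt, (ix, iy, iz), 1.0)
    return SpectrumAccumulator(numerator=num, weights=wgt, config=config,
                               n_evanescent=n_evan)


def wiener_invert(acc: SpectrumAccumulator, params: ReconParams,
                  config: OpticsConfig,
                  ctf: CTFModel | None = None) -> tuple[PotentialVolume, dict]:
    """Wiener-regularized inversion of the stitched spectrum.

    ``F_rec = N / (W + beta * W_max)`` on covered voxels, zero elsewhere;
    inverse 3D FFT; the real part is the potential, the imaginary-part RMS
    is reported as a consistency diagnostic.  A loaded CTF substitutes its
    weights for the accumulated counts.
    """
    wgt = acc.weights if ctf is None else ctf.weights * max(acc.weights.max(), 1.0)
    if not np.any(wgt > 0):
        raise ValueError("empty coverage: no spectrum samples accumulated")
    w_max = wgt.max()
    covered = wgt > 0
    spec = np.zeros_like(acc.numerator)
    spec[covered] = acc.numerator[covered] / (wgt[covered]
                                              + params.wiener_beta * w_max)
    f_complex = ifft_centered(spec, config.voxel_size)
    f_real = f_complex.real
    diag = {
        "imag_rms": float(np.sqrt(np.mean(f_complex.imag ** 2))),
        "real_rms": float(np.sqrt(np.mean(f_real ** 2))),
        "coverage_fraction": acc.coverage_fraction,
        "n_evanescent": acc.n_evanescent,
    }
    return PotentialVolume(data=f_real, voxel_size=config.voxel_size), diag


def potential_to_ri(potential: PotentialVolume, config: OpticsConfig,
                    diagnostics: dict | None = None) -> RIVolume:
    """n(r) = sqrt(n_m**2 + f(r)/k0**2); exact inverse of the scattering
    potential on its range.  Arguments that would give n < 1 are clamped
    (counted in diagnostics), keeping the RI physical."""
    arg = config.medium_ri ** 2 + potential.data / config.k0 ** 2
    n_clamped = int(np.count_nonzero(arg < 1.0))
    n = np.sqrt(np.maximum(arg, 1.0))
    if diagnostics is not None:
        diagnostics["n_clamped_voxels"] = n_clamped
    return RIVolume(data=n, voxel_size=potential.voxel_size,
                    medium_ri=config.medium_ri)


def reconstruct(stack, params: ReconParams | None = None,
                ctf: CTFModel | None = None) -> ReconstructionResult:
    """Full inversion chain on a hologram stack.

    demodulate (VISA-calibrated carriers) -> least-squares unwrap -> Rytov
    formation -> Ewald stitching -> Wiener inversion -> RI conversion.
    Deterministic given the stack and parameters.

    The incident field is, by default, a sample-free hologram at the
    calibrated carrier pushed through the identical demodulation operator
    (the background-normalization step of off-axis ODT practice): dividing
    by it cancels the finite-window truncation ripple that an off-lattice
    carrier leaves in the masked sideband.  ``background="unit"`` uses the
    bare analytic plane wave instead.
    """
    from .forward import synthesize_hologram
    from .holography import (RytovField, demodulate, rytov_from_fields,
                             unit_incident)
    from .visa import calibrate_scan

    params = params or ReconParams()
    config = stack.config
    q_ref = np.asarray(stack.q_ref, dtype=float)
    band_radius = params.band_radius or config.q_det_max
    calibration = None
    if params.calibrate:
        calibration = calibrate_scan(stack, unwrap_method=params.unwrap_method)
        vectors = calibration.refined_vectors
    else:
        vectors = np.array([np.asarray(f.k_designated, dtype=float)
                            for f in stack.frames])

    zero_field = RytovField(
        data=np.zeros(config.detector_shape, dtype=np.complex128),
        k_perp=np.zeros(2), spacing=config.pixel_size)
    fields = []
    floor_frames = 0
    for i, (frame, k_perp) in enumerate(zip(stack.frames, vectors)):
        carrier = k_perp - q_ref
        try:
            fld2d = demodulate(frame, carrier, band_radius, config,
                               band_center=-q_ref)
            if params.background == "synthetic":
                bg = synthesize_hologram(zero_field, k_perp, q_ref, None,
                                         config, index=i)
                incident = demodulate(bg, carrier, band_radius, config,
                                      band_center=-q_ref)
            elif params.background == "unit":
                incident = unit_incident(config.detector_shape,
                                         config.pixel_size)
            else:
                raise ValueError(
                    f"unknown background model {params.background!r}")
            ry = rytov_from_fields(fld2d, incident, k_perp=k_perp,
                                   frame_index=i,
                                   unwrap_method=params.unwrap_method)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
        if ry.diagnostics["amplitude_floor_fraction"] > 1e-3:
            floor_frames += 1
        fields.append(ry)

    acc = map_to_ewald(fields, vectors, config)
    potential, diag = wiener_invert(acc, params, config, ctf=ctf)
    ri = potential_to_ri(potential, config, diagnostics=diag)
    if params.nonneg_ri_contrast:
        np.maximum(ri.data, config.medium_ri, out=ri.data)
    diag["params"] = params.to_dict()
    diag["amplitude_floor_frames"] = floor_frames
    if calibration is not None:
        diag["visa_mean_shift"] = calibration.mean_shift
        diag["visa_failed_frames"] = calibration.n_failed
    return ReconstructionResult(ri=ri, diagnostics=diag, calibration=calibration)
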