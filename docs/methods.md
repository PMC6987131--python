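# Methods

## Scattering model and conventions

All frequencies are angular spatial frequencies in rad/nm; lengths in nm.
Spectra are stored DC-centered with the forward kernel exp(−i q·r);
`fftshift(fftn(ifftshift(·)))` realizes the centered DFT exactly, scaled by
the sample volume so discrete transforms approximate the continuous Fourier
pair.  The coordinate origin sits at the center voxel (index n//2 per
axis); the detector plane coincides with the volume mid-plane z = 0 and
positive k_sz points toward the detector.

The sample enters through the scattering potential f(r) = k0²(n² − n_m²).
Under the first-order Rytov approximation the total field is
U = exp(s)·U0 — genuinely exp(s)·U0, not the linearized U0·(1+s), which
keeps hologram synthesis and demodulation mutually exact.  The forward
simulator evaluates the Fourier diffraction theorem directly: for each
detector frequency q with |q + k_i⊥| inside both the detection aperture and
the propagating band (k_sz ≥ 0.0316·k_m, a guard against the 1/k_sz
divergence at grazing angles), the 2D Rytov spectrum is

    ŝ(q) = F̂(K) / (−2i k_sz),  K = k_s − k_i,

with F̂ sampled at the lattice point nearest to K (lateral components fall
on the lattice exactly when the volume's xy sampling equals the detector's,
which the package requires; only K_z is rounded).  Sampling at the rounded
lattice point puts the gridding error in the forward model and makes
forward and inverse *mutually exact* on every sampled voxel — the
round-trip identity is a hard test, not an approximation.  Evanescent
samples are skipped and counted, never extrapolated.

Default optics (561 nm, n_m = 1.337, NA_ill 1.0, NA_det 1.45, 65-nm pixels,
128×128 detector, 128×128×64 voxels at 65×65×150 nm) describe a
high-NA transmission system.  Since NA_det > n_m, detection is limited by
the propagating band k_m rather than the nominal aperture: the lateral
support of a ring scan reaches ring_fraction·q_ill + min(q_det, k_m), about
0.0256 rad/nm here (amplitude PSF FWHM ≈ 170 nm).  The medium index 1.337
(aqueous) is a package default, exposed in the configuration.

## Scan geometry and reference carrier

One tomographic cycle records 240 holograms.  The default trajectory is a
single ring at 95% of the illumination band limit with uniform azimuths —
the standard galvo pattern, maximizing the synthetic aperture; a
golden-angle Fermat spiral is available where radial diversity matters.

The reference carrier defaults to 65% of Nyquist per axis along the
detector diagonal (|q_ref| ≈ 0.92·Nyquist).  The geometry is forced by
three constraints: the sideband disk (radius q_det_max around −q_ref) must
fit inside the square Nyquist domain, clear the weak-object DC term (radius
q_det_eff + |k_i⊥|), and stay separated from its conjugate.  At these NAs
and pixel size the feasible window is narrow; a carrier much below
0.9·Nyquist overlaps the DC term for ring-scan angles.

## Demodulation and background normalization

Demodulation baseband-shifts the hologram by the exact (sub-bin) carrier in
real space *before* the FFT, then applies a hard circular mask and inverse
transforms.  Shifting first matters: it makes the object sideband
lattice-periodic, so the hard mask passes it without spectral-leakage loss
even for carriers between frequency bins.  Mask legality (excludes DC, fits
inside Nyquist) is checked in the raw hologram's frequency coordinates.

A finite detector window still leaves truncation ripple from the strong
unscattered carrier.  The reconstruction therefore normalizes by a
*background*: a sample-free hologram synthesized at the calibrated carrier
and pushed through the identical demodulation operator — the software
analogue of the sample-free calibration frame a real instrument records.
The ripple is common to sample and background and cancels in the Rytov
ratio; an empty-medium stack reconstructs to |n − n_m| < 1e−4.

Phase unwrapping is deterministic least-squares (Ghiglia–Romero) via DCT
Poisson inversion with Neumann boundaries, followed by a congruence step
anchored at the center pixel so the output equals the input modulo 2π at
every pixel (anchoring pixel differences, not a circular mean, keeps the
rounding away from half-integer boundaries).  scikit-image's
reliability-guided unwrapper is selectable for noisy data.  The Rytov
amplitude ratio is floored at 1e−6 before the log; floored pixels are
counted in diagnostics.

## VISA: illumination-vector self-calibration

High-speed mechanical scanning wobbles the illumination angle; stitching
caps at the designated instead of the actual vectors destroys contrast and
resolution (correlation with band-limited truth drops from ≈1.0 to <0.1 at
0.5-bin wobble in our simulations).  Calibration proceeds per frame:

1. **Coarse**: the off-DC spectral peak of the Hann-windowed hologram FFT,
   searched in the half-plane qx > 0 with a 5-bin DC exclusion zone,
   refined per axis by 3-point parabolic interpolation of the
   log-magnitude (ties break to the lexicographically smallest bin).  The
   window keeps the parabolic bias well under 0.05 bin; if the peak lands
   more than 3 bins from the position predicted by the designated vector,
   the prediction seeds the search instead.
2. **Refinement**: coordinate descent with golden-section line searches
   (bracket ±1 bin, halved per sweep) on the residual-slope objective:
   demodulate at the candidate carrier (exact baseband shift, DC-centered
   mask of 16 bins), unwrap, least-squares-fit a plane over a central
   window, return the norm of its gradient in rad/nm.  For a weak object
   the phase is flat at the true carrier, and a candidate offset by δ
   yields an objective of exactly |δ| — the single-frame objective uses the
   central 50% of pixels; full-scan calibration widens this to 80%, which
   averages the object's own phase structure better and measurably reduces
   the slope bias.  Accepted iterates never increase the objective;
   stopping at 1e−4 rad/µm or on stall counts as convergence, exhausting
   max_iter (50) flags the frame instead of raising.

Convention, pinned package-wide: k_i⊥ = q_ref − q_peak with q_peak the
sideband carrier in the positive half-plane.  The refined result is also
compared against the designated prediction and the better kept, so
calibration can only improve on the designated mapping.  On object-free
frames the recovery is exact to <1e−3 bin; with an object present the
weak-object assumption (zero mean phase slope over the window) leaves a
genuine bias of order 0.01 bin — strongly prismatic samples would need a
higher-order background model, which is a documented limitation.  Under
0.3–0.5-bin Gaussian wobble the calibration recovers vectors to a few
thousandths of a bin and restores reconstruction correlation above 0.95.

## Inversion

Nearest-voxel gridding accumulates F̂ samples (numerator) and unit counts
(weights); Wiener division uses the counts plus β·W_max with β = 1e−2 by
default (acceptance-style comparisons pin β = 1e−3; β is exposed and
echoed in diagnostics).  A loaded, externally measured transfer function
can substitute its weights for the counts.  No missing-cone regularization
is applied by default — plain Wiener only; an optional non-negativity
clamp on (n − n_m) exists for bright-object phantoms and is off by
default.  The inverse FFT's imaginary-part RMS is reported as a
consistency diagnostic, the real part becomes f_rec, and
n = √(n_m² + f_rec/k0²) with sub-unity arguments clamped (counted, not
fatal).

Consequences of the geometry, asserted by tests: a point-like bead's axial
FWHM exceeds twice its lateral FWHM (missing cone); extended 3D objects
lose RI contrast (a 1.2-µm Δn = −0.01 vacuole reconstructs at roughly half
contrast); strong objects ring — Wiener sidelobes around a bright droplet
can cross a dark segmentation threshold, which is why segmentation reports
per-object contrast depth.

## Phantoms: what the generator emulates, and what it does not

Phantoms are unions of spheres (vacuoles, droplets, endosome-like bodies),
cylinders (mitochondrion/filament-like tubes), shells (membranes) and
boxes, with RI in the cellular range 1.30–1.60 in an aqueous background;
later primitives win where they overlap.  Rasterization follows the
voxel-center rule; a supersampling option averages sub-voxel coverage when
spectral fidelity against closed-form transforms matters (binary staircase
error is ~4% on a 600-nm sphere at 65-nm voxels, antialiased <1%).
Illumination wobble is i.i.d. Gaussian per frame per axis — magnitude is a
free parameter since no measured value is available — and noise is Poisson
at a configurable photon budget (default 1e4 photons/pixel; read noise and
camera MTF are deliberately absent).  Real cells add multiple scattering,
aberrations, temporal drift and structured backgrounds that none of this
reproduces: passing tests certify the algorithmic chain (demodulation,
calibration, stitching, inversion, quantification) under its own model
assumptions, not instrument performance on tissue.

## Quantification choices

* Resolution: line profiles are width-averaged with linear interpolation
  and fit by Gaussian+baseline least squares; fwhm = 2√(2 ln 2)·σ by
  construction.  A 50-nm filament at the default optics reconstructs to a
  transverse FWHM of ≈ 140 nm, comfortably inside the 200-nm scale that
  high-NA synthetic-aperture systems report.
* Segmentation: background = median, scale = 1.4826·MAD, detection
  threshold median ∓ k·scale with k = 3 by default (the robust reading of
  "applied thresholds"); 26-connectivity; minimum equivalent diameter
  0.5 µm.  Detected objects are *sized* at half their own contrast depth
  relative to the local background (FWHM sizing): a detection threshold
  near the background crosses the blurred flank of an object wherever the
  blur puts it, inflating blurred dark spheres by ~10%, whereas the
  half-depth boundary of a symmetrically blurred edge sits at the true
  edge (−3% on the same phantom).  The label volume keeps the
  detection-threshold components.
* Contacts: contact at frame t iff the touch-distance dilation of one mask
  intersects the other; runs with internal gaps ≤ gap_tol merge.
  Exponential durations are fit by maximum likelihood (τ = sample mean,
  n ≥ 5); Gaussian mixtures by EM with deterministic quantile
  initialization and a pinned seed, means reported sorted.
* Colocalization: an object is "associated" iff ≥ 30% of its area overlaps
  the other channel (the threshold is exposed; both directional fractions
  are returned with counts).  Registration is the caller's duty.
* Motion blur: T = resolution / empirical-quantile(speeds, q), default
  q = 0.95 — the longest acquisition for which the stated fraction of
  tracked structures moves less than one resolution element.

## Problem sizes

Unit tests run on 64×64×32 volumes with 4–60 angles; the end-to-end checks
use the full default geometry (128×128×64, 240 angles), which simulates in
a few seconds and reconstructs with calibration in well under a minute per
cycle on one CPU.  `scripts/acceptance.py` uses n = 2000 draws for
exponential fits and n = 1000 for the two-component mixture.

## Known limitations

Single scattering only (first-order Rytov); scalar fields (no
polarization, no vectorial pupils); no aberration or defocus model; the
weak-object bias of the VISA objective on asymmetric samples; missing-cone
contrast loss and axial elongation are reported, not corrected; object
tracking is out of scope (tracks are consumed from CSV).
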