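# holotomo

Label-free optical diffraction tomography (ODT) reconstructs the 3D
refractive-index (RI) map of a living cell from off-axis holograms recorded
under many illumination angles.  Because organelles differ in optical
density — lipid droplets are denser than cytosol, certain vacuoles are less
dense — the RI map is a structural image of the whole cell without any
fluorescent label, fast enough to follow organelle contacts for hours.

`holotomo` implements the ODT arm of such a microscope as a reusable
toolkit for method developers and quantitative cell biologists:

* **forward simulation** — voxelized cell-like phantoms (spheres, tubes,
  shells, 1.30 ≤ n ≤ 1.60), first-order Rytov scattering sampled on Ewald
  caps, off-axis hologram synthesis with shot noise and illumination-angle
  jitter;
* **holographic demodulation** — sideband extraction, deterministic
  least-squares phase unwrapping, Rytov-phase formation with background
  normalization;
* **VISA self-calibration** — per-frame recovery of the true illumination
  wave vector by minimizing the residual slope of the unwrapped demodulated
  phase (high-speed galvo scanning wobbles the illumination angle, which
  otherwise misplaces Ewald caps and destroys contrast and resolution);
* **tomographic inversion** — Ewald-sphere stitching of the per-angle
  spectra, Wiener-regularized inversion, conversion to RI;
* **quantification** — Gaussian FWHM resolution profiling, robust
  segmentation of dark vacuoles and bright organelles, per-plane densities
  and axial-slab area fractions, contact-event extraction with exponential
  and Gaussian-mixture duration fits, colocalization fractions against
  fluorescence masks, and the motion-blur limit on acquisition time.

## The model

With vacuum wavenumber k0 = 2π/λ and medium index n_m (k_m = k0·n_m), the
scattering potential of the sample is

    f(r) = k0² (n²(r) − n_m²).

Under the first-order Rytov approximation the total transmitted field for a
tilted plane-wave illumination k_i is U = exp(s)·U0, and the Fourier
diffraction theorem maps the 2D spectrum of the complex Rytov phase s onto
the 3D spectrum of f along a translated Ewald cap:

    F̂(K) = −2i k_sz · ŝ(q),   K = k_s − k_i,
    k_s = (q + k_i⊥, +√(k_m² − |q + k_i⊥|²)).

Each of the 240 illumination angles of one tomographic cycle contributes
one cap; the samples are accumulated into a numerator N(K) and a coverage
count W(K), and the potential is recovered by Wiener filtering,

    F̂_rec(K) = N(K) / (W(K) + β·W_max),   n(r) = √(n_m² + f_rec(r)/k0²).

The frequency support is the union of cap translates: laterally it extends
to ≈ 2π(NA_ill + NA_det)/λ (synthetic aperture — ~170 nm amplitude FWHM at
λ = 561 nm, NA 1.0/1.45), while the axial "missing cone" is never sampled,
so reconstructions are elongated in z.

## Worked example

Simulate a two-organelle phantom (a dark vacuole, Δn = −0.01, d = 1.2 µm,
and a bright droplet, Δn = +0.01) under 60 ring-scan angles with 0.3-bin
illumination jitter, then calibrate, reconstruct and segment:

```python
import numpy as np
import holotomo as ht
from holotomo.forward import simulate_stack, JitterModel
from holotomo.tomography import reconstruct, ReconParams
from holotomo.quantify import segment_by_contrast

cfg = ht.OpticsConfig(detector_shape=(64, 64), volume_shape=(64, 64, 32))
dq = 2 * np.pi / (64 * cfg.pixel_size)
phantom = ht.build_phantom(ht.PhantomSpec.of(
    ht.Primitive("sphere", (-1200.0, -900.0, 0.0), ri=1.327, radius=600.0),
    ht.Primitive("sphere", (1200.0, 900.0, 0.0), ri=1.347, radius=400.0)), cfg)
scan = ht.generate_scan_pattern(cfg, 60)
stack, truth = simulate_stack(phantom, scan,
                              JitterModel(sigma=0.3 * dq, seed=0), None, cfg)
result = reconstruct(stack, ReconParams(wiener_beta=1e-3))
err = np.hypot(*(result.calibration.refined_vectors
                 - truth.true_vectors).T) / dq
print(f"VISA recovery: mean |refined - true| = {err.mean():.4f} bins")
print(f"background RI: {np.median(result.ri.data):.4f}")
_, stats = segment_by_contrast(result.ri, mode="dark", k_sigma=3.0,
                               min_diameter=1.0)
for s in stats:
    print(f"dark vacuole: diameter {s.equivalent_diameter:.2f} um, "
          f"delta RI {s.delta_ri:+.4f}")
```

prints

```
VISA recovery: mean |refined - true| = 0.0159 bins
background RI: 1.3369
dark vacuole: diameter 1.13 um, delta RI -0.0052
dark vacuole: diameter 0.82 um, delta RI -0.0019
```

Reading the output: VISA has recovered the jittered illumination vectors to
about 1/60 of a frequency bin, far below the 0.3-bin wobble that was
injected; the reconstructed background sits at the medium index 1.337; the
seeded 1.2-µm vacuole is found at 1.13 µm with a negative RI contrast of
about half its true −0.01 (the missing cone dilutes the contrast of
extended 3D objects).  The second, shallower "vacuole" (ΔRI −0.0019) is the
dark Wiener sidelobe ring of the *bright* droplet — a reconstruction
artifact worth knowing about when counting real vacuoles; its contrast is
well below the genuine object's.

A CLI wraps the same pipeline for shell use:

```
holotomo simulate    --config run.yaml
holotomo calibrate   --stack stack.h5 --out calibration.csv
holotomo reconstruct --stack stack.h5 --out ri.tif
holotomo quantify    --volume ri.tif --mode dark --out report.json
holotomo selftest
```

Hologram stacks travel as HDF5 (lossless; groups `/holograms`, `/scan`,
`/calibration`, `/reconstruction`, `/truth` — the last written only by the
simulator and never read by reconstruction) or as uint16 multipage TIFF
with a YAML sidecar; RI volumes as ImageJ-compatible float32 TIFF or HDF5.

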