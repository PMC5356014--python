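# pixelsr — all-passive pixel super-resolution for time-stretch imaging

Optical time-stretch line-scan imaging reads each spatial line of a flowing
specimen as a temporal waveform: a diffraction grating maps wavelength to
position (`C_x`, μm/nm) and group-velocity dispersion maps wavelength to
arrival time (`C_t`, ns/nm), so a single photodetector and a digitizer at
sampling rate `f` capture one line per laser pulse (repetition rate `F`).
The fast-axis pixel pitch `Δx = C_x/(C_t·f)` is then set by the digitizer:
at affordable rates (≈5 GSa/s) the pixels are far coarser than the optics
resolve and the images alias.

Because the digitizer clock is free-running with respect to the laser, the
number of samples per line `f/F` is not an integer: every successive line's
sample grid is offset by a deterministic sub-pixel drift

    δx = (f/F − N)·Δx,   N = round(f/F),   |δx| ≤ Δx/2,

shearing the effective sampling lattice by `tan θ = δx/Δy` (slow-axis pitch
`Δy = v_y/F`). This package implements the reconstruction that exploits that
drift — *passive pixel super-resolution*: register the true `f/F` from the
repeating illumination background, place every sample at its true position
on the sheared lattice, restore a fine-pitch 1-D illumination reference by
equivalent-time sampling (shift-and-add with bounded-denominator rational
approximation of the fractional ratio), suppress the background, and fuse
the scattered samples onto a regular grid with a matched Gaussian filter.
The fast-axis pixel improves by `1/cos θ` (≈10× at the reference
condition) with no extra hardware.

The package is aimed at builders of time-stretch / imaging-flow-cytometry
systems and at anyone studying equivalent-time-sampling reconstruction. It
ships with:

* `pixelsr.warpgeom` — closed-form lattice geometry (`Δx`, `Δy`, `δx`, `θ`,
  gain, minimum sub-pixel factor);
* `pixelsr.synth` — a ground-truthed waveform simulator (scenes, PSF,
  electronic bandwidth, free-running clock, noise);
* `pixelsr.register` — coarse cross-correlation + sharpness-refined
  estimation of `f/F` to ~1e-5 samples/line;
* `pixelsr.reconstruct` — the pixel-SR pipeline plus the two conventional
  baselines (dewarp-and-stack alignment; 1-D equivalent-time sampling);
* `pixelsr.phenotype` — label-free morphology classification (brightness
  screen, rotated-box bulk metrics, HoG → PCA morphology score, K-means,
  ROC/AUC);
* a `pixelsr` CLI (`geometry`, `simulate`, `register`, `reconstruct`,
  `classify`, `pipeline`) and narrative scripts under `examples/`.

## Worked example

```bash
pixelsr geometry --f 5e9 --F 11.6142e6 --Cx 7.1 --Ct 0.4 --v 2.0905 --B 10e9
```

```
fast-axis pitch dx    3.55 um
slow-axis pitch dy    0.179995 um
samples per line N    431
pixel drift dx_drift  -1.74844 um
tan(theta)            -9.71381
aspect ratio rho      0.0507029
resolution gain       9.76514
min sub-pixel factor q  4 (effective rate 20 GSa/s)
```

The 3.55 μm fast-axis pixel is ~20× the slow-axis pixel, each line drifts
by about half a pixel, and the lattice shear (tan θ ≈ −10) supports a ~10×
fast-axis gain; four sub-pixels take the effective rate to 20 GSa/s.

`examples/03_pixel_sr_vs_baselines.py` simulates a textured colony plus
droplets at this condition and reconstructs it three ways:

```
registered ratio error: +1.5e-04 samples/line
LR Nyquist spatial frequency: 0.141 1/um

pixel-SR  grid (52, 1723)   pitch (0.89, 0.89) um  RMSE 0.0084  99%-energy bw 0.146 1/um
align     grid (255, 1723)  pitch (0.89, 0.18) um  RMSE 0.0278  99%-energy bw 0.153 1/um
ETS       grid (63, 1722)   pitch (0.89, 0.72) um  RMSE 0.0255  99%-energy bw 0.362 1/um
```

Pixel-SR reaches one third of the alignment baseline's error against the
ground-truth transmittance, with spectral support past the LR Nyquist
(0.141 /μm); the equivalent-time-sampling baseline restores fast-axis
bandwidth but collapses every 4 lines into one row.
`examples/04_classify_cohort.py` continues into the phenotyping stage and
prints a 2- vs 4-daughter colony AUC of 0.966 on a 40-record cohort.

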