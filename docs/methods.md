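# Methods

## The sampling-lattice model

One laser pulse of repetition rate `F` illuminates one specimen line; the
spectral encoder (conversion `C_x`, μm/nm) and the dispersive stretch
(`C_t`, ns/nm) turn that line into a temporal waveform digitized at rate
`f`. The package models the acquisition as a 2-D sampling lattice:

* fast axis: pitch `Δx = C_x/(C_t·f)` μm per sample;
* slow axis: pitch `Δy = v_y/F` μm per line (flow speed `v_y`);
* per-line drift `δx = (f/F − N)·Δx` with `N = round(f/F)`; ties in the
  rounding go away from zero, so an exactly half-integer ratio yields
  `δx = −Δx/2` (the bound `|δx| ≤ Δx/2` is attained; the sign choice is a
  convention, fixed once);
* lattice shear `tan θ = δx/Δy`; interleaved pitches `Δu = Δx·cos θ`,
  `Δv = Δy/cos θ` (area-preserving), fast-axis gain `1/cos θ`.

Units are normalized internally to μm, s, Hz; the configuration object
stores the instrument's natural units (ns/nm, m/s) and converts once.
Sample `k` of a record sits at intra-line position `(k mod r)·Δx` on line
`floor(k/r)`, `r = f/F` — a phase accumulator, so the fractional ratio
carries the sub-pixel drift. Under this convention the *sample grid* of
successive lines moves by `−δx (mod Δx)`; the imaged content appears to
drift by `+δx`.

## The synthetic-data generator

The simulator is the package's only data source, and its defaults are the
reference study condition: `f = 5 GSa/s`, `F = 11.6142 MHz` (430.5075
samples/line), `C_x = 7.1 μm/nm`, `C_t = 400 ps/nm` (`Δx = 3.55 μm`),
`v_y = 2.0905 m/s` (`Δy = 0.18 μm`), analog bandwidth `B = 10 GHz`,
diffraction limit `d_opt = 2 μm`, 256 lines per record. The flow speed is
a free parameter chosen so the slow-axis pitch equals the quoted 0.18 μm.

The forward model is bright-field transmission: detector voltage =
illumination envelope × scene transmittance. Its elements:

* **Scenes.** Objects on a transmittance-1 background: lobed colonies
  (two or four elongated daughter cells, semi-axes ≈5 × 2.5 μm, packed
  side by side across the minor axis with a darker shared wall, interior
  transmittance 0.35–0.55, band-limited multiplicative texture),
  disks/droplets, and translucent ring fragments (transmittance
  0.55–0.68 — faint, but still above the brightness screen after PSF
  blur). The field (default 64–72 μm wide) occupies a small window of the
  ~1.5 mm spectral line; outside it the transmittance is 1.
* **Optics.** Gaussian PSF with FWHM `d_opt`, applied to the scene raster
  (pitch `Δx/8`); the blurred raster is stored as ground truth.
* **Envelope.** One fixed per-pulse profile: an asymmetric bell (the
  laser spectrum) with ~5% ripple from three incommensurate sinusoids
  (~10 cycles per line, seeded phases). The ripple is required — it is the
  structure the drift registration correlates on; shot-to-shot variation
  is zero by construction (the stability premise of passive registration).
* **Electronics and sampling.** The model is evaluated on an internally
  oversampled stream (8×f), low-passed there with a linear-phase
  windowed-sinc at `B`, then decimated by plain subsampling to `f`. This
  ordering matters: at the reference condition `B = 10 GHz` exceeds the
  digitizer Nyquist 2.5 GHz, so the low-rate record *must* alias — that
  aliasing is what the reconstruction removes. Timing jitter is zero;
  noise is additive i.i.d. Gaussian on the samples (s.d. as a fraction of
  the envelope peak; the default 0.02 corresponds to ≈29 dB SNR). Shot
  noise and envelope drift are not modeled, so passing tests bound
  algorithmic error, not every detector effect.
* **Clock.** The true ratio is `f/F·(1 + ε)` with `ε` the configured
  perturbation; cohorts draw `ε ∈ ±5e-5` per record, the order of the
  quoted clock stability. All randomness flows from one integer seed via
  `numpy.random.SeedSequence` spawning.

## Registration

Coarse: a template of two object-free lines from the start of the record
is located near its end by normalized cross-correlation (search window
±0.45 lines, so the one-line-period alias is excluded); the parabolically
interpolated peak lag over the line separation gives `f/F` to a few 1e-4
samples/line at 512 lines.

Refinement maximizes the sharpness (total squared gradient) of the
equivalent-time-sampling reference built with the candidate ratio. The
reference's Fourier coefficients are the record's spectrum at line-rate
harmonics, so the objective is evaluated as `Σ h²·|X(h/r)|²` over the
significant harmonics (selected once at the initial ratio): continuous in
`r`, phase-coherent over the record, maximal when the interleaved phases
align. Bracketed scalar minimization (bounded Brent, ±2e-3 samples/line,
terminating at 1e-7) refines to a median error ≈4e-5 samples/line at the
cohort noise level. Object-crossed lines and the two edge lines (filter
transients) are zero-weighted. A leave-half-out residual objective (even
lines predict odd lines) is available as `method="residual"`; it plateaus
earlier and serves as a cross-check.

Lines are scored for specimen content by the noise-normalized depth of
their lowest samples against a per-phase-bin background proxy; the
clean-line threshold hangs off the cleanest third of the record, since a
busy record's global median is itself contaminated.

Known limitation: the periodogram objective carries an `O(1/N²)`
spectral-leakage bias between neighbouring harmonics — ≈1e-5 samples/line
at 256 lines for a noise-free synchronized record — so a locked clock
refines to the integer ratio to that precision, not to machine precision.

## Reconstruction

1. **Segmentation** is lossless: every sample keeps its value and gets its
   phase-accumulated `(x, y)` position under the registered ratio.
2. **Reference restoration** folds the selected lines to intra-line phase
   and fits a periodic profile at pitch `Δx/q`. The fit aggregates samples
   in sub-bins (mean phase as abscissa) joined by a periodic cubic spline;
   the robust default uses per-sub-bin medians over clean lines with the
   bin width widened until ≥8 samples land in each (specimens only darken
   the waveform and cross any given phase on a minority of lines, so the
   median rides the clean majority; the envelope is smooth at sub-pixel
   scale, so wider bins cost no bandwidth). The non-robust path (used by
   the noise-free fidelity oracle) keeps fixed `Δx/(8q)` bins and plain
   means. The bounded-denominator rational approximation `p/r ≈ |f/F − N|`
   (continued-fraction convergents/semiconvergents, default `max_den` 64)
   reports the number of distinct sub-pixel phases; `r < q` flags
   insufficient coverage, and a locked clock degrades to an upsampled
   single-line profile instead of failing. The profile is band-limited at
   `min(q·f/2, B)`.
3. **Background suppression** subtracts the reference at each sample's
   phase (default, residuals around zero) or divides by it (flat-field,
   recovering transmittance — used wherever images are compared with the
   ground-truth scene). The mode is recorded in provenance.
4. **HR resampling** deposits samples onto the output grid with bilinear
   (cloud-in-cell) weights — nearest-pixel deposition quantizes positions
   by up to half a pixel and measurably degrades sharp interior structure —
   then smooths the value and weight images with the matched Gaussian and
   takes their ratio: an exactly normalized weighted average, bounded by
   the input range. Matched-filter widths: `σx = max(d_opt,
   C_x/(C_t·2B))/2.355`, `σy = d_opt/2.355` (FWHM = resolution limit; the
   Gaussian is chosen for separability and positivity — the spatial
   averaging kernel's exact shape is a design choice). Zero-weight pixels
   are in-filled by fast-axis linear interpolation, so a locked-clock
   acquisition degrades gracefully. Default `q` is the smallest integer
   with `q·f/2 ≥ B` (4 at the reference condition); default pitch `Δx/q`
   on both axes.

Baselines: `baseline_align` interpolates each line to the HR fast-axis
grid at its registered offset and stacks one row per line (no cross-line
fusion — the aliasing-prone conventional restoration); `baseline_ets`
fuses consecutive groups of `q` lines into single rows (fast-axis
bandwidth restored, slow-axis resolution divided by `q`). The HR grid is
rectangular; resampling goes directly to it rather than via the warped
`(u, v)` axes.

## Phenotyping

Screening thresholds brightness (objects absorb, so foreground is below
threshold), keeps the largest connected component, and fits the
minimum-area rotated rectangle (rotating calipers over the convex hull;
verified against a brute-force rotate-and-measure oracle). Opacity is the
mean masked intensity minus the background level (median outside the
mask); area is the box footprint in μm². The morphology metric crops,
rotates upright and rescales the boxed object to a 64×64 patch — the box
is canonicalized to width ≥ height and the patch flipped so the object's
center of mass sits in a fixed half-plane, removing the rectangle's
90°/180° pose ambiguity — standardizes intensity, computes a HoG
descriptor (9 orientation bins, 8×8-pixel cells, 2×2-cell blocks), and
projects the descriptor population onto its first principal component.
The PCA sign is fixed by positive correlation with descriptor energy, so
structurally richer objects score higher. K-means (k = 3, Lloyd via
scikit-learn) is initialized with uniform-random coordinates inside the
(morphology, log10 area) bounding box, best inertia over 10 restarts,
deterministic per seed. AUC is the Mann–Whitney rank statistic with
averaged ties.

## Study conditions and problem sizes

The canned experiments in `pixelsr.experiments` fix the desk-scale study
sizes: registration recovery over 50 records of 512 lines at noise 0.02;
equivalent-time-sampling fidelity on noise-free sinusoids at 0.8 of the
fine-grid Nyquist for q = 2..5; SR-vs-alignment on 8 fixed-seed scenes
(one colony plus eight small droplets, randomized poses), scored as the
ratio of mean RMSEs against the ground truth at the system resolution and
as the 99%-energy bandwidth of the scene-fused mean spectrum (fusing
spectra across frames before reading off bandwidth mirrors how multi-frame
Fourier analyses are normally reported; single-scene bandwidths fluctuate
with object pose); classification on a 200-record cohort (45/45/10% mix),
where both the SR and the aligned reconstruction of every record pass
through the identical feature chain and the two-vs-four-daughter AUC is
compared. Each experiment regenerates its inputs from the given seed.

## Known limitations

* The simulator's envelope ripple, noise spectrum and object families are
  engineering choices; real records add shot noise, envelope drift and
  richer morphology, so quantitative margins (RMSE ratios, AUCs) transfer
  only qualitatively.
* Registration assumes negligible laser timing jitter and a stable
  envelope; neither is estimated from data.
* The reference is global per record; slow envelope drift within a record
  would bias the flat-field.
* `baseline_align`'s brightness screen inherits the LR reference (the
  average line), which is all a naive pipeline would have — its higher
  noise floor is part of the comparison, not an artifact.
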