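"""Pixel super-resolution reconstruction and the two conventional baselines.

The passive pixel-SR pipeline turns a warped low-rate line-scan record into a
regular high-resolution image in five stages:

1. **segment** — every sample is placed at its true (x, y) position on the
   sheared sampling lattice using the registered samples-per-line ratio;
2. **reference restoration** — the first lines are interleaved at their
   sub-pixel phases into a fine-pitch 1-D illumination reference
   (equivalent-time sampling by shift-and-add, with a bounded-denominator
   rational approximation of the fractional ratio describing the phase
   cycle);
3. **background suppression** — the repeating illumination background is
   removed by subtracting (or dividing by, for transmittance recovery) the
   reference evaluated at each sample's intra-line position;
4. **resampling** — the scattered samples are fused onto a regular HR grid
   by Gaussian-weighted averaging, with the kernel matched to the optical
   diffraction limit and the electronic bandwidth so excess measurements
   average noise away without discarding resolvable detail;
5. missing pixels (possible when the clocks are near-locked) are in-filled
   by fast-axis linear interpolation.

``baseline_align`` reproduces the conventional dewarp-and-stack restoration
(per-line interpolation, no cross-line fusion) and ``baseline_ets`` the pure
1-D equivalent-time-sampling alternative that trades slow-axis resolution
for fast-axis bandwidth.  Both serve as comparison points for the SR result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .register import DriftEstimate, line_scores, register
from .synth import RawRecord, lowpass_fir
from .warpgeom import WarpGeometry, geometry, min_subpixel_factor


@dataclass
class WarpedPointCloud:
    """Samples at their true positions on the sheared lattice."""

    x: np.ndarray          # μm, intra-line (fast axis)
    y: np.ndarray          # μm, flow (slow axis)
    value: np.ndarray
    geometry: WarpGeometry
    line: np.ndarray | None = None   # line index per point
    line_length: float = 0.0         # μm, spatial span of one line


@dataclass
class ReferenceProfile:
    """Fine-grid 1-D illumination reference (pitch Δx/q)."""

    values: np.ndarray
    fine_pitch: float      # μm
    q: int
    line_length: float     # μm
    n_lines_used: int = 0
    n_phases: int = 0      # distinct sub-pixel phases available
    coverage_ok: bool = True

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.values.size) * self.fine_pitch

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.x, self.values, period=self.line_length)


@dataclass
class HRImage:
    """Regular-grid reconstructed image."""

    grid: np.ndarray       # (ny, nx)
    pitch_x: float         # μm
    pitch_y: float         # μm
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.grid.shape[1]) * self.pitch_x

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.grid.shape[0]) * self.pitch_y


@dataclass
class ReconParams:
    """Tunables of the HR resampling stage.

    q : sub-pixel (interleave) factor; None → smallest q whose equivalent
    rate q·f resolves the analog bandwidth.  hr_pitch : HR pixel pitch (μm,
    both axes; None → Δx/q).  sigma_x/sigma_y : matched-filter widths (μm;
    None → resolution limit FWHM / 2.355).  bg_mode : 'subtract' (default)
    or 'divide' (flat-field, recovers transmittance).  max_den bounds the
    rational approximation of the fractional drift.
    """

    q: int | None = None
    hr_pitch: float | None = None
    sigma_x: float | None = None
    sigma_y: float | None = None
    bg_mode: str = "subtract"
    denoise: bool = True
    max_den: int = 64


# ---------------------------------------------------------------------------
# rational approximation

def rational_approx(alpha: float, max_den: int) -> tuple[int, int]:
    """Best rational p/r ≈ alpha with r ≤ max_den (ties → smallest r).

    Walks the continued-fraction convergents of ``alpha`` and the final
    semiconvergent admitted by the denominator bound, then picks the
    candidate minimizing |alpha − p/r|.
    """
    if max_den < 1:
        raise ValueError("max_den must be ≥ 1")
    a0 = math.floor(alpha)
    x = alpha - a0
    # convergents of the fractional part
    h_prev, k_prev, h, k = 1, 0, 0, 1          # p_{-1}/q_{-1}, p_0/q_0
    candidates = [(0, 1), (1, 1)]
    frac = x
    for _ in range(64):
        if frac <= 0:
            break
        a = math.floor(1.0 / frac)
        frac = 1.0 / frac - a
        h_next, k_next = a * h + h_prev, a * k + k_prev
        if k_next > max_den:
            # best semiconvergent under the bound
            t = (max_den - k_prev) // k
            if t >= 1:
                candidates.append((t * h + h_prev, t * k + k_prev))
            break
        candidates.append((h_next, k_next))
        h_prev, k_prev, h, k = h, k, h_next, k_next
        if frac < 1e-15:
            break
    best = min(candidates, key=lambda pr: (abs(x - pr[0] / pr[1]), pr[1]))
    p, r = best
    g = math.gcd(p, r) or 1
    p, r = p // g, r // g
    return p + a0 * r, r


# ---------------------------------------------------------------------------
# pipeline stages

class InsufficientDataError(ValueError):
    pass


def segment_lines(record: RawRecord, estimate: DriftEstimate) -> WarpedPointCloud:
    """Place every sample at its true (x, y) position; values untouched.

    The intra-line position of global sample k under ratio r is
    (k mod r)·Δx and its line index floor(k/r) — a phase accumulator over
    the non-integer samples-per-line ratio.
    """
    r = estimate.ratio
    if r <= 2:
        raise ValueError("estimated ratio must exceed 2 samples per line")
    geom = geometry(record.config)
    n = record.samples.size
    if n < 2 * r:
        raise InsufficientDataError("record shorter than 2 lines")
    k = np.arange(n, dtype=float)
    m = np.floor(k / r).astype(np.int64)
    x = (k - m * r) * geom.dx
    y = m * geom.dy
    return WarpedPointCloud(x=x, y=y, value=record.samples.copy(), geometry=geom,
                            line=m, line_length=r * geom.dx)


def _fit_profile(phase: np.ndarray, vals: np.ndarray, nf: int,
                 fine_pitch: float, line_len: float,
                 sub_bins: int = 8, robust: bool = False) -> np.ndarray:
    """Periodic profile from scattered (phase, value) samples.

    Samples are aggregated in sub-bins of ``fine_pitch / sub_bins`` — each
    occupied sub-bin contributes (mean phase, aggregated value) — and a
    periodic cubic spline through those points is evaluated on the fine
    grid.  ``robust=True`` aggregates with the per-bin median: specimens
    only *reduce* the detected transmittance and cross any given intra-line
    position on a minority of lines, so the median rides on the clean
    majority and stray object samples cannot drag the illumination
    estimate.  ``robust=False`` uses the plain mean, which is exact for
    noise-free records.
    """
    from scipy.interpolate import CubicSpline

    width = fine_pitch / sub_bins
    nbins = max(int(round(line_len / width)), 1)
    idx = np.minimum((phase / width).astype(np.int64), nbins - 1)
    order = np.lexsort((vals, idx))
    idx_s, phase_s, vals_s = idx[order], phase[order], vals[order]
    cnt = np.bincount(idx_s, minlength=nbins)
    occ = cnt > 0
    sx = np.bincount(idx_s, weights=phase_s, minlength=nbins)
    xm = sx[occ] / cnt[occ]
    if robust:
        ends = np.cumsum(cnt)
        starts = ends - cnt
        lo = starts[occ] + (cnt[occ] - 1) // 2
        hi = starts[occ] + cnt[occ] // 2
        vm = 0.5 * (vals_s[lo] + vals_s[hi])
    else:
        sv = np.bincount(idx_s, weights=vals_s, minlength=nbins)
        vm = sv[occ] / cnt[occ]
    fine_x = np.arange(nf) * fine_pitch
    if xm.size < 4:
        return np.interp(fine_x, xm, vm, period=line_len)
    # strictly increasing abscissae plus periodic closure
    keep = np.concatenate([[True], np.diff(xm) > 1e-12])
    xm, vm = xm[keep], vm[keep]
    xs = np.concatenate([xm, [xm[0] + line_len]])
    vs = np.concatenate([vm, [vm[0]]])
    spline = CubicSpline(xs, vs, bc_type="periodic")
    return spline(np.mod(fine_x - xm[0], line_len) + xm[0])


def restore_reference(record: RawRecord, estimate: DriftEstimate, q: int, *,
                      n_ref_lines: int | None = None,
                      max_den: int = 64, robust: bool = True) -> ReferenceProfile:
    """Interleave line scans into a fine-pitch 1-D illumination reference.

    Samples of the selected lines are folded to their intra-line phase under
    the registered ratio, sorted, and linearly interpolated onto the fine
    grid of pitch Δx/q (period-aware, so the line wraps cleanly).  The
    result is band-limited at the equivalent bandwidth min(q·f/2, B).

    With ``robust=True`` (default) the least object-occupied lines feed the
    reference (all clean lines unless ``n_ref_lines`` caps them), so
    specimens crossing the leading lines do not imprint on the illumination
    estimate; with ``robust=False`` the leading ``n_ref_lines`` are used
    verbatim.

    Interpolation runs through sub-bin averages (8 sub-bins per fine pixel;
    each contributes its mean phase and mean value) joined by a periodic
    cubic spline: averaging suppresses sample noise roughly by the square
    root of the per-bin occupancy while the mean-position abscissa keeps
    the fit unbiased to first order in the within-bin phase spread.

    The fractional ratio's bounded-denominator rational approximation p/r
    describes the sub-pixel phase cycle: lines repeat their phase after r
    lines, so r is the number of distinct phases available.  When r < q the
    fine grid cannot be fully populated from distinct phases
    (``coverage_ok=False``) and interpolation fills the gaps — a locked
    clock degrades to an upsampled single-line profile.
    """
    if q < 1:
        raise ValueError("q must be ≥ 1")
    r = estimate.ratio
    geom = geometry(record.config)
    n_lines = int(record.samples.size // r)
    if n_ref_lines is not None and n_ref_lines > n_lines:
        raise InsufficientDataError(
            f"requested {n_ref_lines} reference lines but record has {n_lines}")

    frac = abs(r - round(r))
    p_num, p_den = rational_approx(frac, max_den)
    n_phases = p_den if p_num != 0 else 1

    n_use = int(math.floor(n_lines * r))
    k = np.arange(n_use, dtype=float)
    m = np.floor(k / r).astype(np.int64)
    if robust:
        from .register import clean_line_mask
        chosen = clean_line_mask(record, r)
        if n_ref_lines is not None:
            scores = line_scores(record, r)
            ranked = np.argsort(-scores, kind="stable")
            chosen = np.zeros(n_lines, dtype=bool)
            chosen[ranked[:n_ref_lines]] = True
        if chosen.sum() < max(8, 2 * q):       # too few clean lines: use all
            chosen[:] = True
        sel = chosen[m]
        n_ref_used = int(chosen.sum())
    else:
        n_ref_used = n_ref_lines if n_ref_lines is not None else n_lines
        sel = m < n_ref_used
    phase = (k[sel] - m[sel] * r) * geom.dx    # μm within the line
    vals = record.samples[:n_use][sel]

    line_len = r * geom.dx
    fine_pitch = geom.dx / q
    nf = int(round(line_len / fine_pitch))

    # the illumination envelope is smooth at the sub-pixel scale, so the
    # robust (median) fit may widen its bins to keep ≥8 samples in each —
    # statistical robustness costs no envelope bandwidth
    sub_bins = int(np.clip(phase.size // (nf * 8), 1, 8)) if robust else 8
    profile = _fit_profile(phase, vals, nf, fine_pitch, line_len,
                           sub_bins=sub_bins, robust=robust)

    cutoff = min(q * record.config.f / 2.0, record.config.B) \
        if record.config.B > 0 else q * record.config.f / 2.0
    equiv_rate = q * record.config.f
    profile = lowpass_fir(profile, cutoff, equiv_rate)

    coverage_ok = n_phases * 1.0 >= q or q == 1
    return ReferenceProfile(values=profile, fine_pitch=fine_pitch, q=q,
                            line_length=line_len, n_lines_used=n_ref_used,
                            n_phases=n_phases, coverage_ok=bool(coverage_ok))


def suppress_background(cloud: WarpedPointCloud, reference: ReferenceProfile,
                        mode: str = "subtract") -> WarpedPointCloud:
    """Remove the repeating illumination background from a point cloud.

    'subtract' leaves residuals around zero; 'divide' flat-fields the values
    into transmittance units (requires a strictly positive reference).
    """
    ref_at = reference(cloud.x)
    if mode == "subtract":
        out = cloud.value - ref_at
    elif mode == "divide":
        eps = 1e-6 * float(np.abs(reference.values).max())
        if np.any(ref_at <= eps):
            raise ValueError("reference too close to zero for flat-field division")
        out = cloud.value / ref_at
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return WarpedPointCloud(x=cloud.x, y=cloud.y, value=out,
                            geometry=cloud.geometry, line=cloud.line,
                            line_length=cloud.line_length)


def matched_filter_sigmas(config) -> tuple[float, float]:
    """Gaussian matched-filter widths (σx, σy) in μm.

    FWHM along the fast axis is the coarser of the diffraction limit and the
    bandwidth-limited spot C_x/(C_t·2B); along the slow axis the diffraction
    limit.  σ = FWHM / 2.355.
    """
    bw_limit = config.C_x / (config.C_t * 1e-9 * 2.0 * config.B) if config.B > 0 else 0.0
    fwhm_x = max(config.d_opt, bw_limit)
    fwhm_y = config.d_opt
    return fwhm_x / 2.355, fwhm_y / 2.355


def resample_hr(cloud: WarpedPointCloud, params: ReconParams,
                config=None) -> HRImage:
    """Fuse scattered samples onto a regular HR grid by Gaussian averaging.

    Each HR pixel is the Gaussian-weighted mean of nearby cloud points
    (numerator and weight images are accumulated on the grid and smoothed
    with the matched kernel; their ratio is an exactly normalized weighted
    average, bounded by the input value range).  Zero-weight pixels are
    marked missing and in-filled by linear interpolation along the fast
    axis.
    """
    if cloud.value.size == 0:
        raise ValueError("empty point cloud")
    geom = cloud.geometry
    q = params.q if params.q is not None else 1
    px = params.hr_pitch if params.hr_pitch is not None else geom.dx / max(q, 1)
    py = px
    if config is not None:
        sx_def, sy_def = matched_filter_sigmas(config)
    else:
        sx_def, sy_def = geom.dx / 2.355, geom.dx / 2.355
    sx = params.sigma_x if params.sigma_x is not None else sx_def
    sy = params.sigma_y if params.sigma_y is not None else sy_def
    if not params.denoise:
        sx = sy = 0.0
    # σ never below half a pixel: the kernel must bridge the deposit grid
    sx = max(sx, 0.5 * px)
    sy = max(sy, 0.5 * py)

    x0 = 0.0
    y0 = float(cloud.y.min())
    nx = int(math.ceil((cloud.line_length if cloud.line_length > 0
                        else cloud.x.max() + px) / px))
    ny = int(math.floor((cloud.y.max() - y0) / py)) + 1
    # cloud-in-cell deposit: bilinear weights onto the four surrounding
    # pixels preserve each sample's sub-pixel position to first order
    gx = np.clip((cloud.x - x0) / px, 0, nx - 1.000001)
    gy = np.clip((cloud.y - y0) / py, 0, ny - 1.000001)
    c0 = gx.astype(np.int64)
    r0 = gy.astype(np.int64)
    fx = gx - c0
    fy = gy - r0
    num = np.zeros(ny * nx)
    cnt = np.zeros(ny * nx)
    for dr, dc, w in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                      (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        flat = np.minimum(r0 + dr, ny - 1) * nx + np.minimum(c0 + dc, nx - 1)
        num += np.bincount(flat, weights=w * cloud.value, minlength=ny * nx)
        cnt += np.bincount(flat, weights=w, minlength=ny * nx)
    num = num.reshape(ny, nx)
    cnt = cnt.reshape(ny, nx)
    num = ndimage.gaussian_filter(num, (sy / py, sx / px), mode="nearest")
    cnt = ndimage.gaussian_filter(cnt, (sy / py, sx / px), mode="nearest")

    filled = cnt > 1e-8
    grid = np.zeros((ny, nx))
    grid[filled] = num[filled] / cnt[filled]
    if not filled.all():
        cols = np.arange(nx, dtype=float)
        for i in range(ny):
            good = filled[i]
            if good.any() and not good.all():
                grid[i, ~good] = np.interp(cols[~good], cols[good], grid[i, good])
        # rows with no support at all: copy nearest filled row
        rowfill = filled.any(axis=1)
        if rowfill.any() and not rowfill.all():
            idx = np.where(rowfill)[0]
            for i in np.where(~rowfill)[0]:
                grid[i] = grid[idx[np.argmin(np.abs(idx - i))]]
    return HRImage(grid=grid, pitch_x=px, pitch_y=py, origin=(x0, y0),
                   provenance={"sigma_x_um": sx, "sigma_y_um": sy,
                               "missing_pixels": int((~filled).sum())})


def pixel_sr(record: RawRecord, params: ReconParams | None = None, *,
             estimate: DriftEstimate | None = None) -> HRImage:
    """End-to-end passive pixel super-resolution reconstruction.

    register → segment → restore reference → suppress background →
    resample to the regular HR grid.  Full provenance (drift estimate, q,
    filter widths, background mode) rides on the returned image.
    """
    params = params or ReconParams()
    cfg = record.config
    if estimate is None:
        estimate = register(record)
    q = params.q if params.q is not None else (
        min_subpixel_factor(cfg.f, cfg.B) if cfg.B > 0 else 4)
    pr = ReconParams(**{**params.__dict__, "q": q})
    cloud = segment_lines(record, estimate)
    ref = restore_reference(record, estimate, q, max_den=params.max_den)
    cloud = suppress_background(cloud, ref, mode=params.bg_mode)
    img = resample_hr(cloud, pr, cfg)
    img.provenance.update({"method": "pixel_sr", "q": q,
                           "bg_mode": params.bg_mode,
                           "estimate": estimate.to_dict(),
                           "reference_phases": ref.n_phases,
                           "reference_coverage_ok": ref.coverage_ok})
    return img


def baseline_align(record: RawRecord, estimate: DriftEstimate | None = None,
                   params: ReconParams | None = None) -> HRImage:
    """Conventional dewarp-and-stack restoration (no cross-line fusion).

    Each line is independently interpolated onto the HR fast-axis grid at
    its registered offset, then lines are stacked one row per line
    (slow-axis pitch Δy).  Sub-pixel information shared between neighboring
    lines is deliberately ignored — this is the aliasing-prone baseline.
    """
    params = params or ReconParams()
    cfg = record.config
    if estimate is None:
        estimate = register(record)
    geom = geometry(cfg)
    r = estimate.ratio
    q = params.q if params.q is not None else (
        min_subpixel_factor(cfg.f, cfg.B) if cfg.B > 0 else 4)
    px = params.hr_pitch if params.hr_pitch is not None else geom.dx / max(q, 1)
    n_lines = int(record.samples.size // r)
    line_len = r * geom.dx
    xg = np.arange(int(math.ceil(line_len / px))) * px

    # LR background: the average line, upsampled — all a naive pipeline has
    ref = restore_reference(record, estimate, 1, max_den=params.max_den)
    ref_g = ref(xg)

    rows = np.empty((n_lines, xg.size))
    k = np.arange(record.samples.size, dtype=float)
    m = np.floor(k / r).astype(np.int64)
    phase = (k - m * r) * geom.dx
    for i in range(n_lines):
        sel = m == i
        rows[i] = np.interp(xg, phase[sel], record.samples[sel],
                            period=line_len)
    if params.bg_mode == "subtract":
        rows = rows - ref_g[None, :]
    elif params.bg_mode == "divide":
        rows = rows / ref_g[None, :]
    img = HRImage(grid=rows, pitch_x=px, pitch_y=geom.dy, origin=(0.0, 0.0),
                  provenance={"method": "baseline_align",
                              "bg_mode": params.bg_mode,
                              "estimate": estimate.to_dict()})
    return img


def baseline_ets(record: RawRecord, estimate: DriftEstimate | None = None,
                 q: int = 4, params: ReconParams | None = None) -> HRImage:
    """1-D equivalent-time sampling: fuse groups of q lines into one HR row.

    Restores the fast-axis bandwidth q-fold but collapses every q lines to a
    single row, so slow-axis resolution drops q-fold — the classic trade-off
    this baseline demonstrates.
    """
    if q < 2:
        raise ValueError("baseline_ets needs q ≥ 2")
    params = params or ReconParams()
    cfg = record.config
    if estimate is None:
        estimate = register(record)
    geom = geometry(cfg)
    r = estimate.ratio
    n_lines = int(record.samples.size // r)
    n_rows = n_lines // q
    if n_rows < 1:
        raise InsufficientDataError("record shorter than one group of q lines")
    line_len = r * geom.dx
    fine_pitch = geom.dx / q
    nf = int(round(line_len / fine_pitch))
    ref = restore_reference(record, estimate, q, max_den=params.max_den)

    k = np.arange(record.samples.size, dtype=float)
    m = np.floor(k / r).astype(np.int64)
    phase = (k - m * r) * geom.dx
    rows = np.empty((n_rows, nf))
    xg = np.arange(nf) * fine_pitch
    for g in range(n_rows):
        sel = (m >= g * q) & (m < (g + 1) * q)
        xs = phase[sel]
        vs = record.samples[sel]
        order = np.argsort(xs, kind="stable")
        rows[g] = np.interp(xg, xs[order], vs[order], period=line_len)
    if params.bg_mode == "subtract":
        rows = rows - ref.values[None, :nf]
    elif params.bg_mode == "divide":
        rows = rows / ref.values[None, :nf]
    return HRImage(grid=rows, pitch_x=fine_pitch, pitch_y=q * geom.dy,
                   origin=(0.0, 0.0),
                   provenance={"method": "baseline_ets", "q": q,
                               "bg_mode": params.bg_mode,
                               "estimate": estimate.to_dict()})


# ---------------------------------------------------------------------------
# evaluation helpers against simulator ground truth

def truth_on_grid(record: RawRecord, image: HRImage) -> np.ndarray:
    """Ground-truth blurred transmittance evaluated on an image's grid."""
    gt = record.ground_truth
    if gt is None or gt.hr_image is None:
        raise ValueError("record carries no scene ground truth")
    ys = (image.y[:, None] / gt.hr_pitch - 0.5) * np.ones((1, image.x.size))
    xs = ((image.x[None, :] - gt.x_offset) / gt.hr_pitch - 0.5) * np.ones((image.y.size, 1))
    bg = gt.scene.background if gt.scene is not None else 1.0
    out = ndimage.map_coordinates(gt.hr_image, [ys, xs], order=1,
                                  mode="constant", cval=bg)
    outside = (xs < -0.5) | (xs > gt.hr_image.shape[1] - 0.5)
    out[outside] = bg
    return out


def rmse_vs_truth(record: RawRecord, image: HRImage,
                  field_only: bool = True,
                  target_sigmas: tuple[float, float] | None = None) -> float:
    """RMSE of a (transmittance-mode) reconstruction against ground truth.

    ``target_sigmas`` (σx, σy, μm) optionally blurs the ground truth to the
    system resolution (e.g. the matched-filter widths), so both the SR
    result and a baseline are scored against the best image the physical
    chain could deliver rather than the un-filtered scene.
    """
    gt = record.ground_truth
    truth = truth_on_grid(record, image)
    if target_sigmas is not None:
        truth = ndimage.gaussian_filter(
            truth, (target_sigmas[1] / image.pitch_y,
                    target_sigmas[0] / image.pitch_x), mode="nearest")
    mask = np.ones_like(truth, dtype=bool)
    if field_only and gt.scene is not None:
        mask &= (image.x[None, :] >= gt.x_offset) \
            & (image.x[None, :] <= gt.x_offset + gt.scene.width)
        mask &= (image.y[:, None] >= 0) & (image.y[:, None] <= gt.scene.height)
    diff = image.grid[mask] - truth[mask]
    return float(np.sqrt(np.mean(diff ** 2)))


def fast_axis_bandwidth(image: HRImage, energy: float = 0.99,
                        x_range: tuple[float, float] | None = None) -> float:
    """Spatial frequency (1/μm) containing ``energy`` of the fast-axis power.

    Row means are removed and a Hann window applied before the per-row power
    spectra are averaged; the cumulative-energy quantile of the averaged
    spectrum is returned.
    """
    g = image.grid
    if x_range is not None:
        sel = (image.x >= x_range[0]) & (image.x <= x_range[1])
        g = g[:, sel]
    g = g - g.mean(axis=1, keepdims=True)
    w = np.hanning(g.shape[1])
    nfft = 4 * g.shape[1]          # zero-pad: finer frequency sampling
    spec = np.abs(np.fft.rfft(g * w[None, :], n=nfft, axis=1)) ** 2
    pw = spec.mean(axis=0)
    freqs = np.fft.rfftfreq(nfft, d=image.pitch_x)
    cum = np.cumsum(pw)
    if cum[-1] <= 0:
        return 0.0
    cum /= cum[-1]
    idx = int(np.searchsorted(cum, energy))
    return float(freqs[min(idx, freqs.size - 1)])
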