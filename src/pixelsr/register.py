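"""Estimate the true samples-per-line ratio from the waveform itself.

The repeating illumination background (the laser spectrum mapped along every
line) acts as a built-in registration target.  Registration runs in two
stages:

* **coarse** — a template from the start of the record is located near the
  end by normalized cross-correlation; the peak lag (parabolically
  interpolated to sub-sample precision) divided by the line separation
  gives f/F to a small fraction of a sample per line — tight enough to
  bracket the refinement.
* **refine** — bracketed scalar maximization of the sharpness (total
  squared spatial gradient) of the equivalent-time-sampling reference built
  with the candidate ratio.  The reference's Fourier coefficients are the
  record's spectrum sampled at harmonics of the line rate, so the sharpness
  is evaluated in the Fourier domain as Σ h²·|X(h/r)|² over the significant
  harmonics: phase-coherent over the whole record, smooth in r, and maximal
  when the sub-pixel offsets are registered exactly.  A wrong ratio
  phase-mixes the interleaved samples and destroys the coherent sum.

Both stages are invariant to global gain and offset of the waveform (the
mean is removed; h = 0 is never used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .synth import RawRecord
from .warpgeom import geometry


class IllConditionedRegistrationError(RuntimeError):
    """The illumination background carries no usable structure."""


@dataclass
class DriftEstimate:
    """Registered sampling-lattice parameters for one record.

    ratio : estimated samples per line (f/F); delta_x_hat : implied per-line
    drift (μm, signed); theta_hat : implied warp angle (rad);
    objective_value : final refinement score; n_lines_used : lines entering
    the estimate; status : 'ok' or 'coarse-only' when refinement could not
    improve on the coarse estimate.
    """

    ratio: float
    delta_x_hat: float
    theta_hat: float
    objective_value: float = float("nan")
    n_lines_used: int = 0
    n_iterations: int = 0
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio, "delta_x_hat_um": self.delta_x_hat,
            "theta_hat_rad": self.theta_hat, "objective_value": self.objective_value,
            "n_lines_used": self.n_lines_used, "n_iterations": self.n_iterations,
            "status": self.status,
        }


def _estimate_from_ratio(record: RawRecord, ratio: float, **extra) -> DriftEstimate:
    geom = geometry(record.config)
    n = math.floor(ratio + 0.5)
    delta_x = (ratio - n) * geom.dx
    theta = math.atan2(delta_x, geom.dy) if geom.dy > 0 else 0.0
    return DriftEstimate(ratio=ratio, delta_x_hat=delta_x, theta_hat=theta, **extra)


def line_scores(record: RawRecord, ratio: float) -> np.ndarray:
    """Per-line cleanliness score (noise-normalized depth of the deepest dips).

    Each sample's deviation below the binned background proxy (per-phase-bin
    mean over all lines) is expressed in units of the record's noise s.d.
    (estimated from first differences); a line's score is the mean of its
    four lowest z-values.  Object-free lines sit around −3 regardless of
    where the illumination envelope is weak, while lines a specimen crosses
    drop far lower.  A specimen a few μm across covers only a handful of LR
    samples per line, hence the extreme-tail statistic.
    """
    x = record.samples
    n_lines = int(x.size // ratio)
    n_use = int(math.floor(n_lines * ratio))
    k = np.arange(n_use, dtype=float)
    m = np.floor(k / ratio).astype(np.int64)
    phase = k - m * ratio
    nbins = int(round(ratio))
    idx = np.minimum(phase.astype(np.int64), nbins - 1)
    ssum = np.bincount(idx, weights=x[:n_use], minlength=nbins)
    cnt = np.maximum(np.bincount(idx, minlength=nbins), 1)
    proxy = ssum / cnt
    sigma = 1.4826 * float(np.median(np.abs(np.diff(x)))) / math.sqrt(2.0)
    sigma = max(sigma, 1e-12 * float(np.abs(proxy).max()), 1e-300)
    z = (x[:n_use] - proxy[idx]) / sigma
    scores = np.full(n_lines, -np.inf)
    for i in range(n_lines):
        li = z[m == i]
        if li.size:
            low = np.partition(li, min(3, li.size - 1))[:4]
            scores[i] = float(low.mean())
    return scores


def clean_line_mask(record: RawRecord, ratio: float) -> np.ndarray:
    """Boolean mask of lines judged object-free.

    The threshold hangs off the cleanest third of the lines (objects may
    occupy most of a busy record, so a global median would be contaminated):
    lines scoring more than a few cluster-MADs below that cluster are
    flagged as object-crossed.
    """
    scores = line_scores(record, ratio)
    top = np.sort(scores)[-max(scores.size // 3, 2):]
    med_top = float(np.median(top))
    mad_top = float(np.median(np.abs(top - med_top)))
    mask = scores > med_top - max(6.0 * mad_top, 2.0)
    if not mask.any():
        mask[:] = True
    return mask


def _parabolic_peak(c: np.ndarray, i: int) -> float:
    """Sub-sample peak position: parabola through c[i-1:i+2]."""
    if i <= 0 or i >= c.size - 1:
        return float(i)
    denom = c[i - 1] - 2 * c[i] + c[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (c[i - 1] - c[i + 1]) / denom


def _first_clean_run(clean: np.ndarray, length: int, from_end: bool = False) -> int:
    """Start of the first (or last) run of ``length`` consecutive clean lines."""
    n = clean.size
    idxs = range(n - length, -1, -1) if from_end else range(0, n - length + 1)
    for i in idxs:
        if clean[i:i + length].all():
            return i
    return n - length if from_end else 0


def coarse_ratio(record: RawRecord, template_lines: int = 2) -> DriftEstimate:
    """Coarse f/F estimate from background cross-correlation across the record.

    The template and match segments are taken from object-free lines (the
    earliest and latest clean runs) so a specimen crossing the record's ends
    does not disturb the correlation.
    """
    cfg = record.config
    r0 = cfg.ratio
    x = record.samples.astype(float)
    n_lines = int(x.size // r0)
    if n_lines < 4:
        raise ValueError("coarse_ratio needs at least 4 lines")

    clean = clean_line_mask(record, r0)
    m_t = _first_clean_run(clean, template_lines + 1)
    m_s = _first_clean_run(clean, template_lines + 1, from_end=True)
    if m_s - m_t < 2:
        m_t, m_s = 0, n_lines - template_lines - 1

    w = int(round(template_lines * r0))
    k_t = int(math.ceil(m_t * r0))
    template = x[k_t:k_t + w] - x[k_t:k_t + w].mean()
    tnorm = float(np.linalg.norm(template))
    # a flat background (no envelope structure) cannot be registered: the
    # smooth part of the template must rise above the unsmoothed residual
    smooth = np.convolve(x[k_t:k_t + w], np.ones(25) / 25, mode="same")
    sm_std = float(np.std(smooth))
    res_std = float(np.std(x[k_t:k_t + w] - smooth))
    if tnorm == 0 or sm_std < res_std:
        raise IllConditionedRegistrationError(
            "illumination background is flat; drift registration is ill-posed "
            "(no envelope structure to correlate on)")

    m = m_s - m_t                              # line separation of the match
    center = k_t + m * r0
    half = int(round(r0 * 0.45))               # stay away from the ±1-line alias
    lo = max(0, int(round(center)) - half)
    hi = min(x.size - w, int(round(center)) + half)
    if hi <= lo:
        raise ValueError("record too short for the requested template")
    lags = np.arange(lo, hi)
    corr = np.empty(lags.size)
    for j, lag in enumerate(lags):
        seg = x[lag:lag + w]
        seg = seg - seg.mean()
        denom = float(np.linalg.norm(seg)) * tnorm
        corr[j] = float(template @ seg) / denom if denom > 0 else 0.0
    ipk = int(np.argmax(corr))
    lag_star = lo + _parabolic_peak(corr, ipk)
    return _estimate_from_ratio(record, (lag_star - k_t) / m,
                                n_lines_used=m + template_lines)


def _select_harmonics(x: np.ndarray, r0: float, h_max: int = 40,
                      keep: int = 24, snr_factor: float = 5.0) -> list[int]:
    """Line-rate harmonics carrying significant background power at ratio r0."""
    n = x.size
    k = np.arange(n, dtype=float)
    base = np.exp(-2j * np.pi * k / r0)
    z = np.ones(n, dtype=complex)
    h_max = min(h_max, int(r0 // 2))
    powers = np.empty(h_max)
    for h in range(1, h_max + 1):
        z = z * base
        powers[h - 1] = abs(z @ x) ** 2
    floor = np.median(powers)
    order = np.argsort(powers)[::-1][:keep]
    sel = sorted(int(i) + 1 for i in order if powers[i] > snr_factor * floor)
    return sel or [int(np.argmax(powers)) + 1]


def _harmonic_sharpness(x: np.ndarray, ratio: float, harmonics: list[int]) -> float:
    """Σ h²·|X(h/r)|² — gradient energy of the interleaved reference."""
    n = x.size
    k = np.arange(n, dtype=float)
    base = np.exp(-2j * np.pi * k / ratio)
    z = np.ones(n, dtype=complex)
    total = 0.0
    h_prev = 0
    for h in harmonics:
        z = z * base ** (h - h_prev)
        h_prev = h
        total += h * h * abs(z @ x) ** 2
    return total


def _fold_residual(x: np.ndarray, ratio: float) -> float:
    """Leave-half-out misfit: even lines predict odd lines at the candidate ratio."""
    k = np.arange(x.size, dtype=float)
    m = np.floor(k / ratio).astype(np.int64)
    phase = k - m * ratio
    even = (m % 2) == 0
    order = np.argsort(phase[even], kind="stable")
    pred = np.interp(phase[~even], phase[even][order], x[even][order],
                     period=ratio)
    d = x[~even] - pred
    return float(d @ d / max(d.size, 1))


def refine_ratio(record: RawRecord, initial: float | DriftEstimate | None = None,
                 *, method: str = "sharpness", bracket: float = 2e-3,
                 xtol: float = 1e-6) -> DriftEstimate:
    """Refine the samples-per-line ratio by bracketed 1-D optimization.

    ``initial`` may be a value, a coarse DriftEstimate, or None (coarse
    registration runs first) and must be within the ``bracket`` (samples per
    line) of the truth.  ``method``: 'sharpness' (Fourier-domain gradient
    energy of the interleaved reference, default) or 'residual'
    (leave-half-out misfit between even- and odd-line dewarps, minimized at
    the true ratio).  Terminates at ``xtol`` samples/line.
    """
    if initial is None:
        initial = coarse_ratio(record)
    if isinstance(initial, DriftEstimate):
        initial = initial.ratio
    n_lines = int(record.samples.size // initial)
    # zero-weight object-crossed lines: their content is not periodic with
    # the line rate and would drag the objective off the background's peak.
    # The first and last lines carry the electronic filter's edge transient
    # and are always excluded.
    clean = clean_line_mask(record, initial)
    k = np.arange(record.samples.size)
    line_of = np.minimum((k / initial).astype(np.int64), n_lines - 1)
    keep = clean[line_of] & (line_of > 0) & (line_of < n_lines - 1)
    x = record.samples - record.samples[keep].mean()
    x[~keep] = 0.0
    neval = 0

    if method == "sharpness":
        harmonics = _select_harmonics(x, initial)

        def objective(r: float) -> float:
            nonlocal neval
            neval += 1
            return -_harmonic_sharpness(x, r, harmonics)
    elif method == "residual":
        def objective(r: float) -> float:
            nonlocal neval
            neval += 1
            return _fold_residual(x, r)
    else:
        raise ValueError(f"unknown refinement method {method!r}")

    lo, hi = initial - bracket, initial + bracket
    try:
        res = optimize.minimize_scalar(objective, bounds=(lo, hi),
                                       method="bounded",
                                       options={"xatol": xtol / 10})
    except (ValueError, RuntimeError):
        return _estimate_from_ratio(record, initial, n_lines_used=n_lines,
                                    status="coarse-only")
    if objective(initial) < res.fun:
        est = _estimate_from_ratio(record, initial, n_lines_used=n_lines,
                                   n_iterations=neval, status="coarse-only")
        est.objective_value = -objective(initial)
        return est
    est = _estimate_from_ratio(record, float(res.x), n_lines_used=n_lines,
                               n_iterations=neval)
    est.objective_value = -float(res.fun)
    return est


def register(record: RawRecord, *, method: str = "sharpness") -> DriftEstimate:
    """Full registration: coarse cross-correlation then sub-sample refinement."""
    coarse = coarse_ratio(record)
    return refine_ratio(record, coarse, method=method)
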