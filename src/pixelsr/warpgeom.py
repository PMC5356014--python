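"""Geometry of the asynchronously sampled time-stretch line-scan lattice.

A time-stretch line-scan camera reads one spatial line per laser pulse as a
temporal waveform: a diffraction grating maps wavelength to transverse
position (``C_x``, μm/nm) and group-velocity dispersion maps wavelength to
arrival time (``C_t``, ns/nm), so a digitizer sampling at rate ``f`` slices
the line into pixels of pitch ``Δx = C_x / (C_t f)`` along the fast axis,
while the specimen flows past at ``v_y`` giving a slow-axis pitch
``Δy = v_y / F`` per pulse (repetition rate ``F``).

Because the digitizer clock is free-running with respect to the laser, the
number of samples per line ``f/F`` is not an integer.  Each successive line's
sample grid is laterally offset by the signed sub-pixel drift

    δx = (f/F − N) Δx,   N = round(f/F),   |δx| ≤ Δx/2,

which shears the effective sampling lattice by the warp angle
``tan θ = δx / Δy``.  Interpolating along the sheared axes trades the pixel
dimensions to ``Δu = Δx cos θ`` and ``Δv = Δy / cos θ`` at constant pixel
area, so the fast-axis pixel pitch improves by ``gain = 1/cos θ`` — the
resolution-enhancement factor the passive pixel super-resolution scheme
exploits.

All lengths are μm, rates are Hz, angles radians.  ``AcquisitionConfig``
stores the instrument's natural units (``C_t`` in ns/nm, ``v_y`` in m/s) and
conversions happen once inside the derived quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


class InvalidConfigError(ValueError):
    """An acquisition parameter is outside its physical domain."""


class DegenerateGeometryError(ValueError):
    """The sampling lattice is degenerate (no slow-axis motion or |θ| ≥ π/2)."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Physical and electronic parameters of one time-stretch acquisition.

    Parameters
    ----------
    f : float
        Digitizer sampling rate, samples/s.
    F : float
        Laser pulse repetition rate (= line-scan rate), Hz.
    C_x : float
        Wavelength-to-space conversion factor of the spectral encoder, μm/nm.
    C_t : float
        Wavelength-to-time conversion factor of the dispersive stretch, ns/nm.
    v_y : float
        Linear flow speed of the specimen, m/s.
    B : float
        Electronic analog bandwidth of the detection chain, Hz.
    d_opt : float
        Diffraction-limited optical resolution, μm.
    n_lines : int
        Number of line scans in the record.
    """

    f: float
    F: float
    C_x: float
    C_t: float
    v_y: float = 0.0
    B: float = 0.0
    d_opt: float = 0.0
    n_lines: int = 0

    def __post_init__(self) -> None:
        if not (self.f > 0 and self.F > 0):
            raise InvalidConfigError("sampling rate f and pulse rate F must be positive")
        if self.f / self.F <= 2:
            raise InvalidConfigError(
                f"f/F = {self.f / self.F:.3g} but at least two samples per line are required"
            )
        for name in ("C_x", "C_t", "v_y", "B", "d_opt"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if self.n_lines < 0:
            raise InvalidConfigError("n_lines must be nonnegative")

    @property
    def ratio(self) -> float:
        """Nominal samples per line, f/F (dimensionless, non-integer in general)."""
        return self.f / self.F

    def to_dict(self) -> dict:
        return asdict(self)

    # sidecar keys mirror the documented config-file schema
    _KEYMAP = {
        "f_hz": "f", "F_hz": "F", "Cx_um_per_nm": "C_x", "Ct_ns_per_nm": "C_t",
        "v_m_per_s": "v_y", "bandwidth_hz": "B", "d_opt_um": "d_opt", "n_lines": "n_lines",
    }

    def to_sidecar(self) -> dict:
        return {k: getattr(self, v) for k, v in self._KEYMAP.items()}

    @classmethod
    def from_sidecar(cls, d: dict) -> "AcquisitionConfig":
        missing = [k for k in ("f_hz", "F_hz", "Cx_um_per_nm", "Ct_ns_per_nm") if k not in d]
        if missing:
            raise InvalidConfigError(f"config sidecar missing required key(s): {', '.join(missing)}")
        kwargs = {attr: d[key] for key, attr in cls._KEYMAP.items() if key in d}
        kwargs["n_lines"] = int(kwargs.get("n_lines", 0))
        return cls(**kwargs)


def pitch_fast(config: AcquisitionConfig) -> float:
    """Fast-axis (spectral-encoding) pixel pitch Δx = C_x / (C_t f), in μm.

    ``C_t`` is stored in ns/nm; one sample period 1/f (s) spans
    1/(C_t f) nm of spectrum, hence C_x/(C_t f) μm of specimen.
    """
    if not (config.C_x > 0 and config.C_t > 0):
        raise InvalidConfigError("pitch_fast requires positive C_x and C_t")
    return config.C_x / (config.C_t * 1e-9 * config.f)


def pitch_slow(config: AcquisitionConfig) -> float:
    """Slow-axis (flow) pixel pitch Δy = v_y / F, in μm."""
    return config.v_y / config.F * 1e6


def pixel_drift(config: AcquisitionConfig) -> tuple[float, int]:
    """Per-line sub-pixel drift (δx in μm, N samples per line).

    N is f/F rounded to the nearest integer; exact half-integers round away
    from zero so the bound |δx| ≤ Δx/2 is attained with δx = −Δx/2.
    """
    r = config.ratio
    n = math.floor(r + 0.5) if r >= 0 else math.ceil(r - 0.5)
    return (r - n) * pitch_fast(config), n


def aspect_ratio(geom: "WarpGeometry") -> float:
    """LR pixel aspect ratio ρ = Δy/Δx (order 1e-2 in typical configurations)."""
    if geom.dx <= 0:
        raise InvalidConfigError("aspect_ratio requires dx > 0")
    return geom.dy / geom.dx


def warp_angle(geom: "WarpGeometry") -> float:
    """Signed lattice shear angle θ = atan(δx/Δy), radians."""
    if geom.dy == 0:
        raise DegenerateGeometryError("warp angle undefined without slow-axis motion (dy = 0)")
    return math.atan(geom.delta_x / geom.dy)


def interp_pitches(geom: "WarpGeometry") -> tuple[float, float, float]:
    """Interpolated pixel pitches along the warped axes and the resolution gain.

    Returns (Δu, Δv, gain) with Δu = Δx cos θ, Δv = Δy / cos θ and
    gain = Δx/Δu = (cos θ)⁻¹.  Pixel area is invariant: Δu Δv = Δx Δy.
    """
    if not abs(geom.theta) < math.pi / 2:
        raise DegenerateGeometryError("|theta| must be < π/2")
    c = math.cos(geom.theta)
    return geom.dx * c, geom.dy / c, 1.0 / c


def min_subpixel_factor(f: float, B_signal: float) -> int:
    """Smallest sub-pixel count q whose equivalent rate q·f resolves B_signal.

    q·f/2 ≥ B_signal, i.e. q = ceil(2 B_signal / f); never below 1.
    """
    if not (f > 0 and B_signal > 0):
        raise InvalidConfigError("min_subpixel_factor requires positive f and B_signal")
    return max(1, math.ceil(2.0 * B_signal / f - 1e-12))


@dataclass(frozen=True)
class WarpGeometry:
    """Derived sampling-lattice quantities for one acquisition.

    dx, dy : LR pixel pitches (μm); N : nearest-integer samples per line;
    delta_x : signed per-line drift (μm); theta : warp angle (rad);
    rho : pixel aspect ratio; du, dv : interpolated pitches (μm);
    gain : fast-axis pixel-resolution enhancement (cos θ)⁻¹ ≥ 1.
    """

    dx: float
    dy: float
    N: int
    delta_x: float
    theta: float = field(default=0.0)
    rho: float = field(default=0.0)
    du: float = field(default=0.0)
    dv: float = field(default=0.0)
    gain: float = field(default=1.0)

    def report(self) -> str:
        """Plain-text geometry report (6 significant digits)."""
        rows = [
            ("fast-axis pitch dx", self.dx, "um"),
            ("slow-axis pitch dy", self.dy, "um"),
            ("samples per line N", self.N, ""),
            ("pixel drift dx_drift", self.delta_x, "um"),
            ("warp angle theta", self.theta, "rad"),
            ("tan(theta)", math.tan(self.theta), ""),
            ("aspect ratio rho", self.rho, ""),
            ("interp pitch du", self.du, "um"),
            ("interp pitch dv", self.dv, "um"),
            ("resolution gain", self.gain, ""),
        ]
        width = max(len(r[0]) for r in rows)
        lines = []
        for name, val, unit in rows:
            sval = f"{val:d}" if isinstance(val, int) else f"{val:.6g}"
            lines.append(f"{name:<{width}}  {sval} {unit}".rstrip())
        return "\n".join(lines)


def geometry(config: AcquisitionConfig) -> WarpGeometry:
    """Full derived lattice geometry for one acquisition config."""
    dx = pitch_fast(config)
    dy = pitch_slow(config)
    delta_x, n = pixel_drift(config)
    base = WarpGeometry(dx=dx, dy=dy, N=n, delta_x=delta_x)
    theta = warp_angle(base) if dy > 0 else 0.0
    rho = aspect_ratio(base)
    du, dv, gain = interp_pitches(
        WarpGeometry(dx=dx, dy=dy, N=n, delta_x=delta_x, theta=theta)
    )
    return WarpGeometry(dx=dx, dy=dy, N=n, delta_x=delta_x, theta=theta,
                        rho=rho, du=du, dv=dv, gain=gain)


def sample_position(k: int, config: AcquisitionConfig,
                    geom: WarpGeometry | None = None) -> tuple[float, float, int]:
    """Map a global sample index to its (x, y) position and line index.

    Line index m = floor(k·F/f); intra-line position x = (k − m·f/F)·Δx so the
    fractional part of m·f/F carries the accumulated sub-pixel drift.  y = m·Δy.
    """
    if k < 0:
        raise ValueError("sample index must be nonnegative")
    if geom is None:
        geom = geometry(config)
    r = config.ratio
    m = math.floor(k / r)
    # guard against float-edge misassignment at exact line boundaries
    if k < m * r:
        m -= 1
    elif k >= (m + 1) * r:
        m += 1
    x = (k - m * r) * geom.dx
    return x, m * geom.dy, m
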