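"""Ground-truthed synthetic time-stretch waveforms.

The forward model emulates the optical/electronic chain of a bright-field
time-stretch line-scan flow imager:

1. a transmittance scene (objects moving at constant flow speed) is rendered
   on a fine raster and blurred by a Gaussian PSF at the diffraction limit;
2. every laser pulse carries the *same* spectral envelope (the mode-locked
   laser's shot-to-shot spectral stability is the premise of the passive
   registration scheme), mapped to a 1-D illumination profile along the line;
3. the detector voltage is envelope × transmittance, low-passed at the
   electronic analog bandwidth;
4. a free-running digitizer samples the stream at rate ``f`` unlocked from
   the pulse rate ``F``, so the number of samples per line ``f/F`` is not an
   integer and successive lines are sub-pixel shifted;
5. additive Gaussian noise models detector/amplifier noise (no shot noise,
   no timing jitter).

Because the analog bandwidth typically exceeds the digitizer Nyquist rate
(10 GHz vs 2.5 GHz at the reference condition), the model is evaluated on an
internally oversampled stream, filtered there, and then decimated by plain
subsampling — this is what makes the low-rate record alias and the
super-resolution reconstruction meaningful.

All randomness flows from one integer seed through ``numpy.random.SeedSequence``
spawning (scene, envelope, noise each get their own child stream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

from .warpgeom import AcquisitionConfig, WarpGeometry, geometry

#: Reference acquisition condition: 5 GSa/s digitizer against an 11.6142 MHz
#: mode-locked laser, C_x = 7.1 μm/nm, C_t = 400 ps/nm, flow chosen so the
#: slow-axis pitch is 0.18 μm, 10 GHz analog bandwidth, 2 μm diffraction limit.
DEFAULT_CONFIG = AcquisitionConfig(
    f=5e9, F=11.6142e6, C_x=7.1, C_t=0.4,
    v_y=2.0905, B=10e9, d_opt=2.0, n_lines=256,
)

CLASS_NAMES = ("2lobe", "4lobe", "fragment")


class SceneSpecError(ValueError):
    """A scene object falls outside the field or a parameter is invalid."""


@dataclass(frozen=True)
class SceneObject:
    """One specimen in the field.

    shape: 'colony2' / 'colony4' (lobed colonies drawn as overlapping
    ellipses sharing a wall), 'disk' (droplet) or 'ring' (fragment /
    discarded exoskeleton).  ``axes`` are the semi-axes (μm) of a single
    lobe; ``contrast`` is the interior transmittance; ``texture_amp`` the
    amplitude of band-limited multiplicative texture inside the object.
    """

    shape: str
    center: tuple[float, float]
    axes: tuple[float, float]
    orientation: float = 0.0
    contrast: float = 0.5
    texture_amp: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("colony2", "colony4", "disk", "ring"):
            raise SceneSpecError(f"unknown object shape {self.shape!r}")
        if not (0.0 <= self.contrast <= 1.2):
            raise SceneSpecError("transmittance contrast must lie in [0, 1.2]")

    @property
    def n_lobes(self) -> int:
        return {"colony2": 2, "colony4": 4}.get(self.shape, 1)

    def extent(self) -> float:
        """Conservative bounding radius, μm."""
        a, b = self.axes
        return max(a, b + 1.05 * b * (self.n_lobes - 1)) + 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Transmittance scene on a field of ``width`` × ``height`` μm.

    ``x_offset`` places the field along the (much longer) spectral line;
    outside the field the transmittance is the background value.
    """

    width: float
    height: float
    objects: tuple[SceneObject, ...] = ()
    background: float = 1.0
    x_offset: float = 0.0
    texture_scale: float = 1.5  # μm, correlation length of internal texture

    def __post_init__(self) -> None:
        for obj in self.objects:
            cx, cy = obj.center
            r = obj.extent()
            if not (0 <= cx <= self.width and 0 <= cy <= self.height):
                raise SceneSpecError(f"object center {obj.center} outside field")
            if cx - r < -1e-9 or cx + r > self.width + 1e-9 \
                    or cy - r < -1e-9 or cy + r > self.height + 1e-9:
                raise SceneSpecError(
                    f"object at {obj.center} (extent {r:.1f} μm) exceeds the field")


@dataclass
class GroundTruth:
    """Simulator bookkeeping stored with every synthetic record."""

    ratio: float                     # exact samples/line used by the simulator
    envelope_x: np.ndarray           # μm positions of the envelope profile
    envelope: np.ndarray             # illumination profile on that grid
    hr_image: np.ndarray | None      # PSF-blurred scene on a regular fine grid
    hr_pitch: float = 0.0            # μm, raster pitch of hr_image
    x_offset: float = 0.0            # μm, field origin along the line
    scene: SceneSpec | None = None
    label: str | None = None


@dataclass
class RawRecord:
    """A digitized 1-D sample stream with its acquisition config."""

    samples: np.ndarray
    config: AcquisitionConfig
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains non-finite samples")

    @property
    def n_lines(self) -> int:
        return int(self.samples.size // self.config.ratio)


def render_scene(spec: SceneSpec, seed: int, pitch: float = 0.4) -> np.ndarray:
    """Rasterize a scene to a (ny, nx) transmittance image at ``pitch`` μm/px.

    Lobed colonies are overlapping ellipses sharing a darker wall; internal
    texture is band-limited multiplicative noise.  Deterministic for a fixed
    seed.
    """
    nx = max(2, int(round(spec.width / pitch)))
    ny = max(2, int(round(spec.height / pitch)))
    x = (np.arange(nx) + 0.5) * pitch
    y = (np.arange(ny) + 0.5) * pitch
    xx, yy = np.meshgrid(x, y)
    raster = np.full((ny, nx), spec.background, dtype=float)

    rng_children = np.random.SeedSequence(seed).spawn(max(1, len(spec.objects)))
    for obj, ss in zip(spec.objects, rng_children):
        rng = np.random.default_rng(ss)
        cx, cy = obj.center
        a, b = obj.axes
        ct, st = math.cos(obj.orientation), math.sin(obj.orientation)
        u = (xx - cx) * ct + (yy - cy) * st    # along major axis
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = np.zeros_like(raster, dtype=bool)
        wall = np.zeros_like(raster, dtype=bool)
        if obj.shape in ("colony2", "colony4"):
            # elongated daughters packed side by side across the minor axis,
            # touching along their long sides (centres 2.1·b apart)
            n = obj.n_lobes
            offs = (np.arange(n) - (n - 1) / 2) * 2.1 * b
            for o in offs:
                q = (u / a) ** 2 + ((v - o) / b) ** 2
                inside |= q <= 1.0
                wall |= (q > 0.60) & (q <= 1.0)
        elif obj.shape == "disk":
            q = (u / a) ** 2 + (v / b) ** 2
            inside = q <= 1.0
        else:  # ring
            q = (u / a) ** 2 + (v / b) ** 2
            inside = (q <= 1.0) & (q > 0.35)
        val = np.full_like(raster, obj.contrast)
        if obj.shape in ("colony2", "colony4"):
            val[wall] = obj.contrast * 0.55   # shared cell wall, more opaque
        if obj.texture_amp > 0:
            tex = rng.standard_normal(raster.shape)
            tex = ndimage.gaussian_filter(tex, spec.texture_scale / pitch)
            tex /= max(tex.std(), 1e-12)
            val = val * (1.0 + obj.texture_amp * tex)
        raster[inside] = np.clip(val[inside], 0.0, 1.2)
    return raster


def spectral_envelope(n_points: int, seed: int, ripple_amp: float = 0.05,
                      n_ripples: float = 10.0) -> np.ndarray:
    """Per-pulse illumination profile: asymmetric bell plus low-amplitude ripple.

    The bell models the laser spectrum mapped along the line; the ripple (a
    few incommensurate sinusoids with seeded phases) gives the background the
    structure the drift-registration step correlates on.  Identical for every
    pulse of a record.  Strictly positive.
    """
    if n_points < 16:
        raise ValueError("envelope needs at least 16 points")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    # asymmetric bell: different left/right widths around an off-centre peak
    t0, wl, wr = 0.42, 0.26, 0.36
    w = np.where(t < t0, wl, wr)
    bell = np.exp(-0.5 * ((t - t0) / w) ** 2)
    profile = 0.15 + 0.85 * bell
    if ripple_amp > 0:
        freqs = n_ripples * np.array([1.0, 1.618, 2.414])
        phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
        amps = ripple_amp * np.array([1.0, 0.6, 0.35])
        ripple = sum(a * np.sin(2 * np.pi * fq * t + ph)
                     for a, fq, ph in zip(amps, freqs, phases))
        profile = profile * (1.0 + ripple)
    assert profile.min() > 0
    return profile


def lowpass_fir(stream: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Linear-phase windowed-sinc low-pass; no-op when cutoff ≥ Nyquist."""
    nyq = rate / 2.0
    if cutoff <= 0 or cutoff >= nyq:
        return stream
    numtaps = 129
    taps = signal.firwin(numtaps, cutoff / nyq)
    padded = np.pad(stream, numtaps, mode="reflect")
    out = signal.fftconvolve(padded, taps, mode="same")
    return out[numtaps:-numtaps]


def synth_record(scene: SceneSpec | None, config: AcquisitionConfig, *,
                 noise_sd: float = 0.01, ratio_perturb: float = 0.0,
                 seed: int = 0, oversample: int = 8,
                 envelope: np.ndarray | None = None,
                 ripple_amp: float = 0.05, label: str | None = None) -> RawRecord:
    """Simulate one digitized record of ``config.n_lines`` line scans.

    ``ratio_perturb`` is a relative perturbation of the nominal samples-per-
    line ratio f/F (clock inaccuracy; the true ratio is recorded in the
    ground truth).  ``noise_sd`` is the additive Gaussian noise s.d. as a
    fraction of the envelope peak.  ``envelope`` overrides the default
    spectral envelope with an arbitrary profile (evaluated over one line).
    """
    if config.n_lines < 2:
        raise ValueError("config.n_lines must be ≥ 2 to simulate a record")
    geom = geometry(config)
    ss_env, ss_scene, ss_noise = np.random.SeedSequence(seed).spawn(3)
    r_nom = config.ratio
    r_true = r_nom * (1.0 + ratio_perturb)
    line_len = r_nom * geom.dx                      # spatial span of one line, μm

    if envelope is None:
        env_seed = int(ss_env.generate_state(1)[0] % (2 ** 31))
        envelope = spectral_envelope(4096, env_seed, ripple_amp=ripple_amp)
    envelope = np.asarray(envelope, dtype=float)
    env_x = np.linspace(0.0, line_len, envelope.size, endpoint=False)

    hr_image = None
    hr_pitch = 0.0
    x_offset = 0.0
    if scene is not None:
        hr_pitch = geom.dx / 8.0
        scene_seed = int(ss_scene.generate_state(1)[0] % (2 ** 31))
        raster = render_scene(scene, scene_seed, pitch=hr_pitch)
        sigma_psf = config.d_opt / 2.355 / hr_pitch if config.d_opt > 0 else 0.0
        hr_image = ndimage.gaussian_filter(raster, sigma_psf, mode="nearest") \
            if sigma_psf > 0 else raster
        x_offset = scene.x_offset if scene.x_offset > 0 else (line_len - scene.width) / 2

    n_samples = int(math.floor(config.n_lines * r_true))
    s = max(1, int(oversample))
    kf = np.arange(n_samples * s, dtype=float) / s   # in LR-sample units
    m = np.floor(kf / r_true).astype(np.int64)
    x_um = (kf - m * r_true) * geom.dx
    y_um = m * geom.dy

    stream = np.interp(x_um, env_x, envelope, period=line_len)
    if hr_image is not None:
        rows = y_um / hr_pitch - 0.5
        cols = (x_um - x_offset) / hr_pitch - 0.5
        trans = ndimage.map_coordinates(hr_image, [rows, cols], order=1,
                                        mode="constant", cval=scene.background)
        # outside the field along x the transmittance is the background
        outside = (cols < -0.5) | (cols > hr_image.shape[1] - 0.5)
        trans[outside] = scene.background
        stream = stream * trans

    stream = lowpass_fir(stream, config.B, rate=config.f * s)
    samples = stream[::s][:n_samples].copy()
    if noise_sd > 0:
        rng = np.random.default_rng(ss_noise)
        samples = samples + noise_sd * envelope.max() * rng.standard_normal(n_samples)

    gt = GroundTruth(ratio=r_true, envelope_x=env_x, envelope=envelope,
                     hr_image=hr_image, hr_pitch=hr_pitch, x_offset=x_offset,
                     scene=scene, label=label)
    return RawRecord(samples=samples, config=config, ground_truth=gt)


def _random_object(cls: str, rng: np.random.Generator, spec_w: float,
                   spec_h: float) -> SceneObject:
    """Randomized pose/size within class-specific ranges.

    Daughter cells of the model colonies are ≈5 μm across the minor axis;
    four-daughter colonies are roughly twice the footprint of two-daughter
    ones.  Fragments are small, translucent rings.
    """
    scale = rng.uniform(0.85, 1.25)
    angle = rng.uniform(0.0, np.pi)
    if cls == "2lobe":
        obj = SceneObject("colony2", (0, 0), (5.0 * scale, 2.5 * scale),
                          orientation=angle, contrast=rng.uniform(0.35, 0.55),
                          texture_amp=0.15)
    elif cls == "4lobe":
        obj = SceneObject("colony4", (0, 0), (5.0 * scale, 2.5 * scale),
                          orientation=angle, contrast=rng.uniform(0.35, 0.55),
                          texture_amp=0.15)
    elif cls == "fragment":
        obj = SceneObject("ring", (0, 0), (3.2 * scale, 2.4 * scale),
                          orientation=angle, contrast=rng.uniform(0.55, 0.68),
                          texture_amp=0.05)
    else:
        raise ValueError(f"unknown class {cls!r}")
    r = obj.extent()
    if 2 * r > spec_w or 2 * r > spec_h:
        raise SceneSpecError(
            f"field {spec_w:.1f}×{spec_h:.1f} μm too small for a {cls} object "
            f"of extent {r:.1f} μm; increase n_lines or field_width")
    cx = rng.uniform(r, spec_w - r)
    cy = rng.uniform(r, spec_h - r)
    return replace(obj, center=(cx, cy))


def make_cohort(n: int, class_mix: dict[str, float] | tuple[float, float, float],
                config: AcquisitionConfig = DEFAULT_CONFIG, seed: int = 0, *,
                noise_sd: float = 0.02, field_width: float = 64.0,
                ratio_jitter: float = 5e-5) -> list[RawRecord]:
    """Generate ``n`` single-object records with class labels retained.

    ``class_mix`` gives proportions over ('2lobe', '4lobe', 'fragment') and
    must sum to 1.  Each record gets its own scene (randomized pose/size),
    noise stream, and a small random clock perturbation (``ratio_jitter``
    relative, emulating the quoted stability of the laser/digitizer pair).
    """
    if not isinstance(class_mix, dict):
        class_mix = dict(zip(CLASS_NAMES, class_mix))
    probs = np.array([class_mix.get(c, 0.0) for c in CLASS_NAMES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    geom = geometry(config)
    field_h = config.n_lines * geom.dy
    top = np.random.SeedSequence(seed)
    children = top.spawn(n + 1)
    labels_rng = np.random.default_rng(children[0])
    labels = labels_rng.choice(len(CLASS_NAMES), size=n, p=probs)
    records = []
    for lab, ss in zip(labels, children[1:]):
        cls = CLASS_NAMES[lab]
        rng = np.random.default_rng(ss)
        obj = _random_object(cls, rng, field_width, field_h)
        scene = SceneSpec(width=field_width, height=field_h, objects=(obj,))
        rec = synth_record(scene, config, noise_sd=noise_sd,
                           ratio_perturb=rng.uniform(-ratio_jitter, ratio_jitter),
                           seed=int(rng.integers(2 ** 31)), label=cls)
        records.append(rec)
    return records
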