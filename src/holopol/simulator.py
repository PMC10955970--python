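"""Physics-based synthetic generator for four-state polarization holograms.

Forward model of the bench: an ideal circularly polarized 532 nm probe,
Jones vector (1, i)/sqrt(2) at every pixel, traverses a sample plane of
birefringent particles.  Each particle pixel applies the Jones matrix of
an elliptical-amplitude linear retarder,

    J = t * exp(i*phi0) * R(theta) @ diag(e^{+i d/2}, e^{-i d/2}) @ R(-theta),

with amplitude transmittance t, phase thickness phi0, retardance d and
fast-axis orientation theta.  The modulated field propagates to the
sensor by the band-limited angular-spectrum method (exact scalar
diffraction per Jones component, evanescent waves zeroed), producing
in-line holographic fringes.  Recording projects the field onto each
analyzer of the polarization mask (0/45/90/135 degrees, optionally
right-circular), adds Poisson shot noise and Gaussian read noise at the
configured photon budget, and quantizes to the sensor bit depth.

Class profiles carry the discriminating structure: microplastic-like
classes (PC, PET, PP, PVC, PMMA) have strong, per-class-distinct mean
retardance and smooth axis fields; biological-like classes (Chlorella,
Daphnia magna, plant-root sections) are weakly birefringent irregular
blobs with patchy axis domains.  Per-class retardance ranges are this
package's own synthetic choices, not material constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import fft as sfft
from scipy.ndimage import gaussian_filter

from holopol import io_core
from holopol.io_core import DatasetManifest, ManifestRecord, OpticalConfig
from holopol.polarimetry import PolarizationFrame

logger = logging.getLogger("holopol.simulator")

#: class histogram of the reference experimental dataset (3221 frames)
REFERENCE_CLASS_COUNTS = {
    "PC": 518,
    "PET": 240,
    "PP": 232,
    "PVC": 535,
    "PMMA": 573,
    "Chlorella": 208,
    "DaphniaMagna": 126,
    "PlantRoot": 789,
}

MICROPLASTIC_CLASSES = ("PC", "PET", "PP", "PVC", "PMMA")
BIOLOGICAL_CLASSES = ("Chlorella", "DaphniaMagna", "PlantRoot")


@dataclass
class ClassProfile:
    """Sampling distributions for every particle parameter of one class."""

    label: str
    delta_range: tuple[float, float]  # mean retardance, rad
    delta_texture_range: tuple[float, float]  # relative modulation depth
    axis_style: str  # 'uniform' | 'linear' | 'patchy'
    transmittance_range: tuple[float, float]
    phase_range: tuple[float, float]  # rad
    size_range: tuple[float, float]  # equivalent diameter, px
    aspect_range: tuple[float, float]  # major/minor axis ratio
    shape: str = "ellipse"  # 'ellipse' | 'blob'
    irregularity: float = 0.0  # blob boundary modulation depth

    def __post_init__(self) -> None:
        lo, hi = self.delta_range
        if not (0.0 <= lo <= hi <= np.pi):
            raise ValueError(f"{self.label}: delta_range must lie in [0, pi]")
        if self.axis_style not in ("uniform", "linear", "patchy"):
            raise ValueError(f"{self.label}: unknown axis style {self.axis_style!r}")


def builtin_profiles() -> dict[str, ClassProfile]:
    """The eight built-in class profiles.

    Microplastic retardance bands are disjoint across classes (class
    separation is carried primarily by retardance and axis-field style);
    biological classes share low retardance and are distinguished by
    size, shape irregularity and texture.  Sizes honor a 6 px minimum
    equivalent diameter (20 um at 3.45 um pitch).
    """
    return {
        "PC": ClassProfile("PC", (0.60, 0.80), (0.08, 0.18), "uniform",
                           (0.60, 0.90), (0.0, 2 * np.pi), (22, 44), (1.0, 1.8)),
        "PET": ClassProfile("PET", (0.95, 1.15), (0.08, 0.20), "linear",
                            (0.55, 0.85), (0.0, 2 * np.pi), (22, 46), (1.2, 2.2)),
        "PP": ClassProfile("PP", (1.30, 1.50), (0.10, 0.22), "uniform",
                           (0.60, 0.90), (0.0, 2 * np.pi), (20, 42), (1.0, 1.6)),
        "PVC": ClassProfile("PVC", (1.65, 1.85), (0.08, 0.18), "linear",
                            (0.55, 0.85), (0.0, 2 * np.pi), (24, 46), (1.1, 2.0)),
        "PMMA": ClassProfile("PMMA", (2.00, 2.20), (0.06, 0.16), "uniform",
                             (0.65, 0.92), (0.0, 2 * np.pi), (22, 44), (1.0, 1.7)),
        "Chlorella": ClassProfile("Chlorella", (0.06, 0.16), (0.25, 0.45), "patchy",
                                  (0.45, 0.75), (0.0, 2 * np.pi), (8, 16), (1.0, 1.3),
                                  shape="blob", irregularity=0.12),
        "DaphniaMagna": ClassProfile("DaphniaMagna", (0.10, 0.24), (0.30, 0.50), "patchy",
                                     (0.50, 0.80), (0.0, 2 * np.pi), (40, 70), (1.3, 2.0),
                                     shape="blob", irregularity=0.25),
        "PlantRoot": ClassProfile("PlantRoot", (0.18, 0.38), (0.25, 0.45), "patchy",
                                  (0.40, 0.70), (0.0, 2 * np.pi), (36, 64), (1.8, 3.2),
                                  shape="blob", irregularity=0.18),
    }


@dataclass
class ParticleSpec:
    """Sampled ground-truth parameters of one particle."""

    label: str
    center: tuple[float, float]  # (row, col), px
    size: float  # equivalent diameter, px
    aspect: float
    rotation: float  # rad
    mean_delta: float  # rad
    delta_texture: float
    axis_style: str
    axis_angle: float  # deg, base orientation
    transmittance: float
    phase: float  # rad
    shape: str = "ellipse"
    irregularity: float = 0.0
    harmonics: tuple[tuple[float, float], ...] = ()  # (amplitude, phase) per k>=2

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_delta <= np.pi):
            raise ValueError("mean retardance must lie in [0, pi]")
        if not (0.0 <= self.transmittance <= 1.0):
            raise ValueError("transmittance must lie in [0, 1]")


@dataclass
class Scene:
    """Sample-plane ground truth: particle specs plus per-pixel maps.

    Maps: ``label`` (0 = background, else 1-based particle index),
    ``delta`` (rad), ``theta`` (deg in [0, 180)), ``transmittance``,
    ``phase`` (rad).
    """

    specs: list[ParticleSpec]
    maps: dict[str, np.ndarray]
    optics: OpticalConfig
    background_transmittance: float = 1.0


@dataclass
class JonesField:
    """Transverse complex field, x and y components on the pixel grid."""

    Ex: np.ndarray
    Ey: np.ndarray

    def __post_init__(self) -> None:
        if self.Ex.shape != self.Ey.shape:
            raise ValueError("Ex/Ey shape mismatch")
        if not (np.all(np.isfinite(self.Ex)) and np.all(np.isfinite(self.Ey))):
            raise ValueError("non-finite field entries")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.Ex) ** 2 + np.abs(self.Ey) ** 2

    def energy(self) -> float:
        return float(np.sum(self.intensity))


# ---------------------------------------------------------------------------
# scene sampling
# ---------------------------------------------------------------------------


def _particle_mask(spec: ParticleSpec, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    r0, c0 = spec.center
    # ellipse semi-axes from equivalent diameter and aspect ratio
    b = spec.size / (2.0 * np.sqrt(spec.aspect))
    a = b * spec.aspect
    Y, X = np.ogrid[:rows, :cols]
    dy = Y - r0
    dx = X - c0
    ca, sa = np.cos(spec.rotation), np.sin(spec.rotation)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    if spec.shape == "ellipse" or not spec.harmonics:
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # blob: modulate the ellipse radius with low-order harmonics
    ang = np.arctan2(v / b, u / a)
    mod = np.ones_like(ang)
    for k, (amp, ph) in enumerate(spec.harmonics, start=2):
        mod = mod + amp * np.cos(k * ang + ph)
    rad = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return rad <= np.maximum(mod, 0.2)


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Smoothed white noise renormalized to zero mean, unit variance."""
    g = gaussian_filter(rng.standard_normal(shape), sigma)
    sd = g.std()
    return (g - g.mean()) / (sd if sd > 0 else 1.0)


def _local_smooth_patch(
    rng: np.random.Generator,
    spec: ParticleSpec,
    shape: tuple[int, int],
    sigma: float,
) -> np.ndarray:
    """Smooth noise generated in particle-local coordinates.

    The patch is anchored at the particle center so the texture travels
    with the particle under whole-pixel translation (feature extraction
    is translation-invariant by construction).
    """
    side = int(np.ceil(3 * spec.size)) + 9
    patch = _smooth_noise(rng, (side, side), sigma)
    out = np.zeros(shape)
    r0 = int(round(spec.center[0])) - side // 2
    c0 = int(round(spec.center[1])) - side // 2
    rs, re = max(r0, 0), min(r0 + side, shape[0])
    cs, ce = max(c0, 0), min(c0 + side, shape[1])
    if rs < re and cs < ce:
        out[rs:re, cs:ce] = patch[rs - r0: re - r0, cs - c0: ce - c0]
    return out


def _render_particle_fields(
    spec: ParticleSpec, mask: np.ndarray, rng: np.random.Generator, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Retardance and axis-orientation fields for one particle."""
    tex = _local_smooth_patch(rng, spec, shape, sigma=max(spec.size / 10, 1.5))
    delta = np.clip(
        spec.mean_delta * (1.0 + spec.delta_texture * tex), _DELTA_MIN, _DELTA_MAX
    )
    theta = _render_axis_field(spec, mask, rng, shape)
    return delta, theta


# retardance is clipped away from 0 so the axis field stays observable
# (DoLP = sin(delta) must exceed the estimation floor everywhere inside)
_DELTA_MIN = 0.05
_DELTA_MAX = np.pi - 0.02


def _render_axis_field(
    spec: ParticleSpec, mask: np.ndarray, rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    rows, cols = shape
    theta = np.zeros(shape)
    if spec.axis_style == "uniform":
        theta[mask] = spec.axis_angle
    elif spec.axis_style == "linear":
        Y, X = np.mgrid[:rows, :cols]
        direction = rng.uniform(0, np.pi)
        proj = (X - spec.center[1]) * np.cos(direction) + (Y - spec.center[0]) * np.sin(direction)
        slope = rng.uniform(30.0, 60.0) / max(spec.size, 1.0)  # deg per px across the particle
        theta[mask] = spec.axis_angle + slope * proj[mask]
    else:  # patchy: quantized smooth noise -> distinct axis domains
        g = _local_smooth_patch(rng, spec, shape, sigma=max(spec.size / 8.0, 2.0))
        edges = np.quantile(g[mask], [0.25, 0.5, 0.75]) if mask.any() else [0, 0, 0]
        domains = np.digitize(g, edges)
        offsets = rng.uniform(0.0, 180.0, size=4)
        theta[mask] = spec.axis_angle + offsets[domains[mask]]
    theta %= 180.0
    return theta


def sample_particle(
    profile: ClassProfile, rng: np.random.Generator, optics: OpticalConfig,
    center: tuple[float, float] | None = None,
) -> ParticleSpec:
    """Draw one particle's parameters from a class profile."""
    rows, cols = optics.shape
    size = rng.uniform(*profile.size_range)
    # particle plus fringe room should fit inside the grid; on small grids
    # fall back to keeping the center in the middle third
    margin = min(size, rows // 3, cols // 3)
    if center is None:
        center = (rng.uniform(margin, rows - margin), rng.uniform(margin, cols - margin))
    harmonics: tuple[tuple[float, float], ...] = ()
    if profile.shape == "blob":
        harmonics = tuple(
            (rng.uniform(0.3, 1.0) * profile.irregularity / (k - 1), rng.uniform(0, 2 * np.pi))
            for k in range(2, 6)
        )
    return ParticleSpec(
        label=profile.label,
        center=center,
        size=size,
        aspect=rng.uniform(*profile.aspect_range),
        rotation=rng.uniform(0, np.pi),
        mean_delta=rng.uniform(*profile.delta_range),
        delta_texture=rng.uniform(*profile.delta_texture_range),
        axis_style=profile.axis_style,
        axis_angle=rng.uniform(0.0, 180.0),
        transmittance=rng.uniform(*profile.transmittance_range),
        phase=rng.uniform(*profile.phase_range),
        shape=profile.shape,
        irregularity=profile.irregularity,
        harmonics=harmonics,
    )


def sample_scene(
    profiles: Mapping[str, ClassProfile],
    counts: Mapping[str, int],
    seed: int | np.random.Generator,
    optics: OpticalConfig,
    max_retries: int = 200,
) -> Scene:
    """Sample a scene with the requested per-class particle counts.

    Particles are placed by rejection sampling so masks never overlap;
    deterministic given the seed.  Raises ``RuntimeError`` if a particle
    cannot be placed within ``max_retries`` attempts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = optics.shape
    label_map = np.zeros(shape, dtype=np.int32)
    delta_map = np.zeros(shape)
    theta_map = np.zeros(shape)
    t_map = np.ones(shape)
    phase_map = np.zeros(shape)
    specs: list[ParticleSpec] = []
    for cls in counts:
        if cls not in profiles:
            raise KeyError(f"no profile for class {cls!r}")
    occupied = np.zeros(shape, dtype=bool)
    for cls, n in counts.items():
        profile = profiles[cls]
        for _ in range(int(n)):
            for attempt in range(max_retries):
                spec = sample_particle(profile, rng, optics)
                mask = _particle_mask(spec, shape)
                if mask.any() and not (mask & occupied).any():
                    break
            else:
                raise RuntimeError(
                    f"could not place a {cls} particle without overlap "
                    f"after {max_retries} attempts"
                )
            occupied |= mask
            specs.append(spec)
            idx = len(specs)
            label_map[mask] = idx
            delta, theta = _render_particle_fields(spec, mask, rng, shape)
            delta_map[mask] = delta[mask]
            theta_map[mask] = theta[mask]
            t_map[mask] = spec.transmittance
            phase_map[mask] = spec.phase
    logger.info("sampled scene with %d particles over %d classes", len(specs), len(counts))
    return Scene(
        specs=specs,
        maps={
            "label": label_map.astype(np.float64),
            "delta": delta_map,
            "theta": theta_map,
            "transmittance": t_map,
            "phase": phase_map,
        },
        optics=optics,
    )


# ---------------------------------------------------------------------------
# forward optics
# ---------------------------------------------------------------------------


def modulate_field(scene: Scene, optics: OpticalConfig | None = None) -> JonesField:
    """Pass the circular probe through the sample plane.

    The probe is unit-amplitude circular polarization, Jones vector
    (1, i)/sqrt(2), at every pixel; particle pixels are multiplied by the
    retarder Jones matrix, background pixels by the background
    transmittance.
    """
    optics = optics or scene.optics
    shape = optics.shape
    if scene.maps["label"].shape != shape:
        raise ValueError("scene grid inconsistent with optics grid")
    amp = 1.0 / np.sqrt(2.0)
    Ex = np.full(shape, amp, dtype=np.complex128) * scene.background_transmittance
    Ey = np.full(shape, amp * 1j, dtype=np.complex128) * scene.background_transmittance
    mask = scene.maps["label"] > 0
    if mask.any():
        delta = scene.maps["delta"][mask]
        theta = np.deg2rad(scene.maps["theta"][mask])
        t = scene.maps["transmittance"][mask]
        phi = scene.maps["phase"][mask]
        c, s = np.cos(theta), np.sin(theta)
        ep = np.exp(+0.5j * delta)
        em = np.exp(-0.5j * delta)
        pref = t * np.exp(1j * phi)
        Jxx = pref * (c * c * ep + s * s * em)
        Jxy = pref * (c * s * (ep - em))
        Jyy = pref * (s * s * ep + c * c * em)
        ex0, ey0 = Ex[mask] / scene.background_transmittance, Ey[mask] / scene.background_transmittance
        Ex[mask] = Jxx * ex0 + Jxy * ey0
        Ey[mask] = Jxy * ex0 + Jyy * ey0
    return JonesField(Ex=Ex, Ey=Ey)


def propagate(fieldin: JonesField, z: float, optics: OpticalConfig) -> JonesField:
    """Angular-spectrum free-space propagation of each Jones component.

    Transfer function H = exp(i 2 pi z sqrt(1/lambda^2 - fx^2 - fy^2)),
    evanescent components (fx^2 + fy^2 > 1/lambda^2) zeroed.  z = 0
    returns the input identically; |H| = 1 on the propagating band, so
    total energy is conserved whenever the sampled band is propagating.
    """
    if z < 0:
        raise ValueError("propagation distance must be >= 0")
    if z == 0.0:
        return JonesField(Ex=fieldin.Ex.copy(), Ey=fieldin.Ey.copy())
    rows, cols = fieldin.Ex.shape
    if rows % 2 or cols % 2:
        raise ValueError("grid dims must be even for spectral propagation")
    fy = sfft.fftfreq(rows, d=optics.pitch)
    fx = sfft.fftfreq(cols, d=optics.pitch)
    FX, FY = np.meshgrid(fx, fy)
    arg = 1.0 / optics.wavelength**2 - FX**2 - FY**2
    propagating = arg >= 0
    H = np.where(propagating, np.exp(2j * np.pi * z * np.sqrt(np.maximum(arg, 0.0))), 0.0)
    out = []
    for comp in (fieldin.Ex, fieldin.Ey):
        out.append(sfft.ifft2(sfft.fft2(comp) * H))
    return JonesField(Ex=out[0], Ey=out[1])


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

_ANALYZER_ANGLES = {"I0": 0.0, "I45": 45.0, "I90": 90.0, "I135": 135.0}


def analyzer_intensity(fieldin: JonesField, channel: str) -> np.ndarray:
    """Project the field on one analyzer: I = |p^dagger E|^2."""
    if channel in _ANALYZER_ANGLES:
        a = np.deg2rad(_ANALYZER_ANGLES[channel])
        proj = np.cos(a) * fieldin.Ex + np.sin(a) * fieldin.Ey
    elif channel == "IRCP":
        proj = (fieldin.Ex - 1j * fieldin.Ey) / np.sqrt(2.0)
    else:
        raise ValueError(f"unknown analyzer tag {channel!r}")
    return np.abs(proj) ** 2


def record_frame(
    fieldin: JonesField,
    optics: OpticalConfig,
    channels: Sequence[str] = ("I0", "I45", "I90", "I135"),
    seed: int | np.random.Generator | None = None,
) -> PolarizationFrame:
    """Record the field through the analyzer set of the polarization mask.

    Intensities are scaled so ``optics.full_scale`` maps to 1.0.  With a
    seed, Poisson shot noise at the photon budget plus Gaussian read
    noise are applied, then quantization to the configured bit depth;
    without a seed the frame is noiseless (and unquantized when
    ``bit_depth`` is None).
    """
    rng = None
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grids: dict[str, np.ndarray] = {}
    for ch in channels:
        inten = analyzer_intensity(fieldin, ch) / optics.full_scale
        if rng is not None:
            counts = rng.poisson(np.clip(inten, 0, None) * optics.photon_budget).astype(np.float64)
            if optics.read_noise > 0:
                counts += rng.normal(0.0, optics.read_noise, size=counts.shape)
            inten = np.clip(counts / optics.photon_budget, 0.0, None)
        if optics.bit_depth is not None:
            top = 2**optics.bit_depth - 1
            inten = np.clip(np.rint(inten * top), 0, top) / top
        grids[ch] = inten
    return PolarizationFrame(grids, channels=tuple(channels))


def simulate_particle_frame(
    profile: ClassProfile,
    optics: OpticalConfig,
    seed: int | np.random.Generator,
    channels: Sequence[str] = ("I0", "I45", "I90", "I135", "IRCP"),
    noise: bool = True,
    center: tuple[float, float] | None = None,
) -> tuple[PolarizationFrame, Scene]:
    """Simulate one single-particle frame end to end (scene -> sensor)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if center is None:
        rows, cols = optics.shape
        center = (rows / 2.0, cols / 2.0)
    scene = _single_particle_scene(profile, rng, optics, center)
    field = modulate_field(scene, optics)
    field = propagate(field, optics.z, optics)
    frame = record_frame(field, optics, channels=channels, seed=rng if noise else None)
    return frame, scene


def _single_particle_scene(
    profile: ClassProfile, rng: np.random.Generator, optics: OpticalConfig,
    center: tuple[float, float],
) -> Scene:
    shape = optics.shape
    spec = sample_particle(profile, rng, optics, center=center)
    mask = _particle_mask(spec, shape)
    label_map = np.where(mask, 1.0, 0.0)
    delta, theta = _render_particle_fields(spec, mask, rng, shape)
    delta_map = np.where(mask, delta, 0.0)
    theta_map = np.where(mask, theta, 0.0)
    t_map = np.where(mask, spec.transmittance, 1.0)
    phase_map = np.where(mask, spec.phase, 0.0)
    return Scene(
        specs=[spec],
        maps={"label": label_map, "delta": delta_map, "theta": theta_map,
              "transmittance": t_map, "phase": phase_map},
        optics=optics,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def scaled_class_counts(scale: float) -> dict[str, int]:
    """Reference class proportions scaled by ``scale`` (>=1 frame per class)."""
    return {cls: max(1, round(n * scale)) for cls, n in REFERENCE_CLASS_COUNTS.items()}


def generate_dataset(
    out_dir: str | Path,
    counts: Mapping[str, int] | None = None,
    profiles: Mapping[str, ClassProfile] | None = None,
    optics: OpticalConfig | None = None,
    seed: int = 0,
    channels: Sequence[str] = ("I0", "I45", "I90", "I135", "IRCP"),
    noise: bool = True,
) -> DatasetManifest:
    """Write a labeled synthetic dataset: frames, ground truth, manifest.

    One particle per frame; ``counts`` defaults to the reference class
    proportions scaled to ~10 frames/class.  Deterministic given the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = profiles or builtin_profiles()
    optics = optics or OpticalConfig(shape=(256, 256))
    counts = counts or scaled_class_counts(10 * 8 / 3221)
    ss = np.random.SeedSequence(seed)
    records: list[ManifestRecord] = []
    frame_seeds = ss.spawn(sum(int(n) for n in counts.values()))
    i = 0
    for cls in sorted(counts):
        for _ in range(int(counts[cls])):
            rng = np.random.default_rng(frame_seeds[i])
            frame_id = f"{cls}_{i:05d}"
            frame, scene = simulate_particle_frame(
                profiles[cls], optics, rng, channels=channels, noise=noise
            )
            frame_path = f"{frame_id}.tiff"
            gt_path = f"{frame_id}_gt.tiff"
            io_core.write_frame(frame, out_dir / frame_path, bit_depth=optics.bit_depth)
            io_core.write_ground_truth(
                {k: scene.maps[k] for k in ("label", "delta", "theta", "transmittance")},
                out_dir / gt_path,
            )
            records.append(ManifestRecord(frame_id, cls, frame_path, gt_path))
            i += 1
    manifest = DatasetManifest(records, channels=tuple(channels))
    io_core.save_manifest(manifest, out_dir / "manifest.csv")
    logger.info("generated %d frames into %s", len(records), out_dir)
    return manifest
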