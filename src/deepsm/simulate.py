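"""Synthetic-sequence generator: scene scripting and Cox-process shot noise.

Photon counting at the detector is modelled as a doubly stochastic Poisson
(Cox) process whose rate factorizes as

    lambda(u, t) = lambda1(u) * lambda2(t) * S(u, t),

with ``lambda1`` the per-pixel mean rate (background plus particle signal),
``lambda2`` a unit-mean temporal modulation (exponentiated AR(1)), and ``S``
a unit-mean spatio-temporal log-Gaussian field (spatial Gaussian kernel,
AR(1) in time).  Setting both modulation SDs to zero recovers pure Poisson
shot noise.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .optics import OpticalModel, ParticleState, psf_contribution

__all__ = [
    "ImageSequence",
    "NoiseModel",
    "EventSchedule",
    "ParticleScene",
    "GroundTruth",
    "sample_shot_noise",
    "simulate_sequence",
    "simulate_tethered_motion",
    "generate_training_pairs",
]


@dataclasses.dataclass
class ImageSequence:
    """A T x H x W stack of nonnegative intensities with acquisition metadata."""

    frames: np.ndarray
    frame_interval_ms: float = 2.0
    pixel_size_um: float = 0.108
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 1 or h < 1 or w < 1:
            raise ValueError(f"empty sequence: shape {self.frames.shape}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("frames contain negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclasses.dataclass
class NoiseModel:
    """Cox-process specification lambda1(u) * lambda2(t) * S(u, t).

    ``lambda1`` is carried by the clean sequence (background + signal); this
    object holds the unit-mean modulating processes.  ``sigma_t = sigma_s = 0``
    reduces to pure Poisson.
    """

    rho_t: float = 0.0       # AR(1) coefficient of log lambda2
    sigma_t: float = 0.0     # stationary SD of log lambda2
    corr_len_s_px: float = 3.0   # spatial correlation length of log S
    rho_s: float = 0.0       # temporal AR(1) coefficient of log S
    sigma_s: float = 0.0     # stationary SD of log S
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho_t < 1.0 and -1.0 < self.rho_s < 1.0):
            raise ValueError("AR(1) coefficients must lie in (-1, 1)")
        if self.sigma_t < 0 or self.sigma_s < 0 or self.read_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.corr_len_s_px <= 0:
            raise ValueError("corr_len_s_px must be > 0")

    def var_modulation(self) -> float:
        """Variance of the unit-mean product lambda2 * S (lognormal moments)."""
        total = self.sigma_t**2 + self.sigma_s**2
        return math.expm1(total)


@dataclasses.dataclass
class EventSchedule:
    """Time course of one particle.  ``kind`` selects the parameter set.

    stationary: no params.
    collision:  z_waypoints [(frame, z_nm), ...] interpolated linearly;
                coupling_height_nm (default 1) below which the phase switches
                to phase_after.
    oxidation:  t_switch (frame), phase_before/after, amplitude_before/after.
    tether:     contour_length_nm L, step_sd_nm per-frame Brownian step.
    binding:    t1, t2 (frames, particle present for t1 <= t < t2), phase.
    """

    kind: str = "stationary"
    params: dict = dataclasses.field(default_factory=dict)

    _KINDS = ("stationary", "collision", "oxidation", "tether", "binding")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; one of {self._KINDS}")
        if self.kind == "tether" and self.params.get("contour_length_nm", 0.0) < 0:
            raise ValueError("tether contour length must be >= 0")


@dataclasses.dataclass
class ParticleScene:
    """Particles plus their event schedules."""

    particles: list[tuple[ParticleState, EventSchedule]] = dataclasses.field(
        default_factory=list
    )

    def add(self, state: ParticleState, schedule: EventSchedule | None = None) -> None:
        self.particles.append((state, schedule or EventSchedule()))


@dataclasses.dataclass
class GroundTruth:
    """Per-frame particle states and the matching noiseless sequence."""

    table: pd.DataFrame
    clean: ImageSequence

    COLUMNS = ("particle_id", "frame", "x_px", "y_px", "z_nm", "amplitude", "phase")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cox-process sampling


def _lambda2_series(t: int, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean exponentiated stationary AR(1), length t."""
    if noise.sigma_t == 0:
        return np.ones(t)
    x = np.empty(t)
    x[0] = rng.normal(0.0, noise.sigma_t)
    innov_sd = noise.sigma_t * math.sqrt(1.0 - noise.rho_t**2)
    eps = rng.normal(0.0, innov_sd, size=t - 1) if t > 1 else np.empty(0)
    for i in range(1, t):
        x[i] = noise.rho_t * x[i - 1] + eps[i - 1]
    return np.exp(x - 0.5 * noise.sigma_t**2)


def _smoothed_unit_noise(
    shape: tuple[int, int], corr_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to unit pointwise variance."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, corr_len, mode="wrap")
    # variance shrink factor of the filter = sum of squared kernel weights
    delta = np.zeros((int(8 * corr_len) * 2 + 1,) * 2)
    delta[delta.shape[0] // 2, delta.shape[1] // 2] = 1.0
    kernel = ndimage.gaussian_filter(delta, corr_len)
    scale = math.sqrt(float((kernel**2).sum()))
    return smooth / scale


def _s_field(
    t: int, shape: tuple[int, int], noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Unit-mean log-Gaussian field, spatially smooth, AR(1) in time."""
    if noise.sigma_s == 0:
        return np.ones((t, *shape))
    g = np.empty((t, *shape))
    g[0] = _smoothed_unit_noise(shape, noise.corr_len_s_px, rng)
    carry = math.sqrt(1.0 - noise.rho_s**2)
    for i in range(1, t):
        g[i] = noise.rho_s * g[i - 1] + carry * _smoothed_unit_noise(
            shape, noise.corr_len_s_px, rng
        )
    return np.exp(noise.sigma_s * g - 0.5 * noise.sigma_s**2)


def sample_shot_noise(
    clean: ImageSequence | np.ndarray,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> ImageSequence:
    """Draw a Cox-process photon-count realization of a clean rate sequence.

    Per pixel-frame the count is Poisson with rate
    ``clean(u, t) * lambda2(t) * S(u, t)`` (the clean sequence already carries
    the spatial mean rate), optionally plus Gaussian read noise.
    Reproducible under a fixed seed.
    """
    noise = noise or NoiseModel()
    if isinstance(clean, ImageSequence):
        rates = clean.frames
        template = clean
    else:
        rates = np.asarray(clean, dtype=float)
        if rates.ndim == 2:
            rates = rates[None]
        template = None
    if np.any(rates < 0):
        raise ValueError("clean rates must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    t, h, w = rates.shape
    lam2 = _lambda2_series(t, noise, rng)
    s = _s_field(t, (h, w), noise, rng)
    modulated = rates * lam2[:, None, None] * s
    counts = rng.poisson(modulated).astype(np.float64)
    if noise.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, noise.read_noise_sd, size=counts.shape)
        counts = np.clip(counts, 0.0, None)
    meta = dict(template.meta) if template is not None else {}
    meta.update(noise="cox" if noise.var_modulation() > 0 else "poisson")
    return ImageSequence(
        counts,
        frame_interval_ms=template.frame_interval_ms if template else 2.0,
        pixel_size_um=template.pixel_size_um if template else 0.108,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Scene scripting


def _state_at(
    base: ParticleState,
    schedule: EventSchedule,
    frame: int,
    tether_track: np.ndarray | None,
    pixel_size_um: float,
) -> ParticleState | None:
    """Particle state at a frame, or None if absent."""
    kind, p = schedule.kind, schedule.params
    x, y, z = base.x, base.y, base.z_nm
    amp, phase = base.amplitude, base.phase
    if kind == "stationary":
        pass
    elif kind == "collision":
        wps = p["z_waypoints"]
        frames = np.array([w[0] for w in wps], dtype=float)
        zs = np.array([w[1] for w in wps], dtype=float)
        z = float(np.interp(frame, frames, zs))
        if z < p.get("coupling_height_nm", 1.0):
            phase = p.get("phase_after", phase)
    elif kind == "oxidation":
        if frame >= p["t_switch"]:
            amp = p.get("amplitude_after", amp)
            phase = p.get("phase_after", phase)
        else:
            amp = p.get("amplitude_before", amp)
            phase = p.get("phase_before", phase)
    elif kind == "tether":
        dx_nm, dy_nm, z = tether_track[frame]
        x = base.x + dx_nm * 1e-3 / pixel_size_um
        y = base.y + dy_nm * 1e-3 / pixel_size_um
    elif kind == "binding":
        if not (p["t1"] <= frame < p["t2"]):
            return None
        phase = p.get("phase", phase)
    return ParticleState(x=x, y=y, z_nm=z, diameter_nm=base.diameter_nm,
                         amplitude=amp, phase=phase)


def simulate_sequence(
    scene: ParticleScene,
    optical: OpticalModel | None = None,
    noise: NoiseModel | None = None,
    n_frames: int = 8,
    shape: tuple[int, int] = (64, 64),
    seed: int | np.random.Generator = 0,
    frame_interval_ms: float = 2.0,
) -> tuple[ImageSequence, GroundTruth]:
    """Render a scene into (noisy, ground-truth) sequences.

    Clean frames are background plus the sum of particle contributions at
    their scheduled states; the noisy sequence is a Cox-process sample of the
    clean rates.  A shape that is not a multiple of 16 triggers a warning
    (the denoiser requires multiples of 16) but simulation proceeds.
    """
    optical = optical or OpticalModel()
    noise = noise or NoiseModel()
    if n_frames < 4:
        raise ValueError("n_frames must be >= 4")
    h, w = shape
    if h % 16 or w % 16:
        warnings.warn(
            f"shape {shape} is not a multiple of 16; the denoiser will reject it",
            stacklevel=2,
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    noise_rng, walk_rng = rng.spawn(2)

    tether_tracks: list[np.ndarray | None] = []
    for state, schedule in scene.particles:
        if schedule.kind == "tether":
            tether_tracks.append(
                simulate_tethered_motion(
                    schedule.params["contour_length_nm"],
                    state.diameter_nm,
                    n_frames,
                    schedule.params.get("step_sd_nm", 5.0),
                    walk_rng,
                )
            )
        else:
            tether_tracks.append(None)

    clean = np.full((n_frames, h, w), optical.background_level, dtype=float)
    rows = []
    for frame in range(n_frames):
        for pid, (state, schedule) in enumerate(scene.particles):
            st = _state_at(state, schedule, frame, tether_tracks[pid],
                           optical.pixel_size_um)
            if st is None:
                continue
            clean[frame] += psf_contribution(optical, st, (h, w))
            rows.append((pid, frame, st.x, st.y, st.z_nm, st.amplitude, st.phase))
    np.clip(clean, 0.0, None, out=clean)

    clean_seq = ImageSequence(clean, frame_interval_ms, optical.pixel_size_um,
                              meta={"kind": "clean"})
    noisy = sample_shot_noise(clean_seq, noise, noise_rng)
    table = pd.DataFrame(rows, columns=list(GroundTruth.COLUMNS))
    return noisy, GroundTruth(table=table, clean=clean_seq)


def simulate_tethered_motion(
    contour_length_nm: float,
    diameter_nm: float,
    n_steps: int,
    step_sd_nm: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Reflected random walk of a tethered particle center.

    The center sits at height >= D/2 and within a sphere of radius D/2 + L
    around the surface anchor (tether attached to the particle surface), so
    the lateral excursion radius at the surface is sqrt((D/2 + L)^2 - (D/2)^2)
    and the bottom of the particle never rises above L.

    Returns an (n_steps, 3) array of (x_nm, y_nm, z_nm) where x, y are lateral
    center offsets from the anchor and z is the height of the particle's
    *bottom* above the surface.
    """
    if contour_length_nm < 0:
        raise ValueError("contour length must be >= 0")
    if diameter_nm <= 0:
        raise ValueError("diameter must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    r_half = diameter_nm / 2.0
    r_max = r_half + contour_length_nm
    center = np.array([0.0, 0.0, r_half])
    out = np.empty((n_steps, 3))
    steps = rng.normal(0.0, step_sd_nm, size=(n_steps, 3))
    for i in range(n_steps):
        center = center + steps[i]
        # reflect at the floor, then clamp into the tether sphere
        if center[2] < r_half:
            center[2] = 2.0 * r_half - center[2]
        if center[2] > r_max:
            center[2] = r_max
        lat = math.hypot(center[0], center[1])
        lat_max = math.sqrt(max(r_max**2 - center[2] ** 2, 0.0))
        if lat > lat_max:
            scale = lat_max / lat if lat > 0 else 0.0
            center[0] *= scale
            center[1] *= scale
        out[i] = (center[0], center[1], center[2] - r_half)
    return out


# ---------------------------------------------------------------------------
# Training data


def generate_training_pairs(
    n_pairs: int,
    n_frames: int = 8,
    shape: tuple[int, int] = (32, 32),
    optical: OpticalModel | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    amplitude_range: tuple[float, float] = (0.02, 0.3),
    moving_fraction: float = 0.5,
):
    """Synthetic (noisy differential, clean differential) training pairs.

    Half of the scenes hold the particle stationary and half let it drift,
    with amplitude and phase drawn at random.  Targets are the noiseless
    differential frames (the simulator's stand-in for a long frame average).

    Returns a list of ``(input, target)`` float32 array pairs of shape
    ``(n_frames, H, W)``.
    """
    optical = optical or OpticalModel()
    noise = noise or NoiseModel()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    h, w = shape
    pairs = []
    for i in range(n_pairs):
        scene = ParticleScene()
        amp = float(np.exp(rng.uniform(*np.log(amplitude_range))))
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        margin = 6
        x = float(rng.uniform(margin, w - 1 - margin))
        y = float(rng.uniform(margin, h - 1 - margin))
        state = ParticleState(x=x, y=y, amplitude=amp, phase=phase)
        if rng.random() < moving_fraction:
            # gentle drift across frames, scripted as a tether-free walk
            scene.add(state, EventSchedule("tether", {
                "contour_length_nm": 200.0,
                "step_sd_nm": 30.0,
            }))
        else:
            scene.add(state)
        noisy, gt = simulate_sequence(
            scene, optical, noise, n_frames, shape, rng.spawn(1)[0]
        )
        bg = optical.background_level
        pairs.append((
            (noisy.frames - bg).astype(np.float32),
            (gt.clean.frames - bg).astype(np.float32),
        ))
    return pairs
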