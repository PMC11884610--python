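"""Interferometric reconstruction and per-particle estimators.

Covers Richardson-Lucy deconvolution of the bipolar interference image,
5x5 amplitude measurement, SSIM-based phase estimation, sub-pixel Gaussian
localization, evanescent-decay axial inference, the tether-geometry
displacement bound, and binding-lifetime extraction.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import optimize, signal
from skimage.metrics import structural_similarity

from .analysis import DETECTION_LIMIT_DB
from .optics import OpticalModel, ParticleState, psf_contribution, render_psf

__all__ = [
    "PhaseEstimate",
    "BindingEvent",
    "peg_contour_length",
    "theoretical_dmax",
    "infer_z",
    "measure_amplitude",
    "make_rl_kernel",
    "richardson_lucy",
    "estimate_phase_ssim",
    "localize_xy",
    "extract_binding_events",
    "classify_binding_profile",
]

TWO_PI = 2.0 * math.pi

#: contour length per ethylene-oxide monomer (nm) and monomer molar mass (Da)
PEG_MONOMER_LENGTH_NM = 0.28
PEG_MONOMER_MASS_DA = 44.0


@dataclasses.dataclass
class PhaseEstimate:
    phi_hat: float
    ssim_max: float
    phi_grid: np.ndarray
    ssim_profile: np.ndarray


@dataclasses.dataclass
class BindingEvent:
    t1: int                  # first frame above threshold
    t2: int                  # first frame below threshold after t1
    censored: bool = False   # event still open at sequence end

    @property
    def dt(self) -> int:
        return self.t2 - self.t1


def peg_contour_length(molecular_weight_da: float) -> float:
    """Fully stretched PEG chain length: (MW / 44 Da) monomers x 0.28 nm."""
    if molecular_weight_da <= 0:
        raise ValueError("molecular weight must be > 0")
    return molecular_weight_da / PEG_MONOMER_MASS_DA * PEG_MONOMER_LENGTH_NM


def theoretical_dmax(
    diameter_nm: float, contour_length_nm: float
) -> tuple[float, float]:
    """Maximum center displacement of a tethered particle: (lateral, axial).

    Lateral bound is the chord 2*sqrt((D/2 + L)^2 - (D/2)^2); the axial bound
    equals the tether contour length L.
    """
    if diameter_nm <= 0 or contour_length_nm <= 0:
        raise ValueError("diameter and contour length must be > 0")
    r = diameter_nm / 2.0
    lateral = 2.0 * math.sqrt((r + contour_length_nm) ** 2 - r**2)
    return lateral, contour_length_nm


def infer_z(
    intensity: float, i0: float, decay_nm: float = 100.0
) -> float:
    """Height above the surface from I = I0 * exp(-z/d):  z = -d*ln(I/I0)."""
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    if i0 <= 0:
        raise ValueError("I0 must be > 0")
    if intensity > i0:
        warnings.warn("intensity exceeds I0; clamping to z = 0", stacklevel=2)
        return 0.0
    return -decay_nm * math.log(intensity / i0)


def measure_amplitude(image: np.ndarray, center_xy: tuple[float, float]) -> float:
    """Mean of the 5x5 pixel window centered on the particle's brightest point."""
    img = np.asarray(image, dtype=float)
    x, y = int(round(center_xy[0])), int(round(center_xy[1]))
    if not (2 <= x <= img.shape[1] - 3 and 2 <= y <= img.shape[0] - 3):
        raise ValueError(f"5x5 window at ({x}, {y}) clipped by image border")
    return float(img[y - 2:y + 3, x - 2:x + 3].mean())


# ---------------------------------------------------------------------------
# Richardson-Lucy


def make_rl_kernel(
    optical: OpticalModel, phase: float = 0.0, size: int | None = None
) -> np.ndarray:
    """Nonnegative unit-sum deconvolution kernel from the model PSF.

    The bipolar interference pattern is rendered at the given phase, flipped
    so its central lobe is positive, clipped to its positive part, and
    normalized to unit sum.
    """
    size = size or (2 * optical.psf_extent_px + 1)
    probe = ParticleState(x=(size - 1) / 2, y=(size - 1) / 2, amplitude=0.01,
                          phase=phase % TWO_PI)
    pattern = psf_contribution(optical, probe, (size, size))
    if math.cos(phase) < 0:
        pattern = -pattern
    pattern = np.clip(pattern, 0.0, None)
    total = pattern.sum()
    if total <= 0:
        raise ValueError("degenerate kernel")
    return pattern / total


def richardson_lucy(
    diff_image: np.ndarray,
    psf: np.ndarray,
    iterations: int = 30,
    phase: float | None = None,
    eps: float = 1e-12,
    return_flux: bool = False,
):
    """Multiplicative Richardson-Lucy deconvolution of a differential image.

    ``psf`` must be nonnegative and normalized to unit sum.  If ``phase`` is
    given, the image polarity is first matched (multiplied by the sign of
    cos(phase) so the central lobe is positive); the image is then shifted to
    nonnegativity, the standard updates

        u <- u * corr(psf, data / (psf (*) u))

    are run, and the baseline shift is removed from the estimate.  Iterates
    are nonnegative throughout and total flux is conserved per iteration up
    to boundary loss.
    """
    psf = np.asarray(psf, dtype=float)
    if np.any(psf < 0) or not math.isclose(psf.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("psf must be nonnegative and normalized to unit sum")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    img = np.asarray(diff_image, dtype=float)
    if phase is not None and math.cos(phase) < 0:
        img = -img
    shift = max(0.0, -float(img.min()))
    data = img + shift
    u = data.copy()
    psf_mirror = psf[::-1, ::-1]
    flux = []
    for _ in range(iterations):
        blurred = signal.fftconvolve(u, psf, mode="same")
        ratio = data / np.maximum(blurred, eps)
        u = u * signal.fftconvolve(ratio, psf_mirror, mode="same")
        np.clip(u, 0.0, None, out=u)
        flux.append(float(u.sum()))
    out = u - shift
    if return_flux:
        return out, np.asarray(flux)
    return out


# ---------------------------------------------------------------------------
# SSIM phase estimation


def estimate_phase_ssim(
    observed_crop: np.ndarray,
    optical: OpticalModel,
    amplitude: float,
    particle_xy: tuple[float, float] | None = None,
    n_grid: int = 64,
    z_nm: float = 0.0,
) -> PhaseEstimate:
    """Scattering phase by maximizing SSIM against model renderings.

    Model crops are rendered on a phase grid (default 64 points on [0, 2*pi))
    at the measured amplitude; the grid arg-max is refined by a parabolic fit
    on the circularly-extended SSIM profile.
    """
    obs = np.asarray(observed_crop, dtype=float)
    if obs.ndim != 2:
        raise ValueError("observed crop must be 2-D")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    if obs.max() == obs.min():
        raise ValueError("flat observed crop; SSIM undefined")
    h, w = obs.shape
    if particle_xy is None:
        particle_xy = ((w - 1) / 2.0, (h - 1) / 2.0)
    x, y = particle_xy

    data_range = float(obs.max() - obs.min())
    phi_grid = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
    win = min(7, h - (h + 1) % 2, w - (w + 1) % 2)
    scores = np.empty(n_grid)
    for i, phi in enumerate(phi_grid):
        model = render_psf(
            optical,
            ParticleState(x=x, y=y, z_nm=z_nm, amplitude=amplitude, phase=phi),
            (h, w),
        )
        scores[i] = structural_similarity(obs, model, data_range=data_range,
                                          win_size=win)
    k = int(np.argmax(scores))
    ym1, y0, yp1 = scores[k - 1], scores[k], scores[(k + 1) % n_grid]
    denom = ym1 - 2.0 * y0 + yp1
    offset = 0.5 * (ym1 - yp1) / denom if denom < 0 else 0.0
    step = TWO_PI / n_grid
    phi_hat = (phi_grid[k] + offset * step) % TWO_PI
    return PhaseEstimate(float(phi_hat), float(y0), phi_grid, scores)


# ---------------------------------------------------------------------------
# Localization


def _gauss2d(coords, amp, x0, y0, sx, sy, offset):
    x, y = coords
    return (
        amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2)))
        + offset
    )


def localize_xy(
    reconstructed: np.ndarray,
    approx_xy: tuple[float, float],
    window: int = 9,
    pixel_size_um: float | None = None,
) -> tuple[float, float]:
    """Sub-pixel spot center by 2-D Gaussian least-squares fitting.

    Fits a window around the local arg-max near ``approx_xy``.  Falls back to
    the intensity centroid (with a warning) if the fit does not converge.
    Returns pixel coordinates, or nm if ``pixel_size_um`` is given.
    """
    img = np.asarray(reconstructed, dtype=float)
    h, w = img.shape
    half = window // 2
    cx, cy = int(round(approx_xy[0])), int(round(approx_xy[1]))
    cx = min(max(cx, half), w - 1 - half)
    cy = min(max(cy, half), h - 1 - half)
    patch0 = img[cy - half:cy + half + 1, cx - half:cx + half + 1]
    dy, dx = np.unravel_index(np.argmax(patch0), patch0.shape)
    cx = min(max(cx - half + dx, half), w - 1 - half)
    cy = min(max(cy - half + dy, half), h - 1 - half)
    patch = img[cy - half:cy + half + 1, cx - half:cx + half + 1]

    yy, xx = np.mgrid[0:window, 0:window].astype(float)
    offset0 = float(patch.min())
    amp0 = float(patch.max() - offset0)
    p0 = (amp0 if amp0 > 0 else 1.0, float(half), float(half), 2.0, 2.0, offset0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d, (xx.ravel(), yy.ravel()), patch.ravel(), p0=p0, maxfev=2000
        )
        x_fit, y_fit = popt[1], popt[2]
        if not (0 <= x_fit < window and 0 <= y_fit < window):
            raise RuntimeError("fit outside window")
    except (RuntimeError, optimize.OptimizeWarning):
        warnings.warn("Gaussian fit failed; falling back to centroid", stacklevel=2)
        weights = np.clip(patch - offset0, 0.0, None)
        total = weights.sum()
        if total == 0:
            x_fit, y_fit = float(half), float(half)
        else:
            x_fit = float((weights * xx).sum() / total)
            y_fit = float((weights * yy).sum() / total)
    x_px = cx - half + x_fit
    y_px = cy - half + y_fit
    if pixel_size_um is not None:
        return x_px * pixel_size_um * 1e3, y_px * pixel_size_um * 1e3
    return x_px, y_px


# ---------------------------------------------------------------------------
# Binding events


def extract_binding_events(
    snr_series_db: np.ndarray,
    threshold_db: float = DETECTION_LIMIT_DB,
    hysteresis_db: float = 2.0,
    min_dwell_frames: int = 3,
) -> list[BindingEvent]:
    """On/off intervals of a per-frame SNR trace with threshold hysteresis.

    A binding event opens at the first frame whose SNR exceeds the threshold
    (t1) and closes at the first later frame falling below
    threshold - hysteresis (t2); the bound lifetime is t2 - t1.  Events
    shorter than ``min_dwell_frames`` are discarded; an event still open at
    the end of the trace is returned right-censored.
    """
    series = np.asarray(snr_series_db, dtype=float)
    if series.size <= min_dwell_frames:
        raise ValueError("series shorter than the minimum dwell")
    lo = threshold_db - hysteresis_db
    events: list[BindingEvent] = []
    on = False
    t1 = 0
    for t, v in enumerate(series):
        if not on and v >= threshold_db:
            on, t1 = True, t
        elif on and v < lo:
            on = False
            if t - t1 >= min_dwell_frames:
                events.append(BindingEvent(t1, t))
    if on and series.size - t1 >= min_dwell_frames:
        events.append(BindingEvent(t1, series.size, censored=True))
    return events


def classify_binding_profile(
    events: list[BindingEvent],
    frame_interval_ms: float = 2.0,
    long_dwell_s: float = 0.5,
    intermittent_min_events: int = 3,
) -> str:
    """'specific' (one long-lived event), 'nonspecific' (short-lived) or
    'intermittent' (repeated on/off, Brownian revisits)."""
    if not events:
        return "none"
    if len(events) >= intermittent_min_events:
        return "intermittent"
    longest_s = max(e.dt for e in events) * frame_interval_ms * 1e-3
    return "specific" if longest_s >= long_dwell_s else "nonspecific"
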