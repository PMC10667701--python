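"""Tube-orientation analysis of goal-block images via the 2-D FFT.

A square crop of the goal network is Hann-windowed and Fourier transformed;
each retained spectral bin contributes its direction angle (folded to
[0, 180) since the power spectrum is point symmetric) weighted by its power.
The characteristic angle of a frame is the mode of a weighted kernel density
over this angle distribution.  Spectral angles are orthogonal to the
physical tube direction, so a +90 deg correction is applied exactly once, at
reporting time.

Angles follow the package convention: measured from the +column axis toward
the +row axis, mod 180.  Network time t_n counts backward from the end of
the network-formation phase (t_n = 0); a day's final state pools the window
t_n in [-300, 0] min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import GrayImage, ImageStack

logger = logging.getLogger(__name__)

#: KDE evaluation grid step over [0, 180), degrees
GRID_STEP_DEG = 0.25
#: local maxima must reach this fraction of the global density maximum
PEAK_PROMINENCE_FRAC = 0.25
#: default tube-width scale (px) used to set the retained frequency band
DEFAULT_TUBE_WIDTH_SCALE_PX = 4.0


@dataclass(frozen=True)
class AngleDistribution:
    """Power-weighted orientation angles folded to [0, 180).

    ``empty`` flags a degenerate source image (no non-DC spectral power).
    """

    angles_deg: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=float) % 180.0
        w = np.asarray(self.weights, dtype=float)
        if a.shape != w.shape:
            raise ValueError("angles and weights must have the same shape")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "angles_deg", a)
        object.__setattr__(self, "weights", w)

    @property
    def empty(self) -> bool:
        return self.angles_deg.size == 0 or float(self.weights.sum()) == 0.0


@dataclass(frozen=True)
class CharacteristicAngleSeries:
    """Per-time-point peak angles: entries of (t_n, peak_angles, densities).

    Peaks are sorted by density, global mode first.
    """

    t_n: np.ndarray
    peak_angles_deg: tuple  # tuple of ndarray, one per time point
    peak_densities: tuple

    def __len__(self):
        return len(self.t_n)


def default_band(tube_width_scale_px: float = DEFAULT_TUBE_WIDTH_SCALE_PX) -> tuple[float, float]:
    """Retained radial frequency band in cycles/px.

    Keeps wavelengths between 1 and 8 tube widths: low enough to exclude the
    illumination envelope near DC, high enough to keep the band-limited
    ridge signal of Gaussian-profile tubes.
    """
    return 1.0 / (8.0 * tube_width_scale_px), 1.0 / tube_width_scale_px


def power_spectrum_angles(
    image: GrayImage,
    band: tuple[float, float] | None = None,
) -> AngleDistribution:
    """Power-weighted spectral angle distribution of a square crop.

    A Hann window suppresses edge-leakage anisotropy; DC and bins outside
    the radial band (cycles/px) are excluded.  A constant image yields an
    empty (flagged) distribution.
    """
    px = image.astype_float()
    rows, cols = px.shape
    if rows != cols:
        raise ValueError(f"square crop required, got {px.shape}")
    if rows < 64:
        raise ValueError(f"crop side must be >= 64 px, got {rows}")
    if np.ptp(px) == 0:
        return AngleDistribution(np.empty(0), np.empty(0))

    if band is None:
        band = default_band()
    f_lo, f_hi = band

    hann = np.hanning(rows)
    windowed = (px - px.mean()) * np.outer(hann, hann)
    spectrum = np.fft.fft2(windowed)
    power = np.abs(spectrum) ** 2

    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fr, fc)
    keep = (radius > max(f_lo, 1e-12)) & (radius <= f_hi)
    if not keep.any():
        return AngleDistribution(np.empty(0), np.empty(0))
    angles = np.degrees(np.arctan2(fr, fc)) % 180.0  # fold: point-symmetric spectrum
    return AngleDistribution(angles[keep], power[keep])


# ---------------------------------------------------------------------------
# Weighted circular KDE on [0, 180)


def _silverman_bandwidth(angles: np.ndarray, weights: np.ndarray) -> float:
    """Silverman's rule on a weighted sample (effective n = (Σw)²/Σw²)."""
    w = weights / weights.sum()
    mu = float(np.sum(w * angles))
    var = float(np.sum(w * (angles - mu) ** 2))
    sd = np.sqrt(var)
    order = np.argsort(angles)
    cw = np.cumsum(w[order])
    q1 = float(np.interp(0.25, cw, angles[order]))
    q3 = float(np.interp(0.75, cw, angles[order]))
    iqr = q3 - q1
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    neff = 1.0 / float(np.sum(w**2))
    return 0.9 * spread * neff ** (-0.2)


def angle_density(
    dist: AngleDistribution,
    bandwidth: float | None = None,
    grid_step: float = GRID_STEP_DEG,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted kernel density of the angle distribution on [0, 180).

    Implemented as a weighted histogram on a fine grid convolved with a
    wrapped Gaussian kernel (equivalent to replicating the data at ±180 deg,
    which emulates the periodic support).  Bandwidth defaults to Silverman's
    rule on the weighted sample.  Returns (grid_deg, density).
    """
    if dist.empty:
        raise ValueError("cannot estimate a density for an empty distribution")
    n_bins = int(round(180.0 / grid_step))
    grid = grid_step * np.arange(n_bins)
    hist, _ = np.histogram(
        dist.angles_deg, bins=n_bins, range=(0.0, 180.0), weights=dist.weights
    )
    if bandwidth is None:
        bandwidth = _silverman_bandwidth(dist.angles_deg, dist.weights)
    if bandwidth <= grid_step:  # degenerate spread: keep a minimal kernel
        bandwidth = grid_step
    half = int(np.ceil(4 * bandwidth / grid_step))
    kx = grid_step * np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (kx / bandwidth) ** 2)
    kernel /= kernel.sum()
    padded = np.concatenate([hist[-half:], hist, hist[:half]])  # wrap mod 180
    density = np.convolve(padded, kernel, mode="same")[half : half + n_bins]
    total = density.sum() * grid_step
    if total > 0:
        density = density / total
    return grid, density


#: accepted peaks closer than this (circular distance, deg) merge into the
#: strongest one; suppresses near-duplicate modes on noisy densities
PEAK_MERGE_DEG = 15.0


def characteristic_angle(
    dist: AngleDistribution,
    bandwidth: float | None = None,
    prominence_frac: float = PEAK_PROMINENCE_FRAC,
    merge_deg: float = PEAK_MERGE_DEG,
) -> tuple[np.ndarray, np.ndarray]:
    """Modes of the weighted angle density: (peak_angles_deg, peak_densities).

    All local maxima of the periodic density reaching ``prominence_frac`` of
    the global maximum are returned, sorted by density descending (ties
    toward the smaller angle); maxima within ``merge_deg`` of a stronger one
    are absorbed by it.
    """
    if dist.empty:
        raise ValueError("empty angle distribution has no characteristic angle")
    grid, density = angle_density(dist, bandwidth=bandwidth)
    up = density >= np.roll(density, 1)
    down = density > np.roll(density, -1)
    is_peak = up & down & (density >= prominence_frac * density.max())
    peaks = grid[is_peak]
    dens = density[is_peak]
    if peaks.size == 0:  # flat density: fall back to the global argmax
        k = int(np.argmax(density))
        peaks, dens = grid[[k]], density[[k]]
    order = np.lexsort((peaks, -dens))  # density desc, then smaller angle
    peaks, dens = peaks[order], dens[order]
    kept_a, kept_d = [], []
    for a, d in zip(peaks, dens):
        circ = np.array([min(abs(a - b), 180.0 - abs(a - b)) for b in kept_a])
        if kept_a and (circ < merge_deg).any():
            continue
        kept_a.append(a)
        kept_d.append(d)
    return np.asarray(kept_a), np.asarray(kept_d)


def tube_angle_from_spectral(angle_deg: float):
    """Convert a spectral angle to the physical tube orientation.

    Spectral angles are orthogonal to the tube direction, hence +90 mod 180.
    """
    return (np.asarray(angle_deg, dtype=float) + 90.0) % 180.0


def frame_tube_angles(
    image: GrayImage,
    band: tuple[float, float] | None = None,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Characteristic tube angles of one frame: spectrum -> mode -> +90 deg.

    The orthogonality correction is applied here, exactly once, and logged.
    """
    dist = power_spectrum_angles(image, band=band)
    if dist.empty:
        raise ValueError("degenerate (constant) frame: no spectral power")
    spectral, dens = characteristic_angle(dist, bandwidth=bandwidth)
    tube = tube_angle_from_spectral(spectral)
    logger.debug("orthogonality correction applied: spectral %s -> tube %s",
                 np.round(spectral, 2), np.round(tube, 2))
    return tube, dens


def orientation_time_course(
    goal_stack: ImageStack,
    network_times,
    band: tuple[float, float] | None = None,
    bandwidth: float | None = None,
) -> CharacteristicAngleSeries:
    """Per-frame characteristic tube angles over network time.

    ``network_times`` gives t_n (min, <= 0) for each frame.  Angles are
    reported in the tube frame, relative to the advancing direction
    (angle 0 = parallel to advance).
    """
    t_n = np.asarray(network_times, dtype=float)
    if len(goal_stack) == 0 or t_n.size == 0:
        raise ValueError("empty stack")
    if t_n.size != len(goal_stack):
        raise ValueError("network_times must match the stack length")
    peak_angles, peak_dens = [], []
    for k in range(len(goal_stack)):
        angles, dens = frame_tube_angles(goal_stack.frame(k), band=band,
                                         bandwidth=bandwidth)
        peak_angles.append(angles)
        peak_dens.append(dens)
    return CharacteristicAngleSeries(t_n, tuple(peak_angles), tuple(peak_dens))


def final_state_angles(
    series: CharacteristicAngleSeries,
    window: tuple[float, float] = (-300.0, 0.0),
    bandwidth: float | None = None,
) -> tuple[AngleDistribution, np.ndarray, np.ndarray]:
    """Pool peak angles over the final-state window and re-estimate peaks.

    Returns (pooled density-weighted distribution, day peak angles, their
    densities).  The day's characteristic angles are the modes of the pooled
    density.
    """
    lo, hi = window
    inside = (series.t_n >= lo) & (series.t_n <= hi)
    if not inside.any():
        raise ValueError(f"no series entries inside window [{lo}, {hi}]")
    angles = np.concatenate([series.peak_angles_deg[i] for i in np.flatnonzero(inside)])
    weights = np.concatenate([series.peak_densities[i] for i in np.flatnonzero(inside)])
    pooled = AngleDistribution(angles, weights)
    peaks, dens = characteristic_angle(pooled, bandwidth=bandwidth)
    return pooled, peaks, dens
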