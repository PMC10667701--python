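"""Synthetic microscopy generators with known ground truth.

Every analysis stage in this package was designed against undeposited raw
image data, so each stage has a matching generator here that emulates the
optical structure the analysis assumes — dark transport tubes on a bright
agar background, a plasmodial front advancing across an 18 x 18 mm bridge,
and blockwise-periodic thickness (intensity) oscillation — plus a study
table generator with configurable day x condition effects.

All generators are deterministic for a fixed seed, and the ground truth each
returns is recomputable from its spec alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import DEFAULT_PIXEL_SIZE_MM, GrayImage, ImageStack

# ---------------------------------------------------------------------------
# Tube networks


@dataclass(frozen=True)
class TubeNetworkSpec:
    """Parameters of a synthetic transport-tube network image.

    ``orientation_modes`` is a mixture of (angle_deg, weight) pairs: a tree
    network is a one-mode mixture (all tubes roughly parallel to the
    advancing direction), a mesh network a multi-mode one.  Tubes are
    rendered as anti-aliased segments with a Gaussian cross-section of
    FWHM ``tube_width_px``.
    """

    orientation_modes: tuple[tuple[float, float], ...] = ((20.0, 1.0),)
    n_tubes: int = 60
    tube_width_px: float = 4.0
    tube_darkness: float = 70.0
    image_size_px: tuple[int, int] = (256, 256)
    background_level: float = 200.0
    noise_sd: float = 3.0
    tube_length_frac: float = 0.75
    seed: int = 0

    def __post_init__(self):
        modes = tuple((float(a) % 180.0, float(w)) for a, w in self.orientation_modes)
        if not modes:
            raise ValueError("orientation_modes must be nonempty")
        if any(w <= 0 for _, w in modes):
            raise ValueError("orientation mode weights must be positive")
        if self.tube_width_px <= 0:
            raise ValueError("tube_width_px must be positive")
        if self.n_tubes < 0:
            raise ValueError("n_tubes must be nonnegative")
        if not (0 <= self.tube_darkness <= 255):
            raise ValueError("tube_darkness must lie in [0, 255]")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "orientation_modes", modes)


def _render_segment(canvas: np.ndarray, p0, p1, sigma: float, amplitude: float) -> None:
    """Accumulate a Gaussian-cross-section segment onto ``canvas``."""
    rows, cols = canvas.shape
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        return
    u = d / length
    pad = 3.0 * sigma + 1
    r_lo = max(int(np.floor(min(p0[0], p1[0]) - pad)), 0)
    r_hi = min(int(np.ceil(max(p0[0], p1[0]) + pad)) + 1, rows)
    c_lo = max(int(np.floor(min(p0[1], p1[1]) - pad)), 0)
    c_hi = min(int(np.ceil(max(p0[1], p1[1]) + pad)) + 1, cols)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    rel_r = rr - p0[0]
    rel_c = cc - p0[1]
    t = np.clip(rel_r * u[0] + rel_c * u[1], 0.0, length)  # projection onto segment
    dist2 = (rel_r - t * u[0]) ** 2 + (rel_c - t * u[1]) ** 2
    canvas[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(-dist2 / (2.0 * sigma**2))


def make_tube_network_image(spec: TubeNetworkSpec) -> tuple[GrayImage, np.ndarray]:
    """Render a tube-network image; returns (image, drawn tube angles in deg).

    Tube directions are drawn from the orientation mixture (each tube takes
    the angle of the mode it is assigned to), centers are uniform over the
    frame, and segment length is ``tube_length_frac`` of the short side.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size_px
    canvas = np.zeros((rows, cols), dtype=float)

    angles = np.array([a for a, _ in spec.orientation_modes])
    weights = np.array([w for _, w in spec.orientation_modes])
    weights = weights / weights.sum()
    idx = rng.choice(len(angles), size=spec.n_tubes, p=weights)
    drawn = angles[idx]

    sigma = spec.tube_width_px / 2.355  # FWHM -> Gaussian sigma
    half_len = 0.5 * spec.tube_length_frac * min(rows, cols)
    for ang in drawn:
        center = rng.uniform([0, 0], [rows, cols])
        rad = np.deg2rad(ang)
        u = np.array([np.sin(rad), np.cos(rad)])  # (d_row, d_col)
        _render_segment(canvas, center - half_len * u, center + half_len * u,
                        sigma, spec.tube_darkness)

    img = spec.background_level - np.clip(canvas, 0, spec.background_level)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(img, DEFAULT_PIXEL_SIZE_MM), drawn


def make_bridge_connection_image(
    n_spanning: int,
    image_size_px: tuple[int, int] = (288, 288),
    tube_width_px: float = 4.0,
    tube_darkness: float = 80.0,
    background_level: float = 200.0,
    noise_sd: float = 3.0,
    wiggle_px: float = 6.0,
    seed: int = 0,
) -> tuple[GrayImage, int]:
    """Render exactly ``n_spanning`` well-separated tubes spanning all rows.

    Fixture for start-goal connection counting: each tube runs from the
    entry edge (last row) to the far edge (row 0) at a distinct column, with
    a gentle sinusoidal wiggle.  Returns (image, n_spanning).
    """
    if n_spanning < 0:
        raise ValueError("n_spanning must be nonnegative")
    rng = np.random.default_rng(seed)
    rows, cols = image_size_px
    canvas = np.zeros((rows, cols), dtype=float)
    sigma = tube_width_px / 2.355
    if n_spanning > 0:
        margin = cols / (n_spanning + 1)
        centers = margin * (1 + np.arange(n_spanning)) + rng.uniform(
            -0.15 * margin, 0.15 * margin, n_spanning
        )
        rr = np.arange(rows)
        for c0 in centers:
            phase = rng.uniform(0, 2 * np.pi)
            cc = c0 + wiggle_px * np.sin(2 * np.pi * rr / rows + phase)
            for r in range(rows - 1):
                _render_segment(canvas, (r, cc[r]), (r + 1, cc[r + 1]),
                                sigma, tube_darkness)
    canvas = np.clip(canvas, 0, tube_darkness)
    img = background_level - np.clip(canvas, 0, background_level)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(img, DEFAULT_PIXEL_SIZE_MM), n_spanning


# ---------------------------------------------------------------------------
# Bridge-crossing movies


@dataclass(frozen=True)
class CrossingMovieSpec:
    """A plasmodial front advancing over an 18 x 18 mm bridge.

    ``footprint`` selects the shape the plasmodium leaves on the bridge:
    "string" (a narrow meandering path), "branched" (a string with side
    branches and a widening sheet near the front), or "sheet" (full-width
    coverage).  Crossing time te = bridge_length_mm / speed must be an
    integer number of frames.
    """

    speed_mm_per_min: float = 0.18
    bridge_length_mm: float = 18.0
    bridge_width_mm: float = 18.0
    footprint: str = "sheet"
    frame_interval_min: float = 5.0
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    background_level: float = 200.0
    front_darkness: float = 80.0
    noise_sd: float = 2.0
    string_width_px: int = 4
    blur_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.speed_mm_per_min <= 0:
            raise ValueError("speed_mm_per_min must be positive")
        if self.footprint not in ("string", "branched", "sheet"):
            raise ValueError(f"unknown footprint {self.footprint!r}")
        te = self.bridge_length_mm / self.speed_mm_per_min
        n = te / self.frame_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"crossing time {te} min is not an integer number of "
                f"{self.frame_interval_min}-min frames"
            )

    @property
    def te_min(self) -> float:
        return self.bridge_length_mm / self.speed_mm_per_min

    @property
    def n_frames(self) -> int:
        # one empty background frame, then te/interval + 1 crossing frames
        return int(round(self.te_min / self.frame_interval_min)) + 2


def _footprint_mask(spec: CrossingMovieSpec, rng: np.random.Generator) -> np.ndarray:
    rows = int(round(spec.bridge_length_mm / spec.pixel_size_mm))
    cols = int(round(spec.bridge_width_mm / spec.pixel_size_mm))
    mask = np.zeros((rows, cols), dtype=bool)
    if spec.footprint == "sheet":
        mask[:] = True
        return mask
    # meandering main path (rows traversed bottom -> top)
    w = spec.string_width_px
    c = cols // 2 + rng.integers(-cols // 8, cols // 8 + 1)
    for r in range(rows - 1, -1, -1):
        c = int(np.clip(c + rng.integers(-1, 2), w, cols - w - 1))
        mask[r, c - w // 2 : c - w // 2 + w] = True
    if spec.footprint == "branched":
        # short oblique side branches plus a widened sheet behind the tip
        path_cols = {r: np.flatnonzero(mask[r]).mean() for r in range(rows)}
        for _ in range(6):
            r = int(rng.integers(rows // 5, rows))
            c0 = path_cols[r]
            direction = rng.choice([-1, 1])
            length = int(rng.integers(rows // 10, rows // 4))
            for k in range(length):
                rr = r - k
                cc = int(c0 + direction * k)
                if 0 <= rr < rows and w <= cc < cols - w:
                    mask[rr, cc - w // 2 : cc - w // 2 + w] = True
        sheet_rows = slice(rows - rows // 4, rows)
        c_lo = int(max(min(path_cols[r] for r in range(rows - rows // 4, rows)) - cols // 8, 0))
        c_hi = int(min(max(path_cols[r] for r in range(rows - rows // 4, rows)) + cols // 8, cols))
        mask[sheet_rows, c_lo:c_hi] = True
    return mask


#: rows of footprint already on the bridge in the first crossing frame (the
#: tip that has just stepped on); keeps the start detectable above the
#: minimal-pixel guard on its very first frame
ENTRY_SLIVER_ROWS = 8


def make_crossing_movie(spec: CrossingMovieSpec) -> tuple[ImageStack, dict]:
    """Generate a bridge-crossing movie; the front advances linearly.

    Frame 0 is the empty bridge (the background reference).  Frame 1 shows
    the entry sliver of the footprint (the tip that has just stepped onto
    the bridge) and the front then advances linearly, touching the far edge
    (row 0) on the last frame.  The elapsed time between the first occupied
    frame and the far-edge frame is therefore exactly
    te = bridge_length / speed.

    Returns (stack, ground_truth) with ground_truth holding ``t0_min`` (0 by
    the stage-time convention), ``t0_frame``, ``te_min``, ``te_frame``,
    ``final_area_mm2``, ``n_foreground_px`` and the footprint mask.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _footprint_mask(spec, rng)
    rows, cols = mask.shape
    n = spec.n_frames - 2  # crossing spans n frame intervals
    from scipy import ndimage as ndi

    frames = np.empty((spec.n_frames, rows, cols), dtype=np.uint8)
    for k in range(spec.n_frames):
        img = np.full((rows, cols), spec.background_level, dtype=float)
        if k >= 1:
            front_row = int(round((rows - 1 - ENTRY_SLIVER_ROWS) * (1.0 - (k - 1) / n)))
            occupied = mask.copy()
            occupied[:front_row, :] = False
            img -= spec.front_darkness * occupied
        if spec.blur_sigma_px > 0:
            img = ndi.gaussian_filter(img, spec.blur_sigma_px)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = ImageStack(frames, spec.frame_interval_min, "min", spec.pixel_size_mm)
    truth = {
        "t0_min": 0.0,
        "t0_frame": 1,
        "te_min": spec.te_min,
        "te_frame": spec.n_frames - 1,
        "n_foreground_px": int(mask.sum()),
        "final_area_mm2": float(mask.sum()) * spec.pixel_size_mm**2,
        "footprint_mask": mask,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# Oscillation movies


@dataclass(frozen=True)
class OscillationMovieSpec:
    """Blockwise-periodic intensity oscillation over a 320 x 320 px ROI.

    ``period_field`` maps each 10 x 10-px block of a 32 x 32 grid to its
    oscillation period T in seconds (scalar = uniform field; a (32, 32)
    array programs regions).  Per-block intensity is
    baseline + amplitude * sin(2*pi*t/T) + noise.  Default periods follow
    the 60-200 s range of plasmodial thickness oscillation.
    """

    period_field: object = 100.0  # scalar or (grid, grid) array of seconds
    amplitude: float = 40.0
    baseline_level: float = 128.0
    frame_interval_s: float = 5.0
    duration_s: float = 600.0
    noise_sd: float = 0.0
    roi_px: int = 320
    block_px: int = 10
    seed: int = 0

    def __post_init__(self):
        n = self.duration_s / self.frame_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s must be divisible by frame_interval_s")
        if self.roi_px % self.block_px:
            raise ValueError("roi_px must be divisible by block_px")
        periods = self.periods()
        if self.amplitude > 0 and np.any(periods <= 2 * self.frame_interval_s):
            raise ValueError(
                "period_field values must exceed 2*frame_interval_s to be sampled"
            )
        if not (0 <= self.baseline_level - self.amplitude
                and self.baseline_level + self.amplitude <= 255):
            raise ValueError("baseline +/- amplitude must stay within [0, 255]")

    @property
    def grid(self) -> int:
        return self.roi_px // self.block_px

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s)) + 1

    def periods(self) -> np.ndarray:
        """Ground-truth (grid, grid) array of periods in seconds."""
        g = self.grid
        pf = np.asarray(self.period_field, dtype=float)
        if pf.ndim == 0:
            return np.full((g, g), float(pf))
        if pf.shape != (g, g):
            raise ValueError(f"period_field must be scalar or shape {(g, g)}")
        return pf


def make_oscillation_movie(spec: OscillationMovieSpec) -> tuple[ImageStack, np.ndarray]:
    """Generate a thickness-oscillation movie; returns (stack, period map).

    The ground-truth period map is ``spec.periods()`` (seconds per block).
    """
    rng = np.random.default_rng(spec.seed)
    periods = spec.periods()
    t = spec.frame_interval_s * np.arange(spec.n_frames)
    # per-block phase value, broadcast to pixels
    phase = 2.0 * np.pi * t[:, None, None] / periods[None, :, :]
    block_signal = spec.baseline_level + spec.amplitude * np.sin(phase)
    frames = np.repeat(np.repeat(block_signal, spec.block_px, axis=1),
                       spec.block_px, axis=2)
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
    frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    stack = ImageStack(frames, spec.frame_interval_s, "s", DEFAULT_PIXEL_SIZE_MM)
    return stack, periods


# ---------------------------------------------------------------------------
# Study tables


@dataclass(frozen=True)
class StudyTableSpec:
    """Per-sample index tables with configurable day x condition effects.

    ``day_slopes[condition][index]`` is the additive shift per elapsed day
    (mean on day d = baseline + slope * (d - 1)).  ``dispersion[index]`` is
    the between-sample SD (normal family) or SD of log values (lognormal).
    Defaults give plausible magnitudes for the three indices the stats stage
    consumes: bridge area (mm^2), crossing speed (mm/min) and oscillation
    angular frequency (rad/s).
    """

    n_per_cell: int = 15
    conditions: tuple[str, ...] = ("control", "quinine")
    days: tuple[int, ...] = (1, 2, 3, 4)
    baselines: dict = field(
        default_factory=lambda: {"area_mm2": 60.0, "speed": 0.12, "omega": 0.05}
    )
    day_slopes: dict = field(default_factory=dict)  # {cond: {index: per-day shift}}
    dispersion: dict = field(
        default_factory=lambda: {"area_mm2": 12.0, "speed": 0.025, "omega": 0.008}
    )
    family: str = "normal"
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 3:
            raise ValueError("n_per_cell must be >= 3 for multiple comparisons")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if any(v < 0 for v in self.dispersion.values()):
            raise ValueError("dispersion values must be nonnegative")

    def cell_mean(self, condition: str, day: int, index: str) -> float:
        slope = self.day_slopes.get(condition, {}).get(index, 0.0)
        return self.baselines[index] + slope * (day - 1)


def make_study_table(spec: StudyTableSpec) -> pd.DataFrame:
    """Draw one sample record per (condition, day, replicate).

    Returns a DataFrame with columns sample_id, condition, day and one
    column per index in ``spec.baselines``; bit-reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for cond in spec.conditions:
        for day in spec.days:
            for rep in range(spec.n_per_cell):
                rec = {
                    "sample_id": f"{cond}-d{day}-r{rep:02d}",
                    "condition": cond,
                    "day": day,
                }
                for index in spec.baselines:
                    mu = spec.cell_mean(cond, day, index)
                    sd = spec.dispersion[index]
                    if spec.family == "normal":
                        rec[index] = mu + sd * rng.standard_normal()
                    else:  # lognormal about mu with log-SD sd
                        rec[index] = mu * np.exp(sd * rng.standard_normal())
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    df.attrs["seed"] = spec.seed
    return df
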