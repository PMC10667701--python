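"""Blockwise thickness-oscillation frequency mapping of the start block.

A 10-min movie at 5-s intervals of the plasmodium on the start block is
reduced to 1024 block-mean intensity series (a 320 x 320-px region split
into 10 x 10-px blocks).  Each series is smoothed by locally-weighted
polynomial regression (lowess), oscillation periods are read off as the
times between successive peaks, the mode of the period distribution gives
the block period T, and the angular frequency is omega = 2*pi/T.  Blocks
whose frequency exceeds half the Nyquist frequency (f_n = 1/(2*dt) = 0.1 Hz
at 5-s sampling, a stricter-than-usual cutoff) are omitted as noise.  The
median over retained blocks summarizes the sample; quinine samples are
normalized by the same-day control median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .behavior import normalize_by_control
from .images import ImageStack

#: side of the analysis region, px
ROI_PX = 320
#: side of one averaging block, px
BLOCK_PX = 10
#: default lowess span as a fraction of the series (~60 s of a 10-min movie)
LOWESS_FRAC = 0.1
#: peak prominence as a fraction of the series interquartile range
PEAK_PROMINENCE_IQR_FRAC = 0.1


def nyquist_frequency_hz(frame_interval_s: float) -> float:
    """Nyquist frequency f_n = 1/(2*dt) in Hz (0.1 Hz at 5-s sampling)."""
    return 1.0 / (2.0 * frame_interval_s)


def omission_cutoff_rad_s(frame_interval_s: float) -> float:
    """Omission cutoff 2*pi*(f_n/2): half the Nyquist frequency, in rad/s."""
    return 2.0 * np.pi * (nyquist_frequency_hz(frame_interval_s) / 2.0)


@dataclass(frozen=True)
class GridTimeSeries:
    """Block-mean intensity series on a (grid, grid) block grid.

    ``series[i, j]`` is the full-length mean-intensity series of block
    (i, j); shape (grid, grid, n_frames).
    """

    series: np.ndarray
    frame_interval_s: float

    @property
    def grid(self) -> int:
        return self.series.shape[0]

    @property
    def n_frames(self) -> int:
        return self.series.shape[2]


@dataclass(frozen=True)
class OscillationMap:
    """Per-block period/frequency with omission bookkeeping.

    ``omega`` is NaN where a block was omitted; ``reason`` holds "" for
    retained blocks, else "no peaks" or "above half-Nyquist".
    """

    period_s: np.ndarray  # (grid, grid), NaN where omitted
    omega_rad_s: np.ndarray
    omitted: np.ndarray  # bool
    reason: np.ndarray  # object (str)
    frame_interval_s: float

    @property
    def n_retained(self) -> int:
        return int((~self.omitted).sum())

    def to_frame(self) -> pd.DataFrame:
        g = self.period_s.shape[0]
        rows, cols = np.divmod(np.arange(g * g), g)
        return pd.DataFrame(
            {
                "block_row": rows,
                "block_col": cols,
                "T_s": self.period_s.ravel(),
                "omega_rad_s": self.omega_rad_s.ravel(),
                "omitted": self.omitted.ravel(),
                "reason": self.reason.ravel(),
            }
        )


def grid_mean_series(
    stack: ImageStack,
    roi_origin: tuple[int, int] = (0, 0),
    roi_px: int = ROI_PX,
    block_px: int = BLOCK_PX,
) -> GridTimeSeries:
    """Mean intensity per 10 x 10-px block, per frame.

    ``roi_origin`` is the (row, col) of the ROI's upper-left corner.
    """
    if stack.time_unit != "s":
        raise ValueError("oscillation analysis expects a stack timed in seconds")
    if roi_px % block_px:
        raise ValueError("ROI side must be divisible by the block size")
    r0, c0 = roi_origin
    frames = np.asarray(stack.frames, dtype=float)
    if r0 < 0 or c0 < 0 or r0 + roi_px > frames.shape[1] or c0 + roi_px > frames.shape[2]:
        raise ValueError("ROI outside the frame bounds")
    roi = frames[:, r0 : r0 + roi_px, c0 : c0 + roi_px]
    g = roi_px // block_px
    blocks = roi.reshape(len(stack), g, block_px, g, block_px).mean(axis=(2, 4))
    return GridTimeSeries(np.moveaxis(blocks, 0, -1), stack.frame_interval)


def smooth_series(series, frac: float = LOWESS_FRAC) -> np.ndarray:
    """Locally-weighted polynomial regression (lowess) smoother.

    Returns the smoothed series at the original sample points; the default
    span (~60 s of a 10-min window) preserves 60-200-s oscillations while
    removing frame noise.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 10:
        raise ValueError("series too short to smooth (need >= 10 samples)")
    x = np.arange(y.size, dtype=float)
    return sm_lowess(y, x, frac=frac, return_sorted=False)


def peak_periods(series, frame_interval_s: float) -> np.ndarray:
    """Times (s) between successive local maxima of a smoothed series.

    Peaks need a prominence of at least 10% of the interquartile range;
    plateau peaks take their left edge.  Fewer than two peaks -> empty.
    """
    y = np.asarray(series, dtype=float)
    iqr = float(np.subtract(*np.percentile(y, [75, 25])))
    spread = iqr if iqr > 0 else float(np.ptp(y))  # sparse spikes: IQR is 0
    if spread == 0:
        return np.empty(0)
    prominence = PEAK_PROMINENCE_IQR_FRAC * spread
    idx, props = signal.find_peaks(y, prominence=prominence, plateau_size=1)
    # plateau peaks: find_peaks reports the plateau midpoint; take left edge
    idx = np.where(props["plateau_sizes"] > 1, props["left_edges"], idx)
    if idx.size < 2:
        return np.empty(0)
    return np.diff(idx) * frame_interval_s


def block_frequency(
    periods,
    frame_interval_s: float,
) -> tuple[float, float, bool, str]:
    """Mode-of-periods block summary: (T_s, omega_rad_s, omitted, reason).

    T is the mode of the period histogram (bin width = the frame interval;
    ties broken toward the longer period, conservative against the noise
    cutoff), omega = 2*pi/T.  Blocks above half the Nyquist frequency are
    omitted as noise, as are blocks with no period estimates.
    """
    periods = np.asarray(periods, dtype=float)
    if periods.size == 0:
        return np.nan, np.nan, True, "no peaks"
    # histogram with frame-interval bins, centered on multiples of dt
    k = np.rint(periods / frame_interval_s).astype(int)
    counts = np.bincount(k)
    best = counts.max()
    T = frame_interval_s * max(np.flatnonzero(counts == best))  # tie -> longer T
    omega = 2.0 * np.pi / T
    if omega > omission_cutoff_rad_s(frame_interval_s):
        return T, omega, True, "above half-Nyquist"
    return T, omega, False, ""


def oscillation_map(
    grid_series: GridTimeSeries,
    frac: float = LOWESS_FRAC,
) -> OscillationMap:
    """Smooth every block series, estimate periods, map omega per block."""
    g = grid_series.grid
    T = np.full((g, g), np.nan)
    omega = np.full((g, g), np.nan)
    omitted = np.zeros((g, g), dtype=bool)
    reason = np.full((g, g), "", dtype=object)
    dt = grid_series.frame_interval_s
    for i in range(g):
        for j in range(g):
            smoothed = smooth_series(grid_series.series[i, j], frac=frac)
            periods = peak_periods(smoothed, dt)
            T[i, j], omega[i, j], omitted[i, j], reason[i, j] = block_frequency(
                periods, dt
            )
    out = OscillationMap(T, omega, omitted, reason, dt)
    kept = out.omega_rad_s[~out.omitted]
    assert not kept.size or kept.max() <= omission_cutoff_rad_s(dt) + 1e-12
    return out


def sample_frequency(osc_map: OscillationMap) -> float:
    """Median angular frequency over retained blocks (rad/s)."""
    kept = osc_map.omega_rad_s[~osc_map.omitted]
    if kept.size == 0:
        raise ValueError("all blocks omitted; no sample frequency")
    return float(np.median(kept))


def normalize_frequency(values, control_values):
    """Normalize frequencies by the same-day control *median*."""
    return normalize_by_control(values, control_values, statistic="median")
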