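"""Behavioral indices: bridge area at crossing completion and crossing speed.

The plasmodium's response to a (possibly aversive) bridge is summarized by
two numbers per sample: the footprint area it leaves on the bridge at the
moment it finishes crossing, and the crossing speed
bridge_length / (te - t0).  Speeds are normalized by the same-day control
group statistic to compensate for day-to-day environmental drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

from .images import BridgeROI, GrayImage, ImageStack


class NotCrossedError(RuntimeError):
    """The plasmodial front never reached the far edge of the bridge."""


@dataclass(frozen=True)
class StageTimes:
    """Stage-time bookkeeping for one crossing.

    By convention the crossing starts at stage time t0 = 0; ``te_min`` is
    the elapsed minutes until the front touches the far (goal-side) edge.
    Frame indices of both events are retained for traceability.
    """

    te_min: float
    t0_frame: int = 0
    te_frame: int = 0
    t0_min: float = 0.0

    def __post_init__(self):
        if self.te_min <= self.t0_min:
            raise ValueError(f"te ({self.te_min}) must exceed t0 ({self.t0_min})")


#: minimum connected foreground pixels inside the ROI before the crossing
#: start is declared; suppresses noise-triggered starts
T0_GUARD_PX = 20


#: lower bound on the Otsu threshold for difference images, in intensity
#: units; keeps camera noise in signal-free frames from binarizing as
#: foreground (Otsu always splits *something*)
OTSU_FLOOR = 10.0


def _foreground(diff: np.ndarray, threshold_policy) -> np.ndarray:
    """Binarize an absolute-difference image.

    ``threshold_policy`` is "otsu" (default: Otsu's threshold, floored at
    :data:`OTSU_FLOOR`) or a fixed numeric threshold.
    """
    if threshold_policy is None or threshold_policy == "otsu":
        if np.ptp(diff) == 0:
            # constant difference: full coverage if it clears the noise floor
            return np.full(diff.shape, diff.flat[0] > OTSU_FLOOR, dtype=bool)
        thr = filters.threshold_otsu(diff)
        lo, hi = diff[diff <= thr], diff[diff > thr]
        if not lo.size or not hi.size or hi.mean() - lo.mean() < OTSU_FLOOR:
            # unimodal difference (all noise, uniform coverage, or a signal
            # too small for Otsu's class balance): fall back to the floor
            thr = OTSU_FLOOR
        else:
            thr = max(thr, OTSU_FLOOR)
    else:
        thr = float(threshold_policy)
    return diff > thr


def estimate_bridge_area(
    frame_at_te: GrayImage,
    frame_at_t0: GrayImage,
    roi: BridgeROI,
    threshold_policy="otsu",
) -> float:
    """Footprint area (mm^2) on the bridge at crossing completion.

    The background frame (at t0) is subtracted from the frame at te, the
    absolute difference is thresholded and binarized, and foreground pixels
    inside the ROI are counted and scaled by pixel_size^2.
    """
    if frame_at_te.shape != frame_at_t0.shape:
        raise ValueError("frames must have identical shapes")
    if frame_at_te.pixel_size_mm != frame_at_t0.pixel_size_mm:
        raise ValueError("frames must share pixel calibration")
    diff = np.abs(frame_at_te.astype_float() - frame_at_t0.astype_float())
    mask = _foreground(roi.crop(diff), threshold_policy)
    return int(mask.sum()) * frame_at_te.pixel_size_mm**2


def detect_crossing_times(
    stack: ImageStack,
    roi: BridgeROI,
    threshold_policy="otsu",
    background_frame: int = 0,
    guard_px: int = T0_GUARD_PX,
) -> StageTimes:
    """Detect the crossing start (t0) and completion (te) frames.

    t0 is the first frame whose foreground (vs the background frame) forms a
    connected component of at least ``guard_px`` pixels inside the ROI; te is
    the first frame whose foreground touches the far-edge row.  Raises
    :class:`NotCrossedError` if the front never reaches the far edge, and
    ``ValueError`` if the far edge is already occupied at t0 (degenerate
    te <= t0).
    """
    if stack.time_unit != "min":
        raise ValueError("crossing detection expects a stack timed in minutes")
    bg = roi.crop(np.asarray(stack.frames[background_frame], dtype=float))
    t0_frame = None
    te_frame = None
    for k in range(len(stack)):
        if k == background_frame:
            continue
        diff = np.abs(roi.crop(np.asarray(stack.frames[k], dtype=float)) - bg)
        fg = _foreground(diff, threshold_policy)
        if t0_frame is None:
            labels = measure.label(fg, connectivity=2)
            if labels.max() and np.bincount(labels.ravel())[1:].max() >= guard_px:
                t0_frame = k
            else:
                continue
        if fg[roi.far_row].any():
            te_frame = k
            break
    if t0_frame is None or te_frame is None:
        raise NotCrossedError("front never reached the far edge of the bridge")
    if te_frame <= t0_frame:
        raise ValueError(
            "far edge already occupied at the detected start (te <= t0); "
            "the stack does not cover the crossing event"
        )
    te_min = (te_frame - t0_frame) * stack.frame_interval
    return StageTimes(te_min=te_min, t0_frame=t0_frame, te_frame=te_frame)


def crossing_speed(bridge_length_mm: float, times: StageTimes) -> float:
    """Crossing speed in mm/min: bridge_length / (te - t0)."""
    dt = times.te_min - times.t0_min
    if dt <= 0:
        raise ValueError("te must exceed t0")
    return bridge_length_mm / dt


def normalize_by_control(values, control_values, statistic: str = "mean"):
    """Divide each value by the control group's mean (or median).

    Used to express quinine-bridge speeds relative to the same-day control
    samples; a control group normalized by itself has statistic exactly 1.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    if statistic == "mean":
        ref = control.mean()
    elif statistic == "median":
        ref = float(np.median(control))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if ref == 0:
        raise ValueError("control statistic is zero; cannot normalize")
    return np.asarray(values, dtype=float) / ref
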