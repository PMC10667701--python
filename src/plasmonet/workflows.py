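"""End-to-end conveniences combining the per-stage modules.

These are the entry points the CLI and batch scripts use: image(s) in,
per-sample indices and labels out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior, connection, morphology, orientation, oscillation
from .images import BridgeROI, GrayImage, ImageStack


def day_state_from_image(image: GrayImage, band=None, bandwidth=None) -> morphology.NetworkState:
    """Classify one day's final goal image as tree or mesh.

    FFT angle spectrum -> density modes -> orthogonality correction ->
    <45 deg parallel rule.
    """
    angles, _ = orientation.frame_tube_angles(image, band=band, bandwidth=bandwidth)
    return morphology.classify_network_state(angles)


def daily_type_from_images(images, band=None, bandwidth=None) -> int:
    """Classify a 4-day image sequence into daily-change Types 0-5."""
    states = [day_state_from_image(img, band=band, bandwidth=bandwidth) for img in images]
    return morphology.classify_daily_type(states)


def analyze_crossing(
    stack: ImageStack,
    roi: BridgeROI,
    bridge_length_mm: float = 18.0,
    threshold_policy="otsu",
) -> dict:
    """Crossing times, bridge area and speed for one behavioral movie."""
    times = behavior.detect_crossing_times(stack, roi, threshold_policy)
    area = behavior.estimate_bridge_area(
        stack.frame(times.te_frame), stack.frame(0), roi, threshold_policy
    )
    speed = behavior.crossing_speed(bridge_length_mm, times)
    return {
        "t0_frame": times.t0_frame,
        "te_frame": times.te_frame,
        "te_min": times.te_min,
        "area_mm2": area,
        "speed_mm_per_min": speed,
    }


def analyze_oscillation(
    stack: ImageStack,
    roi_origin: tuple[int, int] = (0, 0),
    roi_px: int | None = None,
    frac: float = oscillation.LOWESS_FRAC,
) -> tuple[oscillation.OscillationMap, float]:
    """Block frequency map and sample median for one oscillation movie.

    ``roi_px`` defaults to the standard 320-px region, shrunk to the frame
    (rounded down to a whole number of blocks) when the frame is smaller.
    """
    if roi_px is None:
        r0, c0 = roi_origin
        fit = min(oscillation.ROI_PX, stack.frame_shape[0] - r0,
                  stack.frame_shape[1] - c0)
        roi_px = (fit // oscillation.BLOCK_PX) * oscillation.BLOCK_PX
    grid = oscillation.grid_mean_series(stack, roi_origin, roi_px=roi_px)
    osc_map = oscillation.oscillation_map(grid, frac=frac)
    return osc_map, oscillation.sample_frequency(osc_map)


def classify_connection(
    image: GrayImage,
    roi: BridgeROI,
    threshold_policy="otsu",
    merge_distance_px: float = connection.DEFAULT_MERGE_DISTANCE_PX,
) -> connection.ConnectionType:
    """Start-goal connection type of one final network image."""
    return connection.count_bridge_connections(
        image, roi, threshold_policy, merge_distance_px
    )
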