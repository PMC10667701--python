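"""Start-goal connection typing from the final network image.

The tubes crossing the bridge at the end of network formation are counted:
no connection (n), single (s), double (d), or triple-and-above (t).  A
connection is a skeleton path spanning the whole bridge, from the entry
(start-side) boundary row to the far (goal-side) boundary row — plasmodium
merely sitting on the bridge without a spanning tube counts as n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology as skmorph

from .images import BridgeROI, GrayImage

#: spanning paths whose positions differ by less than this many pixels are
#: counted once (skeleton spurs at junctions would otherwise inflate counts);
#: default 3 x a typical 4-px tube width
DEFAULT_MERGE_DISTANCE_PX = 12.0

#: a skeleton component counts as reaching a boundary row when it comes
#: within this many pixels of it; skeletonization trims path endpoints so an
#: exact-touch test would miss genuine spanning tubes
BOUNDARY_MARGIN_PX = 4

#: minimum intensity separation between the Otsu classes for the split to be
#: treated as tubes-vs-background rather than camera noise
MIN_CLASS_CONTRAST = 20.0

_COUNT_TO_LABEL = {0: "n", 1: "s", 2: "d"}


@dataclass(frozen=True)
class ConnectionType:
    """Connection class label with the underlying spanning-tube count."""

    label: str  # n | s | d | t
    tube_count: int

    def __post_init__(self):
        expected = _COUNT_TO_LABEL.get(self.tube_count, "t")
        if self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with count {self.tube_count}"
            )


def label_for_count(count: int) -> ConnectionType:
    """Map a spanning-tube count to its class: 0->n, 1->s, 2->d, >=3->t."""
    if count < 0:
        raise ValueError("tube count must be nonnegative")
    return ConnectionType(_COUNT_TO_LABEL.get(count, "t"), count)


def _tube_mask(pixels: np.ndarray, threshold_policy) -> np.ndarray:
    """Binarize tubes as the minority intensity class.

    Tubes are dark on bright agar, but taking the minority class of an Otsu
    split makes the count invariant to image inversion and uniform
    brightness shifts.
    """
    if np.ptp(pixels) == 0:
        return np.zeros(pixels.shape, dtype=bool)
    if threshold_policy is None or threshold_policy == "otsu":
        thr = filters.threshold_otsu(pixels)
        dark = pixels < thr
        if dark.all() or (~dark).all():
            return np.zeros(pixels.shape, dtype=bool)
        if pixels[~dark].mean() - pixels[dark].mean() < MIN_CLASS_CONTRAST:
            return np.zeros(pixels.shape, dtype=bool)  # noise-only split
    else:
        dark = pixels < float(threshold_policy)
    return dark if dark.sum() <= dark.size / 2 else ~dark


def count_bridge_connections(
    final_image: GrayImage,
    bridge_roi: BridgeROI,
    threshold_policy="otsu",
    merge_distance_px: float = DEFAULT_MERGE_DISTANCE_PX,
) -> ConnectionType:
    """Count tubes spanning the bridge from start edge to goal edge.

    The tube mask inside the ROI is skeletonized; connected skeleton
    components touching both boundary rows each contribute one connection,
    with components whose boundary crossings lie within ``merge_distance_px``
    of a counted one merged into it.
    """
    bridge_roi.validate_within(final_image.shape)
    crop = bridge_roi.crop(final_image.astype_float())
    mask = _tube_mask(crop, threshold_policy)
    skeleton = skmorph.skeletonize(mask)
    labels = measure.label(skeleton, connectivity=2)
    far, entry = bridge_roi.far_row, bridge_roi.entry_row
    n_rows = mask.shape[0]
    m = BOUNDARY_MARGIN_PX

    def _band(row):  # rows within the boundary margin of a boundary row
        lo = max(row - m, 0)
        return slice(lo, min(row + m + 1, n_rows))

    crossings = []  # mean boundary-crossing column per spanning component
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        far_cols = np.flatnonzero(comp[_band(far)].any(axis=0))
        entry_cols = np.flatnonzero(comp[_band(entry)].any(axis=0))
        if far_cols.size and entry_cols.size:
            crossings.append(0.5 * (far_cols.mean() + entry_cols.mean()))
    count = 0
    counted: list[float] = []
    for c in sorted(crossings):
        if all(abs(c - c0) >= merge_distance_px for c0 in counted):
            count += 1
            counted.append(c)
    return label_for_count(count)


def connection_by_morphology(table: pd.DataFrame) -> pd.DataFrame:
    """Connection-type ratios per (condition, network state).

    ``table`` needs columns condition, network_state and connection_type;
    within each populated (condition, state) cell the ratios over
    {n, s, d, t} sum to 1.  Empty cells are simply absent.
    """
    required = {"condition", "network_state", "connection_type"}
    if missing := required - set(table.columns):
        raise ValueError(f"table missing columns: {sorted(missing)}")
    counts = table.groupby(["condition", "network_state", "connection_type"]).size()
    ratios = counts / counts.groupby(level=["condition", "network_state"]).transform("sum")
    return ratios.rename("ratio").reset_index()
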