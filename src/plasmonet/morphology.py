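"""Tree/mesh network classification and 4-day trajectory typing.

A day's final network is a *tree* when every characteristic tube angle is
approximately parallel (acute deviation < 45 deg) to the direction the
plasmodial tip advanced, and a *mesh* when any multidirectional (>= 45 deg)
component is present.  The 4-day state sequence of a sample is then typed:

    Type 0  tree, tree, tree, tree      (always parallel)
    Type 1  tree, tree, tree, mesh      (multidirection from Day 4)
    Type 2  tree, tree, mesh, mesh      (from Day 3)
    Type 3  tree, mesh, mesh, mesh      (from Day 2)
    Type 4  mesh, mesh, mesh, mesh      (always multidirection)
    Type 5  any other sequence

This replaces the original blindfolded manual classification with a
deterministic rule; evidence angles are retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: acute deviation (deg) from the advancing direction at and above which a
#: characteristic angle counts as multidirectional
MESH_ANGLE_DEG = 45.0

#: the five monotone tree->mesh sequences, Days 1-4 (True = tree)
_MONOTONE_TYPES = {
    (True, True, True, True): 0,
    (True, True, True, False): 1,
    (True, True, False, False): 2,
    (True, False, False, False): 3,
    (False, False, False, False): 4,
}


@dataclass(frozen=True)
class NetworkState:
    """Tree/mesh label with the evidence peak angles that produced it."""

    label: str  # "tree" | "mesh"
    evidence_angles_deg: tuple

    @property
    def is_tree(self) -> bool:
        return self.label == "tree"


def acute_deviation(angle_deg) -> np.ndarray:
    """Acute angle (deg, in [0, 90]) between an orientation and the
    advancing direction (angle 0)."""
    a = np.asarray(angle_deg, dtype=float) % 180.0
    return np.minimum(a, 180.0 - a)


def classify_network_state(peak_angles_deg) -> NetworkState:
    """Tree if every peak deviates < 45 deg from the advancing direction.

    Input angles are tube-frame angles in [0, 180) with the advancing
    direction at 0; a single peak at exactly 45 deg is already mesh.
    """
    peaks = np.atleast_1d(np.asarray(peak_angles_deg, dtype=float))
    if peaks.size == 0:
        raise ValueError("empty peak list")
    label = "tree" if bool(np.all(acute_deviation(peaks) < MESH_ANGLE_DEG)) else "mesh"
    return NetworkState(label, tuple(peaks.tolist()))


def classify_daily_type(states) -> int:
    """Map a 4-day (Days 1-4) tree/mesh sequence to its daily-change type."""
    if len(states) != 4:
        raise ValueError(f"exactly four daily states required, got {len(states)}")
    key = tuple(
        s.is_tree if isinstance(s, NetworkState) else (str(s).lower() == "tree")
        for s in states
    )
    return _MONOTONE_TYPES.get(key, 5)


def type_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Daily-change type frequencies as a ratio per condition.

    ``table`` needs one row per sample with columns ``condition`` and
    ``daily_type``; ratios sum to 1 within each condition.
    """
    if table.empty:
        raise ValueError("empty study table")
    counts = table.groupby(["condition", "daily_type"]).size()
    ratios = counts / counts.groupby(level="condition").transform("sum")
    return ratios.rename("ratio").reset_index()
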