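"""Calibrated grayscale image containers and basic I/O.

The raw observable throughout the package is an 8-bit transmitted-light
image (dark plasmodium / tubes on a bright agar background) with a known
physical pixel size, or an ordered stack of such frames with a known frame
interval.  Angles are measured in array coordinates, from the +column axis
toward the +row axis, and are reported mod 180 degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

#: default physical calibration, mm per pixel (mid-range of the 0.06-0.08
#: mm/px camera resolutions the analysis assumes)
DEFAULT_PIXEL_SIZE_MM = 0.0625


@dataclass(frozen=True)
class GrayImage:
    """A single calibrated 8-bit grayscale frame.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensities in [0, 255]; stored as given (uint8 or float).
    pixel_size_mm : float
        Physical size of one pixel edge, in mm.
    """

    pixels: np.ndarray
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got ndim={px.ndim}")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        lo, hi = float(px.min(initial=0)), float(px.max(initial=0))
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities outside [0, 255]: [{lo}, {hi}]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=float)


@dataclass(frozen=True)
class ImageStack:
    """An ordered sequence of same-shape frames at a fixed interval.

    ``frame_interval`` is expressed in ``time_unit`` ("min" for behavioral
    movies recorded every 5 min, "s" for 5-s oscillation movies).
    """

    frames: np.ndarray  # (n_frames, rows, cols)
    frame_interval: float
    time_unit: str = "min"
    pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM
    start_time: float = 0.0

    def __post_init__(self):
        fr = np.asarray(self.frames)
        if fr.ndim != 3:
            raise ValueError(f"ImageStack requires a 3-D array, got ndim={fr.ndim}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.time_unit not in ("min", "s"):
            raise ValueError(f"time_unit must be 'min' or 's', got {self.time_unit!r}")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        object.__setattr__(self, "frames", fr)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame(self, i: int) -> GrayImage:
        return GrayImage(self.frames[i], self.pixel_size_mm)

    def times(self) -> np.ndarray:
        """Acquisition time of each frame, in ``time_unit``."""
        n = len(self)
        return self.start_time + self.frame_interval * np.arange(n)


@dataclass(frozen=True)
class BridgeROI:
    """Rectangular region of interest in 0-based, half-open pixel coords.

    The far ("upper") edge is the ROI row adjacent to the goal block; the
    entry edge is adjacent to the start block.  ``far_edge`` selects which
    row index plays the goal-side role ("top" = ``r0``, "bottom" = ``r1-1``).
    """

    r0: int
    c0: int
    r1: int
    c1: int
    far_edge: str = "top"

    def __post_init__(self):
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValueError("ROI must be non-empty (r0<r1, c0<c1)")
        if self.far_edge not in ("top", "bottom"):
            raise ValueError("far_edge must be 'top' or 'bottom'")

    def validate_within(self, shape: tuple[int, int]) -> None:
        if self.r0 < 0 or self.c0 < 0 or self.r1 > shape[0] or self.c1 > shape[1]:
            raise ValueError(f"ROI {self} outside image bounds {shape}")

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        self.validate_within(pixels.shape[-2:])
        return pixels[..., self.r0 : self.r1, self.c0 : self.c1]

    @property
    def far_row(self) -> int:
        """Goal-side row index, in ROI-local coordinates."""
        return 0 if self.far_edge == "top" else (self.r1 - self.r0 - 1)

    @property
    def entry_row(self) -> int:
        return (self.r1 - self.r0 - 1) if self.far_edge == "top" else 0


def rotate_image(image: GrayImage, angle_deg: float, order: int = 1) -> GrayImage:
    """Rotate a frame so that directions at angle a map to a + angle_deg.

    Angles follow the package convention (from +columns toward +rows,
    mod 180).  ``scipy.ndimage.rotate`` rotates the opposite way in that
    convention, hence the sign flip.
    """
    rot = ndimage.rotate(
        image.astype_float(),
        -angle_deg,
        reshape=False,
        order=order,
        mode="constant",
        cval=float(np.median(image.pixels)),
    )
    return GrayImage(np.clip(rot, 0, 255), image.pixel_size_mm)


# ---------------------------------------------------------------------------
# I/O helpers: multi-page TIFF stacks with a JSON sidecar for calibration.

def write_stack(path: str | Path, stack: ImageStack, sidecar: dict | None = None) -> None:
    path = Path(path)
    frames = np.asarray(stack.frames)
    if frames.dtype != np.uint8:
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, frames)
    meta = {
        "frame_interval": stack.frame_interval,
        "time_unit": stack.time_unit,
        "pixel_size_mm": stack.pixel_size_mm,
        "start_time": stack.start_time,
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_stack(
    path: str | Path,
    frame_interval: float | None = None,
    time_unit: str | None = None,
    pixel_size_mm: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF stack; sidecar JSON supplies calibration unless
    overridden by keyword arguments."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImageStack(
        frames=frames,
        frame_interval=frame_interval or meta.get("frame_interval", 1.0),
        time_unit=time_unit or meta.get("time_unit", "min"),
        pixel_size_mm=pixel_size_mm or meta.get("pixel_size_mm", DEFAULT_PIXEL_SIZE_MM),
        start_time=meta.get("start_time", 0.0),
    )


def write_image(path: str | Path, image: GrayImage) -> None:
    px = np.clip(np.rint(np.asarray(image.pixels, dtype=float)), 0, 255).astype(np.uint8)
    tifffile.imwrite(Path(path), px)


def read_image(path: str | Path, pixel_size_mm: float = DEFAULT_PIXEL_SIZE_MM) -> GrayImage:
    import imageio.v3 as iio

    px = iio.imread(Path(path))
    if px.ndim == 3:  # collapse RGB(A) to gray
        px = px[..., :3].mean(axis=-1)
    return GrayImage(px, pixel_size_mm)
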