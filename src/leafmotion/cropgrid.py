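"""Image-stack loading and grid-based per-plant cropping.

A camera frame typically contains many seedlings.  A fixed grid of named
rectangles — drawn once against the first and last frame so each plant
stays inside its cell for the whole series — splits the stack into
per-plant sub-stacks that the motion tracker consumes.  Crops are
pixel-exact array slices; no resampling ever happens here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ImageStack", "GridCell", "GridSpec", "load_stack", "crop_stack"]

#: Default minimum pixels per crop cell (100 x 100 px per plant).
DEFAULT_MIN_CELL_PIXELS = 10_000

#: Standard luminance weights for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


@dataclass(frozen=True)
class ImageStack:
    """An ordered grayscale frame sequence with a uniform frame interval.

    ``frames`` is a (n_frames, height, width) float array with intensities
    in [0, 1]; ``source_ids`` records per-frame provenance (filenames for
    loaded stacks, synthetic labels otherwise).
    """

    frames: np.ndarray
    sampling_interval: float  # minutes
    source_ids: list[str]

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if len(self.source_ids) != frames.shape[0]:
            raise ValueError("source_ids length must match frame count")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class GridCell:
    """One named crop rectangle, half-open [x_min, x_min+width) x
    [y_min, y_min+height), 0-based, x right / y down."""

    plant_id: str
    x_min: int
    y_min: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"cell {self.plant_id!r}: width/height must be positive")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"cell {self.plant_id!r}: origin must be non-negative")


@dataclass(frozen=True)
class GridSpec:
    """A set of uniquely named crop rectangles.

    ``min_cell_pixels`` enforces a minimum per-plant area (default 10,000
    px, i.e. 100 x 100); pass a smaller value for deliberately tiny crops.
    """

    cells: tuple[GridCell, ...]
    min_cell_pixels: int = DEFAULT_MIN_CELL_PIXELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        ids = [c.plant_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate plant_ids in grid: {dupes}")
        for c in self.cells:
            if c.width * c.height < self.min_cell_pixels:
                raise ValueError(
                    f"cell {c.plant_id!r} area {c.width * c.height} px is below "
                    f"the minimum of {self.min_cell_pixels} px"
                )

    @classmethod
    def from_csv(cls, path: str | Path, min_cell_pixels: int = DEFAULT_MIN_CELL_PIXELS) -> "GridSpec":
        """Read a grid file with header plant_id,x_min,y_min,width,height."""
        cells = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"plant_id", "x_min", "y_min", "width", "height"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected header {sorted(required)}")
            for row in reader:
                cells.append(
                    GridCell(
                        plant_id=row["plant_id"],
                        x_min=int(row["x_min"]),
                        y_min=int(row["y_min"]),
                        width=int(row["width"]),
                        height=int(row["height"]),
                    )
                )
        return cls(tuple(cells), min_cell_pixels)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["plant_id", "x_min", "y_min", "width", "height"])
            for c in self.cells:
                writer.writerow([c.plant_id, c.x_min, c.y_min, c.width, c.height])


def _to_grayscale_unit(img: np.ndarray, name: str) -> np.ndarray:
    """Convert a loaded image to float grayscale in [0, 1]."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] != 3:
            raise ValueError(f"{name}: unsupported channel count {arr.shape[2]}")
        arr = arr.astype(float) @ _LUMA
        if np.issubdtype(np.asarray(img).dtype, np.integer):
            arr /= np.iinfo(np.asarray(img).dtype).max
        return arr
    if arr.ndim != 2:
        raise ValueError(f"{name}: expected a 2-D or 3-D image, got ndim={arr.ndim}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def load_stack(directory: str | Path, sampling_interval: float) -> ImageStack:
    """Load an ordered frame directory into an :class:`ImageStack`.

    Frames are taken in sorted-filename order (filenames must sort
    chronologically), converted to grayscale and normalized to [0, 1].
    """
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if len(paths) < 2:
        raise ValueError(
            f"{directory}: need at least 2 image frames, found {len(paths)}"
        )
    frames = []
    shape: tuple[int, int] | None = None
    for p in paths:
        try:
            raw = iio.imread(p)
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise ValueError(f"unreadable image file: {p}") from exc
        gray = _to_grayscale_unit(raw, str(p))
        if shape is None:
            shape = gray.shape
        elif gray.shape != shape:
            raise ValueError(
                f"frame dimension mismatch: {p.name} is {gray.shape}, "
                f"expected {shape} (from {paths[0].name})"
            )
        frames.append(gray)
    return ImageStack(np.stack(frames), sampling_interval, [p.name for p in paths])


def crop_stack(stack: ImageStack, grid: GridSpec) -> dict[str, ImageStack]:
    """Crop a stack into per-plant sub-stacks, one per grid cell.

    Every sub-frame is the pixel-exact rectangle of the parent frame; frame
    count and interval are inherited.  Rectangles must lie fully inside the
    frame (checked against the stack's dimensions — draw cells against both
    the first and last frame so the plant never leaves its cell).
    """
    h, w = stack.frame_shape
    out: dict[str, ImageStack] = {}
    for cell in grid.cells:
        if cell.x_min + cell.width > w or cell.y_min + cell.height > h:
            raise ValueError(
                f"cell {cell.plant_id!r} ({cell.x_min},{cell.y_min},"
                f"{cell.width}x{cell.height}) extends outside the "
                f"{h}x{w} frame"
            )
        sub = stack.frames[
            :, cell.y_min : cell.y_min + cell.height, cell.x_min : cell.x_min + cell.width
        ].copy()
        out[cell.plant_id] = ImageStack(sub, stack.sampling_interval, list(stack.source_ids))
    return out
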