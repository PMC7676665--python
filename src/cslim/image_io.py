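"""Image containers and file I/O for the cSLIM pipeline.

Raw data arrive as four co-registered RGB interferograms per field of view,
acquired at phase shifts 0, π/2, π and 3π/2; the unshifted frame is the
ordinary stained brightfield image. Quantitative maps (phase in radians,
dry-mass surface density in pg/μm²) travel as 32-bit float single-channel
TIFFs with their units and pixel pitch stored in the image description.

Conventions: 0-based row-major (row, col) coordinates; physical positions are
pixel centers; channel values are normalized to [0, 1] by the source
bit-depth maximum (not per-image max), so color weighting stays comparable
across slides.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import GridError, ShapeError, ValidationError

#: Default sampling density of the microscope, pixels per micron.
DEFAULT_PIXEL_PITCH = 7.2

#: Phase shifts of the four interferogram frames, radians.
PHASE_SHIFTS = (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)

VALID_UNITS = ("radians", "pg_per_um2", "dimensionless")


@dataclass(frozen=True)
class RgbFrame:
    """One RGB image with channels in [0, 1] and a physical pixel pitch."""

    pixels: np.ndarray  # (H, W, 3) float64
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ShapeError(f"RGB frame must be (H, W, 3), got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ShapeError("empty image")
        if not np.isfinite(px).all():
            raise ValidationError("RGB frame contains non-finite values")
        if px.min() < 0 or px.max() > 1:
            raise ValidationError("RGB channel values must lie in [0, 1]")
        if not self.pixel_pitch > 0:
            raise ValidationError("pixel_pitch must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class InterferogramStack:
    """The four phase-shifted RGB frames of one field of view.

    ``frames[0]`` is the unshifted frame, i.e. the standard brightfield image
    of the stained section.
    """

    frames: tuple[RgbFrame, RgbFrame, RgbFrame, RgbFrame]
    field_id: str = ""
    shifts: tuple[float, float, float, float] = PHASE_SHIFTS

    def __post_init__(self) -> None:
        if len(self.frames) != 4:
            raise ShapeError(f"need exactly 4 frames, got {len(self.frames)}")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) != 1:
            raise ShapeError(f"frames differ in shape: {sorted(shapes)}")
        for m, s in enumerate(self.shifts):
            if abs(s - m * math.pi / 2) > 1e-12:
                raise ValidationError("shifts must be m·π/2 for m = 0..3")
        object.__setattr__(self, "frames", tuple(self.frames))

    @property
    def brightfield(self) -> RgbFrame:
        return self.frames[0]

    @property
    def pixel_pitch(self) -> float:
        return self.frames[0].pixel_pitch


@dataclass(frozen=True)
class QuantMap:
    """A 2D quantitative map: phase (radians), density (pg/μm²) or unitless."""

    values: np.ndarray  # (H, W) float64
    units: str
    pixel_pitch: float = DEFAULT_PIXEL_PITCH

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ShapeError(f"map must be 2D and non-empty, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValidationError("map contains NaN or Inf")
        if self.units not in VALID_UNITS:
            raise ValidationError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if not self.pixel_pitch > 0:
            raise ValidationError("pixel_pitch must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, units: str | None = None) -> "QuantMap":
        return replace(self, values=values, units=units or self.units)


@dataclass(frozen=True)
class TileGrid:
    """Row-major mosaic layout: ``rows × cols`` tiles with a fixed overlap."""

    rows: int
    cols: int
    tile_order: tuple[str, ...] = ()
    overlap_px: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise GridError("grid must have at least one row and column")
        if self.overlap_px < 0:
            raise GridError("overlap_px must be >= 0")
        if self.tile_order and len(self.tile_order) != self.rows * self.cols:
            raise GridError(
                f"tile_order has {len(self.tile_order)} entries, "
                f"grid holds {self.rows * self.cols}"
            )
        object.__setattr__(self, "tile_order", tuple(self.tile_order))


def _bit_depth_max(arr: np.ndarray) -> float:
    if arr.dtype == np.uint8:
        return 255.0
    if arr.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return 1.0
    raise ValidationError(f"unsupported image dtype {arr.dtype}")


def read_rgb_frame(path: Union[str, Path], pixel_pitch: float = DEFAULT_PIXEL_PITCH) -> RgbFrame:
    """Read one RGB image, normalizing channels by the bit-depth maximum."""
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ShapeError(
            f"{path}: expected an RGB image with 3 channels, got shape {arr.shape}"
        )
    scale = _bit_depth_max(arr)
    return RgbFrame(np.clip(arr.astype(np.float64) / scale, 0.0, 1.0), pixel_pitch)


def read_interferogram_stack(
    paths: Sequence[Union[str, Path]],
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    field_id: str = "",
) -> InterferogramStack:
    """Read the 4 phase-shifted frames of one field, in shift order 0..3π/2.

    Each file is normalized by its own bit-depth maximum, so mixing 8- and
    16-bit acquisitions is allowed as long as dimensions agree.
    """
    if len(paths) != 4:
        raise ShapeError(f"an interferogram stack needs 4 files, got {len(paths)}")
    frames = tuple(read_rgb_frame(p, pixel_pitch) for p in paths)
    return InterferogramStack(frames, field_id=field_id)


def write_rgb_frame(frame: RgbFrame, path: Union[str, Path], bit_depth: int = 16) -> None:
    """Write an RGB frame as an 8- or 16-bit TIFF."""
    if bit_depth == 16:
        data = np.round(frame.pixels * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        data = np.round(frame.pixels * 255.0).astype(np.uint8)
    else:
        raise ValidationError("bit_depth must be 8 or 16")
    tifffile.imwrite(str(path), data, photometric="rgb")


def write_quant_map(qmap: QuantMap, path: Union[str, Path]) -> None:
    """Write a map as 32-bit float TIFF with units/pixel_pitch in the description."""
    meta = json.dumps({"units": qmap.units, "pixel_pitch": qmap.pixel_pitch})
    tifffile.imwrite(
        str(path),
        qmap.values.astype(np.float32),
        photometric="minisblack",
        description=meta,
    )


def read_quant_map(path: Union[str, Path]) -> QuantMap:
    """Read a 32-bit float map written by :func:`write_quant_map`.

    Missing metadata degrades gracefully: a warning is issued and the map is
    tagged dimensionless at the default pixel pitch.
    """
    with tifffile.TiffFile(str(path)) as tif:
        values = tif.pages[0].asarray()
        desc = tif.pages[0].description
    units, pitch = "dimensionless", DEFAULT_PIXEL_PITCH
    try:
        meta = json.loads(desc)
        units = meta["units"]
        pitch = float(meta["pixel_pitch"])
    except (json.JSONDecodeError, KeyError, TypeError):
        warnings.warn(f"{path}: no units/pixel_pitch metadata; assuming dimensionless")
    return QuantMap(np.asarray(values, dtype=np.float64), units=units, pixel_pitch=pitch)


def _stitch_arrays(tiles: list[np.ndarray], grid: TileGrid) -> np.ndarray:
    if len(tiles) != grid.rows * grid.cols:
        raise GridError(f"grid expects {grid.rows * grid.cols} tiles, got {len(tiles)}")
    shapes = {t.shape for t in tiles}
    if len(shapes) != 1:
        raise ShapeError("all tiles must share dimensions")
    h, w = tiles[0].shape[:2]
    ov = grid.overlap_px
    if ov >= h or ov >= w:
        raise GridError("overlap_px must be smaller than the tile dimensions")
    out_h = grid.rows * (h - ov) + ov
    out_w = grid.cols * (w - ov) + ov
    out = np.zeros((out_h, out_w) + tiles[0].shape[2:], dtype=tiles[0].dtype)
    for i, tile in enumerate(tiles):
        r, c = divmod(i, grid.cols)
        r0, c0 = r * (h - ov), c * (w - ov)
        # later tiles overwrite earlier ones in overlap zones; no blending
        out[r0 : r0 + h, c0 : c0 + w] = tile
    return out


def stitch_grid(
    tiles: Sequence[Union[QuantMap, RgbFrame]], grid: TileGrid
) -> Union[QuantMap, RgbFrame]:
    """Assemble tiles into a mosaic, row-major, overwrite-on-overlap."""
    if not tiles:
        raise GridError("no tiles given")
    if isinstance(tiles[0], QuantMap):
        units = {t.units for t in tiles}
        if len(units) != 1:
            raise ValidationError("tiles carry mixed units")
        arr = _stitch_arrays([t.values for t in tiles], grid)
        return QuantMap(arr, units=tiles[0].units, pixel_pitch=tiles[0].pixel_pitch)
    arr = _stitch_arrays([t.pixels for t in tiles], grid)
    return RgbFrame(arr, pixel_pitch=tiles[0].pixel_pitch)
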