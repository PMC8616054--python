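"""Partition micrographs into a fixed tile grid and filter tiles.

The featurization pipeline consumes fixed-size tiles rather than whole
frames: each frame is split losslessly into a ``grid_rows x grid_cols``
grid (default 10 x 12, i.e. 120 tiles of 104 x 120 x 3 per frame), and
tiles that carry no fiber signal ("empty") or are saturated with signal
("over-dense") are removed before training.  The fiber signal lives in
the green channel by staining convention; a tile's *fiber fraction* is
the proportion of green-channel pixels at or above an intensity
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from matriscope.synthetic import FiberImage

DEFAULT_GRID = (10, 12)
DEFAULT_TILE_SHAPE = (104, 120)

#: default tile-filter settings: below ``min_fiber_fraction`` a tile is
#: background only; above ``max_fiber_fraction`` it is saturated signal
DEFAULT_MIN_FIBER_FRACTION = 0.01
DEFAULT_MAX_FIBER_FRACTION = 0.60
DEFAULT_INTENSITY_THRESHOLD = 0.1


@dataclass
class Tile:
    """One grid cell of a source image, with provenance."""

    pixels: np.ndarray  # (tile_h, tile_w, 3) in [0, 1]
    source_image_id: str
    row: int
    col: int
    class_label: str = "unlabeled"

    @property
    def tile_id(self) -> str:
        return f"{self.source_image_id}:r{self.row:02d}c{self.col:02d}"


@dataclass
class TileSet:
    """Ordered tiles (row-major within image, images in input order)."""

    tiles: list[Tile]
    grid_rows: int
    grid_cols: int
    #: one row per tile seen by the last operation: tile_id, provenance,
    #: fiber_fraction (NaN before filtering), kept flag and drop reason
    filter_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.tiles)

    def pixel_array(self) -> np.ndarray:
        """Stack tiles into an (n, tile_h, tile_w, 3) float32 array."""
        return np.stack([t.pixels for t in self.tiles]).astype(np.float32)

    def labels(self) -> np.ndarray:
        return np.array([t.class_label for t in self.tiles])

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "tile_id": t.tile_id,
                "source_image_id": t.source_image_id,
                "row": t.row,
                "col": t.col,
                "class_label": t.class_label,
            }
            for t in self.tiles
        ]
        return pd.DataFrame(rows)


def _base_report(tiles: list[Tile]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "tile_id": [t.tile_id for t in tiles],
            "source_image_id": [t.source_image_id for t in tiles],
            "row": [t.row for t in tiles],
            "col": [t.col for t in tiles],
            "class_label": [t.class_label for t in tiles],
        }
    )
    df["fiber_fraction"] = np.nan
    df["kept"] = True
    df["reason"] = ""
    return df


def tile_image(
    image: FiberImage,
    grid_rows: int = DEFAULT_GRID[0],
    grid_cols: int = DEFAULT_GRID[1],
    tile_shape: tuple[int, int] | None = None,
) -> TileSet:
    """Split one image into a lossless row-major grid of tiles.

    Dimensions must divide exactly — images are rejected rather than
    silently cropped.  If ``tile_shape`` is given, the resulting tile
    dimensions must match it.
    """
    h, w, _ = image.pixels.shape
    if h % grid_rows or w % grid_cols:
        raise ValueError(
            f"image height {h} and width {w} must be divisible by the "
            f"{grid_rows}x{grid_cols} grid (tile would be "
            f"{h / grid_rows:g}x{w / grid_cols:g})"
        )
    th, tw = h // grid_rows, w // grid_cols
    if tile_shape is not None and (th, tw) != tuple(tile_shape):
        raise ValueError(
            f"grid {grid_rows}x{grid_cols} on {h}x{w} gives {th}x{tw} tiles, "
            f"expected {tile_shape[0]}x{tile_shape[1]}"
        )
    tiles = [
        Tile(
            pixels=image.pixels[r * th : (r + 1) * th, c * tw : (c + 1) * tw],
            source_image_id=image.image_id,
            row=r,
            col=c,
            class_label=image.class_label,
        )
        for r in range(grid_rows)
        for c in range(grid_cols)
    ]
    ts = TileSet(tiles=tiles, grid_rows=grid_rows, grid_cols=grid_cols)
    ts.filter_report = _base_report(tiles)
    return ts


def tile_images(
    images: list[FiberImage],
    grid_rows: int = DEFAULT_GRID[0],
    grid_cols: int = DEFAULT_GRID[1],
    tile_shape: tuple[int, int] | None = None,
) -> TileSet:
    """Tile many images into one TileSet, preserving input order."""
    tiles: list[Tile] = []
    for img in images:
        tiles.extend(tile_image(img, grid_rows, grid_cols, tile_shape).tiles)
    ts = TileSet(tiles=tiles, grid_rows=grid_rows, grid_cols=grid_cols)
    ts.filter_report = _base_report(tiles)
    return ts


def reassemble(tileset: TileSet, source_image_id: str) -> np.ndarray:
    """Stitch one image's tiles back into a full frame (inverse of tiling)."""
    tiles = [t for t in tileset.tiles if t.source_image_id == source_image_id]
    if not tiles:
        raise ValueError(f"no tiles from image {source_image_id!r}")
    th, tw, ch = tiles[0].pixels.shape
    out = np.zeros((tileset.grid_rows * th, tileset.grid_cols * tw, ch),
                   dtype=tiles[0].pixels.dtype)
    for t in tiles:
        out[t.row * th : (t.row + 1) * th, t.col * tw : (t.col + 1) * tw] = t.pixels
    return out


def fiber_fraction(pixels: np.ndarray, intensity_threshold: float) -> float:
    """Proportion of green-channel pixels at or above the threshold."""
    return float(np.mean(pixels[:, :, 1] >= intensity_threshold))


def filter_tiles(
    tileset: TileSet,
    min_fiber_fraction: float = DEFAULT_MIN_FIBER_FRACTION,
    max_fiber_fraction: float = DEFAULT_MAX_FIBER_FRACTION,
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
) -> TileSet:
    """Drop uninformative ("empty") and saturated ("over-dense") tiles.

    A tile is kept iff ``min_fiber_fraction <= fiber fraction <=
    max_fiber_fraction``.  Survivor order is preserved and the returned
    set's ``filter_report`` covers every input tile with its fraction,
    keep flag, and drop reason.  Filtering is idempotent.
    """
    if not tileset.tiles:
        raise ValueError("cannot filter an empty TileSet")
    if not (0 <= min_fiber_fraction < max_fiber_fraction <= 1):
        raise ValueError("need 0 <= min_fiber_fraction < max_fiber_fraction <= 1")
    if not (0 < intensity_threshold < 1):
        raise ValueError("intensity_threshold must be in (0, 1)")
    report = _base_report(tileset.tiles)
    fracs = np.array(
        [fiber_fraction(t.pixels, intensity_threshold) for t in tileset.tiles]
    )
    report["fiber_fraction"] = fracs
    report["kept"] = (fracs >= min_fiber_fraction) & (fracs <= max_fiber_fraction)
    report.loc[fracs < min_fiber_fraction, "reason"] = "empty"
    report.loc[fracs > max_fiber_fraction, "reason"] = "over-dense"
    kept = [t for t, k in zip(tileset.tiles, report["kept"]) if k]
    return TileSet(
        tiles=kept,
        grid_rows=tileset.grid_rows,
        grid_cols=tileset.grid_cols,
        filter_report=report,
    )
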