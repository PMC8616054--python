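"""File formats: TIFF/PNG images with JSON sidecars, CSV tables, NPZ tiles.

Images are written as 8-bit RGB rasters with a JSON sidecar carrying
generation metadata (class label, seed, generator parameters, branch
point count).  Force curves and group tables are headered CSV with units
in the column names; tiles and masks travel as NPZ containers plus a CSV
manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from matriscope.synthetic import FiberImage, GeneratorParams, SyntheticForceCurve
from matriscope.tiling import Tile, TileSet
from matriscope.autoencoder import FeatureMask


def save_image(image: FiberImage, path: str | Path) -> Path:
    """Write an 8-bit RGB image plus a ``.json`` metadata sidecar."""
    path = Path(path)
    raster = np.clip(np.round(image.pixels * 255), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raster)
    else:
        iio.imwrite(path, raster)
    meta = {
        "image_id": image.image_id,
        "class_label": image.class_label,
        "seed": image.seed,
        "pixel_size_um": image.pixel_size_um,
        "params": dataclasses.asdict(image.params) if image.params else None,
        "branch_point_count": (
            int(len(image.graph.branch_points)) if image.graph is not None else None
        ),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_image(path: str | Path) -> FiberImage:
    """Read a TIFF/PNG (with optional sidecar) back into a FiberImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raster = tifffile.imread(path)
    else:
        raster = iio.imread(path)
    if raster.ndim == 2:  # single channel: treat as the fiber channel
        raster = np.stack([np.zeros_like(raster), raster, np.zeros_like(raster)], -1)
    if raster.dtype == np.uint8:
        pixels = raster.astype(np.float32) / 255.0
    elif raster.dtype == np.uint16:
        pixels = raster.astype(np.float32) / 65535.0
    else:
        pixels = np.clip(raster.astype(np.float32), 0, 1)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    params = meta.get("params")
    if params:
        params["tile_shape"] = tuple(params["tile_shape"])
    img = FiberImage(
        pixels=pixels[:, :, :3],
        class_label=meta.get("class_label", "unlabeled"),
        seed=meta.get("seed", -1),
        pixel_size_um=meta.get("pixel_size_um", 0.2),
        params=GeneratorParams(**params) if params else None,
    )
    img.image_id = meta.get("image_id", path.stem)
    return img


def load_image_dir(directory: str | Path) -> list[FiberImage]:
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    if not paths:
        raise FileNotFoundError(f"no TIFF/PNG images in {directory}")
    return [load_image(p) for p in paths]


def save_force_curve(curve: SyntheticForceCurve, path: str | Path) -> Path:
    """Two-column CSV with units in the headers (indentation_m, force_N)."""
    path = Path(path)
    pd.DataFrame(
        {"indentation_m": curve.indentation_m, "force_N": curve.force_N}
    ).to_csv(path, index=False)
    return path


def load_force_curve_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"indentation_m", "force_N"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing force-curve columns {sorted(missing)}")
    return df


def save_tiles(tileset: TileSet, path: str | Path) -> Path:
    """Single NPZ container: pixel stack + provenance arrays."""
    path = Path(path)
    np.savez_compressed(
        path,
        pixels=tileset.pixel_array(),
        tile_id=np.array([t.tile_id for t in tileset.tiles]),
        source_image_id=np.array([t.source_image_id for t in tileset.tiles]),
        row=np.array([t.row for t in tileset.tiles]),
        col=np.array([t.col for t in tileset.tiles]),
        class_label=np.array([t.class_label for t in tileset.tiles]),
        grid=np.array([tileset.grid_rows, tileset.grid_cols]),
    )
    return path


def load_tiles(path: str | Path) -> TileSet:
    with np.load(path, allow_pickle=False) as data:
        # materialize each archive member once; indexing the lazy NPZ
        # member per tile would re-decompress the full stack every time
        pixels = data["pixels"]
        source = data["source_image_id"]
        rows, cols = data["row"], data["col"]
        labels = data["class_label"]
        grid = data["grid"]
    tiles = [
        Tile(
            pixels=pixels[i],
            source_image_id=str(source[i]),
            row=int(rows[i]),
            col=int(cols[i]),
            class_label=str(labels[i]),
        )
        for i in range(len(pixels))
    ]
    return TileSet(tiles=tiles, grid_rows=int(grid[0]), grid_cols=int(grid[1]))


def save_features_csv(
    features: np.ndarray,
    tile_ids: list[str],
    class_labels: list[str] | np.ndarray,
    path: str | Path,
) -> Path:
    """Feature table: tile_id, class_label, f1..f16."""
    path = Path(path)
    df = pd.DataFrame(
        features, columns=[f"f{k + 1}" for k in range(features.shape[1])]
    )
    df.insert(0, "class_label", list(class_labels))
    df.insert(0, "tile_id", tile_ids)
    df.to_csv(path, index=False)
    return path


def load_features_csv(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray]:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return (
        df[cols].to_numpy(dtype=float),
        df["tile_id"].tolist(),
        df["class_label"].to_numpy(),
    )


def save_masks(masks: list[FeatureMask], path: str | Path) -> Path:
    """NPZ container of per-tile boolean mask stacks and thresholds."""
    path = Path(path)
    np.savez_compressed(
        path,
        masks=np.stack([m.masks for m in masks]),
        thresholds=np.stack([m.thresholds for m in masks]),
        tile_id=np.array([m.tile_id for m in masks]),
    )
    return path
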