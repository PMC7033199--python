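"""Readers and writers for grids, covariate tables and richness layers.

Grids and per-layer fields are written both as single-band TIFF rasters
(row-major, north-up, one file per layer; float32 with NaN over sea) and
as long-format CSV; richness layers as CSV.  CSV is the primary
interchange format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .world import CovariateTable, WorldConfig, WorldGrid

__all__ = [
    "write_layer_tiff",
    "read_layer_tiff",
    "write_world",
    "write_covariates",
    "write_richness",
    "read_covariates",
    "read_richness",
    "load_world_config",
]


def write_layer_tiff(array: np.ndarray, path: str | Path) -> None:
    """Write one 2-D layer as a single-band float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32))


def read_layer_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_world(world: WorldGrid, out_dir: str | Path) -> None:
    """World grid as label TIFFs plus a per-cell CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_layer_tiff(world.is_land.astype(np.float32), out / "is_land.tif")
    for name in ("landmass_id", "ecoregion_id", "region_id"):
        write_layer_tiff(getattr(world, name).astype(np.float32), out / f"{name}.tif")
    world.to_frame().to_csv(out / "world.csv", index=False)


def write_covariates(
    covariates: CovariateTable, world: WorldGrid, out_dir: str | Path
) -> None:
    """Covariates as one TIFF per layer (NaN over sea) plus long CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cols = world.shape
    for name in covariates.names:
        field = np.full(rows * cols, np.nan, dtype=np.float32)
        field[covariates.data.index.to_numpy()] = covariates.data[name].to_numpy()
        write_layer_tiff(field.reshape(rows, cols), out / f"{name}.tif")
    covariates.to_long().to_csv(out / "covariates.csv", index=False)
    pd.Series(covariates.categories, name="category").rename_axis("layer").to_csv(
        out / "covariate_categories.csv"
    )


def write_richness(richness: pd.DataFrame, path: str | Path) -> None:
    richness.to_csv(path, index=False)


def read_covariates(csv_path: str | Path, categories_path: str | Path) -> CovariateTable:
    long = pd.read_csv(csv_path)
    data = long.pivot(index="cell_id", columns="layer", values="value")
    data.columns.name = None
    cats = pd.read_csv(categories_path, index_col="layer")["category"].to_dict()
    data = data[[c for c in cats if c in data.columns]]
    return CovariateTable(data=data, categories=cats)


def read_richness(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_world_config(path: str | Path) -> WorldConfig:
    """World configuration from a YAML mapping of WorldConfig fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return WorldConfig(**raw)
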