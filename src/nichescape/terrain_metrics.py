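"""Per-cell environmental descriptors from terrain and canopy rasters.

TRI (terrain ruggedness index) is the root-mean-square elevation difference
between a cell and its eight neighbours; TPI (topographic position index) is
the cell's elevation minus the neighbourhood mean (positive on ridges,
negative in valleys); slope uses the Horn 3x3 stencil.  Edges shrink the
neighbourhood to the cells actually available rather than padding with
fabricated elevations (slope replicates the edge row/column, the usual GIS
convention for a gradient stencil).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Landscape

__all__ = ["tri", "tpi", "slope", "aggregate_cells", "cell_environment"]

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbour_stack(z: np.ndarray) -> np.ndarray:
    """(8, H, W) stack of neighbour elevations, NaN outside the raster."""
    z = np.asarray(z, dtype=float)
    pad = np.pad(z, 1, constant_values=np.nan)
    h, w = z.shape
    return np.stack([pad[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w] for dr, dc in _OFFSETS])


def tri(elevation: np.ndarray) -> np.ndarray:
    """Terrain ruggedness: sqrt(mean squared difference to 8 neighbours)."""
    z = np.asarray(elevation, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("TRI needs a raster of at least 3x3")
    nb = _neighbour_stack(z)
    with np.errstate(invalid="ignore"):
        out = np.sqrt(np.nanmean((z[None] - nb) ** 2, axis=0))
    return out


def tpi(elevation: np.ndarray) -> np.ndarray:
    """Topographic position: elevation minus the 8-neighbour mean."""
    z = np.asarray(elevation, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("TPI needs a raster of at least 3x3")
    nb = _neighbour_stack(z)
    with np.errstate(invalid="ignore"):
        return z - np.nanmean(nb, axis=0)


def slope(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Slope in degrees from the Horn 3x3 finite-difference stencil."""
    z = np.asarray(elevation, dtype=float)
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    pad = np.pad(z, 1, mode="edge")
    a = pad[:-2, :-2]; b = pad[:-2, 1:-1]; c = pad[:-2, 2:]
    d = pad[1:-1, :-2];                    f = pad[1:-1, 2:]
    g = pad[2:, :-2];  h = pad[2:, 1:-1];  i = pad[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size)
    dz_dy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cell_size)
    return np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))


def aggregate_cells(
    rasters: dict[str, np.ndarray],
    cell_px: int,
    forest_type: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean each raster over square blocks of ``cell_px`` x ``cell_px`` pixels.

    Forest type, if given, is assigned by majority vote within the block.
    Rasters must share dimensions divisible by ``cell_px``.  Rows are indexed
    by cell id ``r{row}c{col}``.
    """
    shapes = {np.shape(r) for r in rasters.values()}
    if len(shapes) != 1:
        raise ValueError("all rasters must share dimensions")
    (h, w), = shapes
    if h % cell_px or w % cell_px:
        raise ValueError("raster extent must be divisible by the cell size")
    nr, nc = h // cell_px, w // cell_px
    rows = []
    for r in range(nr):
        for c in range(nc):
            blk = np.s_[r * cell_px : (r + 1) * cell_px, c * cell_px : (c + 1) * cell_px]
            row = {"site_id": f"r{r}c{c}"}
            for name, ras in rasters.items():
                row[name] = float(np.nanmean(np.asarray(ras, dtype=float)[blk]))
            if forest_type is not None:
                vals, counts = np.unique(forest_type[blk], return_counts=True)
                row["forest_type"] = int(vals[np.argmax(counts)])
            rows.append(row)
    return pd.DataFrame(rows)


def cell_environment(landscape: Landscape, pixels_per_cell: int = 1) -> pd.DataFrame:
    """The standard per-cell predictor table for a synthetic landscape.

    Computes mean elevation, slope, TRI, TPI and mean canopy height (TCH)
    from the landscape's covariate rasters, plus the forest type, one row
    per cell with ids matching :meth:`CommunityMatrix` site ids and the cell
    centre coordinates in metres.
    """
    elev = landscape.covariates["elevation"]
    metrics = {
        "elevation": elev,
        "slope": slope(elev, landscape.cell_size),
        "tri": tri(elev),
        "tpi": tpi(elev),
    }
    if "canopy_height" in landscape.covariates:
        metrics["tch"] = landscape.covariates["canopy_height"]
    df = aggregate_cells(metrics, pixels_per_cell, forest_type=landscape.forest_type)
    centres = landscape.cell_centres()
    df["x"] = centres[:, 0]
    df["y"] = centres[:, 1]
    return df
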