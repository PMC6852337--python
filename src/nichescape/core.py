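"""Shared containers for the beta-diversity pipeline.

The arena of every analysis is a rectangular grid of square cells (default
edge 100 m, i.e. 1-ha cells).  Cell-centre coordinates are metres relative to
``origin``.  Community composition is held as a sites x species (or sites x
spectral-cluster) count matrix; pairwise Bray-Curtis values live in a
:class:`DissimilarityMatrix` next to the site coordinates they refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Landscape", "CommunityMatrix", "DissimilarityMatrix"]


@dataclass
class Landscape:
    """Gridded arena: forest types, per-cell density and terrain covariates.

    Attributes
    ----------
    forest_type : int array (height, width)
        Categorical raster with values in ``1..n_types``; exhaustive (no
        missing cells inside the domain).
    density : int array (height, width)
        Individuals per cell; >= 1 everywhere habitable.
    covariates : dict of str -> float array (height, width)
        Named real-valued rasters (elevation, canopy height, ...).
    cell_size : float
        Cell edge length in metres (default 100, a 1-ha cell).
    origin : (float, float)
        (x, y) of the lower-left corner of cell (row 0, col 0) in metres.
    """

    forest_type: np.ndarray
    density: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.forest_type = np.asarray(self.forest_type, dtype=int)
        self.density = np.asarray(self.density, dtype=int)
        if self.forest_type.shape != self.density.shape:
            raise ValueError("forest_type and density must share dimensions")
        for name, ras in self.covariates.items():
            if np.shape(ras) != self.forest_type.shape:
                raise ValueError(f"covariate {name!r} does not share raster dimensions")
        if (self.density < 1).any():
            raise ValueError("density must be >= 1 in every habitable cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.forest_type.shape

    @property
    def height(self) -> int:
        return self.forest_type.shape[0]

    @property
    def width(self) -> int:
        return self.forest_type.shape[1]

    @property
    def n_types(self) -> int:
        return int(self.forest_type.max())

    def cell_centres(self) -> np.ndarray:
        """(height*width, 2) array of cell-centre (x, y) in metres, row-major."""
        rows, cols = np.indices(self.shape)
        x = self.origin[0] + (cols.ravel() + 0.5) * self.cell_size
        y = self.origin[1] + (rows.ravel() + 0.5) * self.cell_size
        return np.column_stack([x, y])


@dataclass
class CommunityMatrix:
    """Sites x species abundance counts with site coordinates.

    ``counts[j, i]`` is the abundance of species/cluster ``i`` at site ``j``
    (the x_ij of the Bray-Curtis formula).  ``coverage`` is the fraction of a
    site's nominal area backed by valid observations (1.0 for simulated
    censuses).
    """

    site_ids: np.ndarray
    coords: np.ndarray  # (n_sites, 2) metres
    counts: np.ndarray  # (n_sites, n_species) non-negative ints
    species_ids: np.ndarray
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        self.counts = np.asarray(self.counts)
        self.species_ids = np.asarray(self.species_ids)
        n = len(self.site_ids)
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_sites, 2)")
        if self.counts.shape[0] != n or self.counts.shape[1] != len(self.species_ids):
            raise ValueError("counts shape inconsistent with site/species ids")
        if (self.counts < 0).any():
            raise ValueError("abundance counts must be non-negative")
        if self.coverage is None:
            self.coverage = np.ones(n)
        self.coverage = np.asarray(self.coverage, dtype=float)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=[str(s) for s in self.species_ids])
        df.insert(0, "coverage", self.coverage)
        df.insert(0, "y", self.coords[:, 1])
        df.insert(0, "x", self.coords[:, 0])
        df.insert(0, "site_id", self.site_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityMatrix":
        meta = ["site_id", "x", "y", "coverage"]
        species = [c for c in df.columns if c not in meta]
        return cls(
            site_ids=df["site_id"].to_numpy(),
            coords=df[["x", "y"]].to_numpy(float),
            counts=df[species].to_numpy(),
            species_ids=np.array(species),
            coverage=df["coverage"].to_numpy(float),
        )


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with site coordinates."""

    values: np.ndarray  # (n, n) symmetric, zero diagonal
    coords: np.ndarray  # (n, 2) metres
    site_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_sites, 2)")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("dissimilarity values must lie in [0, 1]")
        if self.site_ids is None:
            self.site_ids = np.arange(n)
        self.site_ids = np.asarray(self.site_ids)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy's condensed (row-major) order."""
        iu = np.triu_indices(self.n_sites, k=1)
        return self.values[iu]

    def geographic_distances(self) -> np.ndarray:
        """(n, n) matrix of Euclidean distances between site coordinates."""
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.hypot(d[..., 0], d[..., 1])

    def to_csv(self, path) -> None:
        ids = [str(s) for s in self.site_ids]
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path)
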