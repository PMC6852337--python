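"""From reflectance cube to "spectral species" abundances.

The estimation chain mirrors the standard spectronomics workflow for mapping
beta-diversity from airborne imaging spectroscopy, applied after atmospheric
and BRDF correction (which are upstream of this package):

1. quality filtering (NDVI, illumination zenith angle, finite spectra);
2. brightness normalisation of each pixel spectrum (division by its L2 norm,
   removing albedo differences while keeping spectral shape);
3. spectral resampling — noisy band ranges dropped, neighbouring bands
   averaged in small groups to improve signal-to-noise;
4. unsupervised clustering of pixel spectra (mini-batch k-means); each
   cluster is treated as a proxy "species";
5. gridding cluster abundances into square cells (default 1 ha) with a
   minimum-coverage rule, yielding a :class:`~nichescape.core.CommunityMatrix`
   ready for Bray-Curtis analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, MiniBatchKMeans

from .core import CommunityMatrix

__all__ = [
    "Cube",
    "PixelMask",
    "ClusterModel",
    "filter_pixels",
    "brightness_normalise",
    "resample_bands",
    "fit_clusters",
    "assign_clusters",
    "select_k",
    "grid_abundances",
    "spectral_community",
]

RED_NM = 660.0
NIR_NM = 800.0

# Band windows dropped before clustering: sensor-edge bands below 420 nm and
# above 2400 nm, and the two atmospheric water-vapour absorption windows.
EDGE_MIN_NM = 420.0
EDGE_MAX_NM = 2400.0
WATER_BANDS_NM = ((1350.0, 1480.0), (1780.0, 2032.0))
VNIR_SWIR_SPLIT_NM = 1000.0


@dataclass
class Cube:
    """A reflectance image: (height, width, bands) in [0, 1] with metadata."""

    data: np.ndarray  # (H, W, B) reflectance
    wavelengths: np.ndarray  # (B,) nm
    zenith: np.ndarray | None = None  # (H, W) illumination zenith, degrees
    pixel_size: float = 1.0  # metres
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (height, width, bands)")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValueError("band count does not match wavelength metadata")
        if self.zenith is not None:
            self.zenith = np.asarray(self.zenith, dtype=float)
            if self.zenith.shape != self.data.shape[:2]:
                raise ValueError("zenith raster must match cube spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class PixelMask:
    """Boolean pass raster plus per-filter rejection bookkeeping."""

    mask: np.ndarray  # True where the pixel passed every filter
    n_total: int
    n_pass: int
    rejected: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_pass == int(self.mask.sum())


def filter_pixels(
    cube: Cube,
    zenith: np.ndarray | None = None,
    ndvi_threshold: float = 0.8,
    zenith_max_deg: float = 50.0,
) -> PixelMask:
    """Quality-filter pixels on NDVI, illumination zenith and finiteness.

    NDVI = (NIR - red)/(NIR + red) computed from the bands nearest 800 and
    660 nm; pixels below ``ndvi_threshold`` indicate low forest cover and are
    discarded, as are pixels illuminated at zenith angles above
    ``zenith_max_deg`` (where BRDF correction is unreliable) and pixels with
    non-finite spectra.
    """
    wl = cube.wavelengths
    if wl.min() > RED_NM or wl.max() < NIR_NM:
        raise ValueError("cube wavelengths do not bracket the red/NIR bands needed for NDVI")
    red = cube.data[..., cube.band_index(RED_NM)]
    nir = cube.data[..., cube.band_index(NIR_NM)]
    finite = np.isfinite(cube.data).all(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(finite, (nir - red) / np.where(nir + red == 0, np.nan, nir + red), np.nan)
    ndvi_ok = np.nan_to_num(ndvi, nan=-np.inf) >= ndvi_threshold
    if zenith is None:
        zenith = cube.zenith
    zen_ok = np.ones_like(finite) if zenith is None else (np.asarray(zenith) <= zenith_max_deg)
    mask = finite & ndvi_ok & zen_ok
    rejected = {
        "nonfinite": int((~finite).sum()),
        "ndvi": int((finite & ~ndvi_ok).sum()),
        "zenith": int((~np.asarray(zen_ok)).sum()),
    }
    return PixelMask(mask=mask, n_total=mask.size, n_pass=int(mask.sum()), rejected=rejected)


def brightness_normalise(spectra: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm.

    Accepts a single vector or an array whose last axis is the band axis.
    Raises on all-zero spectra (those pixels should have been masked out).
    """
    arr = np.asarray(spectra, dtype=float)
    norms = np.linalg.norm(arr, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("all-zero spectrum cannot be brightness normalised")
    return arr / norms


def _group_means(block: np.ndarray, wl: np.ndarray, size: int) -> tuple[list[np.ndarray], list[float]]:
    out, out_wl = [], []
    for start in range(0, block.shape[-1], size):
        sl = slice(start, start + size)
        out.append(block[..., sl].mean(axis=-1))
        out_wl.append(float(wl[sl].mean()))
    return out, out_wl


def resample_bands(cube: Cube, vnir_group: int = 3, swir_group: int = 2) -> Cube:
    """Drop noisy band windows and average neighbouring bands.

    Bands below 420 nm, above 2400 nm and inside the water-absorption
    windows (1350-1480, 1780-2032 nm) are removed; the remaining bands are
    averaged in non-overlapping groups of ``vnir_group`` below 1000 nm and
    ``swir_group`` above, with trailing incomplete groups averaged over the
    bands available.
    """
    wl = cube.wavelengths
    keep = (wl >= EDGE_MIN_NM) & (wl <= EDGE_MAX_NM)
    for lo, hi in WATER_BANDS_NM:
        keep &= ~((wl >= lo) & (wl <= hi))
    if not keep.any():
        raise ValueError("no bands remain after exclusion windows")
    data, wl = cube.data[..., keep], wl[keep]
    vnir = wl < VNIR_SWIR_SPLIT_NM
    bands, bands_wl = [], []
    for region, size in ((vnir, vnir_group), (~vnir, swir_group)):
        if region.any():
            b, w = _group_means(data[..., region], wl[region], size)
            bands.extend(b)
            bands_wl.extend(w)
    order = np.argsort(bands_wl)
    stacked = np.stack([bands[i] for i in order], axis=-1)
    return Cube(
        data=stacked,
        wavelengths=np.asarray(bands_wl)[order],
        zenith=cube.zenith,
        pixel_size=cube.pixel_size,
        origin=cube.origin,
    )


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, B')
    wss: float  # within-cluster sum of squares on the training pixels
    seed: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")
        if self.wss < 0:
            raise ValueError("WSS must be non-negative")


def fit_clusters(
    pixels: np.ndarray,
    k: int,
    seed: int,
    batch_size: int = 1024,
    mini_batch: bool = True,
) -> ClusterModel:
    """Cluster pixel spectra into ``k`` spectral species.

    Mini-batch k-means by default (the variant suited to full airborne
    scenes); ``mini_batch=False`` runs full-batch k-means, affordable at desk
    scale.  Deterministic given ``seed``.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape[0] < k:
        raise ValueError(f"need at least k={k} pixels, got {pixels.shape[0]}")
    if mini_batch:
        km = MiniBatchKMeans(n_clusters=k, random_state=seed, batch_size=batch_size, n_init=3)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=5)
    km.fit(pixels)
    model = ClusterModel(k=k, centroids=km.cluster_centers_.copy(), wss=0.0, seed=seed)
    labels = assign_clusters(model, pixels)
    model.wss = float(((pixels - model.centroids[labels]) ** 2).sum())
    return model


def assign_clusters(model: ClusterModel, pixels: np.ndarray) -> np.ndarray:
    """Nearest-centroid (Euclidean) assignment; ties go to the lowest id."""
    pixels = np.asarray(pixels, dtype=float)
    # squared distances via expansion; argmin returns the first (lowest) id on ties
    d2 = (
        (pixels**2).sum(axis=1, keepdims=True)
        - 2 * pixels @ model.centroids.T
        + (model.centroids**2).sum(axis=1)
    )
    return np.argmin(d2, axis=1)


def select_k(pixels: np.ndarray, k_grid, seed: int, **fit_kwargs) -> pd.DataFrame:
    """Elbow diagnostics: mean within-cluster sum of squares per candidate k.

    The mean WSS (per pixel) decreases roughly exponentially with k; the
    returned frame flags the knee — the k with the largest second difference
    of log mean WSS — as a suggestion only.
    """
    k_grid = list(k_grid)
    if sorted(k_grid) != k_grid:
        raise ValueError("k_grid must be sorted ascending")
    n = np.asarray(pixels).shape[0]
    rows = [
        {"k": k, "mean_wss": fit_clusters(pixels, k, seed=seed, **fit_kwargs).wss / n}
        for k in k_grid
    ]
    df = pd.DataFrame(rows)
    df["knee"] = False
    if len(df) >= 3:
        logw = np.log(np.maximum(df["mean_wss"].to_numpy(), 1e-300))
        second = np.diff(logw, 2)
        df.loc[1 + int(np.argmax(second)), "knee"] = True
    return df


def grid_abundances(
    cluster_raster: np.ndarray,
    mask: np.ndarray,
    n_clusters: int,
    pixel_size: float = 1.0,
    cell_size_m: float = 100.0,
    min_coverage: float = 0.25,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Count cluster abundances inside square cells, dropping sparse cells.

    ``cluster_raster`` holds the per-pixel cluster id (ignored where ``mask``
    is False).  Coverage of a cell is the valid-pixel fraction of its nominal
    area; cells under ``min_coverage`` (default 25%) are excluded and
    reported in the second return value.

    Returns the retained-cell :class:`CommunityMatrix` (one abundance column
    per cluster; x_ij = pixels of cluster i in cell j) and a frame describing
    the dropped cells.
    """
    if cell_size_m < pixel_size:
        raise ValueError("cell size must be at least the pixel size")
    px_per_side = cell_size_m / pixel_size
    if abs(px_per_side - round(px_per_side)) > 1e-9:
        raise ValueError("cell size must be an integer multiple of pixel size")
    side = int(round(px_per_side))
    h, w = cluster_raster.shape
    n_rows, n_cols = int(np.ceil(h / side)), int(np.ceil(w / side))
    nominal = side * side

    kept_rows, dropped = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            blk = np.s_[r * side : (r + 1) * side, c * side : (c + 1) * side]
            m = mask[blk]
            coverage = m.sum() / nominal
            cid = f"r{r}c{c}"
            cx = origin[0] + (c + 0.5) * cell_size_m
            cy = origin[1] + (r + 0.5) * cell_size_m
            if coverage < min_coverage:
                dropped.append({"site_id": cid, "x": cx, "y": cy, "coverage": coverage})
                continue
            counts = np.bincount(cluster_raster[blk][m].ravel(), minlength=n_clusters)
            kept_rows.append((cid, cx, cy, coverage, counts))

    if not kept_rows:
        raise ValueError("no cell reaches the minimum coverage")
    community = CommunityMatrix(
        site_ids=np.array([r[0] for r in kept_rows]),
        coords=np.array([[r[1], r[2]] for r in kept_rows]),
        counts=np.array([r[4] for r in kept_rows]),
        species_ids=np.arange(n_clusters),
        coverage=np.array([r[3] for r in kept_rows]),
    )
    return community, pd.DataFrame(dropped, columns=["site_id", "x", "y", "coverage"])


def spectral_community(
    cube: Cube,
    k: int,
    seed: int,
    ndvi_threshold: float = 0.8,
    zenith_max_deg: float = 50.0,
    cell_size_m: float = 100.0,
    min_coverage: float = 0.25,
    mini_batch: bool = True,
    batch_size: int = 1024,
):
    """End-to-end spectral species pipeline.

    Runs filtering, brightness normalisation, band resampling, clustering and
    gridding; returns ``(community, cluster_raster, pixel_mask, model)``.
    The cluster raster holds -1 at masked pixels.
    """
    pm = filter_pixels(cube, ndvi_threshold=ndvi_threshold, zenith_max_deg=zenith_max_deg)
    resampled = resample_bands(cube)
    valid = pm.mask & (np.linalg.norm(resampled.data, axis=-1) > 0)
    pixels = brightness_normalise(resampled.data[valid])
    model = fit_clusters(pixels, k=k, seed=seed, mini_batch=mini_batch, batch_size=batch_size)
    labels = assign_clusters(model, pixels)
    raster = np.full(valid.shape, -1, dtype=int)
    raster[valid] = labels
    community, _dropped = grid_abundances(
        raster,
        valid,
        n_clusters=k,
        pixel_size=cube.pixel_size,
        cell_size_m=cell_size_m,
        min_coverage=min_coverage,
        origin=cube.origin,
    )
    return community, raster, pm, model
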