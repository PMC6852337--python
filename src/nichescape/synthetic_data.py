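"""Synthetic landscapes, communities and reflectance cubes with known truth.

Every downstream stage (spectral clustering, Bray-Curtis, Mantel, GDM and
the neutral simulations) can be exercised on data from this module, whose
generating parameters — niche strength, dispersal aggregation, noise level,
seed — are known exactly.

The generator emulates the structure of a lowland tropical-forest mosaic:

* a categorical forest-type map obtained by thresholding a spatially
  autocorrelated Gaussian random field into contiguous-tending regions
  (emulating e.g. alluvial / sandstone / heath associations);
* terrain covariates (elevation, canopy height) as independent seeded
  Gaussian random fields with a stated autocorrelation range;
* pixel-level species maps where species prefer their affiliated forest type
  and an elevational optimum (niche filtering) and occur in dispersal-shaped
  patches (a Thomas-process-like clustering term);
* a multi-band reflectance cube drawn from per-species mean spectra plus
  noise, with planted invalid pixels (low NDVI or high illumination zenith)
  so the quality filters have something to reject.

All randomness flows from one integer seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._rng import substream
from .core import CommunityMatrix, Landscape
from .spectral_diversity import Cube

__all__ = [
    "SpeciesSpectrum",
    "SyntheticTruth",
    "gaussian_random_field",
    "gen_landscape",
    "gen_community",
    "make_species_spectra",
    "gen_cube",
]


def gaussian_random_field(
    shape: tuple[int, int], corr_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, ~unit-variance field with exponential covariance.

    Spectral (FFT) synthesis on a doubled grid (approximate circulant
    embedding).  ``corr_range`` is the *practical* range: the distance, in
    cells, at which the variogram reaches ~95% of its sill, i.e. the
    covariance is exp(-3 h / corr_range).
    """
    ny, nx = shape
    if ny < 1 or nx < 1:
        raise ValueError("field dimensions must be positive")
    if corr_range <= 0:
        raise ValueError("autocorrelation range must be positive")
    Ny, Nx = 2 * ny, 2 * nx
    dy = np.minimum(np.arange(Ny), Ny - np.arange(Ny))
    dx = np.minimum(np.arange(Nx), Nx - np.arange(Nx))
    h = np.hypot(dy[:, None], dx[None, :])
    cov = np.exp(-3.0 * h / corr_range)
    spec = np.fft.fft2(cov).real
    spec[spec < 0] = 0.0  # embedding may be slightly indefinite
    noise = rng.standard_normal((Ny, Nx))
    field_big = np.fft.ifft2(np.sqrt(spec) * np.fft.fft2(noise)).real / np.sqrt(Ny * Nx)
    out = field_big[:ny, :nx]
    return (out - out.mean()) / max(out.std(), 1e-12)


def gen_landscape(
    width: int,
    height: int,
    n_types: int,
    autocorr_range: float,
    seed: int,
    cell_size: float = 100.0,
    elevation_range: tuple[float, float] = (0.0, 60.0),
    canopy_height_range: tuple[float, float] = (20.0, 55.0),
    density: int = 1,
) -> Landscape:
    """Generate a forest-type mosaic with terrain covariates.

    The forest-type raster is a seeded Gaussian random field quantile-
    thresholded into ``n_types`` classes of near-equal area (values 1..T);
    elevation and canopy height are independent fields with the same
    autocorrelation range, rescaled to the given min/max.
    """
    if width < 2 or height < 2:
        raise ValueError("landscape must be at least 2x2 cells")
    if n_types < 1:
        raise ValueError("need at least one forest type")
    if n_types > width * height:
        raise ValueError("more forest types than cells")

    def rescale(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
        fmin, fmax = f.min(), f.max()
        span = max(fmax - fmin, 1e-12)
        return lo + (f - fmin) * (hi - lo) / span

    shape = (height, width)
    type_field = gaussian_random_field(shape, autocorr_range, substream(seed, "landscape-types"))
    if n_types == 1:
        forest_type = np.ones(shape, dtype=int)
    else:
        qs = np.quantile(type_field, np.linspace(0, 1, n_types + 1)[1:-1])
        forest_type = 1 + np.searchsorted(qs, type_field).reshape(shape)
    elevation = rescale(
        gaussian_random_field(shape, autocorr_range, substream(seed, "landscape-elevation")),
        *elevation_range,
    )
    canopy = rescale(
        gaussian_random_field(shape, autocorr_range, substream(seed, "landscape-canopy")),
        *canopy_height_range,
    )
    return Landscape(
        forest_type=forest_type,
        density=np.full(shape, density, dtype=int),
        covariates={"elevation": elevation, "canopy_height": canopy},
        cell_size=cell_size,
    )


@dataclass
class SyntheticTruth:
    """Ground truth for a generated community.

    ``species`` is the per-pixel species-id raster (pixels subdivide cells);
    ``community`` the per-cell abundance table derived from it by counting;
    ``params`` the generating parameters.
    """

    species: np.ndarray  # (H_px, W_px) int species ids, 0..S-1
    community: CommunityMatrix
    landscape: Landscape
    pixels_per_cell: int  # pixels per cell edge
    params: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return int(self.species.max()) + 1


def _pixel_counts(species: np.ndarray, n_species: int, side: int, landscape: Landscape) -> CommunityMatrix:
    h, w = landscape.shape
    counts = np.zeros((h * w, n_species), dtype=int)
    ids, xs, ys = [], [], []
    for r in range(h):
        for c in range(w):
            blk = species[r * side : (r + 1) * side, c * side : (c + 1) * side]
            counts[r * w + c] = np.bincount(blk.ravel(), minlength=n_species)
            ids.append(f"r{r}c{c}")
            xs.append(landscape.origin[0] + (c + 0.5) * landscape.cell_size)
            ys.append(landscape.origin[1] + (r + 0.5) * landscape.cell_size)
    return CommunityMatrix(
        site_ids=np.array(ids),
        coords=np.column_stack([xs, ys]),
        counts=counts,
        species_ids=np.arange(n_species),
    )


def gen_community(
    landscape: Landscape,
    n_species: int,
    niche_strength: float,
    aggregation: float,
    seed: int,
    pixels_per_cell: int = 10,
    env_weight: float = 0.5,
    patch_size: int = 64,
) -> SyntheticTruth:
    """Assign a species to every pixel under niche filtering + clustering.

    Each species receives a forest-type affinity and an elevational optimum.
    Pixel suitability of species s is ``1[type match] + env_weight *
    exp(-((elev - opt_s)/scale)^2)`` and assignment probabilities are
    proportional to ``exp(niche_strength * suitability)``.  Spatial
    clustering follows a Thomas-process approximation: parent points are
    scattered over the arena, each carrying a species drawn at its own
    location, and a pixel copies its nearest parent with probability
    ``aggregation / (1 + aggregation)`` (otherwise it draws independently).

    ``niche_strength=0`` and ``aggregation=0`` therefore yield i.i.d.
    uniform assignment.
    """
    if n_species < 1:
        raise ValueError("need at least one species")
    if niche_strength < 0 or aggregation < 0:
        raise ValueError("niche_strength and aggregation must be >= 0")
    rng = substream(seed, "community")
    h, w = landscape.shape
    side = pixels_per_cell
    H, W = h * side, w * side

    # per-pixel environment by nearest-cell (block) upsampling
    elev = np.repeat(np.repeat(landscape.covariates["elevation"], side, 0), side, 1)
    ftype = np.repeat(np.repeat(landscape.forest_type, side, 0), side, 1)

    affinities = rng.integers(1, landscape.n_types + 1, size=n_species)
    lo, hi = float(elev.min()), float(elev.max())
    optima = rng.uniform(lo, hi, size=n_species)
    scale = max((hi - lo) / 4.0, 1e-9)

    # (n_pixels, n_species) assignment probabilities
    flat_elev = elev.ravel()[:, None]
    flat_type = ftype.ravel()[:, None]
    suit = (flat_type == affinities[None, :]).astype(float)
    suit += env_weight * np.exp(-(((flat_elev - optima[None, :]) / scale) ** 2))
    logits = niche_strength * suit
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)

    # independent component: inverse-CDF draw per pixel
    u = rng.random(H * W)
    cdf = np.cumsum(probs, axis=1)
    indep = (u[:, None] < cdf).argmax(axis=1)

    species = indep
    if aggregation > 0:
        n_parents = max(1, (H * W) // patch_size)
        px = rng.uniform(0, W, n_parents)
        py = rng.uniform(0, H, n_parents)
        parent_pixel = np.minimum(py.astype(int), H - 1) * W + np.minimum(px.astype(int), W - 1)
        u_p = rng.random(n_parents)
        parent_species = (u_p[:, None] < cdf[parent_pixel]).argmax(axis=1)
        yy, xx = np.indices((H, W))
        tree = cKDTree(np.column_stack([px, py]))
        _, nearest = tree.query(np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5]))
        copy = rng.random(H * W) < aggregation / (1.0 + aggregation)
        species = np.where(copy, parent_species[nearest], indep)

    species = species.reshape(H, W)
    community = _pixel_counts(species, n_species, side, landscape)
    return SyntheticTruth(
        species=species,
        community=community,
        landscape=landscape,
        pixels_per_cell=side,
        params={
            "n_species": n_species,
            "niche_strength": niche_strength,
            "aggregation": aggregation,
            "seed": seed,
            "affinities": affinities,
            "optima": optima,
        },
    )


@dataclass
class SpeciesSpectrum:
    """Mean reflectance (per band, in [0, 1]) and within-species sd."""

    species_id: int
    mean: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.min() < 0 or self.mean.max() > 1:
            raise ValueError("mean reflectance must lie in [0, 1]")
        if self.sd is None:
            self.sd = np.zeros_like(self.mean)
        self.sd = np.asarray(self.sd, dtype=float)
        if (self.sd < 0).any():
            raise ValueError("spectral sd must be non-negative")


def _vegetation_base(wl: np.ndarray) -> np.ndarray:
    # green-leaf-like shape: dark visible, sharp red edge near 720 nm, bright
    # NIR plateau, declining SWIR — keeps NDVI of healthy pixels above 0.85
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 720.0) / 12.0))
    swir_decay = np.where(wl > 1300.0, np.exp(-(wl - 1300.0) / 1500.0), 1.0)
    return 0.02 + 0.46 * red_edge * swir_decay


def make_species_spectra(
    n_species: int,
    n_bands: int,
    seed: int,
    separation: float = 0.08,
    wl_range: tuple[float, float] = (400.0, 2450.0),
) -> list[tuple[np.ndarray, SpeciesSpectrum]] | tuple[np.ndarray, list[SpeciesSpectrum]]:
    """Smooth vegetation-like mean spectra, one per species.

    Species differ by a few smooth Gaussian bumps (amplitude ``separation``)
    placed beyond the red band so the NDVI filter is unaffected.  Returns
    ``(wavelengths, [SpeciesSpectrum, ...])``.
    """
    rng = substream(seed, "spectra")
    wl = np.linspace(*wl_range, n_bands)
    base = _vegetation_base(wl)
    spectra = []
    for s in range(n_species):
        bump = np.zeros_like(wl)
        for _ in range(3):
            centre = rng.uniform(850.0, 2300.0)
            width = rng.uniform(60.0, 200.0)
            amp = rng.uniform(-separation, separation)
            bump += amp * np.exp(-(((wl - centre) / width) ** 2))
        mean = np.clip(base + bump, 0.01, 0.95)
        spectra.append(SpeciesSpectrum(species_id=s, mean=mean))
    return wl, spectra


def gen_cube(
    truth: SyntheticTruth,
    spectra: list[SpeciesSpectrum],
    wavelengths: np.ndarray,
    noise_sd: float,
    invalid_fraction: float,
    seed: int,
) -> tuple[Cube, np.ndarray]:
    """Render the species raster as a reflectance cube with planted noise.

    Each pixel's spectrum is its species mean plus seeded Gaussian noise
    (clipped to [0, 1]).  An ``invalid_fraction`` of pixels is planted to
    fail the quality filters: half get a flat low-NDVI spectrum, half an
    illumination zenith above 50 degrees.  Valid pixels get zenith angles
    uniform in [0, 45].

    Returns ``(cube, planted_invalid_mask)``.
    """
    if not 0 <= invalid_fraction <= 1:
        raise ValueError("invalid_fraction must lie in [0, 1]")
    by_id = {sp.species_id: sp for sp in spectra}
    present = np.unique(truth.species)
    missing = [int(s) for s in present if s not in by_id]
    if missing:
        raise ValueError(f"no spectrum for species present in truth: {missing}")
    wavelengths = np.asarray(wavelengths, dtype=float)
    rng = substream(seed, "cube")
    H, W = truth.species.shape
    B = len(wavelengths)
    means = np.zeros((int(present.max()) + 1, B))
    for s in present:
        means[s] = by_id[int(s)].mean
    data = means[truth.species]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.0)

    zenith = rng.uniform(0.0, 45.0, size=(H, W))
    n_px = H * W
    n_invalid = int(round(invalid_fraction * n_px))
    planted = np.zeros((H, W), dtype=bool)
    if n_invalid:
        idx = rng.choice(n_px, size=n_invalid, replace=False)
        planted.ravel()[idx] = True
        half = n_invalid // 2
        flat_idx_ndvi, flat_idx_zen = idx[:half], idx[half:]
        rr, cc = np.unravel_index(flat_idx_ndvi, (H, W))
        data[rr, cc, :] = 0.2  # flat spectrum: NDVI = 0
        rr, cc = np.unravel_index(flat_idx_zen, (H, W))
        zenith[rr, cc] = rng.uniform(50.5, 70.0, size=len(flat_idx_zen))

    cube = Cube(data=data, wavelengths=wavelengths, zenith=zenith, pixel_size=truth.landscape.cell_size / truth.pixels_per_cell)
    return cube, planted
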