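"""Spatially explicit neutral community simulation by coalescence.

Samples of individuals are traced backwards in time: each event picks an
active lineage uniformly at random; with probability nu (the per-birth
speciation rate) the lineage speciates — all its descendant samples receive
a fresh species — otherwise it steps to a parent drawn through a fat-tailed
dispersal kernel and a uniform index within the parent cell's density.  Two
lineages landing on the same (cell, index) coalesce.  The census at the end
assigns every sampled individual exactly one species.

The dispersal kernel is a two-dimensional Student-t-type family with radial
density

    f(r) proportional to r (1 + r^2 / (tau sigma^2))^(-(tau+2)/2),

where sigma sets the scale (conceptually the mean dispersal distance) and
tau the fatness of the tail; as tau -> infinity it converges to the
Rayleigh/Gaussian kernel of scale sigma.  Radii are drawn by inverse-CDF:
r = sigma sqrt(tau ((1-U)^(-2/tau) - 1)).

Two modes are provided.  The forest-type-naive mode treats the landscape as
one neutral arena with a single kernel.  The forest-type-aware mode keeps
dynamics neutral *within* forest types but penalises mixing between them: a
proposed parent cell in a different forest type is accepted only with
probability m (the mixing penalty; m=1 recovers the naive code path
exactly, m=0 forbids any cross-type ancestry).  Each forest type may carry
its own kernel.  A third, spatially implicit "global" mode draws the parent
uniformly among all individuals and exists as the analytic (Ewens sampling
formula) reference case.

The landscape boundary is closed: dispersal proposals landing outside are
redrawn (no torus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .core import CommunityMatrix, Landscape

__all__ = [
    "DispersalKernel",
    "SimulationConfig",
    "Census",
    "sample_kernel",
    "apply_mixing_rule",
    "coalesce",
    "census_to_community",
    "ewens_expected_richness",
]


@dataclass(frozen=True)
class DispersalKernel:
    """Fat-tailed 2D dispersal kernel with scale sigma and tail exponent tau."""

    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be positive and finite")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError("tau must be positive and finite")

    def sample_radius(self, u: np.ndarray | float) -> np.ndarray | float:
        """Inverse-CDF radius for uniform variate(s) ``u`` in [0, 1)."""
        return self.sigma * np.sqrt(self.tau * np.expm1((-2.0 / self.tau) * np.log1p(-u)))


def sample_kernel(kernel: DispersalKernel, rng: np.random.Generator, size: int | None = None):
    """Draw displacement(s) (dx, dy): fat-tailed radius, uniform angle."""
    n = 1 if size is None else size
    r = kernel.sample_radius(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    dx, dy = r * np.cos(theta), r * np.sin(theta)
    if size is None:
        return float(dx[0]), float(dy[0])
    return dx, dy


def apply_mixing_rule(
    proposed_type: int, current_type: int, m: float, rng: np.random.Generator
) -> bool:
    """Accept/reject a proposed parent cell under the mixing penalty.

    Same-type proposals are always accepted.  Cross-type proposals are
    accepted with probability ``m``; the boundary cases consume no random
    draw, so ``m=1`` is bit-identical to the naive (no-penalty) path and
    ``m=0`` never crosses a type boundary.
    """
    if proposed_type == current_type or m >= 1.0:
        return True
    if m <= 0.0:
        return False
    return bool(rng.random() < m)


@dataclass
class SimulationConfig:
    """Everything one coalescent run needs.

    ``kernels`` is a single :class:`DispersalKernel` (naive/global mode) or
    a dict mapping forest-type id -> kernel (aware mode).  ``sample_map`` is
    an (H, W) int raster of individuals sampled per cell (<= density); by
    default every individual in every cell is sampled.
    """

    landscape: Landscape
    nu: float
    kernels: DispersalKernel | dict[int, DispersalKernel] | None = None
    mode: str = "naive"  # naive | aware | global
    mixing: float = 1.0
    sample_map: np.ndarray | None = None
    seed: int = 0
    max_events: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.nu <= 1:
            raise ValueError("speciation probability nu must lie in (0, 1]")
        if self.mode not in ("naive", "aware", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "aware":
            if not isinstance(self.kernels, dict):
                raise ValueError("aware mode needs one kernel per forest type")
            types = set(np.unique(self.landscape.forest_type).tolist())
            if not types <= set(self.kernels):
                raise ValueError("aware mode: missing kernel for some forest type")
            if not 0 <= self.mixing <= 1:
                raise ValueError("mixing penalty must lie in [0, 1]")
        elif self.mode == "naive":
            if not isinstance(self.kernels, DispersalKernel):
                raise ValueError("naive mode needs a single kernel")
        if self.sample_map is None:
            self.sample_map = self.landscape.density.copy()
        self.sample_map = np.asarray(self.sample_map, dtype=int)
        if self.sample_map.shape != self.landscape.shape:
            raise ValueError("sample map must match landscape dimensions")
        if (self.sample_map > self.landscape.density).any():
            raise ValueError("cannot sample more individuals than a cell's density")
        if (self.sample_map < 0).any() or self.sample_map.sum() == 0:
            raise ValueError("sample map must be non-negative and non-empty")


@dataclass
class Census:
    """Species assignment per sampled individual, plus sample locations."""

    rows: np.ndarray  # cell row per sample
    cols: np.ndarray  # cell col per sample
    species: np.ndarray  # dense int species ids, 0..S-1
    landscape: Landscape
    n_events: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.species)

    @property
    def richness(self) -> int:
        return len(np.unique(self.species))


_MAX_REJECT = 100_000


def coalesce(config: SimulationConfig) -> Census:
    """Run the backwards-in-time neutral simulation to completion.

    Fully deterministic given the config (including seed).  When a single
    active lineage remains it speciates immediately — its eventual
    speciation is certain and assigns one species to all its descendants,
    so the shortcut is exact.
    """
    ls = config.landscape
    H, W = ls.shape
    rng = substream(config.seed, "coalesce")
    density = ls.density
    ftype = ls.forest_type

    # initial lineages: one per sampled individual, distinct indices per cell
    rows, cols = np.nonzero(config.sample_map)
    samp_rows, samp_cols, samp_idx = [], [], []
    for r, c in zip(rows, cols):
        k = config.sample_map[r, c]
        samp_rows.extend([r] * k)
        samp_cols.extend([c] * k)
        samp_idx.extend(range(k))
    n_samples = len(samp_rows)
    species = np.full(n_samples, -1, dtype=int)

    # active lineage state (parallel lists; id = position)
    lin_row = list(samp_rows)
    lin_col = list(samp_cols)
    lin_idx = list(samp_idx)
    lin_desc: list[list[int]] = [[i] for i in range(n_samples)]
    active = list(range(n_samples))
    occupancy: dict[tuple[int, int, int], int] = {
        (lin_row[i], lin_col[i], lin_idx[i]): i for i in active
    }

    if config.mode == "global":
        flat_density = density.ravel().astype(float)
        cum = np.cumsum(flat_density)
        total_j = cum[-1]

    next_species = 0
    nu = config.nu
    max_events = config.max_events or max(1_000_000, int(50 * n_samples / nu))
    n_events = 0

    while active:
        n_events += 1
        if n_events > max_events:
            raise RuntimeError(
                f"coalescent did not terminate within {max_events} events "
                f"({len(active)} lineages still active)"
            )
        pos = int(rng.integers(len(active))) if len(active) > 1 else 0
        lid = active[pos]

        if len(active) == 1 or rng.random() < nu:
            for s in lin_desc[lid]:
                species[s] = next_species
            next_species += 1
            occupancy.pop((lin_row[lid], lin_col[lid], lin_idx[lid]), None)
            active[pos] = active[-1]
            active.pop()
            continue

        r, c = lin_row[lid], lin_col[lid]
        if config.mode == "global":
            flat = int(np.searchsorted(cum, rng.random() * total_j, side="right"))
            pr, pc = divmod(flat, W)
        else:
            kernel = (
                config.kernels
                if config.mode == "naive"
                else config.kernels[int(ftype[r, c])]
            )
            cur_type = int(ftype[r, c])
            for attempt in range(_MAX_REJECT):
                dx, dy = sample_kernel(kernel, rng)
                pr, pc = r + int(round(dy)), c + int(round(dx))
                if not (0 <= pr < H and 0 <= pc < W):
                    continue
                if config.mode == "aware" and not apply_mixing_rule(
                    int(ftype[pr, pc]), cur_type, config.mixing, rng
                ):
                    continue
                break
            else:
                raise RuntimeError(
                    f"dispersal starved after {_MAX_REJECT} rejected proposals "
                    f"from cell ({r}, {c}); check mixing penalty and landscape connectivity"
                )
        p_idx = int(rng.integers(density[pr, pc]))

        occupancy.pop((r, c, lin_idx[lid]), None)
        key = (pr, pc, p_idx)
        other = occupancy.get(key)
        if other is not None and other != lid:
            lin_desc[other].extend(lin_desc[lid])
            lin_desc[lid] = []
            active[pos] = active[-1]
            active.pop()
        else:
            lin_row[lid], lin_col[lid], lin_idx[lid] = pr, pc, p_idx
            occupancy[key] = lid

    return Census(
        rows=np.asarray(samp_rows),
        cols=np.asarray(samp_cols),
        species=species,
        landscape=ls,
        n_events=n_events,
    )


def census_to_community(census: Census, landscape: Landscape | None = None) -> CommunityMatrix:
    """Count species per grid cell; conserves individuals.

    Only cells holding at least one sampled individual become sites.
    """
    ls = landscape if landscape is not None else census.landscape
    cell_flat = census.rows * ls.width + census.cols
    cells = np.unique(cell_flat)
    n_species = int(census.species.max()) + 1
    counts = np.zeros((len(cells), n_species), dtype=int)
    cell_pos = {cf: i for i, cf in enumerate(cells)}
    for cf, sp in zip(cell_flat, census.species):
        counts[cell_pos[cf], sp] += 1
    rows_c, cols_c = np.divmod(cells, ls.width)
    x = ls.origin[0] + (cols_c + 0.5) * ls.cell_size
    y = ls.origin[1] + (rows_c + 0.5) * ls.cell_size
    return CommunityMatrix(
        site_ids=np.array([f"r{r}c{c}" for r, c in zip(rows_c, cols_c)]),
        coords=np.column_stack([x, y]),
        counts=counts,
        species_ids=np.arange(n_species),
    )


def ewens_expected_richness(j: int, nu: float) -> float:
    """Expected species count in a well-mixed neutral sample.

    Ewens sampling formula: E[S] = sum_{i=0}^{J-1} theta/(theta+i) with
    theta = nu (J-1) / (1-nu).  This is the closed-form reference for the
    simulator's global-dispersal mode.
    """
    theta = nu * (j - 1) / (1.0 - nu)
    i = np.arange(j)
    return float(np.sum(theta / (theta + i)))
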