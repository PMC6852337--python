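"""Bray-Curtis beta-diversity, Mantel tests and Mantel correlograms.

The Bray-Curtis dissimilarity between sites j and k is

    d_jk = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik)

over species (or spectral-cluster) abundances x.  The Mantel statistic Mr is
the Pearson correlation of the upper triangles of two dissimilarity
matrices; its significance comes from jointly permuting rows and columns of
one matrix, which respects the non-independence of pairwise entries.  The
Mantel correlogram resolves Mr by distance class (class count from Sturges'
rule), with bootstrap confidence intervals from resampling sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._rng import substream
from .core import CommunityMatrix, DissimilarityMatrix

__all__ = [
    "bray_curtis",
    "pair_count",
    "sturges_classes",
    "MantelResult",
    "mantel",
    "mantel_correlogram",
]


def bray_curtis(community: CommunityMatrix) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity between all sites.

    Values lie in [0, 1]: 0 for identical composition, 1 for disjoint
    support.  Raises if any site has all-zero abundances (its dissimilarity
    would be undefined).
    """
    x = np.asarray(community.counts, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two sites")
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = np.asarray(community.site_ids)[totals == 0]
        raise ValueError(f"sites with all-zero abundances: {list(bad)}")
    # numerator is the Manhattan (city-block) distance between count rows
    num = squareform(pdist(x, metric="cityblock"))
    den = totals[:, None] + totals[None, :]
    values = num / den
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(values=values, coords=community.coords, site_ids=community.site_ids)


def pair_count(n_sites: int) -> int:
    """Number of unordered site pairs, n(n-1)/2."""
    if n_sites < 2:
        raise ValueError("need at least two sites")
    return n_sites * (n_sites - 1) // 2


def sturges_classes(n_pairs: int) -> int:
    """Sturges' rule class count: ceil(1 + log2(m)) for m pairwise distances."""
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    return math.ceil(1.0 + math.log2(n_pairs))


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None = None
    method: str = "permutation"

    def __post_init__(self) -> None:
        assert -1 - 1e-9 <= self.r <= 1 + 1e-9
        assert 0 < self.p <= 1


def _upper(values: np.ndarray) -> np.ndarray:
    return values[np.triu_indices(values.shape[0], k=1)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise ValueError("constant upper triangle: Mantel correlation undefined")
    return float((a * b).sum() / denom)


def mantel(
    dx: np.ndarray | DissimilarityMatrix,
    dy: np.ndarray | DissimilarityMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test between two square dissimilarity matrices.

    Mr is the Pearson correlation of the upper triangles.  The two-sided
    p-value permutes rows and columns of ``dy`` jointly: the sampled
    estimator is p = (1 + #{|Mr*| >= |Mr|}) / (n_perm + 1); with
    ``exhaustive=True`` all n! relabelings are enumerated instead and the
    p-value is the exact fraction (identity included).
    """
    mx = dx.values if isinstance(dx, DissimilarityMatrix) else np.asarray(dx, dtype=float)
    my = dy.values if isinstance(dy, DissimilarityMatrix) else np.asarray(dy, dtype=float)
    if mx.shape != my.shape or mx.shape[0] != mx.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    n = mx.shape[0]
    ux = _upper(mx)
    r_obs = _pearson(ux, _upper(my))

    if exhaustive:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r_p = _pearson(ux, _upper(my[np.ix_(perm, perm)]))
            total += 1
            if abs(r_p) >= abs(r_obs) - 1e-12:
                hits += 1
        return MantelResult(r=r_obs, p=hits / total, n_perm=total, seed=seed, method="exhaustive")

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = substream(seed if seed is not None else 0, "mantel")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(_pearson(ux, _upper(my[np.ix_(perm, perm)]))) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, p=(1 + hits) / (n_perm + 1), n_perm=n_perm, seed=seed)


def _class_mr(d: np.ndarray, member: np.ndarray) -> float:
    """Per-class Mantel statistic.

    Correlates the dissimilarities with class membership, sign-flipped so a
    positive value means within-class pairs are *more similar* (lower
    dissimilarity) than the background — positive spatial autocorrelation.
    """
    if member.all() or not member.any():
        return np.nan
    return -_pearson(d, member.astype(float))


def mantel_correlogram(
    dissim: DissimilarityMatrix,
    n_boot: int = 500,
    seed: int | None = None,
    n_classes: int | None = None,
) -> pd.DataFrame:
    """Mantel correlogram with bootstrap confidence intervals.

    Distances between site coordinates are cut into equal-width classes
    covering [0, max distance]; the class count follows Sturges' rule on the
    number of pairs unless overridden.  Per class, Mr correlates the
    dissimilarity matrix with class membership (positive Mr = sites in that
    distance class are more similar than expected by chance).  Confidence
    intervals (percentile 2.5/97.5) come from ``n_boot`` bootstrap
    replicates resampling sites with replacement; pairs formed by a site and
    its own duplicate are excluded from replicate statistics.

    Returns a frame with columns class, lo, hi, mr, ci_lo, ci_hi, n_pairs.
    """
    n = dissim.n_sites
    if n < 3:
        raise ValueError("correlogram needs at least three sites")
    d = dissim.condensed()
    geo = _upper(dissim.geographic_distances())
    m = len(d)
    k = n_classes if n_classes is not None else sturges_classes(m)
    edges = np.linspace(0.0, geo.max(), k + 1)

    def membership(g: np.ndarray, cls: int) -> np.ndarray:
        hi_edge = edges[cls + 1]
        mem = (g >= edges[cls]) & ((g < hi_edge) | (cls == k - 1) & (g <= hi_edge))
        return mem

    rows = []
    rng = substream(seed if seed is not None else 0, "correlogram")
    # bootstrap replicate statistics, one pass per replicate
    boot_stats = np.full((n_boot, k), np.nan)
    iu = np.triu_indices(n, k=1)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        db = dissim.values[np.ix_(idx, idx)][iu]
        cb = dissim.coords[idx]
        gb = np.hypot(*(cb[:, None, :] - cb[None, :, :]).transpose(2, 0, 1))[iu]
        keep = idx[iu[0]] != idx[iu[1]]  # drop duplicate-site self pairs
        db, gb = db[keep], gb[keep]
        for cls in range(k):
            mem = membership(gb, cls)
            if mem.any() and not mem.all():
                try:
                    boot_stats[b, cls] = _class_mr(db, mem)
                except ValueError:
                    pass

    for cls in range(k):
        mem = membership(geo, cls)
        n_pairs = int(mem.sum())
        mr = np.nan
        if 0 < n_pairs < m:
            try:
                mr = _class_mr(d, mem)
            except ValueError:
                pass
        col = boot_stats[:, cls]
        ok = np.isfinite(col)
        ci_lo, ci_hi = (np.percentile(col[ok], [2.5, 97.5]) if ok.sum() >= 2 else (np.nan, np.nan))
        rows.append(
            {
                "class": cls,
                "lo": edges[cls],
                "hi": edges[cls + 1],
                "mr": mr,
                "ci_lo": ci_lo,
                "ci_hi": ci_hi,
                "n_pairs": n_pairs,
            }
        )
    return pd.DataFrame(rows)
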