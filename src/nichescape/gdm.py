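"""Generalised Dissimilarity Modelling (GDM).

GDM regresses pairwise compositional dissimilarity d in [0, 1) on monotone
transforms of predictor differences under a negative-exponential link:

    d_hat = 1 - exp(-eta),
    eta = a0 + sum_k |f_k(x_jk) - f_k(x_ik)|,

where each f_k is a non-negative combination of I-splines (monotone
non-decreasing basis functions, 0 at the lowest knot and 1 at the highest).
Geographic distance enters as a single I-spline term of the pair distance.
Coefficients (and the intercept) are constrained non-negative and estimated
by iteratively reweighted non-negative least squares on the binomial-type
deviance

    dev = sum 2 [ d ln(d/d_hat) + (1-d) ln((1-d)/(1-d_hat)) ].

Percent deviance explained is 100 (1 - dev_model / dev_null) against the
intercept-only null.  The deviance partition splits the full-model explained
deviance into a unique distance component (D), a unique environment
component (E) and their spatially autocorrelated overlap (DxE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from ._rng import substream
from .core import DissimilarityMatrix

__all__ = [
    "ispline_basis",
    "build_site_pairs",
    "forest_type_contrasts",
    "GDMModel",
    "fit_gdm",
    "PartitionResult",
    "partition",
    "variable_importance",
]

_EPS = 1e-9


def ispline_basis(x: np.ndarray, knots: np.ndarray, order: int = 3) -> np.ndarray:
    """Evaluate the I-spline basis at ``x``.

    Each I-spline is the running integral of an M-spline on the given knots
    (default order 3), normalised to 0 at the lowest knot and 1 at the
    highest; values outside the knot span are clamped.  Returns an array of
    shape ``(len(x), n_basis)`` with ``n_basis = order + len(knots) - 2``.
    """
    knots = np.unique(np.asarray(knots, dtype=float))
    if len(knots) < 2:
        raise ValueError("need at least two distinct knots")
    t = np.r_[[knots[0]] * order, knots[1:-1], [knots[-1]] * order]
    n_basis = len(t) - order
    xc = np.clip(np.atleast_1d(np.asarray(x, dtype=float)), knots[0], knots[-1])
    out = np.empty((len(xc), n_basis))
    for i in range(n_basis):
        coefs = np.zeros(n_basis)
        coefs[i] = 1.0
        anti = BSpline(t, coefs, order - 1).antiderivative()
        lo, hi = anti(knots[0]), anti(knots[-1])
        out[:, i] = (anti(xc) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def forest_type_contrasts(types: np.ndarray) -> pd.DataFrame:
    """Orthogonal (Helmert) contrast codes for a categorical forest type.

    For T levels returns T-1 numeric columns ``ftype_c1..``; contrast
    vectors are mutually orthogonal and zero-sum over the levels, so for a
    balanced design the coded site columns are orthogonal too.
    """
    levels = np.unique(types)
    T = len(levels)
    if T < 2:
        raise ValueError("contrasts need at least two forest types")
    codes = np.zeros((T, T - 1))
    for j in range(T - 1):
        codes[: j + 1, j] = -1.0
        codes[j + 1, j] = j + 1.0
    level_index = {lv: i for i, lv in enumerate(levels)}
    rows = codes[[level_index[t] for t in np.asarray(types)]]
    return pd.DataFrame(rows, columns=[f"ftype_c{j + 1}" for j in range(T - 1)])


def build_site_pairs(
    dissim: DissimilarityMatrix,
    env: pd.DataFrame | None = None,
    predictors: list[str] | None = None,
    include_type_contrasts: bool = False,
) -> pd.DataFrame:
    """One row per unordered site pair: observed d, distance, predictor values.

    ``env`` must carry one row per site with a ``site_id`` column matching
    the dissimilarity matrix's site ids (order-insensitive).  Environmental
    predictors appear as paired columns ``<name>_1``/``<name>_2``; forest
    type, when requested, is encoded as orthogonal contrasts.
    """
    n = dissim.n_sites
    iu = np.triu_indices(n, k=1)
    geo = dissim.geographic_distances()
    out = pd.DataFrame(
        {
            "site_1": np.asarray(dissim.site_ids)[iu[0]],
            "site_2": np.asarray(dissim.site_ids)[iu[1]],
            "d": dissim.values[iu],
            "distance": geo[iu],
        }
    )
    if env is not None:
        env = env.set_index("site_id")
        missing = set(map(str, dissim.site_ids)) - set(map(str, env.index))
        if missing:
            raise ValueError(f"environment table lacks sites: {sorted(missing)[:5]}")
        aligned = env.loc[np.asarray(dissim.site_ids)].reset_index(drop=True)
        cols = predictors if predictors is not None else [
            c for c in aligned.columns if c not in ("x", "y", "forest_type")
        ]
        if include_type_contrasts:
            contrasts = forest_type_contrasts(aligned["forest_type"].to_numpy())
            aligned = pd.concat([aligned, contrasts], axis=1)
            cols = list(cols) + list(contrasts.columns)
        for c in cols:
            vals = aligned[c].to_numpy(float)
            out[f"{c}_1"] = vals[iu[0]]
            out[f"{c}_2"] = vals[iu[1]]
    return out


def _pair_predictors(pairs: pd.DataFrame) -> list[str]:
    names = {c[:-2] for c in pairs.columns if c.endswith("_1") and f"{c[:-2]}_2" in pairs.columns}
    return sorted(names - {"site"})


@dataclass
class GDMModel:
    """Fitted GDM: per-predictor knots and non-negative I-spline coefficients."""

    intercept: float
    predictors: dict[str, dict] = field(default_factory=dict)  # name -> {knots, coefs}
    order: int = 3
    deviance_null: float = np.nan
    deviance_model: float = np.nan
    converged: bool = True
    n_iter: int = 0
    dropped: list[str] = field(default_factory=list)

    @property
    def explained(self) -> float:
        """Raw percent deviance explained (can be negative)."""
        return 100.0 * (1.0 - self.deviance_model / self.deviance_null)

    @property
    def pct_explained(self) -> float:
        """Percent deviance explained, clamped to [0, 100] for reporting."""
        return float(np.clip(self.explained, 0.0, 100.0))

    def _design(self, pairs: pd.DataFrame) -> np.ndarray:
        blocks = []
        for name, spec in self.predictors.items():
            if name == "distance":
                blocks.append(ispline_basis(pairs["distance"].to_numpy(), spec["knots"], self.order))
            else:
                b1 = ispline_basis(pairs[f"{name}_1"].to_numpy(), spec["knots"], self.order)
                b2 = ispline_basis(pairs[f"{name}_2"].to_numpy(), spec["knots"], self.order)
                blocks.append(np.abs(b1 - b2))
        return np.hstack(blocks) if blocks else np.empty((len(pairs), 0))

    def linear_predictor(self, pairs: pd.DataFrame) -> np.ndarray:
        coefs = np.concatenate([spec["coefs"] for spec in self.predictors.values()]) if self.predictors else np.empty(0)
        return self.intercept + self._design(pairs) @ coefs

    def predict(self, pairs: pd.DataFrame) -> np.ndarray:
        """Fitted dissimilarities, 1 - exp(-eta), in [0, 1)."""
        return 1.0 - np.exp(-self.linear_predictor(pairs))

    def spline(self, name: str, x: np.ndarray) -> np.ndarray:
        """The fitted monotone transform f_name evaluated at ``x``."""
        spec = self.predictors[name]
        return ispline_basis(np.asarray(x), spec["knots"], self.order) @ spec["coefs"]

    def spline_max(self, name: str) -> float:
        """Maximum (total turnover) of a fitted spline: the coefficient sum."""
        return float(self.predictors[name]["coefs"].sum())

    def export_splines(self, grid_size: int = 100) -> pd.DataFrame:
        """All fitted splines on per-predictor grids of ``grid_size`` points."""
        rows = []
        for name, spec in self.predictors.items():
            knots = spec["knots"]
            grid = np.linspace(knots[0], knots[-1], grid_size)
            vals = self.spline(name, grid)
            rows.append(pd.DataFrame({"predictor": name, "x": grid, "f": vals}))
        return pd.concat(rows, ignore_index=True)


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    y = np.clip(y, _EPS, 1 - _EPS)
    mu = np.clip(mu, _EPS, 1 - _EPS)
    return float(np.sum(2.0 * (y * np.log(y / mu) + (1 - y) * np.log((1 - y) / (1 - mu)))))


def fit_gdm(
    pairs: pd.DataFrame,
    predictors: list[str] | None = None,
    order: int = 3,
    knot_quantiles: tuple[float, ...] = (0.0, 0.5, 1.0),
    max_iter: int = 200,
    tol: float = 1e-8,
) -> GDMModel:
    """Fit a GDM to a site-pair table.

    ``predictors`` names the terms to include: ``"distance"`` and/or any
    environmental predictor present as ``<name>_1``/``<name>_2`` columns.
    Knots sit at the given quantiles of the pooled predictor values (pair
    distances for the distance term).  Constant predictors are dropped with
    a warning.  Observed d outside (0, 1) is truncated to keep the deviance
    finite.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 site pairs")
    if predictors is None:
        predictors = ["distance"] + _pair_predictors(pairs)

    model = GDMModel(intercept=0.0, order=order)
    for name in predictors:
        if name == "distance":
            vals = pairs["distance"].to_numpy(float)
        else:
            vals = np.concatenate([pairs[f"{name}_1"].to_numpy(float), pairs[f"{name}_2"].to_numpy(float)])
        knots = np.unique(np.quantile(vals, knot_quantiles))
        if len(knots) < 2:
            warnings.warn(f"predictor {name!r} is constant; dropped from the GDM")
            model.dropped.append(name)
            continue
        model.predictors[name] = {"knots": knots, "coefs": None}

    y = np.clip(pairs["d"].to_numpy(float), _EPS, 1 - _EPS)
    X = model._design(pairs)
    A = np.column_stack([np.ones(len(y)), X])
    p = A.shape[1]

    # the linear predictor is capped: eta = 15 already maps to d_hat within
    # 3e-7 of 1, and an uncapped working response diverges on saturated pairs
    eta_max = 15.0

    def dev_at(b: np.ndarray) -> float:
        mu = np.clip(1.0 - np.exp(-np.clip(A @ b, 0.0, eta_max)), _EPS, 1 - _EPS)
        return _deviance(y, mu)

    beta = np.zeros(p)
    beta[0] = -np.log1p(-y.mean())
    dev_prev = dev_at(beta)
    for it in range(1, max_iter + 1):
        eta = np.clip(A @ beta, 0.0, eta_max)
        mu = np.clip(1.0 - np.exp(-eta), _EPS, 1 - _EPS)
        dmu = 1.0 - mu  # d mu / d eta
        w = dmu / np.clip(mu, _EPS, None)  # (dmu)^2 / var, var = mu(1-mu)
        z = np.clip(eta + (y - mu) / dmu, 0.0, eta_max)
        sw = np.sqrt(w)
        new_beta, _ = nnls(A * sw[:, None], z * sw)
        # step-halve towards the previous iterate if the deviance worsened
        dev_new = dev_at(new_beta)
        halvings = 0
        while dev_new > dev_prev + 1e-12 and halvings < 12:
            new_beta = 0.5 * (new_beta + beta)
            dev_new = dev_at(new_beta)
            halvings += 1
        if dev_new > dev_prev + 1e-12:
            # no descent along the IRLS direction: previous iterate is optimal
            model.converged = True
            model.n_iter = it
            break
        step = np.max(np.abs(new_beta - beta))
        dev_step = dev_prev - dev_new
        beta, dev_prev = new_beta, dev_new
        if step < tol or dev_step < 1e-7 * (abs(dev_new) + 1.0):
            model.converged = True
            model.n_iter = it
            break
    else:
        model.converged = False
        model.n_iter = max_iter
        warnings.warn(f"GDM IRLS did not converge in {max_iter} iterations (last step {step:.2e})")

    model.intercept = float(beta[0])
    pos = 1
    for name, spec in model.predictors.items():
        n_b = order + len(spec["knots"]) - 2
        spec["coefs"] = beta[pos : pos + n_b]
        pos += n_b

    mu = np.clip(model.predict(pairs), _EPS, 1 - _EPS)
    model.deviance_model = _deviance(y, mu)
    model.deviance_null = _deviance(y, np.full_like(y, y.mean()))
    return model


@dataclass
class PartitionResult:
    """Percent deviance split into distance, environment and overlap."""

    d: float  # unique to geographic distance
    e: float  # unique to environment
    dxe: float  # shared (spatially autocorrelated environment)
    full: float  # full-model percent explained
    models: dict[str, GDMModel] = field(default_factory=dict)

    @property
    def unexplained(self) -> float:
        return 100.0 - self.full

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": ["D", "E", "DxE", "total", "unexplained"],
                "pct_deviance": [self.d, self.e, self.dxe, self.full, self.unexplained],
            }
        )


def partition(
    pairs: pd.DataFrame,
    env_predictors: list[str],
    **fit_kwargs,
) -> PartitionResult:
    """Partition explained deviance into D, E and DxE.

    Fits distance-only, environment-only and full models; unique D = full -
    explained(E), unique E = full - explained(D), shared DxE =
    explained(D) + explained(E) - full.  A negative component is clamped to
    zero and the others rescaled so the three still sum to the full-model
    percent explained (matching the reporting convention in which a purely
    independent environment shows DxE = 0).

    The distance spline of the full model describes spatial turnover *not*
    attributable to spatially structured environment ("D only without
    DxE"); the distance spline of the distance-only model describes the
    observed spatial pattern ("D + DxE").
    """
    m_d = fit_gdm(pairs, predictors=["distance"], **fit_kwargs)
    m_e = fit_gdm(pairs, predictors=list(env_predictors), **fit_kwargs)
    m_full = fit_gdm(pairs, predictors=["distance"] + list(env_predictors), **fit_kwargs)

    expl_d, expl_e, full = m_d.pct_explained, m_e.pct_explained, m_full.pct_explained
    unique_d = full - expl_e
    unique_e = full - expl_d
    shared = expl_d + expl_e - full
    parts = np.array([unique_d, unique_e, shared])
    if (parts < 0).any():
        parts = np.clip(parts, 0.0, None)
        total = parts.sum()
        parts = parts * (full / total) if total > 0 else np.zeros(3)
    return PartitionResult(
        d=float(parts[0]),
        e=float(parts[1]),
        dxe=float(parts[2]),
        full=float(full),
        models={"distance_only": m_d, "environment_only": m_e, "full": m_full},
    )


def variable_importance(
    dissim: DissimilarityMatrix,
    env: pd.DataFrame,
    predictors: list[str],
    n_perm: int = 50,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Permutation importance of each environmental predictor.

    For each predictor, its site values are shuffled (consistently across
    all pairs containing a site), the GDM refitted, and the loss in percent
    deviance explained recorded; the mean over ``n_perm`` permutations is
    reported.
    """
    base_pairs = build_site_pairs(dissim, env, predictors=predictors)
    baseline = fit_gdm(base_pairs, predictors=["distance"] + list(predictors), **fit_kwargs).pct_explained
    rng = substream(seed, "gdm-importance")
    rows = []
    for name in predictors:
        losses = []
        for _ in range(n_perm):
            shuffled = env.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            pairs = build_site_pairs(dissim, shuffled, predictors=predictors)
            expl = fit_gdm(pairs, predictors=["distance"] + list(predictors), **fit_kwargs).pct_explained
            losses.append(baseline - expl)
        rows.append({"predictor": name, "importance": float(np.mean(losses)), "baseline": baseline})
    return pd.DataFrame(rows)
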