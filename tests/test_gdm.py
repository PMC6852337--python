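import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.interpolate import BSpline

from nichescape.core import DissimilarityMatrix
from nichescape.gdm import (
    build_site_pairs,
    fit_gdm,
    forest_type_contrasts,
    ispline_basis,
    partition,
    variable_importance,
)


def simulate_gdm(
    seed,
    n=50,
    coef_d=(0.3, 0.2, 0.1, 0.2),
    coef_e=(0.1, 0.3, 0.05, 0.1),
    a0=0.05,
    noise=0.0,
    env_mode="random",
):
    """Site-pair data generated exactly from a known GDM."""
    rng = np.random.default_rng(seed)
    if env_mode == "line":
        x = np.sort(rng.uniform(0, 1000, n))
        coords = np.column_stack([x, np.zeros(n)])
        env = x / 100.0
    else:
        coords = rng.uniform(0, 1000, (n, 2))
        env = rng.uniform(0, 10, n)
    df = pd.DataFrame({"site_id": np.arange(n), "x": coords[:, 0], "y": coords[:, 1], "elev": env})
    dm = DissimilarityMatrix(np.zeros((n, n)), coords, np.arange(n))
    pairs = build_site_pairs(dm, df, predictors=["elev"])
    kd = np.quantile(pairs["distance"], [0, 0.5, 1])
    ke = np.quantile(np.r_[pairs["elev_1"], pairs["elev_2"]], [0, 0.5, 1])
    eta = (
        a0
        + ispline_basis(pairs["distance"].to_numpy(), kd) @ np.asarray(coef_d)
        + np.abs(
            ispline_basis(pairs["elev_1"].to_numpy(), ke) - ispline_basis(pairs["elev_2"].to_numpy(), ke)
        )
        @ np.asarray(coef_e)
    )
    d = 1 - np.exp(-eta)
    if noise:
        d = np.clip(d + rng.normal(0, noise, len(d)), 1e-6, 1 - 1e-6)
    pairs["d"] = d
    return pairs, df, dm, {"coef_d": np.asarray(coef_d), "coef_e": np.asarray(coef_e), "a0": a0}


class TestIsplineBasis:
    def test_bounds(self):
        knots = np.array([0.0, 0.4, 1.0])
        assert np.allclose(ispline_basis(np.array([0.0]), knots), 0.0)
        assert np.allclose(ispline_basis(np.array([1.0]), knots), 1.0)

    def test_clamped_outside(self):
        knots = np.array([0.0, 0.5, 1.0])
        assert np.allclose(ispline_basis(np.array([-3.0]), knots), 0.0)
        assert np.allclose(ispline_basis(np.array([9.0]), knots), 1.0)

    def test_monotone_nondecreasing(self):
        knots = np.array([0.0, 0.3, 1.0])
        grid = np.linspace(0, 1, 200)
        basis = ispline_basis(grid, knots)
        assert (np.diff(basis, axis=0) >= -1e-12).all()

    def test_quadrature_oracle(self):
        """I-spline values match numerical integration of the M-spline."""
        knots = np.array([0.0, 0.35, 1.0])
        order = 3
        t = np.r_[[knots[0]] * order, knots[1:-1], [knots[-1]] * order]
        n_basis = len(t) - order
        xs = np.array([0.1, 0.35, 0.6, 0.9])
        vals = ispline_basis(xs, knots, order=order)
        for i in range(n_basis):
            c = np.zeros(n_basis)
            c[i] = 1.0
            b = BSpline(t, c, order - 1)
            norm = quad(b, knots[0], knots[-1], limit=200)[0]
            for j, x in enumerate(xs):
                integral = quad(b, knots[0], x, limit=200)[0] / norm
                assert abs(vals[j, i] - integral) < 1e-8

    def test_too_few_knots(self):
        with pytest.raises(ValueError):
            ispline_basis(np.array([0.5]), np.array([1.0, 1.0]))


class TestSitePairs:
    def test_three_sites_three_rows(self):
        dm = DissimilarityMatrix(np.zeros((3, 3)), np.array([[0, 0], [1, 0], [0, 1.0]]))
        pairs = build_site_pairs(dm)
        assert len(pairs) == 3

    def test_distances_in_metres(self):
        coords = np.array([[0.0, 0.0], [300.0, 400.0]])
        dm = DissimilarityMatrix(np.zeros((2, 2)), coords)
        assert np.isclose(build_site_pairs(dm)["distance"].iloc[0], 500.0)

    def test_contrasts_orthogonal_zero_sum(self):
        types = np.repeat([1, 2, 3], 10)  # balanced 3-type design
        con = forest_type_contrasts(types)
        assert con.shape == (30, 2)
        cols = con.to_numpy()
        assert abs(cols[:, 0].sum()) < 1e-12 and abs(cols[:, 1].sum()) < 1e-12
        assert abs(cols[:, 0] @ cols[:, 1]) < 1e-12

    def test_id_mismatch_raises(self):
        dm = DissimilarityMatrix(np.zeros((2, 2)), np.zeros((2, 2)), site_ids=np.array(["a", "b"]))
        env = pd.DataFrame({"site_id": ["a", "zzz"], "elev": [1.0, 2.0]})
        with pytest.raises(ValueError, match="lacks sites"):
            build_site_pairs(dm, env, predictors=["elev"])


class TestFitGDM:
    def test_exact_recovery(self):
        """Noise-free data from a known GDM: >=99% deviance explained and
        coefficients within 5% in the sup norm."""
        pairs, _, _, truth = simulate_gdm(seed=0)
        m = fit_gdm(pairs, predictors=["distance", "elev"])
        assert m.explained >= 99.0
        assert np.abs(m.predictors["distance"]["coefs"] - truth["coef_d"]).max() <= 0.05
        assert np.abs(m.predictors["elev"]["coefs"] - truth["coef_e"]).max() <= 0.05
        assert abs(m.intercept - truth["a0"]) <= 0.05

    def test_link_identity_no_signal(self):
        """With a constant response the fit collapses to the intercept and
        d_hat = 1 - exp(-a0)."""
        rng = np.random.default_rng(1)
        pairs = pd.DataFrame(
            {"d": np.full(30, 0.4), "distance": rng.uniform(0, 10, 30)}
        )
        m = fit_gdm(pairs, predictors=["distance"])
        assert np.allclose(m.predict(pairs), 0.4, atol=1e-6)
        assert np.isclose(m.intercept, -np.log(0.6), atol=1e-6)

    def test_shuffled_response_near_zero(self):
        expl = []
        for seed in range(20):
            pairs, _, _, _ = simulate_gdm(seed=seed, n=30, noise=0.02)
            rng = np.random.default_rng(seed + 1000)
            pairs["d"] = rng.permutation(pairs["d"].to_numpy())
            expl.append(fit_gdm(pairs, predictors=["distance", "elev"]).pct_explained)
        assert np.median(expl) < 2.0

    def test_row_order_and_site_swap_invariance(self):
        pairs, _, _, _ = simulate_gdm(seed=2, n=25, noise=0.01)
        m1 = fit_gdm(pairs, predictors=["distance", "elev"])
        shuffled = pairs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        swapped = shuffled.rename(columns={"elev_1": "elev_2", "elev_2": "elev_1"})
        m2 = fit_gdm(swapped, predictors=["distance", "elev"])
        assert np.allclose(m1.predictors["elev"]["coefs"], m2.predictors["elev"]["coefs"], atol=1e-6)
        assert np.isclose(m1.explained, m2.explained, atol=1e-6)

    def test_irrelevant_predictor_negligible(self):
        deltas = []
        for seed in range(20):
            pairs, df, dm, _ = simulate_gdm(seed=seed, n=30, noise=0.02)
            base = fit_gdm(pairs, predictors=["distance", "elev"]).pct_explained
            rng = np.random.default_rng(seed + 2000)
            df2 = df.copy()
            df2["noise"] = rng.uniform(0, 1, len(df2))
            pairs2 = build_site_pairs(dm, df2, predictors=["elev", "noise"])
            pairs2["d"] = pairs["d"].to_numpy()
            full = fit_gdm(pairs2, predictors=["distance", "elev", "noise"]).pct_explained
            deltas.append(abs(full - base))
        assert np.median(deltas) < 1.0

    def test_fitted_splines_monotone_and_max_is_coef_sum(self):
        pairs, _, _, _ = simulate_gdm(seed=3, noise=0.01)
        m = fit_gdm(pairs, predictors=["distance", "elev"])
        for name in ("distance", "elev"):
            knots = m.predictors[name]["knots"]
            vals = m.spline(name, np.linspace(knots[0], knots[-1], 100))
            assert (np.diff(vals) >= -1e-10).all()
            assert np.isclose(vals[-1], m.spline_max(name))

    def test_constant_predictor_dropped(self):
        pairs, _, _, _ = simulate_gdm(seed=4, n=20)
        pairs["flat_1"] = 1.0
        pairs["flat_2"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            m = fit_gdm(pairs, predictors=["distance", "flat"])
        assert "flat" in m.dropped and "flat" not in m.predictors

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            fit_gdm(pd.DataFrame({"d": [0.1] * 5, "distance": range(5)}))


class TestPartition:
    def test_components_sum_to_full(self):
        for seed in range(5):
            pairs, _, _, _ = simulate_gdm(seed=seed, n=35, noise=0.02)
            p = partition(pairs, ["elev"])
            assert np.isclose(p.d + p.e + p.dxe, p.full, atol=1e-9)
            assert min(p.d, p.e, p.dxe) >= 0

    def test_independent_environment_no_overlap(self):
        dxes = [
            partition(simulate_gdm(seed=s, n=40, noise=0.02)[0], ["elev"]).dxe for s in range(10)
        ]
        assert np.mean(dxes) < 2.0

    def test_coordinate_determined_environment_no_unique_distance(self):
        """Environment a pure (linear) function of position on a transect:
        everything distance explains is shared with environment."""
        uds = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            x = np.sort(rng.uniform(0, 1000, n))
            df = pd.DataFrame({"site_id": np.arange(n), "x": x, "y": 0.0, "elev": x / 100.0})
            dm = DissimilarityMatrix(np.zeros((n, n)), np.column_stack([x, np.zeros(n)]), np.arange(n))
            pairs = build_site_pairs(dm, df, predictors=["elev"])
            eta = 0.05 + 0.0012 * pairs["distance"].to_numpy()
            pairs["d"] = np.clip(1 - np.exp(-eta) + rng.normal(0, 0.02, len(eta)), 1e-6, 1 - 1e-6)
            uds.append(partition(pairs, ["elev"]).d)
        assert np.mean(uds) < 2.0


class TestVariableImportance:
    def test_generating_and_null_predictors(self):
        pairs, df, dm, _ = simulate_gdm(seed=6, n=30, coef_d=(0, 0, 0, 0), a0=0.05, noise=0.01)
        rng = np.random.default_rng(7)
        df["noise"] = rng.uniform(0, 1, len(df))
        pairs_full = build_site_pairs(dm, df, predictors=["elev", "noise"])
        pairs_full["d"] = pairs["d"].to_numpy()
        dm_obs = DissimilarityMatrix(np.zeros((30, 30)), dm.coords, dm.site_ids)
        # rebuild an observed dissimilarity matrix from the pair table
        iu = np.triu_indices(30, 1)
        vals = np.zeros((30, 30))
        vals[iu] = pairs_full["d"].to_numpy()
        vals += vals.T
        dm_obs = DissimilarityMatrix(vals, dm.coords, dm.site_ids)
        imp = variable_importance(dm_obs, df, ["elev", "noise"], n_perm=8, seed=1)
        imp = imp.set_index("predictor")
        base = imp["baseline"].iloc[0]
        assert imp.loc["elev", "importance"] > 0.5 * base  # generating predictor dominates
        assert imp.loc["noise", "importance"] < 0.2 * base + 1.0
        assert (imp["importance"] > -1.0).all()  # non-negative up to refit noise
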