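import numpy as np
import pytest
from scipy.stats import ks_2samp, spearmanr

from nichescape._rng import substream
from nichescape.core import Landscape
from nichescape.diversity_stats import bray_curtis
from nichescape.neutral_sim import (
    Census,
    DispersalKernel,
    SimulationConfig,
    apply_mixing_rule,
    census_to_community,
    coalesce,
    ewens_expected_richness,
    sample_kernel,
)


def flat_landscape(h=10, w=10, density=1, ftype=None):
    ft = np.ones((h, w), int) if ftype is None else ftype
    return Landscape(forest_type=ft, density=np.full((h, w), density, int))


def split_landscape(h=16, w=16):
    ft = np.ones((h, w), int)
    ft[:, w // 2 :] = 2
    return Landscape(forest_type=ft, density=np.ones((h, w), int))


class TestDispersalKernel:
    def test_gaussian_limit_mean(self):
        """tau -> infinity reduces to a Rayleigh kernel with mean sigma*sqrt(pi/2)."""
        rng = substream(0, "kernel-test")
        dx, dy = sample_kernel(DispersalKernel(2.0, 1e6), rng, size=1_000_000)
        r = np.hypot(dx, dy)
        target = 2.0 * np.sqrt(np.pi / 2)
        assert abs(r.mean() - target) / target < 0.02

    def test_scale_family(self):
        """Draws with (2 sigma, tau) are distributed as 2x draws with (sigma, tau)."""
        r1 = DispersalKernel(1.5, 4.0).sample_radius(substream(1, "a").random(20_000))
        r2 = DispersalKernel(3.0, 4.0).sample_radius(substream(2, "b").random(20_000))
        assert ks_2samp(2 * r1, r2).pvalue > 0.01

    def test_angle_isotropy(self):
        rng = substream(3, "angles")
        dx, dy = sample_kernel(DispersalKernel(1.0, 8.0), rng, size=1_000_000)
        r = np.hypot(dx, dy)
        resultant = np.hypot((dx / r).mean(), (dy / r).mean())
        assert resultant < 0.01

    @pytest.mark.parametrize("sigma,tau", [(0.0, 1.0), (1.0, -2.0), (np.inf, 1.0)])
    def test_invalid_parameters(self, sigma, tau):
        with pytest.raises(ValueError):
            DispersalKernel(sigma, tau)


class TestMixingRule:
    def test_same_type_always_accepted(self):
        rng = substream(0, "mix")
        assert all(apply_mixing_rule(1, 1, 0.0, rng) for _ in range(100))

    def test_m_one_accepts_without_draw(self):
        rng = substream(1, "mix")
        state = rng.bit_generator.state
        assert apply_mixing_rule(2, 1, 1.0, rng)
        assert rng.bit_generator.state == state  # no random draw consumed

    def test_m_zero_rejects_without_draw(self):
        rng = substream(2, "mix")
        state = rng.bit_generator.state
        assert not apply_mixing_rule(2, 1, 0.0, rng)
        assert rng.bit_generator.state == state

    def test_half_penalty_acceptance_rate(self):
        rng = substream(3, "mix")
        accepted = sum(apply_mixing_rule(2, 1, 0.5, rng) for _ in range(100_000))
        assert abs(accepted / 100_000 - 0.5) < 0.01


class TestCoalesce:
    def test_nu_one_all_distinct(self):
        ls = flat_landscape(5, 5)
        c = coalesce(SimulationConfig(landscape=ls, nu=1.0, kernels=DispersalKernel(1, 1), mode="naive", seed=0))
        assert c.richness == c.n_samples == 25

    def test_deterministic_given_config(self):
        ls = flat_landscape(8, 8)
        kw = dict(landscape=ls, nu=0.01, kernels=DispersalKernel(2.0, 8.0), mode="naive", seed=77)
        a, b = coalesce(SimulationConfig(**kw)), coalesce(SimulationConfig(**kw))
        assert np.array_equal(a.species, b.species)
        assert a.n_events == b.n_events

    def test_nu_to_zero_single_species(self):
        """On a connected landscape, vanishing speciation collapses the
        sample to the most recent common ancestor's single species."""
        ls = flat_landscape(10, 10)
        singles = sum(
            coalesce(
                SimulationConfig(landscape=ls, nu=1e-9, kernels=DispersalKernel(2.0, 8.0), mode="naive", seed=rep)
            ).richness
            == 1
            for rep in range(100)
        )
        assert singles >= 95

    def test_ewens_well_mixed_oracle(self):
        """Global-dispersal richness matches the Ewens sampling formula."""
        ls = flat_landscape(20, 20)
        rich = [
            coalesce(SimulationConfig(landscape=ls, nu=0.05, mode="global", seed=rep)).richness
            for rep in range(100)
        ]
        expected = ewens_expected_richness(400, 0.05)
        se = np.std(rich, ddof=1) / np.sqrt(len(rich))
        assert abs(np.mean(rich) - expected) < 3 * se

    def test_richness_monotone_in_nu(self):
        ls = flat_landscape(10, 10)
        means = []
        for nu in (1e-4, 1e-3, 1e-2):
            rich = [
                coalesce(
                    SimulationConfig(landscape=ls, nu=nu, kernels=DispersalKernel(2.0, 8.0), mode="naive", seed=rep)
                ).richness
                for rep in range(30)
            ]
            means.append(np.mean(rich))
        assert means[0] < means[1] < means[2]

    def test_distance_decay(self):
        """Naive-mode Bray-Curtis increases with distance between cells."""
        ls = flat_landscape(20, 20, density=4)
        rhos = []
        for rep in range(5):
            cfg = SimulationConfig(landscape=ls, nu=0.005, kernels=DispersalKernel(1.5, 8.0), mode="naive", seed=rep)
            d = bray_curtis(census_to_community(coalesce(cfg)))
            geo = d.geographic_distances()
            iu = np.triu_indices(d.n_sites, 1)
            edges = np.quantile(geo[iu], np.linspace(0, 1, 8))
            cls = np.searchsorted(edges[1:-1], geo[iu])
            means = [d.values[iu][cls == c].mean() for c in range(7)]
            rhos.append(spearmanr(np.arange(7), means).statistic)
        assert np.mean(rhos) > 0

    def test_event_cap_signalled(self):
        ls = flat_landscape(6, 6)
        cfg = SimulationConfig(
            landscape=ls, nu=1e-6, kernels=DispersalKernel(1.0, 4.0), mode="naive", seed=0, max_events=5
        )
        with pytest.raises(RuntimeError, match="did not terminate"):
            coalesce(cfg)

    def test_invalid_configs(self):
        ls = split_landscape()
        with pytest.raises(ValueError, match="nu"):
            SimulationConfig(landscape=ls, nu=0.0, kernels=DispersalKernel(1, 1), mode="naive")
        with pytest.raises(ValueError, match="per forest type"):
            SimulationConfig(landscape=ls, nu=0.1, kernels=DispersalKernel(1, 1), mode="aware")
        with pytest.raises(ValueError, match="single kernel"):
            SimulationConfig(landscape=ls, nu=0.1, kernels={1: DispersalKernel(1, 1)}, mode="naive")


class TestAwareMode:
    def test_m_one_bit_identical_to_naive(self):
        ls = split_landscape()
        k = DispersalKernel(2.0, 8.0)
        naive = coalesce(SimulationConfig(landscape=ls, nu=0.01, kernels=k, mode="naive", seed=42))
        aware = coalesce(
            SimulationConfig(landscape=ls, nu=0.01, kernels={1: k, 2: k}, mode="aware", mixing=1.0, seed=42)
        )
        assert np.array_equal(naive.species, aware.species)
        assert naive.n_events == aware.n_events

    def test_m_zero_confines_species_to_types(self):
        """With no mixing, point speciation means no shared ancestry across
        the boundary: between-type Bray-Curtis is exactly 1."""
        ls = split_landscape()
        cfg = SimulationConfig(
            landscape=ls,
            nu=0.005,
            kernels={1: DispersalKernel(2.0, 8.0), 2: DispersalKernel(2.0, 8.0)},
            mode="aware",
            mixing=0.0,
            seed=9,
        )
        census = coalesce(cfg)
        comm = census_to_community(census)
        rc = [(int(s[1 : s.index("c")]), int(s[s.index("c") + 1 :])) for s in comm.site_ids]
        stype = np.array([ls.forest_type[r, c] for r, c in rc])
        d = bray_curtis(comm)
        cross = d.values[np.ix_(stype == 1, stype == 2)]
        assert (cross == 1.0).all()


class TestCensusToCommunity:
    def test_conserves_individuals(self):
        ls = flat_landscape(6, 6, density=3)
        census = coalesce(SimulationConfig(landscape=ls, nu=0.1, kernels=DispersalKernel(1, 4), mode="naive", seed=1))
        comm = census_to_community(census)
        assert comm.counts.sum() == census.n_samples

    def test_single_cell_sample(self):
        ls = flat_landscape(5, 5, density=4)
        sm = np.zeros((5, 5), int)
        sm[2, 3] = 4
        census = coalesce(
            SimulationConfig(landscape=ls, nu=0.5, kernels=DispersalKernel(1, 4), mode="naive", sample_map=sm, seed=2)
        )
        comm = census_to_community(census)
        assert comm.n_sites == 1 and comm.site_ids[0] == "r2c3"

    def test_manual_tally(self):
        ls = flat_landscape(3, 3, density=10)
        census = Census(
            rows=np.array([0, 0, 0, 1, 1, 2, 2, 2, 2, 2]),
            cols=np.array([0, 0, 1, 1, 1, 2, 2, 2, 2, 2]),
            species=np.array([0, 1, 0, 2, 2, 1, 1, 0, 2, 2]),
            landscape=ls,
        )
        comm = census_to_community(census)
        table = {sid: row for sid, row in zip(comm.site_ids, comm.counts)}
        assert list(table["r0c0"]) == [1, 1, 0]
        assert list(table["r0c1"]) == [1, 0, 0]
        assert list(table["r1c1"]) == [0, 0, 2]
        assert list(table["r2c2"]) == [1, 2, 2]
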