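import numpy as np
import pytest

from craterdemog.coalescent import (
    expected_branch_sfs,
    simulate_genealogy,
    simulate_sfs,
)
from craterdemog.demography import (
    CRATER_MLE,
    AdmixturePulse,
    Deme,
    DemographicModel,
    EpochTable,
    SizeChange,
    crater_colonization_model,
)


def single_deme(n_samples, size=1000.0, growth=0.0):
    return DemographicModel(
        demes=[Deme("a", size, growth)], sample_config={"a": n_samples}
    )


class TestEpochTable:
    def test_exponential_trajectory_between_events(self):
        m = DemographicModel(
            demes=[Deme("a", 1000.0, 0.01)],
            events=[SizeChange(100.0, "a", 500.0, 0.0)],
            sample_config={"a": 2},
        )
        t = EpochTable(m)
        assert t.size_at(0, 0.0) == pytest.approx(1000.0)
        assert t.size_at(0, 50.0) == pytest.approx(1000.0 * np.exp(-0.5))
        assert t.size_at(0, 100.0) == pytest.approx(500.0)
        assert t.size_at(0, 5000.0) == pytest.approx(500.0)

    def test_crater_model_growth_endpoints(self):
        m = crater_colonization_model(**CRATER_MLE)
        t = EpochTable(m)
        crater = m.deme_index("crater")
        source = m.deme_index("source")
        assert t.size_at(crater, 0.0) == pytest.approx(CRATER_MLE["n_crater_now"])
        assert t.size_at(crater, CRATER_MLE["t_col"] - 1e-9) == pytest.approx(
            CRATER_MLE["n_founder"], rel=1e-6
        )
        assert t.size_at(source, CRATER_MLE["t_bneck"] - 1e-9) == pytest.approx(
            CRATER_MLE["n_bneck"], rel=1e-6
        )
        assert t.size_at(source, CRATER_MLE["t_bneck"] + 1e-9) == pytest.approx(
            CRATER_MLE["n_anc"], rel=1e-6
        )


class TestGenealogy:
    def test_pairwise_tmrca_expectation(self):
        """E[T2] = 2N generations for two lineages in a constant deme."""
        m = single_deme(2, size=1000.0)
        t = np.mean([simulate_genealogy(m, seed=s).tmrca for s in range(4000)])
        assert t == pytest.approx(2000.0, rel=0.05)

    def test_total_branch_length_watterson(self):
        """E[L] = 4N * sum_{i<n} 1/i for n samples, constant N."""
        m = single_deme(10, size=1000.0)
        _, total = expected_branch_sfs(m, 10_000, seed=1)
        expect = 4 * 1000.0 * sum(1.0 / i for i in range(1, 10))
        assert total == pytest.approx(expect, rel=0.03)

    def test_tree_is_valid(self):
        g = simulate_genealogy(single_deme(8), seed=3)
        assert g.n_leaves == 8
        assert np.all(g.node_time[:8] == 0.0)
        for c, p in enumerate(g.parent):
            if p >= 0:
                assert g.node_time[p] > g.node_time[c]
        assert (g.parent < 0).sum() == 1  # single root
        assert np.array_equal(g.leaves_below(g.root), np.arange(8))

    def test_zero_migration_stays_in_sampled_deme(self):
        """With no migration and samples in one deme only, coalescence uses
        only that deme: TMRCA matches its size, not the other deme's."""
        m = DemographicModel(
            demes=[Deme("a", 500.0), Deme("b", 1e8)],
            events=[SizeChange(1e7, "b", 1.0)],  # irrelevant to deme a
            sample_config={"a": 2, "b": 0},
        )
        t = np.mean([simulate_genealogy(m, seed=s).tmrca for s in range(2000)])
        assert t == pytest.approx(2 * 500.0, rel=0.08)

    def test_fixed_seed_reproducible(self):
        m = crater_colonization_model(**CRATER_MLE, samples=(10, 10))
        g1 = simulate_genealogy(m, seed=7)
        g2 = simulate_genealogy(m, seed=7)
        assert np.array_equal(g1.parent, g2.parent)
        assert np.array_equal(g1.node_time, g2.node_time)


class TestSfsSimulation:
    def test_single_deme_spectrum_proportional_to_one_over_i(self):
        """Counts of i-ton sites at 1e5 candidate sites follow ~1/i."""
        m = single_deme(10, size=5000.0)
        sfs = simulate_sfs(m, mu=1e-6, n_sites=100_000, seed=5, fold=False)
        xi = sfs.counts[1:10, 0]
        theta = xi.sum() / sum(1.0 / i for i in range(1, 10))
        expect = theta / np.arange(1, 10)
        # each class is ~Poisson; allow 4 sigma around the closed form
        assert np.all(np.abs(xi - expect) <= 4.0 * np.sqrt(expect))

    def test_mu_zero_all_monomorphic(self):
        sfs = simulate_sfs(single_deme(6), mu=0.0, n_sites=500, seed=1, fold=False)
        assert sfs.n_polymorphic == 0
        assert sfs.counts[0, 0] == 500

    def test_doubling_mu_doubles_polymorphic_sites(self):
        m = single_deme(10, size=5000.0)
        s1 = simulate_sfs(m, mu=5e-7, n_sites=100_000, seed=2)
        s2 = simulate_sfs(m, mu=1e-6, n_sites=100_000, seed=3)
        assert s2.n_polymorphic / s1.n_polymorphic == pytest.approx(2.0, rel=0.05)

    def test_long_isolation_kills_shared_polymorphism(self):
        m = DemographicModel(
            demes=[Deme("a", 1000.0), Deme("b", 1000.0)],
            events=[
                AdmixturePulse(50_000.0, "a", "b", 1.0)  # merge far in the past
            ],
            sample_config={"a": 6, "b": 6},
        )
        sfs = simulate_sfs(m, mu=1e-6, n_sites=20_000, seed=4)
        shared = sfs.counts[1:, 1:].sum()
        assert shared / max(sfs.n_polymorphic, 1) < 0.01

    def test_seed_determinism(self):
        m = crater_colonization_model(**CRATER_MLE, samples=(10, 10))
        a = simulate_sfs(m, mu=7.5e-9, n_sites=5000, seed=9)
        b = simulate_sfs(m, mu=7.5e-9, n_sites=5000, seed=9)
        assert np.array_equal(a.counts, b.counts)


@pytest.fixture(scope="module")
def models():
    """Matched engine / msprime two-deme founding-plus-migration models."""
    import msprime

    n_crater_now, n_founder, t_col = 5000.0, 50.0, 400.0
    n_source, mig = 20_000.0, 1e-4
    growth = np.log(n_crater_now / n_founder) / t_col
    ours = crater_colonization_model(
        n_anc=n_source, n_bneck=n_source, t_bneck=1e9, n_source_now=n_source,
        n_founder=n_founder, t_col=t_col, n_crater_now=n_crater_now,
        mig=mig, samples=(10, 10), source_bottlegrowth=False,
    )
    dem = msprime.Demography()
    dem.add_population(name="crater", initial_size=n_crater_now,
                       growth_rate=growth, initially_active=True)
    dem.add_population(name="source", initial_size=n_source,
                       initially_active=True)
    dem.set_migration_rate(source="crater", dest="source", rate=mig)
    # founding emulated by a total mass migration so both populations
    # stay active (a population_split would deactivate the crater)
    dem.add_migration_rate_change(time=t_col, rate=0.0)
    dem.add_mass_migration(time=t_col, source="crater", dest="source",
                           proportion=1.0)
    dem.add_population_parameters_change(time=t_col, population="crater",
                                         initial_size=100.0, growth_rate=0.0)
    dem.sort_events()
    return ours, dem


class TestAgainstMsprime:
    """Independent cross-check of the engine against msprime on a two-deme
    model with a founding event, growth and migration."""

    def test_expected_branch_sfs_agrees(self, models):
        import msprime

        ours, dem = models
        n_rep = 20_000
        B, total = expected_branch_sfs(ours, n_rep, seed=11)
        reps = msprime.sim_ancestry(
            samples={"crater": 5, "source": 5}, demography=dem, ploidy=2,
            num_replicates=n_rep, random_seed=12,
        )
        grid = np.zeros((11, 11))
        tot_ms = 0.0
        for ts in reps:
            tree = ts.first()
            p1 = set(ts.samples(population=0))
            for node in tree.nodes():
                if tree.parent(node) == -1:
                    continue
                ln = tree.branch_length(node)
                leaves = set(tree.leaves(node))
                i = len(leaves & p1)
                j = len(leaves) - i
                grid[i, j] += ln
                tot_ms += ln
        grid /= n_rep
        tot_ms /= n_rep
        assert total == pytest.approx(tot_ms, rel=0.03)
        # dominant cells agree within Monte-Carlo slack, and the whole
        # spectra are close in total-variation distance
        ours_flat = B / B.sum()
        ms_flat = grid / grid.sum()
        big = ms_flat > 5e-3
        assert np.allclose(ours_flat[big], ms_flat[big], rtol=0.2)
        assert 0.5 * np.abs(ours_flat - ms_flat).sum() < 0.02
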