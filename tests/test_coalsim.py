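import math

import numpy as np
import pytest

from shandiv._kernels import (
    draw_subsamples,
    pairwise_coalescence_times,
    simulate_locus_states,
)
from shandiv.coalsim import (
    ALLELE_CAPS,
    MUTATION_RATES,
    Demography,
    LocusSpec,
    SimulationConfig,
    default_loci,
    default_scenarios,
    simulate_locus,
    simulate_population,
    _simulate_population_seeded,
)
from shandiv.estimators import gene_diversity
from shandiv.popdata import allele_counts


class TestDesignDefaults:
    def test_locus_grid_layout(self):
        loci = default_loci()
        assert len(loci) == 24
        assert (loci[0].name, loci[0].mu, loci[0].k_max) == ("L01", 0.0001, 3)
        assert (loci[23].name, loci[23].mu, loci[23].k_max) == ("L24", 0.001, 20)
        assert (loci[6].name, loci[6].mu, loci[6].k_max) == ("L07", 0.0002, 3)
        assert [l.mu for l in loci] == [
            mu for mu in MUTATION_RATES for _ in ALLELE_CAPS
        ]
        assert [l.k_max for l in loci] == list(ALLELE_CAPS) * 4

    def test_four_scenarios(self):
        sc = default_scenarios()
        assert set(sc) == {"P_C", "P_500", "P_50", "P_20"}
        assert sc["P_C"].epochs == ((math.inf, 10000),)
        assert sc["P_20"].epochs == ((20.0, 10000), (20.0, 20), (math.inf, 10000))

    def test_demography_validation(self):
        with pytest.raises(ValueError):
            Demography(epochs=((5.0, 100),))  # final epoch must be unbounded
        with pytest.raises(ValueError):
            Demography(epochs=((math.inf, 100), (math.inf, 100)))
        with pytest.raises(ValueError):
            Demography(epochs=((10.0, 0), (math.inf, 100)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(pop_size=100, sample_sizes=(200,))
        with pytest.raises(ValueError):
            SimulationConfig(n_resamples=1)
        with pytest.raises(ValueError):
            SimulationConfig(boundary="bounce")


class TestLocusSimulation:
    def test_no_mutation_gives_root_state_everywhere(self):
        ends = np.array([np.inf])
        sizes = np.array([100.0])
        states = simulate_locus_states(50, ends, sizes, 0.0, 9, 4, 123, False)
        assert np.all(states == 4)

    def test_states_bounded_and_sample_sized(self):
        d = Demography.constant(200)
        locus = LocusSpec("L", mu=0.01, k_max=6)
        rng = np.random.default_rng(5)
        states = simulate_locus(d, locus, 300, rng)
        assert states.shape == (300,)
        assert states.min() >= 0 and states.max() <= 5

    def test_seed_determinism(self):
        d = Demography.constant(500)
        locus = LocusSpec("L", mu=0.005, k_max=10)
        a = simulate_locus(d, locus, 100, np.random.default_rng(9))
        b = simulate_locus(d, locus, 100, np.random.default_rng(9))
        c = simulate_locus(d, locus, 100, np.random.default_rng(10))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_few_copies_rejected(self):
        d = Demography.constant(100)
        locus = LocusSpec("L", mu=0.001, k_max=5)
        with pytest.raises(ValueError, match="at least 2"):
            simulate_locus(d, locus, 1, np.random.default_rng(0))


class TestCoalescentCalibration:
    def test_constant_size_pair_coalescence_mean_is_2n(self):
        ends = np.array([np.inf])
        sizes = np.array([1000.0])
        times = pairwise_coalescence_times(ends, sizes, 8000, 77)
        assert np.mean(times) == pytest.approx(2000.0, rel=0.05)

    def test_bottleneck_pair_coalescence_matches_survival_integral(self):
        """Mean pair coalescence time through a bottleneck equals the
        integral of the analytic survival function."""
        d = Demography(epochs=((20.0, 1000), (20.0, 50), (math.inf, 1000)))
        ends, sizes = d._arrays()
        times = pairwise_coalescence_times(ends, sizes, 20000, 78)

        # survival: S(t) = exp(-integral of 1/(2N(u)) du)
        def mean_time():
            h1, h2, h3 = 1 / 2000, 1 / 100, 1 / 2000
            m1 = (1 - math.exp(-20 * h1)) / h1
            s1 = math.exp(-20 * h1)
            m2 = s1 * (1 - math.exp(-20 * h2)) / h2
            s2 = s1 * math.exp(-20 * h2)
            return m1 + m2 + s2 / h3 + 0  # last epoch exponential tail
        assert np.mean(times) == pytest.approx(mean_time(), rel=0.05)

    def test_identity_probability_matches_stepwise_mutation_theory(self):
        """Unbounded stepwise mutation: P(two random copies identical) is
        1/sqrt(1+2*theta) (Ohta-Kimura), theta = 4*N*mu."""
        n_pop, mu = 2500, 0.0004
        theta = 4 * n_pop * mu
        ends = np.array([np.inf])
        sizes = np.array([float(n_pop)])
        same = 0
        runs = 15000
        for r in range(runs):
            s = simulate_locus_states(2, ends, sizes, mu, 4001, 2000, 10_000 + r, False)
            same += s[0] == s[1]
        assert same / runs == pytest.approx(1 / math.sqrt(1 + 2 * theta), abs=0.02)


class TestPopulationSimulation:
    def test_shape_and_pairing(self):
        d = Demography.constant(300)
        loci = [LocusSpec("A", 0.001, 6), LocusSpec("B", 0.002, 9)]
        pop = simulate_population(d, loci, 50, np.random.default_rng(2))
        assert pop.genotypes.shape == (50, 2, 2)
        assert pop.loci == ["A", "B"]
        assert allele_counts(pop, "A").n == 100

    def test_master_seed_determinism(self):
        d = Demography.constant(300)
        loci = [LocusSpec("A", 0.001, 6)]
        a = _simulate_population_seeded(d, loci, 40, 11, 0, 0)
        b = _simulate_population_seeded(d, loci, 40, 11, 0, 0)
        c = _simulate_population_seeded(d, loci, 40, 11, 0, 1)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert not np.array_equal(a.genotypes, c.genotypes)

    def test_bottleneck_reduces_gene_diversity_in_paired_replicates(self):
        """Reduced-scale check: a severe 20-generation bottleneck lowers
        mean gene diversity relative to a constant-size control in nearly
        every paired replicate."""
        loci = [LocusSpec(f"L{i}", mu, 10)
                for i, mu in enumerate((0.002, 0.001, 0.0005, 0.002, 0.001, 0.0005))]
        control = Demography.constant(1000)
        crash = Demography(epochs=((20.0, 1000), (20.0, 5), (math.inf, 1000)))
        wins = 0
        n_pairs = 50
        for r in range(n_pairs):
            pc = _simulate_population_seeded(control, loci, 150, 101, r, 0)
            pb = _simulate_population_seeded(crash, loci, 150, 101, r, 1)
            hc = np.mean([gene_diversity(allele_counts(pc, l.name)) for l in loci])
            hb = np.mean([gene_diversity(allele_counts(pb, l.name)) for l in loci])
            wins += hb < hc
        assert wins >= 0.95 * n_pairs

    def test_gene_diversity_increases_with_mutation_rate(self):
        """At a fixed allelic cap of 20, mean control-population gene
        diversity is strictly increasing across the four design rates."""
        control = Demography.constant(2000)
        means = []
        for m_idx, mu in enumerate(MUTATION_RATES):
            locus = LocusSpec("L", mu, 20)
            vals = [
                gene_diversity(
                    allele_counts(
                        _simulate_population_seeded(control, [locus], 200, 55, m_idx, r),
                        "L",
                    )
                )
                for r in range(60)
            ]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_allelic_cap_binds_at_high_mutation_rate(self):
        control = Demography.constant(2000)
        for cap in (3, 6):
            locus = LocusSpec("L", 0.001, cap)
            k_obs = [
                allele_counts(
                    _simulate_population_seeded(control, [locus], 200, 56, cap, r),
                    "L",
                ).k_obs
                for r in range(40)
            ]
            assert max(k_obs) <= cap
            if cap == 3:
                assert np.mean(k_obs) > 2.5

    def test_agrees_with_msprime_bounded_stepwise_model(self):
        """Independent oracle: msprime's bounded stepwise microsatellite
        model gives the same mean gene diversity for one design locus."""
        msprime = pytest.importorskip("msprime")
        n_pop, mu, k = 2000, 0.001, 6
        reps = 40
        ours = []
        d = Demography.constant(n_pop)
        locus = LocusSpec("L", mu, k)
        for r in range(reps):
            pop = _simulate_population_seeded(d, [locus], 250, 77, r)
            ours.append(gene_diversity(allele_counts(pop, "L")))
        theirs = []
        root = [1.0 if i == k // 2 else 0.0 for i in range(k)]
        model = msprime.SMM(lo=0, hi=k - 1, root_distribution=root)
        for r in range(reps):
            ts = msprime.sim_ancestry(
                samples=250, population_size=n_pop, random_seed=1000 + r
            )
            mts = msprime.sim_mutations(
                ts, rate=mu, model=model, random_seed=2000 + r
            )
            if mts.num_sites == 0:
                theirs.append(0.0)
                continue
            var = next(mts.variants())
            states = np.array([int(var.alleles[g]) for g in var.genotypes])
            c = np.bincount(states)
            theirs.append(gene_diversity(c[c > 0]))
        assert np.mean(ours) == pytest.approx(np.mean(theirs), abs=0.05)


def test_subsample_kernel_draws_uniform_distinct_indices():
    draws = draw_subsamples(30, 5, 4000, 99)
    assert draws.shape == (4000, 5)
    for row in draws[:50]:
        assert len(set(row.tolist())) == 5
    # uniform inclusion: each index appears in ~ ns/n of draws
    freq = np.bincount(draws.ravel(), minlength=30) / (4000 * 5)
    assert np.allclose(freq, 1 / 30, atol=0.01)
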