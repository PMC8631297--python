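"""Coalescent simulator: priors, genealogies, datasets, plastid locus.

msprime serves as the independent oracle for the structured-scenario
cross-check; the simulator itself never calls it.
"""

import math
import random

import numpy as np
import pytest

from cliffpop.coalescent import (
    CAPRI,
    DEFAULT_SAMPLE_SIZES,
    PALINURO,
    STROMBOLICCHIO,
    DemographicModel,
    ParameterDraw,
    PriorSet,
    default_population_map,
    sample_prior,
    simulate_dataset,
    simulate_genealogy,
    simulate_plastid,
)
from cliffpop.genotypes import MISSING
from cliffpop.popgen import _per_locus_ho_he

MID_DRAW = ParameterDraw(300, 255, 30, 28, 28, 37500, 12500, 55)


class TestPriors:
    def test_constraints_hold_over_many_draws(self):
        p = PriorSet()
        rnd = random.Random(123)
        for _ in range(1000):
            d = sample_prior(p, rng=rnd)
            assert d.t1 > d.t2 and d.db < d.t2
            for name in p.parameter_names:
                lo, hi = getattr(p, name)
                assert lo <= getattr(d, name) <= hi

    def test_degenerate_ranges_give_unique_draw(self):
        p = PriorSet(
            n_palinuro=(200, 200), n_capri=(100, 100), n_strombolicchio=(20, 20),
            n1b=(8, 8), n2b=(9, 9), t1=(40000, 40000), t2=(5000, 5000), db=(50, 50),
        )
        d = sample_prior(p, seed=0)
        assert (d.t1, d.t2, d.db, d.n1b) == (40000, 5000, 50, 8)

    def test_uniform_mean_of_island_size(self):
        p = PriorSet()
        rnd = random.Random(7)
        draws = [sample_prior(p, rng=rnd).n_strombolicchio for _ in range(10000)]
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 30.0) < 3 * se

    def test_infeasible_constraint_fails(self):
        p = PriorSet(t1=(10, 20), t2=(30, 40))
        with pytest.raises(RuntimeError):
            sample_prior(p, seed=0, max_attempts=200)

    def test_invalid_draw_rejected(self):
        with pytest.raises(ValueError):
            ParameterDraw(300, 255, 30, 28, 28, 100, 200, 55)  # t1 < t2
        with pytest.raises(ValueError):
            ParameterDraw(300, 255, 30, 28, 28, 300, 200, 250)  # db >= t2


class TestSimulateDataset:
    def test_every_locus_polymorphic(self):
        g = simulate_dataset(DemographicModel(1), MID_DRAW, n_loci=60, seed=4)
        ac = g.genotypes.sum(axis=0)
        assert ((ac > 0) & (ac < 2 * g.n_individuals)).all()

    def test_bit_identical_for_same_seed(self):
        a = simulate_dataset(DemographicModel(2), MID_DRAW, n_loci=30, seed=9)
        b = simulate_dataset(DemographicModel(2), MID_DRAW, n_loci=30, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.individual_ids == b.individual_ids

    def test_seed_changes_output(self):
        a = simulate_dataset(DemographicModel(2), MID_DRAW, n_loci=30, seed=9)
        b = simulate_dataset(DemographicModel(2), MID_DRAW, n_loci=30, seed=10)
        assert not np.array_equal(a.genotypes, b.genotypes)

    def test_missingness_overlay(self):
        g = simulate_dataset(
            DemographicModel(1), MID_DRAW, n_loci=200, seed=2, missing_prob=0.3
        )
        frac = (g.genotypes == MISSING).mean()
        assert 0.25 < frac < 0.35

    def test_exchangeability_within_demes(self):
        """Population-level statistics are invariant to relabelling individuals."""
        from cliffpop.abcrf import summary_vector

        pm = default_population_map()
        g = simulate_dataset(DemographicModel(1), MID_DRAW, n_loci=80, seed=6)
        v1 = summary_vector(g, pm).values
        # permute rows within each population block
        rng = np.random.default_rng(0)
        order = np.concatenate([rng.permutation(10), 10 + rng.permutation(8), 18 + rng.permutation(7)])
        from cliffpop.genotypes import select_individuals

        ids = [g.individual_ids[i] for i in order]
        g2 = select_individuals(g, ids)
        v2 = summary_vector(g2, pm).values
        assert np.allclose(v1, v2, equal_nan=True)

    def test_founder_bottleneck_reduces_island_diversity(self):
        """At fixed split times, a stronger founder bottleneck lowers He."""
        pm = default_population_map()

        def mean_str_he(d, tag):
            vals = []
            for s in range(120):
                g = simulate_dataset(DemographicModel(1), d, n_loci=40, seed=tag * 100000 + s)
                idx = pm.indices_by_population(g)[STROMBOLICCHIO]
                _, he = _per_locus_ho_he(g.genotypes[idx])
                vals.append(np.nanmean(he))
            return float(np.mean(vals))

        strong = ParameterDraw(300, 255, 30, 28, 5, 20000, 200, 90)
        weak = ParameterDraw(300, 255, 30, 28, 50, 20000, 200, 10)
        assert mean_str_he(strong, 1) < mean_str_he(weak, 2)

    def test_scenario_separability_capri_strombolicchio_fst(self):
        """Strombolicchio founded from Capri (scenario 1) vs from Palinuro
        (scenario 2) shifts the Capri-Strombolicchio Fst distribution down."""
        from cliffpop.popgen import wc_theta

        pm = default_population_map()
        means = {}
        for scen in (1, 2):
            vals = []
            for s in range(200):
                g = simulate_dataset(DemographicModel(scen), MID_DRAW, n_loci=40, seed=scen * 50000 + s)
                idx = pm.indices_by_population(g)
                vals.append(wc_theta([g.genotypes[idx[CAPRI]], g.genotypes[idx[STROMBOLICCHIO]]]))
            means[scen] = (np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals)))
        assert means[1][0] < means[2][0] - 2 * (means[1][1] + means[2][1])


class TestGenealogy:
    def test_pairwise_tmrca_matches_theory(self):
        """Two lineages in a diploid deme of size N coalesce in ~2N generations."""
        times = [
            simulate_genealogy(
                DemographicModel.panmictic(), MID_DRAW, {PALINURO: 1}, seed=s
            ).tmrca
            for s in range(800)
        ]
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - 2 * MID_DRAW.n_palinuro) < 3 * se

    def test_structured_scenario_matches_msprime(self):
        """Cross-check within/between-deme branch diversity against msprime
        for scenario 1 at fixed parameters."""
        import msprime

        d = ParameterDraw(300, 200, 40, 10, 10, 3000, 1000, 90)
        sizes = {PALINURO: 3, CAPRI: 3, STROMBOLICCHIO: 3}

        dem = msprime.Demography()
        dem.add_population(name="Pal", initial_size=300)
        dem.add_population(name="Cap", initial_size=200)
        dem.add_population(name="Str", initial_size=40)
        dem.add_population_parameters_change(time=d.t2 - d.db, population="Str", initial_size=d.n2b)
        dem.add_mass_migration(time=d.t2, source="Str", dest="Cap", proportion=1.0)
        dem.add_population_parameters_change(time=d.t1 - d.db, population="Cap", initial_size=d.n1b)
        dem.add_mass_migration(time=d.t1, source="Cap", dest="Pal", proportion=1.0)

        reps = msprime.sim_ancestry(
            samples={"Pal": 3, "Cap": 3, "Str": 3},
            demography=dem,
            num_replicates=400,
            random_seed=17,
        )
        ms_within_pal, ms_between_cs = [], []
        for ts in reps:
            p = ts.samples(population=0)
            c = ts.samples(population=1)
            s = ts.samples(population=2)
            ms_within_pal.append(float(np.squeeze(ts.diversity([p], mode="branch"))))
            ms_between_cs.append(float(np.squeeze(ts.divergence([c, s], mode="branch"))))

        my_within_pal, my_between_cs = [], []
        rnd = random.Random(23)
        for _ in range(400):
            t = simulate_genealogy(DemographicModel(1), d, sizes, rng=rnd)
            pal = [i for i, dm in enumerate(t.leaf_demes) if dm == PALINURO]
            cap = [i for i, dm in enumerate(t.leaf_demes) if dm == CAPRI]
            stm = [i for i, dm in enumerate(t.leaf_demes) if dm == STROMBOLICCHIO]
            my_within_pal.append(_mean_pair_time(t, pal, pal))
            my_between_cs.append(_mean_pair_time(t, cap, stm))
        # 2*T for branch-mode diversity; compare means within Monte-Carlo error
        for ms_vals, my_vals in (
            (ms_within_pal, np.array(my_within_pal) * 2),
            (ms_between_cs, np.array(my_between_cs) * 2),
        ):
            se = math.hypot(
                np.std(ms_vals, ddof=1) / math.sqrt(len(ms_vals)),
                np.std(my_vals, ddof=1) / math.sqrt(len(my_vals)),
            )
            assert abs(np.mean(ms_vals) - np.mean(my_vals)) < 4 * se


def _mean_pair_time(tree, group_a, group_b):
    """Mean coalescence time over pairs (a in A, b in B, a != b)."""
    # ancestor chains per leaf
    anc_time = []
    for leaf in range(tree.n_leaves):
        chain = {}
        v = leaf
        while v != -1:
            chain[v] = tree.time[v]
            v = tree.parent[v]
        anc_time.append(chain)
    times = []
    for a in group_a:
        for b in group_b:
            if a >= b:
                continue
            shared = [t for v, t in anc_time[a].items() if v in anc_time[b]]
            times.append(min(shared))
    return float(np.mean(times))


class TestPlastid:
    def test_zero_mutation_rate_single_haplotype(self):
        h = simulate_plastid(DemographicModel(1), MID_DRAW, seq_len=500, mu_per_seq=0.0, seed=1)
        assert len(h.ids) == 1
        assert sum(h.frequencies.values()) == sum(DEFAULT_SAMPLE_SIZES.values())

    def test_watterson_segregating_sites(self):
        """Panmictic haploid locus: E[S] = 2 * (N/2) * mu * sum 1/i."""
        n, N, mu = 10, 300, 1e-3
        a = sum(1.0 / i for i in range(1, n))
        expected = 2 * (N / 2) * mu * a
        counts = []
        for s in range(400):
            h = simulate_plastid(
                DemographicModel.panmictic(),
                MID_DRAW,
                {PALINURO: n},
                seq_len=5000,
                mu_per_seq=mu,
                seed=s,
            )
            seqs = list(h.sequences.values())
            S = sum(
                1
                for col in zip(*seqs)
                if len(set(col)) > 1
            )
            counts.append(S)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_isolated_demes_carry_private_haplotypes(self):
        d = ParameterDraw(300, 255, 30, 28, 28, 49000, 48000, 55)
        private = 0
        for s in range(40):
            h = simulate_plastid(DemographicModel(1), d, seq_len=5000, mu_per_seq=5e-4, seed=s)
            pops_per_hap = [set(pc) for pc in h.population_counts.values()]
            if any(len(ps) == 1 for ps in pops_per_hap):
                private += 1
        assert private >= 30  # isolation implies lineage sorting in most replicates

    def test_population_counts_sum_to_frequencies(self):
        h = simulate_plastid(DemographicModel(3), MID_DRAW, seq_len=800, mu_per_seq=1e-3, seed=5)
        for hid, f in h.frequencies.items():
            assert sum(h.population_counts[hid].values()) == f
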