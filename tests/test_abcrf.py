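"""Summary statistics, reference tables and the ABC random-forest steps."""

import numpy as np
import pandas as pd
import pytest

from cliffpop.abcrf import (
    ParameterEstimator,
    ReferenceTable,
    ScenarioClassifier,
    build_reference_table,
    choose_scenario,
    estimate_parameters,
    generations_to_years,
    simulate_reference_row,
    summary_vector,
)
from cliffpop.coalescent import (
    DemographicModel,
    ParameterDraw,
    PriorSet,
    default_population_map,
    sample_prior,
    simulate_dataset,
)
from cliffpop.genotypes import GenotypeMatrix, PopulationMap

MID_DRAW = ParameterDraw(300, 255, 30, 28, 28, 37500, 12500, 55)


@pytest.fixture(scope="module")
def small_table():
    """30 simulations per scenario; enough for interface-level checks."""
    return build_reference_table(n_per_scenario=30, n_loci=40, seed=11)


class TestSummaryVector:
    def test_fixed_population_zero_polymorphism(self):
        g = GenotypeMatrix(
            np.array([[0, 2], [0, 2], [1, 0], [1, 2]], dtype=np.int8),
            ("a", "b", "c", "d"),
            ("L1", "L2"),
        )
        pm = PopulationMap({"a": "X", "b": "X", "c": "Y", "d": "Y"})
        v = summary_vector(g, pm).as_series()
        assert v["poly_X"] == 0.0
        assert v["poly_Y"] == 1.0

    def test_identical_populations_no_differentiation(self):
        rng = np.random.default_rng(5)
        block = rng.integers(0, 3, size=(4, 30)).astype(np.int8)
        g = GenotypeMatrix(
            np.vstack([block, block]).astype(np.int8),
            tuple(f"i{k}" for k in range(8)),
            tuple(f"L{k}" for k in range(30)),
        )
        pm = PopulationMap({f"i{k}": ("X" if k < 4 else "Y") for k in range(8)})
        v = summary_vector(g, pm).as_series()
        assert v["Fst_X_Y"] < 0.05
        assert v["NeiD_X_Y"] == pytest.approx(0.0, abs=1e-12)

    def test_cross_module_consistency(self):
        """Vector entries equal direct recomputation via the statistics module."""
        from cliffpop.popgen import allele_sharing_distance, diversity_stats, wc_theta

        pm = default_population_map()
        g = simulate_dataset(DemographicModel(1), MID_DRAW, n_loci=50, seed=3)
        v = summary_vector(g, pm).as_series()
        div = diversity_stats(g, pm).table
        for pop in ("Palinuro", "Capri", "Strombolicchio"):
            assert v[f"Ho_{pop}"] == pytest.approx(div.loc[pop, "Ho"], abs=1e-12)
            assert v[f"He_{pop}"] == pytest.approx(div.loc[pop, "He"], abs=1e-12)
        groups = pm.indices_by_population(g)
        fst = wc_theta([g.genotypes[groups["Palinuro"]], g.genotypes[groups["Capri"]]])
        assert v["Fst_Palinuro_Capri"] == pytest.approx(fst, abs=1e-12)
        asd = allele_sharing_distance(g)
        cross = asd.values[np.ix_(groups["Palinuro"], groups["Capri"])]
        assert v["ASD_Palinuro_Capri"] == pytest.approx(np.nanmean(cross), abs=1e-12)

    def test_contrast_entries_are_pair_differences(self):
        pm = default_population_map()
        g = simulate_dataset(DemographicModel(2), MID_DRAW, n_loci=40, seed=8)
        v = summary_vector(g, pm).as_series()
        d = v["Fst_Palinuro_Capri"] - v["Fst_Palinuro_Strombolicchio"]
        assert v["dFst_Palinuro.Capri_vs_Palinuro.Strombolicchio"] == pytest.approx(d, abs=1e-12)


class TestReferenceTable:
    def test_row_counts_per_scenario(self):
        rt = build_reference_table(n_per_scenario=2, n_loci=10, seed=0)
        assert rt.n_rows == 8
        assert {int(s): int((rt.scenario_ids == s).sum()) for s in (1, 2, 3, 4)} == {
            1: 2, 2: 2, 3: 2, 4: 2,
        }

    def test_same_master_seed_identical(self):
        a = build_reference_table(n_per_scenario=3, n_loci=10, seed=5)
        b = build_reference_table(n_per_scenario=3, n_loci=10, seed=5)
        assert np.array_equal(a.row_seeds, b.row_seeds)
        pd.testing.assert_frame_equal(a.stats, b.stats)
        pd.testing.assert_frame_equal(a.params, b.params)

    def test_row_replay_from_recorded_seed(self, small_table):
        rt = small_table
        k = 17
        pm = default_population_map(rt.sample_sizes)
        draw, vec = simulate_reference_row(
            int(rt.scenario_ids[k]), int(rt.row_seeds[k]), rt.priors,
            rt.sample_sizes, rt.n_loci, pm,
        )
        assert draw.as_dict() == rt.params.iloc[k].to_dict()
        assert np.allclose(vec.values, rt.stats.iloc[k].to_numpy(), equal_nan=True)

    def test_tsv_round_trip(self, small_table, tmp_path):
        p = tmp_path / "rt.tsv"
        small_table.to_tsv(p)
        rt2 = ReferenceTable.from_tsv(p)
        assert rt2.n_rows == small_table.n_rows
        assert list(rt2.stats.columns) == list(small_table.stats.columns)
        assert np.allclose(
            rt2.stats.to_numpy(), small_table.stats.to_numpy(), equal_nan=True
        )
        assert rt2.priors == small_table.priors


class TestChooseScenario:
    def test_votes_sum_to_n_trees(self, small_table):
        pm = default_population_map()
        g = simulate_dataset(DemographicModel(1), MID_DRAW, n_loci=40, seed=1)
        res = choose_scenario(small_table, summary_vector(g, pm), n_trees=50, seed=0)
        assert sum(res.votes.values()) == 50
        assert 0.0 <= res.posterior_probability <= 1.0

    def test_indistinguishable_scenarios_vote_uniformly(self):
        """Labels assigned to identical panmictic simulations: votes near
        uniform, posterior probability near chance level."""
        pm = default_population_map()
        rows = []
        for k in range(160):
            g = simulate_dataset(
                DemographicModel.panmictic(), MID_DRAW, n_loci=40, seed=4000 + k
            )
            rows.append(summary_vector(g, pm).values)
        names = summary_vector(
            simulate_dataset(DemographicModel.panmictic(), MID_DRAW, n_loci=40, seed=1), pm
        ).names
        rt = ReferenceTable(
            scenario_ids=np.tile(np.array([1, 2, 3, 4]), 40),
            params=pd.DataFrame({"t1": np.ones(160)}),
            stats=pd.DataFrame(np.vstack(rows), columns=list(names)),
            row_seeds=np.arange(160),
            priors=PriorSet(),
            sample_sizes={"Palinuro": 10, "Capri": 8, "Strombolicchio": 7},
            n_loci=40,
            master_seed=0,
        )
        g_obs = simulate_dataset(DemographicModel.panmictic(), MID_DRAW, n_loci=40, seed=9999)
        res = choose_scenario(rt, summary_vector(g_obs, pm), n_trees=400, seed=2)
        fracs = np.array([res.votes[s] for s in (1, 2, 3, 4)]) / 400
        assert fracs.max() < 0.45  # no scenario dominates
        assert 0.05 <= res.posterior_probability <= 0.5  # near the 0.25 chance level

    def test_dimension_mismatch_rejected(self, small_table):
        from cliffpop.abcrf import SummaryStatVector

        bad = SummaryStatVector(("x", "y"), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="ordering"):
            choose_scenario(small_table, bad, n_trees=10, seed=0)

    def test_row_order_invariance_of_best_scenario(self, small_table):
        """Shuffling reference rows leaves the winning scenario unchanged
        (vote counts may shift within RF seed sensitivity)."""
        rt = small_table
        pm = default_population_map()
        g = simulate_dataset(
            DemographicModel(3), ParameterDraw(500, 500, 50, 5, 50, 500, 150, 90),
            n_loci=40, seed=77,
        )
        obs = summary_vector(g, pm)
        res1 = choose_scenario(rt, obs, n_trees=200, seed=1)
        perm = np.random.default_rng(0).permutation(rt.n_rows)
        rt_shuffled = ReferenceTable(
            rt.scenario_ids[perm],
            rt.params.iloc[perm].reset_index(drop=True),
            rt.stats.iloc[perm].reset_index(drop=True),
            rt.row_seeds[perm],
            rt.priors,
            rt.sample_sizes,
            rt.n_loci,
            rt.master_seed,
        )
        res2 = choose_scenario(rt_shuffled, obs, n_trees=200, seed=1)
        assert res1.best_scenario == res2.best_scenario


class TestEstimateParameters:
    def test_degenerate_prior_recovered_exactly(self):
        p = PriorSet(
            n_palinuro=(200, 200), n_capri=(100, 100), n_strombolicchio=(20, 20),
            n1b=(8, 8), n2b=(9, 9), t1=(40000, 40000), t2=(5000, 5000), db=(50, 50),
        )
        rt = build_reference_table(
            scenarios=(1, 2), priors=p, n_per_scenario=20, n_loci=20, seed=3
        )
        pm = default_population_map()
        g = simulate_dataset(DemographicModel(1), sample_prior(p, seed=1), n_loci=20, seed=5)
        post = estimate_parameters(rt.restrict_to(1), summary_vector(g, pm), n_trees=50, seed=0)
        assert post.table.loc["t1", "mean"] == 40000
        assert post.table.loc["t1", "q5"] == post.table.loc["t1", "q95"] == 40000
        assert "t1" in post.degenerate

    def test_quantile_ordering_and_prior_range(self, small_table):
        pm = default_population_map()
        g = simulate_dataset(DemographicModel(1), MID_DRAW, n_loci=40, seed=21)
        post = estimate_parameters(
            small_table.restrict_to(1), summary_vector(g, pm), n_trees=100, seed=0
        )
        t = post.table
        assert (t["q5"] <= t["median"]).all() and (t["median"] <= t["q95"]).all()
        assert (t["variance"] >= 0).all()
        for name in ("t1", "t2", "db", "n_palinuro"):
            lo, hi = getattr(small_table.priors, name)
            assert lo <= t.loc[name, "mean"] <= hi

    def test_parameter_subset(self, small_table):
        pm = default_population_map()
        g = simulate_dataset(DemographicModel(2), MID_DRAW, n_loci=40, seed=31)
        est = ParameterEstimator(
            small_table.restrict_to(2), n_trees=50, seed=0, params=("t1",)
        )
        post = est.predict(summary_vector(g, pm))
        assert list(post.table.index) == ["t1"]


class TestGenerationsToYears:
    @pytest.mark.parametrize(
        "gens,expected_mya",
        [(24615, 0.25), (9003, 0.09), (0, 0.0)],
    )
    def test_conversion(self, gens, expected_mya):
        years, mya = generations_to_years(gens, 10.0)
        assert years == gens * 10.0
        assert mya == expected_mya

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            generations_to_years(-1)
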