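"""The synthetic-data generator: networks, deaths, reports, samples, truth."""

import numpy as np
import pytest

from netsurvival.errors import EstimationError, GenerationError
from netsurvival.groups import DemographicGroup, DEFAULT_ADULT_SCHEDULE
from netsurvival.mortality import estimate_totals
from netsurvival.degree import estimate_avg_degree
from netsurvival.sensitivity import adjusted_death_count
from netsurvival.simulate import (
    ScenarioConfig,
    census_death_count_estimand,
    draw_survey,
    simulate_population,
    simulate_reports,
    simulate_survey,
    true_adjustment_factors,
)

ALL = DemographicGroup()


def small_config(**kw):
    defaults = dict(
        n_population=400,
        degree_mean=20.0,
        known_pops={"teachers": 12, "nurses": 20, "name_group": 30},
        n_strata=2,
        psus_per_stratum=4,
        psus_sampled=2,
        respondents_per_psu=20,
        seed=1,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestPopulation:
    def test_zero_rates_mean_no_decedents(self):
        cfg = small_config(death_rates={})
        pop = simulate_population(cfg)
        assert pop.death_count() == 0

    def test_fixed_seed_reproduces_population(self):
        cfg = small_config()
        a, b = simulate_population(cfg), simulate_population(cfg)
        np.testing.assert_array_equal(a.age, b.age)
        np.testing.assert_array_equal(a.alive, b.alive)
        assert all(np.array_equal(x, y) for x, y in zip(a.ties, b.ties))

    def test_ties_are_symmetric(self):
        pop = simulate_population(small_config())
        for i, adj in enumerate(pop.ties):
            for j in adj:
                assert i in pop.ties[j]

    def test_infeasible_degrees_raise(self):
        cfg = small_config(n_population=50, degree_mean=200.0)
        with pytest.raises(GenerationError, match="probability"):
            simulate_population(cfg)

    def test_degree_multiplier_moves_delta(self):
        rates = {k: v * 4 for k, v in ScenarioConfig().death_rates.items()}
        cfg = small_config(
            n_population=4000, degree_mean=30.0, death_rates=rates,
            decedent_degree_multiplier=1.6, seed=4,
        )
        pop = simulate_population(cfg)
        rep = simulate_reports(pop)
        delta = true_adjustment_factors(pop, rep, ALL).degree_ratio
        assert delta == pytest.approx(1.6, rel=0.15)

    def test_known_pop_membership_sizes(self):
        pop = simulate_population(small_config())
        assert {k: v.size for k, v in pop.known_pop_members.items()} == {
            "teachers": 12, "nurses": 20, "name_group": 30,
        }


class TestReports:
    def test_perfect_reporting_reproduces_decedent_ties(self):
        pop = simulate_population(small_config(seed=2))
        rep = simulate_reports(pop)
        dead = set(np.flatnonzero(~pop.alive))
        expected = {
            int(i): tuple(int(j) for j in pop.ties[i] if j in dead)
            for i in np.flatnonzero(pop.alive)
            if any(j in dead for j in pop.ties[i])
        }
        assert {k: tuple(sorted(v)) for k, v in rep.reports.items()} == {
            k: tuple(sorted(v)) for k, v in expected.items()
        }
        factors = true_adjustment_factors(pop, rep, ALL)
        assert factors.true_positive_rate == 1.0
        assert factors.precision == 1.0

    def test_total_false_negatives_empty_graph(self):
        pop = simulate_population(small_config(seed=2))
        rep = simulate_reports(pop, ScenarioConfig(**{**small_config().__dict__, "false_negative_prob": 1.0}))
        assert rep.n_reports == 0

    def test_false_positives_with_no_deaths_are_all_wrong(self):
        cfg = small_config(death_rates={}, false_positive_intensity=0.3, seed=3)
        pop = simulate_population(cfg)
        rep = simulate_reports(pop)
        assert rep.n_reports > 0
        assert all(pop.alive[j] for _, j in rep.pairs())
        # with no decedents the factor triple is undefined by construction
        with pytest.raises(EstimationError):
            true_adjustment_factors(pop, rep, ALL)


class TestSurveyDraw:
    def test_census_interviews_every_living_member_at_weight_one(self):
        cfg = small_config(census=True)
        pop = simulate_population(cfg)
        rep = simulate_reports(pop)
        sample, registry = draw_survey(pop, rep)
        assert sample.n == pop.living_count()
        assert set(sample.weights) == {1.0}
        assert registry.total_size == 62

    def test_design_weights_are_products_of_stage_probabilities(self):
        cfg = small_config()
        pop = simulate_population(cfg)
        rep = simulate_reports(pop)
        sample, _ = draw_survey(pop, rep)
        p_ratio = cfg.psus_per_stratum / cfg.psus_sampled
        for psu in np.unique(sample.psus):
            in_psu = sample.weights[sample.psus == psu]
            assert len(set(in_psu)) == 1  # same weight within a PSU
            living_in_psu = in_psu[0] / p_ratio * in_psu.size
            assert living_in_psu == pytest.approx(round(living_in_psu))
            assert living_in_psu >= in_psu.size

    def test_fixed_seed_reproduces_sample(self):
        cfg = small_config()
        pop = simulate_population(cfg)
        rep = simulate_reports(pop)
        s1, _ = draw_survey(pop, rep)
        s2, _ = draw_survey(pop, rep)
        assert s1 == s2

    def test_census_degree_estimate_recovers_true_mean_degree(self):
        """With membership independent of degree, the known-population
        estimator at census recovers the group's true mean network size."""
        cfg = small_config(
            n_population=3000, degree_mean=25.0, census=True,
            known_pops={"a": 150, "b": 250, "c": 200}, seed=6,
        )
        pop = simulate_population(cfg)
        rep = simulate_reports(pop)
        sample, registry = draw_survey(pop, rep)
        est = estimate_avg_degree(sample, registry, ALL, n_falpha="estimate")
        true_mean = np.mean([t.size for t in pop.ties])
        assert est.dbar == pytest.approx(true_mean, rel=0.1)


class TestTruthFactors:
    def test_hand_built_population_factors_match_hand_tallies(self, hand_population):
        pop = hand_population
        rep = simulate_reports(pop)
        # ties to living members: dead 5 -> {0,1,3}, dead 6 -> {1,2};
        # living degrees to living: 0:{1,2}=2, 1:{0}=1... full tallies:
        deg = pop.degree_to_living
        assert deg.tolist() == [2, 1, 2, 1, 0, 3, 2]
        factors = true_adjustment_factors(pop, rep, ALL)
        assert factors.degree_ratio == pytest.approx((5 / 2) / (6 / 5))
        assert factors.true_positive_rate == 1.0
        assert factors.precision == 1.0
        estimand = census_death_count_estimand(pop, rep, ALL)
        assert estimand == pytest.approx(5 / (6 / 5))
        assert adjusted_death_count(estimand, factors) == pytest.approx(2.0, abs=1e-12)

    def test_identity_with_misreporting(self):
        rates = {k: v * 6 for k, v in ScenarioConfig().death_rates.items()}
        cfg = small_config(
            n_population=600, death_rates=rates, decedent_degree_multiplier=0.7,
            false_negative_prob=0.3, false_positive_intensity=0.02, seed=9,
        )
        pop = simulate_population(cfg)
        rep = simulate_reports(pop)
        factors = true_adjustment_factors(pop, rep, ALL)
        estimand = census_death_count_estimand(pop, rep, ALL)
        assert adjusted_death_count(estimand, factors) == pytest.approx(
            pop.death_count(ALL), rel=1e-12
        )
        assert factors.precision < 1.0 and factors.true_positive_rate < 1.0


class TestScalableSurveyPath:
    def test_fixed_seed_reproduces_survey(self):
        cfg = ScenarioConfig(n_population=5000, seed=11)
        s1, r1, t1 = simulate_survey(cfg)
        s2, r2, t2 = simulate_survey(cfg)
        assert s1 == s2 and r1 == r2 and t1 == t2

    def test_truth_accounts_add_up(self):
        cfg = ScenarioConfig(n_population=8000, seed=12)
        sample, registry, truth = simulate_survey(cfg)
        n_total = sum(
            truth["death_counts"][k] + truth["living_counts"][k]
            for k in truth["death_counts"]
            if k.startswith("all:")
        )
        assert n_total == cfg.n_population
        assert sample.frame_total == sum(
            truth["living_counts"][k] for k in truth["living_counts"] if k.startswith("all:")
        )

    def test_estimates_track_realized_rates(self):
        cfg = ScenarioConfig(seed=13)
        sample, registry, truth = simulate_survey(cfg)
        m = estimate_totals(sample, registry, ALL).m_hat
        realized = sum(truth["death_counts"][f"all:{b.label}"] for b in DEFAULT_ADULT_SCHEDULE) / float(
            sample.frame_total
        )
        assert m == pytest.approx(realized, rel=0.25)

    def test_deaths_per_interview_scale(self):
        from netsurvival.mortality import deaths_per_interview

        sample, _, _ = simulate_survey(ScenarioConfig(seed=14))
        # mean degree 100 and ~1% annual mortality put reports per interview
        # in the high tenths, the scale seen with weak-tie definitions
        assert 0.3 < deaths_per_interview(sample) < 1.5
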