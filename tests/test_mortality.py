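"""Reported deaths, exposure, death counts and the composed death rate."""

import numpy as np
import pytest

from netsurvival.data import DeathReport, KnownPopulationRegistry, Respondent, SurveySample
from netsurvival.errors import EstimationError
from netsurvival.groups import DemographicGroup, DEFAULT_ADULT_SCHEDULE
from netsurvival.mortality import (
    deaths_per_interview,
    estimate_death_rate,
    estimate_exposure,
    estimate_num_deaths,
    estimate_reported_deaths,
    estimate_totals,
    rate_table,
)

SCHED = DEFAULT_ADULT_SCHEDULE
B15, B25 = SCHED.bands[0], SCHED.bands[1]
ALL = DemographicGroup()


def _sample(respondents, frame_total=100.0):
    return SurveySample(respondents, frame_total=frame_total)


def _resp(i, weight, reports=(), sex="female", band=B15, kp=None):
    return Respondent(
        str(i),
        "s",
        f"p{i}",
        weight,
        sex,
        band,
        known_pop_counts=kp or {},
        death_reports=reports,
    )


class TestReportedDeaths:
    def test_weighted_total(self):
        report = DeathReport("female", B25, 1.0)
        sample = _sample([_resp(i, 2.0, (report,)) for i in range(3)])
        assert estimate_reported_deaths(sample, DemographicGroup("female", B25)) == 6.0

    def test_census_unit_weights_is_raw_count(self):
        reports = (DeathReport("male", B15, 1.0), DeathReport("male", B15, 2.0))
        sample = _sample([_resp(0, 1.0, reports), _resp(1, 1.0, ())])
        assert estimate_reported_deaths(sample, DemographicGroup("male", B15)) == 2.0

    def test_additive_over_band_partition(self):
        rng = np.random.default_rng(5)
        respondents = []
        for i in range(20):
            reports = tuple(
                DeathReport(rng.choice(["female", "male"]), rng.choice(SCHED.bands), 2.0)
                for _ in range(rng.integers(0, 4))
            )
            respondents.append(_resp(i, float(rng.uniform(0.5, 3)), reports))
        sample = _sample(respondents)
        total = estimate_reported_deaths(sample, ALL)
        by_band = sum(
            estimate_reported_deaths(sample, DemographicGroup("all", b)) for b in SCHED.bands
        )
        assert by_band == pytest.approx(total, rel=1e-12)

    def test_reports_count_toward_decedent_group_not_respondent_group(self):
        # a male 25-34 respondent reporting a female 15-24 death contributes
        # to the female 15-24 numerator
        sample = _sample(
            [_resp(0, 3.0, (DeathReport("female", B15, 1.0),), sex="male", band=B25)]
        )
        assert estimate_reported_deaths(sample, DemographicGroup("female", B15)) == 3.0
        assert estimate_reported_deaths(sample, DemographicGroup("male", B25)) == 0.0


class TestExposure:
    def test_srs_returns_frame_size(self):
        sample = _sample([_resp(i, 25.0) for i in range(4)], frame_total=100.0)
        assert estimate_exposure(sample, ALL) == 100.0

    def test_empty_group_is_zero(self):
        sample = _sample([_resp(0, 1.0)])
        assert estimate_exposure(sample, DemographicGroup("male", None)) == 0.0

    def test_linear_in_weights(self, tiny_sample):
        base = estimate_exposure(tiny_sample, ALL)
        assert estimate_exposure(tiny_sample.with_scaled_weights(2.0), ALL) == pytest.approx(
            2 * base
        )


class TestNumDeaths:
    def _sample_with_degree_ten(self, reports_per_respondent):
        # 10 respondents, weight 10 (SRS of 100), 2 known-pop connections
        # each with sum N_A = 20  ->  dbar = 10
        registry = KnownPopulationRegistry((("teachers", 12), ("nurses", 8)))
        kp = {"teachers": 1, "nurses": 1}
        sample = _sample(
            [_resp(i, 10.0, reports_per_respondent, kp=kp) for i in range(10)]
        )
        return sample, registry

    def test_ratio_of_reports_to_degree(self):
        reports = tuple(DeathReport("female", B15, 1.0) for _ in range(5))
        sample, registry = self._sample_with_degree_ten(reports)
        # y_hat = 10 * 5 * 10 = 500, dbar = 10  ->  D_hat = 50
        assert estimate_num_deaths(sample, registry, DemographicGroup("female", B15)) == (
            pytest.approx(50.0, rel=1e-12)
        )

    def test_zero_reports_give_zero_regardless_of_degree(self):
        sample, registry = self._sample_with_degree_ten(())
        assert estimate_num_deaths(sample, registry, ALL) == 0.0

    def test_zero_degree_raises_pointing_at_sensitivity(self):
        registry = KnownPopulationRegistry((("teachers", 12),))
        sample = _sample(
            [_resp(0, 1.0, (DeathReport("female", B15, 1.0),), kp={"teachers": 0})]
        )
        with pytest.raises(EstimationError, match="sensitivity"):
            estimate_num_deaths(sample, registry, ALL)


class TestDeathRate:
    def test_rate_is_count_over_exposure(self):
        registry = KnownPopulationRegistry((("teachers", 12), ("nurses", 8)))
        kp = {"teachers": 1, "nurses": 1}
        reports = (DeathReport("female", B15, 1.0),)
        # y_hat = 100, dbar = 10, N_hat = 100  ->  M = 0.1
        sample = _sample([_resp(i, 10.0, reports, kp=kp) for i in range(10)])
        est = estimate_death_rate(sample, registry, ALL)
        assert est.point == pytest.approx(100.0 / (10.0 * 100.0), rel=1e-12)

    def test_no_reports_give_zero_rate(self):
        registry = KnownPopulationRegistry((("teachers", 12), ("nurses", 8)))
        sample = _sample([_resp(0, 1.0, (), kp={"teachers": 1, "nurses": 0})])
        assert estimate_death_rate(sample, registry, ALL).point == 0.0

    def test_invariant_to_common_weight_rescaling(self):
        registry = KnownPopulationRegistry((("teachers", 12), ("nurses", 8)))
        kp = {"teachers": 2, "nurses": 1}
        reports = (DeathReport("female", B15, 1.0),)
        sample = _sample([_resp(i, 1.0 + i, reports, kp=kp) for i in range(5)])
        base = estimate_death_rate(sample, registry, ALL).point
        scaled = estimate_death_rate(sample.with_scaled_weights(13.7), registry, ALL).point
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_internal_estimate_identity(self):
        """M_hat must equal y_hat * sum(N_A) / (y_known * N_F) exactly."""
        rng = np.random.default_rng(42)
        registry = KnownPopulationRegistry((("a", 30), ("b", 50), ("c", 20)))
        respondents = []
        for i in range(40):
            reports = tuple(
                DeathReport(rng.choice(["female", "male"]), rng.choice(SCHED.bands), 1.0)
                for _ in range(rng.integers(0, 3))
            )
            respondents.append(
                _resp(
                    i,
                    float(rng.uniform(0.5, 4)),
                    reports,
                    sex=str(rng.choice(["female", "male"])),
                    band=SCHED.bands[rng.integers(0, 6)],
                    kp={n: int(rng.integers(0, 5)) for n in registry.names},
                )
            )
        sample = _sample(respondents, frame_total=5000.0)
        for group in [ALL, DemographicGroup("female", None), DemographicGroup("all", B25)]:
            totals = estimate_totals(sample, registry, group)
            w = sample.weights
            mask = sample.group_mask(group)
            y_known = float(
                np.sum(sample.known_pop_matrix(registry.names)[mask].sum(axis=1) * w[mask])
            )
            closed_form = totals.y_hat * registry.total_size / (y_known * sample.frame_total)
            assert totals.m_hat == pytest.approx(closed_form, rel=1e-13)

    def test_window_scaling_annualizes(self):
        registry = KnownPopulationRegistry((("teachers", 12), ("nurses", 8)))
        kp = {"teachers": 1, "nurses": 1}
        reports = (DeathReport("female", B15, 1.0),)
        sample = _sample([_resp(i, 10.0, reports, kp=kp) for i in range(10)])
        annual = estimate_totals(sample, registry, ALL, window_months=12).m_hat
        half = estimate_totals(sample, registry, ALL, window_months=6).m_hat
        assert half == pytest.approx(2 * annual, rel=1e-12)


class TestDeathsPerInterview:
    def test_unweighted_mean(self):
        reports = [0, 1, 2, 0]
        sample = _sample(
            [
                _resp(i, 1.0, tuple(DeathReport("female", B15, 1.0) for _ in range(k)))
                for i, k in enumerate(reports)
            ]
        )
        assert deaths_per_interview(sample) == pytest.approx(0.75)

    def test_all_zero(self):
        sample = _sample([_resp(i, 1.0) for i in range(3)])
        assert deaths_per_interview(sample) == 0.0

    def test_weighted_mean(self):
        sample = _sample(
            [
                _resp(0, 1.0, ()),
                _resp(1, 3.0, (DeathReport("female", B15, 1.0), DeathReport("male", B15, 2.0))),
            ]
        )
        assert deaths_per_interview(sample, weighted=True) == pytest.approx(1.5)

    def test_arm_restriction(self, tiny_sample):
        # respondents a and c are in the acquaintance arm with 2 and 1 reports
        assert deaths_per_interview(tiny_sample, arm="acquaintance") == pytest.approx(1.5)
        assert deaths_per_interview(tiny_sample, arm="meal") == 0.0


def test_rate_table_has_one_row_per_sex_band(tiny_sample, registry):
    table = rate_table(tiny_sample, registry)
    assert len(table) == 12
    assert set(table["sex"]) == {"female", "male"}
    # groups with no respondents carry an error note instead of a rate
    assert (table["error"] != "").any()
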