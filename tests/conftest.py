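"""Shared fixtures: tiny hand-built surveys and brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from netsurvival.data import (
    DeathReport,
    KnownPopulationRegistry,
    Respondent,
    SurveySample,
)
from netsurvival.groups import AgeBand, AgeSchedule, DEFAULT_ADULT_SCHEDULE


@pytest.fixture
def schedule() -> AgeSchedule:
    return DEFAULT_ADULT_SCHEDULE


@pytest.fixture
def registry() -> KnownPopulationRegistry:
    return KnownPopulationRegistry((("teachers", 12), ("nurses", 8)))


@pytest.fixture
def tiny_sample(schedule) -> SurveySample:
    """Three respondents, two strata, hand-checkable weights and reports."""
    b15, b25 = schedule.bands[0], schedule.bands[1]
    return SurveySample(
        [
            Respondent(
                id="a",
                stratum="north",
                psu="n1",
                weight=1.5,
                sex="female",
                age_band=b15,
                arm="acquaintance",
                known_pop_counts={"teachers": 2, "nurses": 1},
                death_reports=(
                    DeathReport("female", b25, 3.0),
                    DeathReport("male", None, None),
                ),
            ),
            Respondent(
                id="b",
                stratum="north",
                psu="n2",
                weight=2.25,
                sex="male",
                age_band=b25,
                arm="meal",
                known_pop_counts={"teachers": 0, "nurses": 3},
                death_reports=(),
            ),
            Respondent(
                id="c",
                stratum="south",
                psu="s1",
                weight=0.875,
                sex="female",
                age_band=b25,
                arm="acquaintance",
                known_pop_counts={"teachers": 1, "nurses": None},
                death_reports=(DeathReport(None, b15, 11.5),),
            ),
        ],
        frame_total=100.0,
    )


def srs_subsample(sample: SurveySample, indices, weight: float) -> SurveySample:
    """The survey that an SRS drawing exactly ``indices`` would produce."""
    from dataclasses import replace

    chosen = [replace(sample.respondents[i], weight=weight) for i in indices]
    return SurveySample(chosen, frame_total=sample.frame_total)


def monthly_sibling_tally(records, interview_cmc, window_months, schedule, sex="all"):
    """Brute-force month-by-month exposure and death tally.

    Walks every calendar month in the window; a sibling alive for the whole
    month contributes 1/12 person-years to the band of their age that
    month, a sibling dying that month contributes the half month before the
    mid-month death instant.  Exact under month-resolution dates because
    band boundaries fall on month edges.
    """
    index = [b.label for b in schedule]
    exposure = {lab: 0.0 for lab in index}
    deaths = {lab: 0.0 for lab in index}
    t0 = interview_cmc - window_months
    for rec in records:
        if sex != "all" and rec.sex != sex:
            continue
        for m in range(t0, interview_cmc):
            if m < rec.birth_cmc:
                continue
            band = None
            age_months = m - rec.birth_cmc
            for b in schedule:
                if b.lo * 12 <= age_months < (b.hi * 12 if not math.isinf(b.hi) else math.inf):
                    band = b
                    break
            if band is None:
                continue
            if rec.alive or rec.death_cmc > m:
                exposure[band.label] += rec.weight / 12.0
            elif rec.death_cmc == m:
                exposure[band.label] += rec.weight * 0.5 / 12.0
        if not rec.alive and t0 <= rec.death_cmc < interview_cmc:
            age_at_death = (rec.death_cmc + 0.5 - rec.birth_cmc) / 12.0
            band = schedule.band_of(age_at_death)
            if band is not None:
                deaths[band.label] += rec.weight
    return exposure, deaths


@pytest.fixture
def hand_population():
    """Seven members, two decedents, explicit symmetric ties.

    Layout (ids): 0-4 alive, 5 and 6 dead.  Ties:
      0-1, 0-2, 0-5, 1-5, 1-6, 2-6, 3-5, 2-3  (symmetric)
    Member 4 is isolated.  All are female, ages spread over two bands.
    """
    from netsurvival.simulate import ScenarioConfig, SyntheticPopulation

    edges = [(0, 1), (0, 2), (0, 5), (1, 5), (1, 6), (2, 6), (3, 5), (2, 3)]
    neighbors = [[] for _ in range(7)]
    for i, j in edges:
        neighbors[i].append(j)
        neighbors[j].append(i)
    ties = [np.array(sorted(a), dtype=np.int64) for a in neighbors]
    alive = np.array([True, True, True, True, True, False, False])
    cfg = ScenarioConfig(n_population=7, degree_mean=2.0, known_pops={"teachers": 1})
    return SyntheticPopulation(
        config=cfg,
        schedule=DEFAULT_ADULT_SCHEDULE,
        sex=np.array(["female"] * 7, dtype=object),
        age=np.array([20.0, 30.0, 40.0, 50.0, 60.0, 35.0, 45.0]),
        expected_degree=np.full(7, 2.0),
        alive=alive,
        death_month=np.where(alive, np.nan, 6.0),
        known_pop_members={"teachers": np.array([4])},
        ties=ties,
    )
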