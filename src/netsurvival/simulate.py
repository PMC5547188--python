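"""Synthetic populations, reporting graphs and survey samples with known truth.

The generator embodies the population model the network survival estimator
assumes, so every estimand and every adjustment factor is computable
exactly:

* a finite adult population with sex, age, and a gamma-distributed expected
  personal network size;
* an undirected social network in which a tie between two members forms
  independently with probability proportional to the product of their
  expected degrees (a degree-configurable random graph — the one model
  under which all truths have closed forms);
* a 12-month mortality process with configurable age- and sex-specific
  rates; decedents' ties are frozen at death, and a configurable multiplier
  on decedents' expected degrees manipulates the degree ratio directly;
* a reporting process in which each living member reports each deceased
  network neighbour independently (with a configurable false-negative
  probability) and may erroneously report living neighbours as dead (a
  configurable false-positive intensity);
* membership in known populations assigned independently of degree;
* a stratified two-stage cluster sample with exact design weights.

Two generation paths are provided.  :func:`simulate_population` realises
the full network, which keeps every census quantity and adjustment factor
exactly computable; it is meant for populations up to a few tens of
thousands.  :func:`simulate_survey` exploits the independence of ties to
generate only what a survey observes — respondents' connection counts to
known-population members and decedents — which scales replication studies
to arbitrary population sizes at identical sampled-data distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from netsurvival.data import (
    DeathReport,
    KnownPopulationRegistry,
    Respondent,
    SurveySample,
)
from netsurvival.errors import DesignError, EstimationError, GenerationError
from netsurvival.groups import AgeBand, AgeSchedule, DemographicGroup, DEFAULT_ADULT_SCHEDULE
from netsurvival.sensitivity import AdjustmentFactors

#: Default 12-month death rates (deaths per person-year) by sex and band —
#: a schedule in the range typical of a high-mortality sub-Saharan setting.
DEFAULT_DEATH_RATES: dict[str, float] = {
    "female:15-24": 0.0030,
    "female:25-34": 0.0040,
    "female:35-44": 0.0055,
    "female:45-54": 0.0080,
    "female:55-64": 0.0140,
    "female:65+": 0.0400,
    "male:15-24": 0.0035,
    "male:25-34": 0.0050,
    "male:35-44": 0.0070,
    "male:45-54": 0.0100,
    "male:55-64": 0.0170,
    "male:65+": 0.0450,
}

#: Default adult age structure (young pyramid).
DEFAULT_AGE_STRUCTURE: dict[str, float] = {
    "15-24": 0.30,
    "25-34": 0.24,
    "35-44": 0.18,
    "45-54": 0.12,
    "55-64": 0.09,
    "65+": 0.07,
}

#: Default known populations as fractions of the population (Table-2-like
#: mix of occupations, name groups and demographic categories, ~7% total).
DEFAULT_KNOWN_POP_FRACTIONS: dict[str, float] = {
    "priests": 0.0008,
    "nurses": 0.0030,
    "teachers": 0.0100,
    "widowers": 0.0075,
    "new_mothers": 0.0120,
    "name_group_a": 0.0090,
    "name_group_b": 0.0130,
    "name_group_c": 0.0180,
}

_AGE_CAP = 90.0  # open-ended bands draw ages uniformly up to this


@dataclass
class ScenarioConfig:
    """Everything that defines one synthetic scenario.

    Death rates are keyed ``"sex:band"`` (e.g. ``"female:25-34"``).  The
    sampling design is ``n_strata`` strata, each containing
    ``psus_per_stratum`` equally sized PSUs of which ``psus_sampled`` are
    drawn, then ``respondents_per_psu`` living members per sampled PSU.
    The default design yields 10 x 4 x 60 = 2,400 respondents, the scale of
    one arm of a national survey experiment.
    """

    n_population: int = 20_000
    schedule: AgeSchedule = field(default_factory=lambda: DEFAULT_ADULT_SCHEDULE)
    age_structure: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_STRUCTURE))
    female_share: float = 0.52
    degree_mean: float = 100.0
    degree_shape: float = 2.0
    death_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DEATH_RATES))
    decedent_degree_multiplier: float = 1.0
    false_negative_prob: float = 0.0
    false_positive_intensity: float = 0.0
    known_pops: Optional[Mapping[str, int]] = None
    n_strata: int = 10
    psus_per_stratum: int = 20
    psus_sampled: int = 4
    respondents_per_psu: int = 60
    census: bool = False
    arm: str = "acquaintance"
    window_months: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_population <= 0:
            raise GenerationError("population size must be positive")
        if not 0 <= self.false_negative_prob <= 1:
            raise GenerationError("false-negative probability must lie in [0, 1]")
        if not 0 <= self.false_positive_intensity <= 1:
            raise GenerationError("false-positive intensity must lie in [0, 1]")
        if not 0 <= self.female_share <= 1:
            raise GenerationError("female share must lie in [0, 1]")
        if self.degree_mean <= 0 or self.degree_shape <= 0:
            raise GenerationError("degree distribution parameters must be positive")
        for key, rate in self.death_rates.items():
            if rate < 0:
                raise GenerationError(f"death rate for {key} must be nonnegative")
        if min(self.n_strata, self.psus_per_stratum, self.psus_sampled, self.respondents_per_psu) <= 0:
            raise GenerationError("design sizes must be positive")
        if self.psus_sampled > self.psus_per_stratum:
            raise DesignError("cannot sample more PSUs than a stratum contains")

    def rate(self, sex: str, band: AgeBand) -> float:
        return float(self.death_rates.get(f"{sex}:{band.label}", 0.0))

    def known_pop_sizes(self) -> dict[str, int]:
        if self.known_pops is not None:
            return {k: int(v) for k, v in self.known_pops.items()}
        return {
            name: max(1, round(frac * self.n_population))
            for name, frac in DEFAULT_KNOWN_POP_FRACTIONS.items()
        }

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "ScenarioConfig":
        """Build from a parsed config file (plain scalars and mappings)."""
        kwargs = dict(raw)
        if "schedule" in kwargs and isinstance(kwargs["schedule"], str):
            kwargs["schedule"] = AgeSchedule.parse(kwargs["schedule"])
        return cls(**kwargs)


@dataclass
class SyntheticPopulation:
    """A fully realised population: people, network, deaths, memberships.

    ``ties[i]`` is the array of member ids adjacent to member ``i``; ties
    are symmetric, and a decedent's ties represent the connections held
    during the 12 months before death.
    """

    config: ScenarioConfig
    schedule: AgeSchedule
    sex: np.ndarray
    age: np.ndarray
    expected_degree: np.ndarray
    alive: np.ndarray
    death_month: np.ndarray
    known_pop_members: dict[str, np.ndarray]
    ties: list[np.ndarray]
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.sex.size

    def group_mask(self, group: DemographicGroup) -> np.ndarray:
        key = ("mask", group.sex, group.age_band)
        if key not in self._cache:
            mask = np.ones(self.n, dtype=bool)
            if group.sex != "all":
                mask &= self.sex == group.sex
            if group.age_band is not None:
                mask &= (self.age >= group.age_band.lo) & (self.age < group.age_band.hi)
            self._cache[key] = mask
        return self._cache[key]

    @property
    def degree_to_living(self) -> np.ndarray:
        """Number of ties each member holds to living members (their reporters)."""
        if "deg_living" not in self._cache:
            self._cache["deg_living"] = np.array(
                [int(self.alive[t].sum()) for t in self.ties], dtype=float
            )
        return self._cache["deg_living"]

    def death_count(self, group: DemographicGroup = DemographicGroup()) -> int:
        return int(np.sum(self.group_mask(group) & ~self.alive))

    def living_count(self, group: DemographicGroup = DemographicGroup()) -> int:
        return int(np.sum(self.group_mask(group) & self.alive))

    def realized_death_rate(self, group: DemographicGroup = DemographicGroup()) -> float:
        """Finite-population deaths over survivors — the survey's estimand."""
        living = self.living_count(group)
        if living == 0:
            raise EstimationError(f"no living members in group {group.label}")
        return self.death_count(group) / living


@dataclass
class ReportingGraph:
    """Directed death reports: reporter member id -> claimed decedent ids.

    A claim about a living member is a false positive by construction.
    """

    reports: dict[int, tuple[int, ...]]

    @property
    def n_reports(self) -> int:
        return sum(len(v) for v in self.reports.values())

    def pairs(self):
        for reporter, targets in self.reports.items():
            for target in targets:
                yield reporter, target


def _rng(config_seed: int, seed: Optional[Union[int, np.random.Generator]]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(config_seed if seed is None else seed)


def _draw_ages(rng, bands: Sequence[AgeBand], band_idx: np.ndarray) -> np.ndarray:
    lo = np.array([b.lo for b in bands])
    hi = np.array([min(b.hi, _AGE_CAP) for b in bands])
    u = rng.random(band_idx.size)
    return lo[band_idx] + u * (hi[band_idx] - lo[band_idx])


def simulate_population(
    config: ScenarioConfig, seed: Optional[Union[int, np.random.Generator]] = None
) -> SyntheticPopulation:
    """Realise a full population with its social network and mortality.

    Ties are drawn independently with probability ``d_i * d_j / sum(d)``;
    a configuration whose largest such probability exceeds 1 cannot be
    realised and raises, suggesting a smaller mean degree or a larger
    population.
    """
    rng = _rng(config.seed, seed)
    n = config.n_population
    bands = list(config.schedule.bands)
    struct = np.array([config.age_structure.get(b.label, 0.0) for b in bands], dtype=float)
    if struct.sum() <= 0:
        raise GenerationError("age structure has no mass on the configured schedule")
    struct = struct / struct.sum()

    sex = np.where(rng.random(n) < config.female_share, "female", "male").astype(object)
    band_idx = rng.choice(len(bands), size=n, p=struct)
    age = _draw_ages(rng, bands, band_idx)
    degree = rng.gamma(config.degree_shape, config.degree_mean / config.degree_shape, size=n)

    death_prob = np.array(
        [1.0 - math.exp(-config.rate(s, bands[b])) for s, b in zip(sex, band_idx)]
    )
    alive = rng.random(n) >= death_prob
    death_month = np.where(alive, np.nan, rng.integers(1, 13, size=n).astype(float))
    degree = np.where(alive, degree, degree * config.decedent_degree_multiplier)

    sum_d = float(degree.sum())
    if degree.max() ** 2 / sum_d > 1.0:
        raise GenerationError(
            "tie probability d_i*d_j/sum(d) exceeds 1 for the largest degrees; "
            "reduce degree_mean (or its spread) or increase the population size"
        )

    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i in range(n - 1):
        p = degree[i] * degree[i + 1 :] / sum_d
        hits = np.flatnonzero(rng.random(n - 1 - i) < p) + i + 1
        if hits.size:
            neighbors[i].extend(hits.tolist())
            for j in hits:
                neighbors[j].append(i)
    ties = [np.array(sorted(adj), dtype=np.int64) for adj in neighbors]

    sizes = config.known_pop_sizes()
    if sum(sizes.values()) > n:
        raise GenerationError("known populations exceed the population size")
    perm = rng.permutation(n)
    members: dict[str, np.ndarray] = {}
    offset = 0
    for name, size in sizes.items():
        members[name] = np.sort(perm[offset : offset + size])
        offset += size

    return SyntheticPopulation(
        config=config,
        schedule=config.schedule,
        sex=sex,
        age=age,
        expected_degree=degree,
        alive=alive,
        death_month=death_month,
        known_pop_members=members,
        ties=ties,
    )


def simulate_reports(
    population: SyntheticPopulation,
    config: Optional[ScenarioConfig] = None,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> ReportingGraph:
    """Generate each living member's death reports about their network.

    Each living member reports each deceased network neighbour with
    probability ``1 - false_negative_prob`` and erroneously reports each
    living neighbour with probability ``false_positive_intensity``.
    Decedents never report.
    """
    config = config or population.config
    rng = _rng(config.seed + 1, seed)
    alive = population.alive
    keep_p = 1.0 - config.false_negative_prob
    fp = config.false_positive_intensity
    reports: dict[int, tuple[int, ...]] = {}
    for i in np.flatnonzero(alive):
        adj = population.ties[i]
        if adj.size == 0:
            continue
        dead_alters = adj[~alive[adj]]
        claimed = dead_alters[rng.random(dead_alters.size) < keep_p] if keep_p < 1 else dead_alters
        if fp > 0:
            living_alters = adj[alive[adj]]
            false_claims = living_alters[rng.random(living_alters.size) < fp]
            claimed = np.concatenate([claimed, false_claims])
        if claimed.size:
            reports[int(i)] = tuple(int(j) for j in claimed)
    return ReportingGraph(reports=reports)


def true_adjustment_factors(
    population: SyntheticPopulation,
    reports: ReportingGraph,
    group: DemographicGroup = DemographicGroup(),
) -> AdjustmentFactors:
    """Compute the exact (delta, tau, eta) triple for one group.

    delta: mean ties-to-living of the group's decedents over the same mean
    for its living members.  tau: true-positive reports about the group's
    deaths over the group's total decedent visibility.  eta: true-positive
    reports over all reports naming a member of the group as dead.  These
    are the definitions under which the multiplicative decomposition is an
    exact identity on any realised (population, reports) pair.
    """
    mask = population.group_mask(group)
    dead = mask & ~population.alive
    living = mask & population.alive
    if not dead.any():
        raise EstimationError(f"no decedents in group {group.label}; factors undefined")
    if not living.any():
        raise EstimationError(f"no living members in group {group.label}; factors undefined")
    deg = population.degree_to_living
    delta = float(deg[dead].mean() / deg[living].mean())
    visibility = float(deg[dead].sum())
    tp = 0
    total = 0
    for _, target in reports.pairs():
        if mask[target]:
            total += 1
            if not population.alive[target]:
                tp += 1
    if visibility == 0 or tp == 0 or total == 0:
        raise EstimationError(
            f"group {group.label}: no visibility or no (true) reports; factors undefined"
        )
    return AdjustmentFactors(
        degree_ratio=delta,
        true_positive_rate=tp / visibility,
        precision=tp / total,
    )


def census_death_count_estimand(
    population: SyntheticPopulation,
    reports: ReportingGraph,
    group: DemographicGroup = DemographicGroup(),
) -> float:
    """The network survival estimand ``y_F,Da / dbar_Fa,F`` at census values.

    ``y`` counts every report naming a member of the group as dead (one per
    reporting tie, so multiply-reported deaths count multiply) and ``dbar``
    is the group's true mean ties-to-living among living members.
    """
    mask = population.group_mask(group)
    living = mask & population.alive
    if not living.any():
        raise EstimationError(f"no living members in group {group.label}")
    dbar = float(population.degree_to_living[living].mean())
    if dbar == 0:
        raise EstimationError(f"zero mean degree in group {group.label}")
    y = sum(1 for _, target in reports.pairs() if mask[target])
    return y / dbar


def _months_before_interview(death_month: float) -> float:
    # death months are 1..12 within the recall year; mid-month placement
    return 12.0 - death_month + 0.5


def draw_survey(
    population: SyntheticPopulation,
    reports: ReportingGraph,
    config: Optional[ScenarioConfig] = None,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> tuple[SurveySample, KnownPopulationRegistry]:
    """Draw a stratified two-stage cluster sample of the living population.

    Members are partitioned into equal PSUs within strata; ``psus_sampled``
    PSUs per stratum and ``respondents_per_psu`` living members per sampled
    PSU are drawn, giving each respondent the exact design weight
    ``(PSUs in stratum / PSUs sampled) * (living in PSU / members sampled)``.
    With ``census=True`` every living member is interviewed at weight 1.
    Known-population counts are the respondent's ties into each registered
    group; death reports come from the reporting graph.
    """
    config = config or population.config
    rng = _rng(config.seed + 2, seed)
    schedule = population.schedule
    registry = KnownPopulationRegistry(
        tuple((name, idx.size) for name, idx in population.known_pop_members.items())
    )
    member_flags = {
        name: np.isin(np.arange(population.n), idx)
        for name, idx in population.known_pop_members.items()
    }
    frame_total = float(population.alive.sum())

    n_psus_total = config.n_strata * config.psus_per_stratum
    if n_psus_total > population.n:
        raise DesignError("more PSUs requested than members exist")
    assignment = rng.permutation(population.n) % n_psus_total  # member -> psu index

    chosen: list[tuple[int, float]] = []  # (member id, weight)
    member_psu: dict[int, int] = {}
    if config.census:
        for i in np.flatnonzero(population.alive):
            chosen.append((int(i), 1.0))
            member_psu[int(i)] = int(assignment[i])
    else:
        for h in range(config.n_strata):
            stratum_psus = np.arange(h * config.psus_per_stratum, (h + 1) * config.psus_per_stratum)
            sampled = rng.choice(stratum_psus, size=config.psus_sampled, replace=False)
            for psu in sampled:
                in_psu = np.flatnonzero((assignment == psu) & population.alive)
                if in_psu.size == 0:
                    raise DesignError(f"PSU {psu} contains no living members")
                take = min(config.respondents_per_psu, in_psu.size)
                picked = rng.choice(in_psu, size=take, replace=False)
                w = (config.psus_per_stratum / config.psus_sampled) * (in_psu.size / take)
                for i in picked:
                    chosen.append((int(i), w))
                    member_psu[int(i)] = int(psu)

    respondents = []
    for i, w in chosen:
        adj = population.ties[i]
        kp_counts = {name: int(member_flags[name][adj].sum()) for name in registry.names}
        death_reports = []
        for j in reports.reports.get(i, ()):
            band = schedule.band_of(population.age[j])
            if population.alive[j]:  # false positive about a living member
                months = float(rng.uniform(0.0, 12.0))
            else:
                months = _months_before_interview(population.death_month[j])
            death_reports.append(
                DeathReport(
                    decedent_sex=str(population.sex[j]),
                    decedent_age_band=band,
                    months_before_interview=months,
                )
            )
        psu = member_psu[i]
        respondents.append(
            Respondent(
                id=str(i),
                stratum=f"h{psu // config.psus_per_stratum:02d}",
                psu=f"p{psu:04d}",
                weight=w,
                sex=str(population.sex[i]),
                age_band=schedule.band_of(population.age[i]),
                arm=config.arm,
                known_pop_counts=kp_counts,
                death_reports=tuple(death_reports),
            )
        )
    return SurveySample(respondents, frame_total=frame_total), registry


# ---------------------------------------------------------------------------
# scalable survey-level generation
# ---------------------------------------------------------------------------

def simulate_survey(
    config: ScenarioConfig, seed: Optional[Union[int, np.random.Generator]] = None
) -> tuple[SurveySample, KnownPopulationRegistry, dict]:
    """Generate one survey directly, without realising the full network.

    Because ties form independently across pairs, a respondent's observable
    data — connection counts to known-population members and to decedents —
    depend only on the respondent's own expected degree and the degrees of
    the "special" members (decedents and known-population members).  This
    path therefore draws deaths at population scale, draws the sample, and
    realises only the respondent-by-special tie matrix, giving sampled data
    with the same distribution as the full-graph path at any population
    size.  (Overlaps between respondents, decedents and known-population
    members are ignored; they are O(1/N) effects.)

    Returns ``(sample, registry, truth)`` where ``truth`` carries the
    realised death and survivor counts and the finite-population death rate
    ``D/N_living`` per group — the estimand a survey of this population
    targets.
    """
    rng = _rng(config.seed, seed)
    bands = list(config.schedule.bands)
    struct = np.array([config.age_structure.get(b.label, 0.0) for b in bands], dtype=float)
    if struct.sum() <= 0:
        raise GenerationError("age structure has no mass on the configured schedule")
    struct /= struct.sum()

    # population cells: (sex, band)
    cells = [(s, b) for s in ("female", "male") for b in bands]
    cell_probs = np.array(
        [
            (config.female_share if s == "female" else 1 - config.female_share) * struct[bands.index(b)]
            for s, b in cells
        ]
    )
    n_cell = rng.multinomial(config.n_population, cell_probs)
    death_p = np.array([1.0 - math.exp(-config.rate(s, b)) for s, b in cells])
    d_cell = rng.binomial(n_cell, death_p)
    living_cell = n_cell - d_cell
    living_total = int(living_cell.sum())

    # special members: decedents then known-population members
    dec_cell_idx = np.repeat(np.arange(len(cells)), d_cell)
    n_dec = dec_cell_idx.size
    sizes = config.known_pop_sizes()
    registry = KnownPopulationRegistry(tuple(sizes.items()))
    n_kp = sum(sizes.values())
    gamma_scale = config.degree_mean / config.degree_shape
    d_special = rng.gamma(config.degree_shape, gamma_scale, size=n_dec + n_kp)
    d_special[:n_dec] *= config.decedent_degree_multiplier
    dec_months = rng.integers(1, 13, size=n_dec).astype(float)
    sum_d = config.n_population * config.degree_mean

    kp_slices: dict[str, slice] = {}
    offset = n_dec
    for name, size in sizes.items():
        kp_slices[name] = slice(offset, offset + size)
        offset += size

    # sample design
    n_psus_total = config.n_strata * config.psus_per_stratum
    psu_living = rng.multinomial(living_total, np.full(n_psus_total, 1.0 / n_psus_total))
    living_probs = living_cell / living_total
    resp_cell: list[int] = []
    resp_weight: list[float] = []
    resp_stratum: list[str] = []
    resp_psu: list[str] = []
    for h in range(config.n_strata):
        stratum_psus = np.arange(h * config.psus_per_stratum, (h + 1) * config.psus_per_stratum)
        sampled = rng.choice(stratum_psus, size=config.psus_sampled, replace=False)
        for psu in sampled:
            m = int(psu_living[psu])
            if m == 0:
                raise DesignError(f"PSU {psu} contains no living members")
            take = min(config.respondents_per_psu, m)
            w = (config.psus_per_stratum / config.psus_sampled) * (m / take)
            cell_draws = rng.choice(len(cells), size=take, p=living_probs)
            resp_cell.extend(int(c) for c in cell_draws)
            resp_weight.extend([w] * take)
            resp_stratum.extend([f"h{h:02d}"] * take)
            resp_psu.extend([f"p{psu:04d}"] * take)
    n_resp = len(resp_cell)
    resp_cell_arr = np.array(resp_cell)
    d_resp = rng.gamma(config.degree_shape, gamma_scale, size=n_resp)

    # respondent x special tie matrix
    tie_p = np.outer(d_resp, d_special) / sum_d
    if tie_p.max() > 1.0:
        raise GenerationError(
            "tie probability exceeds 1; reduce degree_mean or increase the population"
        )
    ties = rng.random((n_resp, n_dec + n_kp)) < tie_p

    keep_p = 1.0 - config.false_negative_prob
    if n_dec and keep_p < 1.0:
        reported = ties[:, :n_dec] & (rng.random((n_resp, n_dec)) < keep_p)
    else:
        reported = ties[:, :n_dec]

    band_idx_of_cell = np.array([bands.index(b) for _, b in cells])
    sex_of_cell = np.array([s for s, _ in cells], dtype=object)
    fp_rate = config.false_positive_intensity * (living_total / config.n_population)

    respondents = []
    for r in range(n_resp):
        kp_counts = {name: int(ties[r, sl].sum()) for name, sl in kp_slices.items()}
        death_reports = []
        for j in np.flatnonzero(reported[r]):
            c = dec_cell_idx[j]
            death_reports.append(
                DeathReport(
                    decedent_sex=str(sex_of_cell[c]),
                    decedent_age_band=bands[band_idx_of_cell[c]],
                    months_before_interview=_months_before_interview(dec_months[j]),
                )
            )
        if fp_rate > 0:
            n_fp = rng.poisson(fp_rate * d_resp[r])
            for _ in range(n_fp):
                c = rng.choice(len(cells), p=living_probs)
                death_reports.append(
                    DeathReport(
                        decedent_sex=str(sex_of_cell[c]),
                        decedent_age_band=bands[band_idx_of_cell[c]],
                        months_before_interview=float(rng.uniform(0.0, 12.0)),
                    )
                )
        c = resp_cell_arr[r]
        respondents.append(
            Respondent(
                id=f"r{r}",
                stratum=resp_stratum[r],
                psu=resp_psu[r],
                weight=resp_weight[r],
                sex=str(sex_of_cell[c]),
                age_band=bands[band_idx_of_cell[c]],
                arm=config.arm,
                known_pop_counts=kp_counts,
                death_reports=tuple(death_reports),
            )
        )
    sample = SurveySample(respondents, frame_total=float(living_total))

    truth: dict = {
        "death_counts": {},
        "living_counts": {},
        "realized_rates": {},
        "estimand_rates": {},
        "config_rates": {},
    }
    # the census value of the network survival estimand, conditional on the
    # realised degrees: S_D * sum(N_A) * (1 - fn) / (S_KP * N_living,a) —
    # the finite-population quantity a design-based interval targets
    # (false-positive contributions are not included here)
    s_kp = float(d_special[n_dec:].sum())
    for s in ("female", "male", "all"):
        for b in bands:
            sel = [
                k
                for k, (cs, cb) in enumerate(cells)
                if (s == "all" or cs == s) and cb == b
            ]
            dd = int(d_cell[sel].sum())
            ll = int(living_cell[sel].sum())
            key = f"{s}:{b.label}"
            truth["death_counts"][key] = dd
            truth["living_counts"][key] = ll
            truth["realized_rates"][key] = dd / ll if ll else math.nan
            dec_sel = np.isin(dec_cell_idx, sel)
            s_d = float(d_special[:n_dec][dec_sel].sum())
            truth["estimand_rates"][key] = (
                s_d * registry.total_size * keep_p / (s_kp * ll) if ll and s_kp else math.nan
            )
            if s == "all":
                num = sum(n_cell[k] * death_p[k] for k in sel)
                den = sum(n_cell[k] for k in sel)
                truth["config_rates"][key] = -math.log(1 - num / den) if den else math.nan
            else:
                truth["config_rates"][key] = config.rate(s, b)
    return sample, registry, truth
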