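"""Aggregation of age-specific death rates into conditional probabilities.

Rates are treated as piecewise-constant hazards: within an age band of
width ``n`` and rate ``M`` the probability of dying is ``1 - exp(-n*M)``,
and probabilities compose multiplicatively across bands.  The summary
reported here is 45q15 — the probability of dying before age 60 for
someone who survives to age 15 and then faces the schedule's rates.
Constant hazards are the minimal assumption and are exactly invariant to
subdividing a band, which keeps the aggregation independent of the band
layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from netsurvival.errors import ScheduleError
from netsurvival.groups import AgeBand


@dataclass(frozen=True)
class RateSchedule:
    """An ordered sequence of (age band, deaths per person-year) pairs."""

    bands: Sequence[tuple[AgeBand, float]]

    def __post_init__(self) -> None:
        bands = sorted(self.bands, key=lambda br: br[0])
        for (a, ra), (b, rb) in zip(bands, bands[1:]):
            if b.lo < a.hi:
                raise ScheduleError(f"rate schedule bands overlap: {a.label} and {b.label}")
        for band, rate in bands:
            if rate < 0 or not math.isfinite(rate):
                raise ScheduleError(f"rate for band {band.label} must be finite and >= 0, got {rate}")
        object.__setattr__(self, "bands", tuple(bands))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "RateSchedule":
        return cls(tuple((AgeBand.parse(label), rate) for label, rate in pairs))


def band_probability(rate: float, width: float) -> float:
    """Probability of dying within ``width`` years at constant hazard ``rate``."""
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    if not width > 0:
        raise ValueError(f"width must be positive, got {width}")
    return 1.0 - math.exp(-width * rate)


def conditional_probability(schedule: RateSchedule, lo: float, hi: float) -> float:
    """Probability of dying in [lo, hi) given survival to ``lo``.

    Bands are intersected with [lo, hi); partial overlaps are pro-rated by
    width (valid under the constant-hazard assumption).  The schedule must
    cover [lo, hi) completely.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    survival = 1.0
    cursor = lo
    for band, rate in schedule.bands:
        if band.hi <= cursor or band.lo >= hi:
            continue
        if band.lo > cursor:
            raise ScheduleError(
                f"rate schedule has a gap covering [{cursor}, {band.lo}) within [{lo}, {hi})"
            )
        width = min(band.hi, hi) - cursor
        survival *= 1.0 - band_probability(rate, width)
        cursor = min(band.hi, hi)
        if cursor >= hi:
            break
    if cursor < hi:
        raise ScheduleError(f"rate schedule has a gap covering [{cursor}, {hi}) within [{lo}, {hi})")
    return 1.0 - survival


def compute_45q15(schedule: RateSchedule) -> float:
    """Probability of dying before age 60 given survival to age 15.

    A value of 0.2 means 20% of people who reach age 15 and then face the
    schedule's age-specific rates die before their 60th birthday.
    """
    return conditional_probability(schedule, 15.0, 60.0)
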