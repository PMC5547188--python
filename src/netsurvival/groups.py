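"""Demographic groups: sexes and half-open age bands.

A demographic group is a (sex, age band) pair; the sex ``"all"`` and the
age band ``None`` each mean "no restriction on this dimension".  Age bands
are half-open integer intervals ``[lo, hi)`` in completed years; the upper
bound may be infinite (an open-ended band such as 65+).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from netsurvival.errors import ScheduleError

SEXES = ("female", "male")


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open interval of completed ages, ``[lo, hi)`` in years."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo < 0:
            raise ValueError(f"age band lower bound must be >= 0, got {self.lo}")
        if not self.lo < self.hi:
            raise ValueError(f"age band requires lo < hi, got [{self.lo}, {self.hi})")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, age: float) -> bool:
        return self.lo <= age < self.hi

    @property
    def label(self) -> str:
        if math.isinf(self.hi):
            return f"{int(self.lo)}+"
        return f"{int(self.lo)}-{int(self.hi) - 1}"

    @classmethod
    def parse(cls, text: str) -> "AgeBand":
        """Parse labels like ``"15-24"`` (meaning [15, 25)) or ``"65+"``."""
        text = text.strip()
        if text.endswith("+"):
            return cls(float(text[:-1]), math.inf)
        lo, hi = text.split("-")
        return cls(float(lo), float(hi) + 1.0)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class DemographicGroup:
    """A (sex, age band) cell; ``sex="all"`` / ``age_band=None`` relax a dimension."""

    sex: str = "all"
    age_band: Optional[AgeBand] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES and self.sex != "all":
            raise ValueError(f"sex must be one of {SEXES + ('all',)}, got {self.sex!r}")

    def matches_person(self, sex: str, age: float) -> bool:
        """Whether a person with known sex and age belongs to this group."""
        if self.sex != "all" and sex != self.sex:
            return False
        if self.age_band is not None and not self.age_band.contains(age):
            return False
        return True

    def matches_report(self, sex: Optional[str], age_band: Optional[AgeBand]) -> bool:
        """Whether a death report falls in this group.

        A report missing sex or age is counted only by groups that do not
        restrict the missing dimension, so partial reports still contribute
        to all-adult totals while age-sex cells stay conservative.
        """
        if self.sex != "all":
            if sex is None or sex != self.sex:
                return False
        if self.age_band is not None:
            if age_band is None:
                return False
            # report bands come from the same schedule, so containment is
            # either exact or empty; accept any overlap-by-identity
            if not (self.age_band.lo <= age_band.lo and age_band.hi <= self.age_band.hi):
                return False
        return True

    @property
    def label(self) -> str:
        band = self.age_band.label if self.age_band is not None else "all"
        return f"{self.sex}:{band}"


class AgeSchedule:
    """An ordered, disjoint, contiguous sequence of age bands."""

    def __init__(self, bands: Iterable[AgeBand]):
        bands = sorted(bands)
        if not bands:
            raise ScheduleError("age schedule must contain at least one band")
        for a, b in zip(bands, bands[1:]):
            if not math.isclose(a.hi, b.lo):
                raise ScheduleError(
                    f"age bands must be contiguous and disjoint; gap or overlap "
                    f"between [{a.lo}, {a.hi}) and [{b.lo}, {b.hi})"
                )
        self.bands: Sequence[AgeBand] = tuple(bands)

    @property
    def lo(self) -> float:
        return self.bands[0].lo

    @property
    def hi(self) -> float:
        return self.bands[-1].hi

    def band_of(self, age: float) -> Optional[AgeBand]:
        for band in self.bands:
            if band.contains(age):
                return band
        return None

    def parse_band(self, label: str) -> AgeBand:
        band = AgeBand.parse(label)
        if band not in self.bands:
            raise ScheduleError(f"band {label!r} is not in the configured schedule")
        return band

    def groups(self, sex: str = "all") -> list[DemographicGroup]:
        return [DemographicGroup(sex, band) for band in self.bands]

    @classmethod
    def parse(cls, text: str) -> "AgeSchedule":
        """Parse ``"15-24,25-34,...,65+"`` into a schedule."""
        return cls(AgeBand.parse(part) for part in text.split(","))

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __eq__(self, other) -> bool:
        return isinstance(other, AgeSchedule) and self.bands == other.bands

    def __repr__(self) -> str:  # pragma: no cover
        return f"AgeSchedule({','.join(b.label for b in self.bands)})"


#: Ten-year adult bands used by default: 15-24 ... 55-64, 65+.
DEFAULT_ADULT_SCHEDULE = AgeSchedule.parse("15-24,25-34,35-44,45-54,55-64,65+")
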