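"""Direct sibling-survival estimation of age-specific death rates.

Respondents enumerate their siblings with sex, birth date, survival status
and (when dead) date of death.  Within a pooling window before the
interview — 84 months by default, the length conventionally needed for
stable direct estimates — each sibling contributes person-years of exposure
to the age band they occupy at each instant, and each in-window death
contributes a weighted death to the band of age at death.  Rates are
weighted deaths over weighted person-years per band.

Dates are century month codes (CMC: months since January 1900, the DHS
convention), so everything is computed at month resolution.  Windows and
age bands are half-open ``[lo, hi)``; deaths are placed at mid-month, which
fixes every boundary case and makes a month-by-month tally exact.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from netsurvival.errors import EstimationError, SchemaError, ValidationError
from netsurvival.groups import AgeSchedule, DEFAULT_ADULT_SCHEDULE, SEXES
from netsurvival.lifetable import RateSchedule

logger = logging.getLogger(__name__)

#: Default pooling window: 84 months (seven years) before the interview.
DEFAULT_WINDOW_MONTHS = 84


def cmc(year: int, month: int) -> int:
    """Century month code of a calendar month (DHS convention)."""
    return (year - 1900) * 12 + month


@dataclass(frozen=True)
class SiblingRecord:
    """One reported sibling of one respondent."""

    respondent_id: str
    weight: float
    stratum: str
    psu: str
    sex: str
    birth_cmc: int
    alive: bool
    death_cmc: Optional[int] = None
    is_respondent: bool = False

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValidationError(f"sibling record for {self.respondent_id!r}: nonpositive weight")
        if self.sex not in SEXES:
            raise ValidationError(f"sibling record for {self.respondent_id!r}: bad sex {self.sex!r}")
        if not self.alive:
            if self.death_cmc is None:
                raise ValidationError(
                    f"sibling record for {self.respondent_id!r}: dead sibling without death date"
                )
            if self.death_cmc < self.birth_cmc:
                raise ValidationError(
                    f"sibling record for {self.respondent_id!r}: death before birth"
                )


SIBLING_COLUMNS = ("respondent_id", "weight", "stratum", "psu", "sex", "birth_cmc", "alive", "death_cmc")

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def read_sibling_histories(path: Union[str, Path]) -> list[SiblingRecord]:
    """Read one-row-per-sibling delimited text; invalid rows are logged and skipped."""
    path = Path(path)
    records: list[SiblingRecord] = []
    skipped = 0
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = set(reader.fieldnames or ())
        for col in SIBLING_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        for idx, row in enumerate(reader):
            try:
                alive_raw = row["alive"].strip().lower()
                if alive_raw in _TRUE:
                    alive = True
                elif alive_raw in _FALSE:
                    alive = False
                else:
                    raise ValidationError(f"unparseable survival status {row['alive']!r}")
                death_raw = row["death_cmc"].strip()
                records.append(
                    SiblingRecord(
                        respondent_id=row["respondent_id"],
                        weight=float(row["weight"]),
                        stratum=row["stratum"],
                        psu=row["psu"],
                        sex=row["sex"],
                        birth_cmc=int(row["birth_cmc"]),
                        alive=alive,
                        death_cmc=int(death_raw) if death_raw else None,
                        is_respondent=row.get("is_respondent", "0").strip().lower() in _TRUE,
                    )
                )
            except (ValidationError, ValueError) as exc:
                skipped += 1
                logger.warning("%s: row %d skipped: %s", path, idx, exc)
    if skipped:
        logger.info("%s: skipped %d invalid sibling records", path, skipped)
    return records


def _usable(records: Sequence[SiblingRecord], interview_cmc: int, include_respondent: bool):
    for rec in records:
        if rec.is_respondent and not include_respondent:
            continue
        if not rec.alive and rec.death_cmc is not None and rec.death_cmc >= interview_cmc:
            logger.warning(
                "sibling of %r: death date at or after interview; record skipped", rec.respondent_id
            )
            continue
        yield rec


def _death_time(rec: SiblingRecord) -> float:
    """Death instant in months: deaths are placed at mid-month."""
    assert rec.death_cmc is not None
    return rec.death_cmc + 0.5


def sibling_exposure(
    histories: Sequence[SiblingRecord],
    interview_cmc: int,
    window_months: int = DEFAULT_WINDOW_MONTHS,
    schedule: AgeSchedule = DEFAULT_ADULT_SCHEDULE,
    include_respondent: bool = False,
) -> pd.DataFrame:
    """Weighted person-years by (age band, sex) inside the pooling window.

    A sibling crossing a band boundary mid-window splits exposure exactly at
    the crossing; a dead sibling contributes exposure up to the (mid-month)
    death instant.  Returns a DataFrame indexed by band label with columns
    ``female``, ``male`` and ``all``.
    """
    if window_months < 1:
        raise ValueError("window_months must be at least 1")
    index = [b.label for b in schedule]
    out = pd.DataFrame(0.0, index=index, columns=["female", "male", "all"])
    t1 = float(interview_cmc)
    t0 = t1 - window_months
    for rec in _usable(histories, interview_cmc, include_respondent):
        end = min(t1, _death_time(rec)) if not rec.alive else t1
        start = max(t0, float(rec.birth_cmc))
        if end <= start:
            continue
        for band in schedule:
            b_lo = rec.birth_cmc + 12.0 * band.lo
            b_hi = math.inf if math.isinf(band.hi) else rec.birth_cmc + 12.0 * band.hi
            overlap = min(end, b_hi) - max(start, b_lo)
            if overlap > 0:
                py = rec.weight * overlap / 12.0
                out.loc[band.label, rec.sex] += py
                out.loc[band.label, "all"] += py
    return out


def sibling_deaths(
    histories: Sequence[SiblingRecord],
    interview_cmc: int,
    window_months: int = DEFAULT_WINDOW_MONTHS,
    schedule: AgeSchedule = DEFAULT_ADULT_SCHEDULE,
    include_respondent: bool = False,
) -> pd.DataFrame:
    """Weighted death counts by (age band at death, sex) inside the window.

    The window is half-open ``[interview - window, interview)`` in whole
    months of the death date, closed at the lower bound.
    """
    if window_months < 1:
        raise ValueError("window_months must be at least 1")
    index = [b.label for b in schedule]
    out = pd.DataFrame(0.0, index=index, columns=["female", "male", "all"])
    t0 = interview_cmc - window_months
    for rec in _usable(histories, interview_cmc, include_respondent):
        if rec.alive:
            continue
        if not (t0 <= rec.death_cmc < interview_cmc):
            continue
        age_at_death = (_death_time(rec) - rec.birth_cmc) / 12.0
        band = schedule.band_of(age_at_death)
        if band is None:
            continue  # death outside the configured age range
        out.loc[band.label, rec.sex] += rec.weight
        out.loc[band.label, "all"] += rec.weight
    return out


def sibling_death_rates(
    histories: Sequence[SiblingRecord],
    interview_cmc: int,
    window_months: int = DEFAULT_WINDOW_MONTHS,
    schedule: AgeSchedule = DEFAULT_ADULT_SCHEDULE,
    sex: str = "all",
    include_respondent: bool = False,
) -> RateSchedule:
    """Weighted deaths over weighted person-years for each band.

    Every band of ``schedule`` must have positive exposure; a band with
    none has an undefined rate and is reported by name (pass a restricted
    schedule to exclude it).
    """
    exposure = sibling_exposure(histories, interview_cmc, window_months, schedule, include_respondent)
    deaths = sibling_deaths(histories, interview_cmc, window_months, schedule, include_respondent)
    pairs = []
    for band in schedule:
        e = exposure.loc[band.label, sex]
        d = deaths.loc[band.label, sex]
        if e == 0:
            raise EstimationError(
                f"zero person-years of exposure in band {band.label} ({sex}); "
                "rate undefined for that band"
            )
        pairs.append((band, d / e))
    return RateSchedule(tuple(pairs))
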