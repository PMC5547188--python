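"""Survey containers, delimited-text readers/writers and weight handling.

The central object is :class:`SurveySample`: one record per respondent
carrying the design information (stratum, primary sampling unit, design
weight), the respondent's own demographic cell, the reported connection
counts to each known population, and the child records describing deaths
reported from the respondent's personal network.

Weights are design weights ``w_i`` and are treated as inverse inclusion
probabilities ``1/pi_i`` after denormalization to an external frame total,
the convention used by DHS-style survey files.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from netsurvival.errors import (
    RegistryMismatchError,
    SchemaError,
    ValidationError,
)
from netsurvival.groups import AgeBand, AgeSchedule, DemographicGroup, DEFAULT_ADULT_SCHEDULE, SEXES

logger = logging.getLogger(__name__)

_MISSING = ("", "na", "nan", "none", ".")


@dataclass(frozen=True)
class DeathReport:
    """One reported death from a respondent's personal network.

    ``decedent_sex`` and ``decedent_age_band`` may be missing; such reports
    contribute to all-adult totals but not to age-sex-specific cells.
    ``months_before_interview`` is in [0, 12] when recorded.
    """

    decedent_sex: Optional[str] = None
    decedent_age_band: Optional[AgeBand] = None
    months_before_interview: Optional[float] = None

    def __post_init__(self) -> None:
        if self.decedent_sex is not None and self.decedent_sex not in SEXES:
            raise ValidationError(f"decedent sex must be in {SEXES}, got {self.decedent_sex!r}")
        if self.months_before_interview is not None and not (
            0 <= self.months_before_interview <= 12
        ):
            raise ValidationError(
                f"months_before_interview must lie in [0, 12], got {self.months_before_interview}"
            )


@dataclass(frozen=True)
class Respondent:
    """One interviewed member of the frame population."""

    id: str
    stratum: str
    psu: str
    weight: float
    sex: str
    age_band: AgeBand
    arm: str = "other"
    known_pop_counts: Mapping[str, Optional[int]] = field(default_factory=dict)
    death_reports: Sequence[DeathReport] = ()

    def __post_init__(self) -> None:
        if not (self.weight > 0) or not math.isfinite(self.weight):
            raise ValidationError(f"respondent {self.id!r}: weight must be positive, got {self.weight}")
        if self.sex not in SEXES:
            raise ValidationError(f"respondent {self.id!r}: sex must be in {SEXES}, got {self.sex!r}")
        for name, count in self.known_pop_counts.items():
            if count is not None and count < 0:
                raise ValidationError(
                    f"respondent {self.id!r}: negative count for known population {name!r}"
                )


@dataclass(frozen=True)
class KnownPopulationRegistry:
    """The groups of externally known size used to estimate network sizes."""

    entries: Sequence[tuple[str, int]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("known-population names must be unique")
        for name, size in self.entries:
            if size <= 0:
                raise ValidationError(f"known population {name!r} must have positive size")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def total_size(self) -> int:
        return sum(size for _, size in self.entries)

    def validate_against_frame(self, frame_total: float) -> None:
        if not self.total_size < frame_total:
            raise ValidationError(
                f"total known-population size ({self.total_size}) must be strictly "
                f"less than the frame population size ({frame_total})"
            )


@dataclass(frozen=True)
class RateEstimate:
    """A scalar estimate with optional bootstrap replicates and interval."""

    point: float
    replicates: Sequence[float] = ()
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_contributing: int = 0

    def __post_init__(self) -> None:
        if math.isfinite(self.ci_low) and math.isfinite(self.ci_high):
            if self.ci_low > self.ci_high:
                raise ValidationError("ci_low must not exceed ci_high")


class SurveySample:
    """A validated collection of respondents plus frame-level metadata.

    ``frame_total`` is the external size of the frame population ``N_F``
    (for instance a UN Population Division estimate of the adult
    population).  Numeric columns are cached as numpy arrays so repeated
    estimation — notably under bootstrap replicate weights — is cheap;
    :meth:`with_weights` returns a view sharing those caches.
    """

    def __init__(
        self,
        respondents: Sequence[Respondent],
        frame_total: float,
        design_note: str = "",
        _weights: Optional[np.ndarray] = None,
        _shared_cache: Optional[dict] = None,
    ):
        if not respondents:
            raise ValidationError("a survey sample must contain at least one respondent")
        if not frame_total > 0:
            raise ValidationError("frame_total must be positive")
        self.respondents: tuple[Respondent, ...] = tuple(respondents)
        self.frame_total = float(frame_total)
        self.design_note = design_note
        psu_stratum: dict[str, str] = {}
        for r in self.respondents:
            prev = psu_stratum.setdefault(r.psu, r.stratum)
            if prev != r.stratum:
                raise ValidationError(
                    f"PSU {r.psu!r} appears in strata {prev!r} and {r.stratum!r}; "
                    "every PSU must belong to exactly one stratum"
                )
        self._cache: dict = _shared_cache if _shared_cache is not None else {}
        if _weights is not None:
            self._weights = np.asarray(_weights, dtype=float)
            if self._weights.shape != (len(self.respondents),):
                raise ValidationError("replicate weights must have one entry per respondent")
            if np.any(self._weights < 0):
                raise ValidationError("replicate weights must be nonnegative")
        else:
            self._weights = np.array([r.weight for r in self.respondents], dtype=float)

    # -- array accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.respondents)

    @property
    def weights(self) -> np.ndarray:
        return self._weights

    def _array(self, key: str, build: Callable[[], np.ndarray]) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def strata(self) -> np.ndarray:
        return self._array("strata", lambda: np.array([r.stratum for r in self.respondents], dtype=object))

    @property
    def psus(self) -> np.ndarray:
        return self._array("psus", lambda: np.array([r.psu for r in self.respondents], dtype=object))

    @property
    def arms(self) -> np.ndarray:
        return self._array("arms", lambda: np.array([r.arm for r in self.respondents], dtype=object))

    def group_mask(self, group: DemographicGroup) -> np.ndarray:
        """Boolean mask of respondents belonging to ``group``."""
        key = ("group_mask", group.sex, group.age_band)
        return self._array(
            key,
            lambda: np.array(
                [group.matches_report(r.sex, r.age_band) for r in self.respondents], dtype=bool
            ),
        )

    def report_counts(self, group: DemographicGroup) -> np.ndarray:
        """Per-respondent count of death reports whose decedent is in ``group``."""
        key = ("report_counts", group.sex, group.age_band)
        return self._array(
            key,
            lambda: np.array(
                [
                    sum(
                        group.matches_report(d.decedent_sex, d.decedent_age_band)
                        for d in r.death_reports
                    )
                    for r in self.respondents
                ],
                dtype=float,
            ),
        )

    def known_pop_matrix(self, names: Sequence[str]) -> np.ndarray:
        """(n, len(names)) float matrix of reported connection counts, NaN if missing."""
        key = ("kp_matrix", tuple(names))

        def build() -> np.ndarray:
            mat = np.full((self.n, len(names)), np.nan)
            for i, r in enumerate(self.respondents):
                for j, name in enumerate(names):
                    v = r.known_pop_counts.get(name)
                    if v is not None:
                        mat[i, j] = v
            return mat

        return self._array(key, build)

    # -- derived samples -------------------------------------------------
    def with_weights(self, weights: np.ndarray) -> "SurveySample":
        """Lightweight view with replacement weights (bootstrap replicates)."""
        return SurveySample(
            self.respondents,
            self.frame_total,
            self.design_note,
            _weights=weights,
            _shared_cache=self._cache,
        )

    def with_scaled_weights(self, factor: float) -> "SurveySample":
        """New sample whose respondents carry weights scaled by ``factor``."""
        respondents = [replace(r, weight=r.weight * factor) for r in self.respondents]
        return SurveySample(respondents, self.frame_total, self.design_note)

    def filter(self, predicate: Callable[[Respondent], bool], design_note: str = "") -> "SurveySample":
        kept = [r for r in self.respondents if predicate(r)]
        if not kept:
            raise ValidationError("filter removed every respondent")
        return SurveySample(kept, self.frame_total, design_note or self.design_note)

    def filter_arm(self, arm: str) -> "SurveySample":
        return self.filter(lambda r: r.arm == arm, design_note=f"{self.design_note} [arm={arm}]")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SurveySample)
            and self.respondents == other.respondents
            and self.frame_total == other.frame_total
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"SurveySample(n={self.n}, frame_total={self.frame_total})"


# ---------------------------------------------------------------------------
# weight denormalization
# ---------------------------------------------------------------------------

def denormalize_weights(sample: SurveySample, target_total: float) -> SurveySample:
    """Rescale all design weights by one constant so they sum to ``target_total``.

    DHS-style files ship weights normalized to the sample size; estimation of
    population totals requires rescaling them to an external estimate of the
    frame population (e.g. the UN Population Division count of adults).
    Relative weights are unchanged.
    """
    if not target_total > 0:
        raise ValueError(f"target_total must be positive, got {target_total}")
    current = float(np.sum(sample.weights))
    if not current > 0:
        raise ValueError("sum of current weights must be positive")
    return sample.with_scaled_weights(target_total / current)


# ---------------------------------------------------------------------------
# delimited-text input/output
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "id": "id",
    "stratum": "stratum",
    "psu": "psu",
    "weight": "weight",
    "sex": "sex",
    "age_band": "age_band",
    "arm": "arm",
}

DEATH_COLUMNS = ("respondent_id", "decedent_sex", "decedent_age_band", "months_before_interview")


def _parse_optional(text: str) -> Optional[str]:
    return None if text.strip().lower() in _MISSING else text.strip()


def read_registry(path: Union[str, Path]) -> KnownPopulationRegistry:
    """Read a two-column (name, size) known-population registry file."""
    path = Path(path)
    entries = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "size"} <= set(reader.fieldnames):
            raise SchemaError(f"{path}: registry file must have 'name' and 'size' columns")
        for row in reader:
            try:
                size = int(row["size"])
            except ValueError as exc:
                raise ValidationError(f"{path}: unparseable size for {row['name']!r}") from exc
            entries.append((row["name"], size))
    return KnownPopulationRegistry(tuple(entries))


def write_registry(registry: KnownPopulationRegistry, path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "size"])
        for name, size in registry.entries:
            writer.writerow([name, size])


def read_survey(
    path: Union[str, Path],
    registry: KnownPopulationRegistry,
    schema_config: Optional[Mapping] = None,
    deaths_path: Optional[Union[str, Path]] = None,
    schedule: AgeSchedule = DEFAULT_ADULT_SCHEDULE,
    frame_total: Optional[float] = None,
) -> SurveySample:
    """Read a respondent table plus a companion death-report table.

    ``schema_config`` may remap column names (keys of ``DEFAULT_COLUMNS``),
    name the known-population columns (``known_pop_columns``: mapping from
    registry name to column; default ``kp_<name>``), point at the death
    table (``deaths_path``), supply ``frame_total`` and an ``age_bands``
    schedule string.  Rows with unparseable weights raise, naming the row.
    """
    path = Path(path)
    cfg = dict(schema_config or {})
    columns = {**DEFAULT_COLUMNS, **cfg.get("columns", {})}
    kp_columns: Mapping[str, str] = cfg.get(
        "known_pop_columns", {name: f"kp_{name}" for name in registry.names}
    )
    unknown = set(kp_columns) - set(registry.names)
    if unknown:
        raise RegistryMismatchError(
            f"known-population columns {sorted(unknown)} are not in the registry"
        )
    if "age_bands" in cfg:
        schedule = AgeSchedule.parse(cfg["age_bands"])
    frame_total = cfg.get("frame_total", frame_total)
    if frame_total is None:
        raise SchemaError("frame_total must be given in schema_config or as an argument")
    deaths_path = cfg.get("deaths_path", deaths_path)

    death_reports: dict[str, list[DeathReport]] = {}
    if deaths_path is not None:
        death_reports = _read_death_table(Path(deaths_path), schedule)

    respondents = []
    seen_ids = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = set(reader.fieldnames or ())
        for logical, col in columns.items():
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column {col!r} (for {logical!r})")
        for name, col in kp_columns.items():
            if col not in header:
                raise SchemaError(f"{path}: missing known-population column {col!r} ({name!r})")
        for idx, row in enumerate(reader):
            try:
                weight = float(row[columns["weight"]])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: row {idx}: unparseable weight {row[columns['weight']]!r}"
                ) from exc
            if not weight > 0:
                raise ValidationError(f"{path}: row {idx}: nonpositive weight {weight}")
            rid = row[columns["id"]]
            kp_counts = {}
            for name, col in kp_columns.items():
                raw = _parse_optional(row[col])
                kp_counts[name] = None if raw is None else int(raw)
            respondents.append(
                Respondent(
                    id=rid,
                    stratum=row[columns["stratum"]],
                    psu=row[columns["psu"]],
                    weight=weight,
                    sex=row[columns["sex"]],
                    age_band=schedule.parse_band(row[columns["age_band"]]),
                    arm=row[columns["arm"]],
                    known_pop_counts=kp_counts,
                    death_reports=tuple(death_reports.pop(rid, ())),
                )
            )
            seen_ids.add(rid)
    orphans = set(death_reports)
    if orphans:
        raise ValidationError(
            f"death reports reference respondent ids not in the main table: {sorted(orphans)[:5]}"
        )
    registry.validate_against_frame(frame_total)
    return SurveySample(respondents, frame_total=frame_total)


def _read_death_table(path: Path, schedule: AgeSchedule) -> dict[str, list[DeathReport]]:
    reports: dict[str, list[DeathReport]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = set(reader.fieldnames or ())
        for col in DEATH_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        for row in reader:
            sex = _parse_optional(row["decedent_sex"])
            band_raw = _parse_optional(row["decedent_age_band"])
            months_raw = _parse_optional(row["months_before_interview"])
            reports.setdefault(row["respondent_id"], []).append(
                DeathReport(
                    decedent_sex=sex,
                    decedent_age_band=schedule.parse_band(band_raw) if band_raw else None,
                    months_before_interview=float(months_raw) if months_raw else None,
                )
            )
    return reports


def write_survey(
    sample: SurveySample,
    path: Union[str, Path],
    deaths_path: Union[str, Path],
    registry: Optional[KnownPopulationRegistry] = None,
) -> None:
    """Write respondent and death-report tables; inverse of :func:`read_survey`.

    Floats are written with ``repr`` so a round trip reproduces them to full
    precision.
    """
    names = registry.names if registry is not None else _collect_kp_names(sample)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(DEFAULT_COLUMNS.values()) + [f"kp_{n}" for n in names])
        for r in sample.respondents:
            writer.writerow(
                [r.id, r.stratum, r.psu, repr(float(r.weight)), r.sex, r.age_band.label, r.arm]
                + [
                    "" if r.known_pop_counts.get(n) is None else r.known_pop_counts[n]
                    for n in names
                ]
            )
    with Path(deaths_path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DEATH_COLUMNS)
        for r in sample.respondents:
            for d in r.death_reports:
                writer.writerow(
                    [
                        r.id,
                        d.decedent_sex or "",
                        d.decedent_age_band.label if d.decedent_age_band else "",
                        "" if d.months_before_interview is None else repr(float(d.months_before_interview)),
                    ]
                )


def _collect_kp_names(sample: SurveySample) -> tuple[str, ...]:
    names: list[str] = []
    for r in sample.respondents:
        for n in r.known_pop_counts:
            if n not in names:
                names.append(n)
    return tuple(names)
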