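"""Domain types, validation, and CSV/config I/O for xenograft efficacy trials.

The core objects mirror how a caliper-based efficacy study is recorded in
practice: each animal carries an ordered series of measurements (study day,
caliper width/length in mm, body weight in g, optional serum lipase in U/L),
an optional death record, and a group assignment. The study design captures
the trial-level constants: the tumor-volume endpoint triggering euthanasia,
the last study day, randomization constraints on baseline volumes, and the
toxicity limits that define the maximum tolerated dose (MTD).

Day numbering convention: day 1 is the randomization / first-dose day, and
the day-1 measurement is the pre-dose baseline.

Caliper convention: volume is computed as V = w^2 * l / 2 with w the smaller
of the two caliper axes, so measurements are canonicalized on ingest such
that ``width_mm <= length_mm``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

logger = logging.getLogger("pdxtrial")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PdxTrialError(Exception):
    """Base class for all package errors."""


class SchemaError(PdxTrialError):
    """An input file does not match the documented schema."""


class ParseError(PdxTrialError):
    """A row of an input file could not be parsed; names the offending line."""


class DomainError(PdxTrialError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class DeathCause(str, Enum):
    """Observed cause category recorded at necropsy / clinical observation."""

    treatment_evidence = "treatment_evidence"
    unrelated_evidence = "unrelated_evidence"
    unknown = "unknown"
    accidental = "accidental"


class DeathClass(str, Enum):
    """Derived classification: treatment-related (TR) or not (NTR)."""

    TR = "TR"
    NTR = "NTR"


@dataclass(frozen=True)
class Measurement:
    """One caliper / body-weight observation of one animal on one study day."""

    day: int
    width_mm: float
    length_mm: float
    body_weight_g: float
    lipase_u_per_l: Optional[float] = None

    def __post_init__(self) -> None:
        if self.day < 1:
            raise DomainError(f"day must be >= 1, got {self.day}")
        if self.width_mm < 0 or self.length_mm < 0:
            raise DomainError("caliper dimensions must be non-negative")

    def canonicalized(self) -> "Measurement":
        """Return a copy with width <= length (swap axes if needed)."""
        if self.width_mm > self.length_mm:
            return replace(self, width_mm=self.length_mm, length_mm=self.width_mm)
        return self


@dataclass
class DeathRecord:
    """A death event with its observed cause and (derived) TR/NTR class.

    ``classification`` is populated only by :func:`pdxtrial.toxicity.classify_death`.
    """

    animal_id: str
    day: int
    observed_cause: DeathCause
    classification: Optional[DeathClass] = None


@dataclass
class Animal:
    animal_id: str
    group_id: str
    measurements: list[Measurement] = field(default_factory=list)
    death: Optional[DeathRecord] = None

    def __post_init__(self) -> None:
        if not self.measurements:
            raise SchemaError(f"animal {self.animal_id} has no measurements")
        days = [m.day for m in self.measurements]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise SchemaError(
                f"animal {self.animal_id}: measurement days must be strictly increasing"
            )

    @property
    def days(self) -> list[int]:
        return [m.day for m in self.measurements]


class Route(str, Enum):
    ip = "ip"
    iv = "iv"
    po = "po"


@dataclass(frozen=True)
class Schedule:
    """Structured dosing schedule.

    ``count`` intervals of ``interval_days`` each, with ``doses_per_interval``
    doses placed at ``offsets`` (days within the interval). Shorthand codes:
    qwk (weekly), q3d (every 3 days), biwk (twice weekly: offsets 0 and 3
    within each week), qd (daily).
    """

    interval_days: int
    count: int
    doses_per_interval: int = 1
    offsets: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise DomainError("schedule count must be >= 1")
        if self.interval_days < 1:
            raise DomainError("schedule interval must be >= 1 day")
        if len(self.offsets) != self.doses_per_interval:
            raise DomainError("offsets must have one entry per dose in the interval")
        if any(o < 0 or o >= self.interval_days for o in self.offsets):
            raise DomainError("offsets must lie within the interval")


@dataclass(frozen=True)
class Regimen:
    agent: str
    dose_mg_per_kg: float
    route: Route
    schedule: Schedule
    first_dose_day: int = 1

    def __post_init__(self) -> None:
        if self.dose_mg_per_kg < 0:
            raise DomainError("dose must be >= 0")


@dataclass
class StudyDesign:
    """Trial-level constants shared by every stage of the analysis.

    bw_loss_limit_pct / tr_mortality_limit_pct encode the MTD criterion:
    acceptable toxicity is a group-mean body-weight loss of less than
    ``bw_loss_limit_pct`` percent and TR mortality of no more than
    ``tr_mortality_limit_pct`` percent of the group.

    ``censor_last_day`` controls how animals that never reach the endpoint
    enter the logrank test: True (default) treats the assigned last-day TTE
    as censored; False feeds every TTE as an event.
    """

    endpoint_volume_mm3: float = 800.0
    last_day: int = 74
    dosing_volume_ml_per_kg: float = 10.0
    baseline_min_mm3: float = 75.0
    baseline_max_mm3: float = 245.0
    group_mean_band_mm3: tuple[float, float] = (164.0, 170.0)
    bw_loss_limit_pct: float = 20.0
    tr_mortality_limit_pct: float = 10.0
    tr_window_days: int = 14
    per_animal_bw_limit_pct: float = 20.0
    censor_last_day: bool = True


def validate_design(design: StudyDesign) -> list[str]:
    """Check StudyDesign invariants; return one message per violation.

    Violations are data, not exceptions: an empty list means the design is
    valid.
    """
    violations: list[str] = []
    if not design.endpoint_volume_mm3 > 0:
        violations.append("endpoint_volume_mm3: must be > 0")
    if design.last_day < 1:
        violations.append("last_day: must be >= 1")
    if design.dosing_volume_ml_per_kg <= 0:
        violations.append("dosing_volume_ml_per_kg: must be > 0")
    if not design.baseline_min_mm3 < design.baseline_max_mm3:
        violations.append("baseline_min_mm3: must be < baseline_max_mm3")
    lo, hi = design.group_mean_band_mm3
    if not lo <= hi:
        violations.append("group_mean_band_mm3: empty interval (low > high)")
    for name in ("bw_loss_limit_pct", "tr_mortality_limit_pct"):
        value = getattr(design, name)
        if not (0 < value <= 100):
            violations.append(f"{name}: must be in (0, 100]")
    if design.tr_window_days < 0:
        violations.append("tr_window_days: must be >= 0")
    return violations


# ---------------------------------------------------------------------------
# Measurement CSV I/O
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = (
    "animal_id",
    "group_id",
    "day",
    "width_mm",
    "length_mm",
    "body_weight_g",
    "lipase_u_per_l",
)
REQUIRED_MEASUREMENT_COLUMNS = MEASUREMENT_COLUMNS[:-1]

DEATH_COLUMNS = ("animal_id", "day", "observed_cause")


def _parse_float(text: str, column: str, line_no: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"line {line_no}: non-numeric value {text!r} in column {column}"
        ) from None


def read_measurements(path: Union[str, Path]) -> list[Animal]:
    """Read a long-format measurement CSV into Animals.

    Rows are grouped by animal id and sorted by study day; caliper axes are
    canonicalized so width <= length. Malformed rows raise errors naming the
    file line.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = [c for c in REQUIRED_MEASUREMENT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

        rows: dict[str, dict] = {}
        for line_no, row in enumerate(reader, start=2):
            animal_id = (row["animal_id"] or "").strip()
            if not animal_id:
                raise ParseError(f"line {line_no}: empty animal_id")
            lipase_raw = (row.get("lipase_u_per_l") or "").strip()
            m = Measurement(
                day=int(_parse_float(row["day"], "day", line_no)),
                width_mm=_parse_float(row["width_mm"], "width_mm", line_no),
                length_mm=_parse_float(row["length_mm"], "length_mm", line_no),
                body_weight_g=_parse_float(row["body_weight_g"], "body_weight_g", line_no),
                lipase_u_per_l=(
                    _parse_float(lipase_raw, "lipase_u_per_l", line_no) if lipase_raw else None
                ),
            ).canonicalized()
            entry = rows.setdefault(
                animal_id, {"group_id": row["group_id"].strip(), "measurements": []}
            )
            if entry["group_id"] != row["group_id"].strip():
                raise ParseError(
                    f"line {line_no}: animal {animal_id} assigned to multiple groups"
                )
            entry["measurements"].append(m)

    if not rows:
        logger.warning("%s: no measurement rows (header only)", path)
        return []

    animals = []
    for animal_id, entry in rows.items():
        measurements = sorted(entry["measurements"], key=lambda m: m.day)
        animals.append(
            Animal(animal_id=animal_id, group_id=entry["group_id"], measurements=measurements)
        )
    return animals


def write_measurements(animals: Iterable[Animal], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for animal in animals:
            for m in animal.measurements:
                writer.writerow(
                    [
                        animal.animal_id,
                        animal.group_id,
                        m.day,
                        repr(m.width_mm),
                        repr(m.length_mm),
                        repr(m.body_weight_g),
                        "" if m.lipase_u_per_l is None else repr(m.lipase_u_per_l),
                    ]
                )


def read_deaths(path: Union[str, Path]) -> dict[str, DeathRecord]:
    """Read the death-record CSV; returns a mapping animal_id -> DeathRecord."""
    path = Path(path)
    deaths: dict[str, DeathRecord] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = [c for c in DEATH_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        for line_no, row in enumerate(reader, start=2):
            animal_id = row["animal_id"].strip()
            try:
                cause = DeathCause(row["observed_cause"].strip())
            except ValueError:
                raise ParseError(
                    f"line {line_no}: unknown observed_cause {row['observed_cause']!r}"
                ) from None
            if animal_id in deaths:
                raise ParseError(f"line {line_no}: duplicate death record for {animal_id}")
            deaths[animal_id] = DeathRecord(
                animal_id=animal_id,
                day=int(_parse_float(row["day"], "day", line_no)),
                observed_cause=cause,
            )
    return deaths


def write_deaths(deaths: Iterable[DeathRecord], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DEATH_COLUMNS)
        for d in sorted(deaths, key=lambda d: d.animal_id):
            writer.writerow([d.animal_id, d.day, d.observed_cause.value])


# ---------------------------------------------------------------------------
# Design / regimen config I/O (YAML or JSON)
# ---------------------------------------------------------------------------

def _regimen_from_dict(spec: Mapping) -> Regimen:
    from .dosing import parse_schedule  # local import to avoid a cycle

    return Regimen(
        agent=spec["agent"],
        dose_mg_per_kg=float(spec.get("dose_mg_per_kg", 0.0)),
        route=Route(spec.get("route", "ip")),
        schedule=parse_schedule(spec["schedule"]),
        first_dose_day=int(spec.get("first_dose_day", 1)),
    )


def load_design(path: Union[str, Path]) -> tuple[StudyDesign, dict[str, Regimen]]:
    """Load a study-design config (YAML or JSON).

    Top-level keys mirror StudyDesign field names; an optional ``regimens``
    mapping of group_id -> regimen spec provides the dosing schedules needed
    for TR/NTR death classification.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    raw = dict(raw or {})
    regimen_specs = raw.pop("regimens", {}) or {}
    design_fields = {f.name for f in StudyDesign.__dataclass_fields__.values()}
    unknown = set(raw) - design_fields
    if unknown:
        raise SchemaError(f"{path}: unknown design field(s): {', '.join(sorted(unknown))}")
    if "group_mean_band_mm3" in raw:
        raw["group_mean_band_mm3"] = tuple(raw["group_mean_band_mm3"])
    design = StudyDesign(**raw)
    regimens = {gid: _regimen_from_dict(spec) for gid, spec in regimen_specs.items()}
    return design, regimens


def group_animals(animals: Sequence[Animal]) -> dict[str, list[Animal]]:
    """Partition animals by group id, preserving input order."""
    groups: dict[str, list[Animal]] = {}
    for animal in animals:
        groups.setdefault(animal.group_id, []).append(animal)
    return groups
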