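"""Tumor volume computation and group growth-curve summaries.

Tumor volume from two caliper axes uses the standard prolate-ellipsoid
approximation V = w^2 * l / 2 (mm^3), with w the smaller axis. Tumor weight
is estimated under the 1 mg = 1 mm^3 density assumption.

Group curves follow the carry-forward convention of efficacy studies: once
an animal exits at the endpoint volume or through a treatment-related (TR)
death, its final recorded volume keeps contributing to the group mean and
median at later time points, so the summary does not drop as the largest
tumors leave. Animals lost to non-treatment-related (NTR) causes are removed
from the summaries entirely. Curves are truncated once a strict majority of
assessable animals have reached the endpoint volume, or once the group
exceeded the maximum tolerated dose, whichever comes first.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .trial_model import (
    Animal,
    DeathClass,
    DeathRecord,
    DomainError,
    PdxTrialError,
    StudyDesign,
)


@dataclass
class GrowthCurve:
    """Per-animal (day, volume) series with optional exit bookkeeping."""

    animal_id: str
    points: list[tuple[int, float]]
    exit_day: Optional[int] = None
    exit_volume_mm3: Optional[float] = None

    def __post_init__(self) -> None:
        days = [d for d, _ in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise DomainError(f"curve {self.animal_id}: days must be strictly increasing")
        if any(v < 0 for _, v in self.points):
            raise DomainError(f"curve {self.animal_id}: volumes must be >= 0")

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.points]

    @property
    def volumes(self) -> list[float]:
        return [v for _, v in self.points]

    def first_exceedance_day(self, endpoint_volume_mm3: float) -> Optional[int]:
        """Day of the first observation strictly above the endpoint volume."""
        for day, volume in self.points:
            if volume > endpoint_volume_mm3:
                return day
        return None


@dataclass
class GroupCurve:
    group_id: str
    days: list[int]
    n_contributing: list[int]
    mean_mm3: list[float]
    median_mm3: list[float]
    sem_mm3: list[float]
    truncation_day: Optional[int] = None


def caliper_volume(width_mm: float, length_mm: float) -> float:
    """Tumor volume in mm^3 from canonicalized caliper axes: w^2 * l / 2."""
    if width_mm < 0 or length_mm < 0:
        raise DomainError("caliper dimensions must be >= 0")
    return width_mm * width_mm * length_mm / 2.0


def estimated_weight_mg(volume_mm3: float) -> float:
    """Estimated tumor weight in mg, assuming 1 mg per mm^3 of volume."""
    if volume_mm3 < 0:
        raise DomainError("volume must be >= 0")
    return volume_mm3


def growth_curve(animal: Animal) -> GrowthCurve:
    """Build an animal's growth curve from its caliper measurements."""
    points = [
        (m.day, caliper_volume(m.width_mm, m.length_mm)) for m in animal.measurements
    ]
    return GrowthCurve(animal_id=animal.animal_id, points=points)


def _bin_days(days: Sequence[int]) -> list[int]:
    """Collapse measurement days one day apart into a single grid day.

    The twice-weekly schedule leaves gaps of at least 3 days, so clusters of
    adjacent days are unambiguous; the earliest day of a cluster represents it.
    """
    grid: list[int] = []
    for day in days:
        if grid and day - grid[-1] <= 1:
            continue
        grid.append(day)
    return grid


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1) / math.sqrt(values.size))


def group_summary_curve(
    group_id: str,
    curves: Sequence[GrowthCurve],
    design: StudyDesign,
    deaths: Mapping[str, DeathRecord] = {},
    mtd_day: Optional[int] = None,
) -> GroupCurve:
    """Per-day group mean/median/SEM with carry-forward after animal exits.

    ``deaths`` must carry classified records (TR/NTR); NTR animals are dropped
    from the summaries entirely. For every other animal, once its series ends
    (endpoint exit or TR death), its last recorded volume is carried forward
    to all later grid days. The carry-forward applies to the mean as well as
    the median so the two summary curves stay consistent.
    """
    if not curves:
        raise PdxTrialError(f"group {group_id}: no growth curves")

    included = [
        c
        for c in curves
        if not (
            c.animal_id in deaths
            and deaths[c.animal_id].classification == DeathClass.NTR
        )
    ]
    if not included:
        raise PdxTrialError(f"group {group_id}: all animals excluded as NTR")

    grid = _bin_days(sorted({d for c in included for d in c.days}))
    lookups = [dict(c.points) for c in included]
    days_out: list[int] = []
    n_out: list[int] = []
    mean_out: list[float] = []
    median_out: list[float] = []
    sem_out: list[float] = []
    for day in grid:
        values = []
        for c, lookup in zip(included, lookups):
            if day in lookup:
                values.append(lookup[day])
            elif day - 1 in lookup:
                # off-grid measurement binned to the scheduled day (+/-1)
                values.append(lookup[day - 1])
            elif day + 1 in lookup:
                values.append(lookup[day + 1])
            elif day > c.days[-1]:
                # exited at endpoint or TR death: final volume carried forward
                values.append(c.volumes[-1])
            # measurement gap before the animal's own last day: skip that day
        arr = np.asarray(values, dtype=float)
        days_out.append(day)
        n_out.append(arr.size)
        mean_out.append(float(arr.mean()))
        median_out.append(float(np.median(arr)))
        sem_out.append(_sem(arr))

    trunc = truncation_day(included, design, mtd_day)
    return GroupCurve(
        group_id=group_id,
        days=days_out,
        n_contributing=n_out,
        mean_mm3=mean_out,
        median_mm3=median_out,
        sem_mm3=sem_out,
        truncation_day=trunc,
    )


def truncation_day(
    curves: Sequence[GrowthCurve],
    design: StudyDesign,
    mtd_day: Optional[int] = None,
) -> Optional[int]:
    """Day a group's curve stops being plotted.

    The earliest day on which strictly more than 50% of the assessable
    animals have reached the endpoint volume, or the day the MTD was
    exceeded, whichever is earlier. None if neither occurred. ``curves``
    must already exclude NTR animals.
    """
    if not curves:
        raise PdxTrialError("truncation_day: no curves")
    n = len(curves)
    exceed_days = sorted(
        d
        for d in (c.first_exceedance_day(design.endpoint_volume_mm3) for c in curves)
        if d is not None
    )
    majority_day: Optional[int] = None
    # >50% is strict: with 10 assessable animals the 6th exceedance triggers it
    threshold = n // 2 + 1
    if len(exceed_days) >= threshold:
        majority_day = exceed_days[threshold - 1]
    candidates = [d for d in (majority_day, mtd_day) if d is not None]
    return min(candidates) if candidates else None


def write_group_curves(
    curves: Iterable[GroupCurve], path: Union[str, Path]
) -> None:
    """Emit per-group summary curves as TSV (one row per group-day)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["group_id", "day", "n_contributing", "mean_mm3", "sem_mm3", "median_mm3", "truncated"]
        )
        for gc in curves:
            for i, day in enumerate(gc.days):
                truncated = int(gc.truncation_day is not None and day > gc.truncation_day)
                writer.writerow(
                    [
                        gc.group_id,
                        day,
                        gc.n_contributing[i],
                        f"{gc.mean_mm3[i]:.1f}",
                        f"{gc.sem_mm3[i]:.1f}",
                        f"{gc.median_mm3[i]:.1f}",
                        truncated,
                    ]
                )
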