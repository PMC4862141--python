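"""Body-weight monitoring, MTD criteria, death classification, evaluability.

Toxicity in caliper-based efficacy studies is tracked through group-mean
body weight, expressed as percent change from the day-1 (pre-dose) weight.
The nadir is the lowest group-mean percent change over the study. The
maximum tolerated dose (MTD) is exceeded when the group-mean body-weight
loss reaches the limit (default 20%) on any day, or when treatment-related
(TR) mortality exceeds its limit (default 10% of the initial group size).
A group that exceeded the MTD is not evaluable for efficacy.

A death is TR when clinical signs or necropsy tie it to treatment, or when
its cause is unknown and it falls during the dosing period or within a
fixed window (default 14 days) after the last dose; deaths with evidence of
unrelated or accidental causes, or unknown deaths outside that window, are
non-treatment-related (NTR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from . import dosing
from .trial_model import (
    Animal,
    DeathCause,
    DeathClass,
    DeathRecord,
    DomainError,
    PdxTrialError,
    Regimen,
    StudyDesign,
)


@dataclass
class ToxicitySummary:
    group_id: str
    mean_bw_nadir_pct: float  # % change from day 1; negative = loss
    nadir_day: int
    tr_deaths: int
    ntr_deaths: int
    mtd_exceeded: bool
    mtd_reason: Optional[str] = None
    mtd_day: Optional[int] = None  # day the MTD criterion was first exceeded
    evaluable: bool = True


def bw_percent_change(
    series: Sequence[tuple[int, float]]
) -> list[tuple[int, float]]:
    """Body weight as percent change from the day-1 baseline."""
    weights = dict(series)
    if 1 not in weights:
        raise PdxTrialError("missing day-1 baseline body weight")
    baseline = weights[1]
    if baseline <= 0:
        raise DomainError("day-1 body weight must be > 0")
    return [(day, 100.0 * (bw - baseline) / baseline) for day, bw in series]


def group_bw_nadir(
    group_series: Sequence[Sequence[tuple[int, float]]]
) -> tuple[float, int]:
    """Lowest group-mean percent BW change and its day (ties: earliest day).

    The group mean on each day is taken over the animals with a measurement
    on that day, so animals that died stop contributing.
    """
    per_animal = [dict(bw_percent_change(s)) for s in group_series]
    days = sorted({d for pct in per_animal for d in pct})
    if not days:
        raise PdxTrialError("no body-weight measurements")
    best_day, best_val = None, None
    for day in days:
        values = [pct[day] for pct in per_animal if day in pct]
        mean = float(np.mean(values))
        if best_val is None or mean < best_val:
            best_val, best_day = mean, day
    return best_val, best_day


def classify_death(
    record: DeathRecord, regimen: Regimen, design: StudyDesign
) -> DeathClass:
    """TR/NTR classification of a death record.

    Deterministic and total over the cause enum: treatment evidence is TR;
    unrelated evidence and accidents are NTR; unknown causes are TR when the
    death falls in the dosing period or within ``design.tr_window_days`` of
    the last dose, NTR afterwards.
    """
    if record.observed_cause is DeathCause.treatment_evidence:
        return DeathClass.TR
    if record.observed_cause in (DeathCause.unrelated_evidence, DeathCause.accidental):
        return DeathClass.NTR
    window_end = dosing.last_dose_day(regimen) + design.tr_window_days
    return DeathClass.TR if record.day <= window_end else DeathClass.NTR


def mtd_check(
    mean_bw_nadir_pct: float,
    tr_deaths: int,
    initial_n: int,
    design: StudyDesign,
) -> tuple[bool, Optional[str]]:
    """Whether the group exceeded the maximum tolerated dose, with the reason.

    Acceptable toxicity is mean BW loss strictly less than the limit and TR
    mortality no more than the limit, so a nadir of exactly -20% or
    mortality strictly above 10% of the initial group size both exceed.
    """
    if initial_n < 1:
        raise DomainError("initial group size must be >= 1")
    reasons = []
    if -mean_bw_nadir_pct >= design.bw_loss_limit_pct:
        reasons.append(
            f"mean BW loss {-mean_bw_nadir_pct:.1f}% >= {design.bw_loss_limit_pct:g}% limit"
        )
    mortality_pct = 100.0 * tr_deaths / initial_n
    if mortality_pct > design.tr_mortality_limit_pct:
        reasons.append(
            f"TR mortality {mortality_pct:.1f}% > {design.tr_mortality_limit_pct:g}% limit"
        )
    if reasons:
        return True, "; ".join(reasons)
    return False, None


def evaluable(summary: ToxicitySummary) -> bool:
    """A group is evaluable for efficacy iff it did not exceed the MTD."""
    return not summary.mtd_exceeded


def write_toxicity_table(summaries, path) -> None:
    """Emit per-group toxicity TSV (nadir, deaths, evaluability)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["group_id", "mean_bw_nadir_pct", "nadir_day", "tr_deaths",
             "ntr_deaths", "evaluable"]
        )
        for s in summaries:
            writer.writerow(
                [s.group_id, f"{s.mean_bw_nadir_pct:.1f}", s.nadir_day,
                 s.tr_deaths, s.ntr_deaths, "yes" if s.evaluable else "ne"]
            )


def summarize_group_toxicity(
    group_id: str,
    animals: Sequence[Animal],
    deaths: Mapping[str, DeathRecord],
    regimen: Regimen,
    design: StudyDesign,
) -> ToxicitySummary:
    """Full per-group toxicity summary; classifies this group's deaths in place."""
    if not animals:
        raise PdxTrialError(f"group {group_id}: no animals")
    series = [
        [(m.day, m.body_weight_g) for m in a.measurements] for a in animals
    ]
    nadir_pct, nadir_day = group_bw_nadir(series)

    tr = ntr = 0
    tr_days: list[int] = []
    for a in animals:
        record = deaths.get(a.animal_id)
        if record is None:
            continue
        record.classification = classify_death(record, regimen, design)
        if record.classification is DeathClass.TR:
            tr += 1
            tr_days.append(record.day)
        else:
            ntr += 1

    exceeded, reason = mtd_check(nadir_pct, tr, len(animals), design)

    mtd_day: Optional[int] = None
    if exceeded:
        # earliest day either criterion tripped
        candidates: list[int] = []
        per_animal = [dict(bw_percent_change(s)) for s in series]
        for day in sorted({d for pct in per_animal for d in pct}):
            values = [pct[day] for pct in per_animal if day in pct]
            if -float(np.mean(values)) >= design.bw_loss_limit_pct:
                candidates.append(day)
                break
        limit = design.tr_mortality_limit_pct / 100.0 * len(animals)
        for k, day in enumerate(sorted(tr_days), start=1):
            if k > limit:
                candidates.append(day)
                break
        mtd_day = min(candidates) if candidates else None

    summary = ToxicitySummary(
        group_id=group_id,
        mean_bw_nadir_pct=nadir_pct,
        nadir_day=nadir_day,
        tr_deaths=tr,
        ntr_deaths=ntr,
        mtd_exceeded=exceeded,
        mtd_reason=reason,
        mtd_day=mtd_day,
    )
    summary.evaluable = evaluable(summary)
    return summary
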