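"""Dose and dilution arithmetic plus schedule expansion for dosing regimens.

A fixed dosing volume (mL per kg of body weight) links a formulation
concentration to the delivered dose: dose (mg/kg) = concentration (mg/mL)
x dosing volume (mL/kg). Injection volumes are scaled linearly to each
animal's weight. Schedules are expressed as shorthand codes (qwk, q3d,
biwk, qd) or as a structured {interval_days, doses_per_interval, count}
spec and expand to explicit dosing days.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Union

from .trial_model import DomainError, Regimen, Schedule


@dataclass(frozen=True)
class Formulation:
    """A stock concentration and the final (diluted) dosing concentration."""

    stock_mg_per_ml: float
    final_mg_per_ml: float

    def __post_init__(self) -> None:
        if not (0 < self.final_mg_per_ml <= self.stock_mg_per_ml):
            raise DomainError("final concentration must be in (0, stock]")


def dose_mg_per_kg(final_mg_per_ml: float, dosing_volume_ml_per_kg: float) -> float:
    """Delivered dose in mg/kg for a concentration at a fixed dosing volume."""
    if final_mg_per_ml <= 0 or dosing_volume_ml_per_kg <= 0:
        raise DomainError("concentration and dosing volume must be > 0")
    return final_mg_per_ml * dosing_volume_ml_per_kg


def injection_volume_ml(body_weight_g: float, dosing_volume_ml_per_kg: float) -> float:
    """Injection volume in mL scaled to an individual animal's weight."""
    if body_weight_g <= 0 or dosing_volume_ml_per_kg <= 0:
        raise DomainError("body weight and dosing volume must be > 0")
    return body_weight_g / 1000.0 * dosing_volume_ml_per_kg


# Shorthand codes -> (interval_days, doses_per_interval, offsets)
_SHORTHAND = {
    "qwk": (7, 1, (0,)),
    "q3d": (3, 1, (0,)),
    "qd": (1, 1, (0,)),
    # "twice weekly": day offsets within the week are a study convention;
    # {0, 3} (e.g. Mon/Thu) is used here.
    "biwk": (7, 2, (0, 3)),
}

_CODE_RE = re.compile(r"^\s*(qwk|q3d|biwk|qd)\s*[x×]\s*(\d+)\s*$", re.IGNORECASE)


def parse_schedule(spec: Union[str, Mapping, Schedule]) -> Schedule:
    """Parse a shorthand code ("qwk x 3") or structured mapping into a Schedule."""
    if isinstance(spec, Schedule):
        return spec
    if isinstance(spec, str):
        match = _CODE_RE.match(spec)
        if not match:
            raise DomainError(f"unknown schedule code: {spec!r}")
        interval, dpi, offsets = _SHORTHAND[match.group(1).lower()]
        return Schedule(
            interval_days=interval,
            count=int(match.group(2)),
            doses_per_interval=dpi,
            offsets=offsets,
        )
    return Schedule(
        interval_days=int(spec["interval_days"]),
        count=int(spec["count"]),
        doses_per_interval=int(spec.get("doses_per_interval", 1)),
        offsets=tuple(spec.get("offsets", (0,))[: int(spec.get("doses_per_interval", 1))])
        or (0,),
    )


def schedule_days(regimen: Regimen) -> list[int]:
    """Expand a regimen to its explicit, strictly increasing dosing days."""
    s = regimen.schedule
    days = [
        regimen.first_dose_day + block * s.interval_days + offset
        for block in range(s.count)
        for offset in s.offsets
    ]
    return sorted(days)


def last_dose_day(regimen: Regimen) -> int:
    return schedule_days(regimen)[-1]


def treatment_window(regimen: Regimen) -> tuple[int, int]:
    """Half-open day span [first dose, end of last scheduled interval).

    Each dose is taken to cover one scheduling interval, so qwk x 3 spans 21
    days and qd x 15 spans 15 days. The simulator uses this span as the
    drug-effect window.
    """
    s = regimen.schedule
    return regimen.first_dose_day, regimen.first_dose_day + s.interval_days * s.count
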