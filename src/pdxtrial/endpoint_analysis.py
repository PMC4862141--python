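"""Per-animal time-to-endpoint (TTE) and tumor growth delay (TGD).

The time-to-endpoint of a mouse is the study day its tumor is estimated to
cross the endpoint volume. It is interpolated from a log-linear regression
over a short window of observations: the first observation whose volume
exceeds the endpoint plus up to the three observations immediately before
it. With slope m and intercept b of the ordinary least-squares fit of
log10(volume) on day,

    TTE = (log10(endpoint volume) - b) / m   [days]

Animals that never reach the endpoint are assigned the last study day;
treatment-related (TR) deaths are assigned the day of death; animals lost
to non-treatment-related (NTR) causes are excluded from analysis.

Efficacy is summarized as tumor growth delay, TGD = T - C, where T and C are
the median TTEs of a treated group and the control group, optionally as a
percentage of the control median: %TGD = 100 * (T - C) / C.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .trial_model import DeathClass, DeathRecord, DomainError, PdxTrialError, StudyDesign
from .volumetrics import GrowthCurve


class InsufficientDataError(PdxTrialError):
    """Fewer than two usable observations where a regression is required."""


class SingularFitError(PdxTrialError):
    """All observation days coincide; the regression is undefined."""


class NonGrowingFitError(PdxTrialError):
    """The fitted slope is not positive, so the crossing is undefined."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of log10(volume) on study day over the endpoint window."""

    slope_m: float      # per-day change of log10(volume)
    intercept_b: float  # log10(mm^3) at day 0
    n_points: int
    window_days: tuple[int, ...]


class TTEStatus(str, Enum):
    interpolated = "interpolated"
    assigned_last_day = "assigned_last_day"
    assigned_death_day = "assigned_death_day"
    excluded_ntr = "excluded_ntr"


@dataclass
class TTEResult:
    animal_id: str
    tte_days: Optional[float]
    status: TTEStatus
    fit: Optional[RegressionFit] = None
    flags: tuple[str, ...] = ()

    @property
    def excluded(self) -> bool:
        return self.status is TTEStatus.excluded_ntr


@dataclass
class EfficacyResult:
    group_id: str
    median_tte_days: float
    tgd_days: Optional[float] = None  # None for the control group itself
    pct_tgd: Optional[float] = None


def select_endpoint_window(
    curve: GrowthCurve, endpoint_volume_mm3: float
) -> list[tuple[int, float]]:
    """Observations used for the TTE regression.

    The first observation with volume strictly greater than the endpoint,
    plus up to the three immediately preceding observations (fewer if fewer
    exist). Empty if the curve never exceeds the endpoint; an exceedance
    with no preceding observation at all is an insufficient-data error.
    """
    for i, (_, volume) in enumerate(curve.points):
        if volume > endpoint_volume_mm3:
            window = curve.points[max(0, i - 3) : i + 1]
            if len(window) < 2:
                raise InsufficientDataError(
                    f"{curve.animal_id}: endpoint exceeded at the first observation; "
                    "no preceding data to regress on"
                )
            return list(window)
    return []


def fit_log_linear(window: Sequence[tuple[int, float]]) -> RegressionFit:
    """Ordinary least squares of log10(volume) on day; exact on collinear input."""
    if len(window) < 2:
        raise InsufficientDataError("regression window needs >= 2 observations")
    days = np.asarray([d for d, _ in window], dtype=float)
    volumes = np.asarray([v for _, v in window], dtype=float)
    if np.any(volumes <= 0):
        raise DomainError("all volumes in the regression window must be > 0")
    if np.all(days == days[0]):
        raise SingularFitError("all observation days are equal")
    y = np.log10(volumes)
    dbar = days.mean()
    ybar = y.mean()
    slope = float(np.sum((days - dbar) * (y - ybar)) / np.sum((days - dbar) ** 2))
    intercept = float(ybar - slope * dbar)
    return RegressionFit(
        slope_m=slope,
        intercept_b=intercept,
        n_points=len(window),
        window_days=tuple(int(d) for d, _ in window),
    )


def interpolate_tte(fit: RegressionFit, endpoint_volume_mm3: float) -> float:
    """Estimated endpoint-crossing day: (log10(endpoint volume) - b) / m.

    The result is deliberately not clamped to the window's day range; the
    regression may place the crossing after the exceedance day.
    """
    if endpoint_volume_mm3 <= 0:
        raise DomainError("endpoint volume must be > 0")
    if fit.slope_m <= 0:
        raise NonGrowingFitError(
            f"fitted slope {fit.slope_m:.4g} is not positive; crossing undefined"
        )
    return (math.log10(endpoint_volume_mm3) - fit.intercept_b) / fit.slope_m


def assign_tte(
    curve: GrowthCurve,
    design: StudyDesign,
    death: Optional[DeathRecord] = None,
) -> TTEResult:
    """Total TTE assignment over the four mutually exclusive animal fates.

    Endpoint reached -> interpolated TTE from the window regression; else a
    TR death -> the day of death; an NTR death -> excluded from analysis;
    otherwise the animal survived to study end and is assigned the last
    study day. ``death``, when present, must already be classified TR/NTR.

    Degenerate windows fall back to the day of first exceedance rather than
    dropping the animal: the endpoint was factually attained and the
    regression only refines where. Such results carry an explanatory flag.
    """
    if death is not None and curve.points:
        if death.day > curve.days[-1] + 7:
            warnings.warn(
                f"{curve.animal_id}: death on day {death.day} is more than 7 days "
                f"after the last measurement (day {curve.days[-1]})",
                stacklevel=2,
            )

    exceed_day = curve.first_exceedance_day(design.endpoint_volume_mm3)
    if exceed_day is not None:
        try:
            window = select_endpoint_window(curve, design.endpoint_volume_mm3)
        except InsufficientDataError:
            return TTEResult(
                curve.animal_id,
                float(exceed_day),
                TTEStatus.interpolated,
                flags=("short_window_fallback",),
            )
        flags: list[str] = []
        usable = [(d, v) for d, v in window if v > 0]
        if len(usable) < len(window):
            flags.append("zero_volume_dropped")
        if len(usable) < 2:
            return TTEResult(
                curve.animal_id,
                float(exceed_day),
                TTEStatus.interpolated,
                flags=tuple(flags + ["short_window_fallback"]),
            )
        if len(usable) < 4:
            flags.append("short_window")
        fit = fit_log_linear(usable)
        try:
            tte = interpolate_tte(fit, design.endpoint_volume_mm3)
        except NonGrowingFitError:
            return TTEResult(
                curve.animal_id,
                float(exceed_day),
                TTEStatus.interpolated,
                fit=fit,
                flags=tuple(flags + ["nonpositive_slope_fallback"]),
            )
        return TTEResult(
            curve.animal_id, tte, TTEStatus.interpolated, fit=fit, flags=tuple(flags)
        )

    if death is not None and death.classification is DeathClass.TR:
        return TTEResult(curve.animal_id, float(death.day), TTEStatus.assigned_death_day)
    if death is not None and death.classification is DeathClass.NTR:
        return TTEResult(curve.animal_id, None, TTEStatus.excluded_ntr)
    return TTEResult(curve.animal_id, float(design.last_day), TTEStatus.assigned_last_day)


def group_median_tte(results: Sequence[TTEResult]) -> float:
    """Median TTE over non-excluded animals (even n: mean of the central pair)."""
    ttes = [r.tte_days for r in results if not r.excluded]
    if not ttes:
        raise PdxTrialError("no non-excluded TTE results in group")
    return float(np.median(ttes))


def tgd(t_days: float, c_days: float) -> float:
    """Tumor growth delay T - C in days."""
    return t_days - c_days


def pct_tgd(t_days: float, c_days: float) -> float:
    """TGD as a percentage of the control median TTE: 100 * (T - C) / C."""
    if c_days <= 0:
        raise DomainError("control median TTE must be > 0")
    return 100.0 * (t_days - c_days) / c_days
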