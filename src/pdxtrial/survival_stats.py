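"""Two-group logrank test on time-to-endpoint data and significance coding.

Each animal contributes a survival record (TTE in days, event flag). By
default, animals assigned the last study day because they never reached the
endpoint enter as censored observations; interpolated endpoint crossings and
treatment-related deaths enter as events. Setting
``StudyDesign.censor_last_day = False`` instead feeds every TTE as an event
(the naive all-events reading of the per-animal TTE list).

The test is the standard logrank: at each distinct event time, the observed
number of events in group A minus its hypergeometric expectation, with the
hypergeometric variance; chi_square = (sum O - sum E)^2 / sum V, and p is
the upper tail of the chi-square distribution with 1 df (the conventional
realization of a two-sided logrank). Tied events at one time are counted
together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .endpoint_analysis import TTEResult, TTEStatus
from .trial_model import DomainError, PdxTrialError, StudyDesign


@dataclass(frozen=True)
class SurvivalRecord:
    time_days: float
    event: bool  # True = reached endpoint or TR death; False = censored at study end

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise DomainError("survival time must be > 0")


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    n1: int
    n2: int


def survival_records(
    results: Sequence[TTEResult], design: StudyDesign
) -> list[SurvivalRecord]:
    """Map TTE results to survival records; NTR-excluded animals are dropped."""
    records = []
    for r in results:
        if r.excluded:
            continue
        censored = design.censor_last_day and r.status is TTEStatus.assigned_last_day
        records.append(SurvivalRecord(time_days=r.tte_days, event=not censored))
    return records


def logrank_two_group(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Standard two-group logrank test (chi-square with 1 df)."""
    if not group_a or not group_b:
        raise PdxTrialError("both groups must be nonempty")
    times = np.asarray([r.time_days for r in group_a] + [r.time_days for r in group_b])
    events = np.asarray([r.event for r in group_a] + [r.event for r in group_b])
    in_a = np.asarray([True] * len(group_a) + [False] * len(group_b))
    if not events.any():
        raise PdxTrialError("logrank statistic undefined with zero events")

    observed_minus_expected = 0.0
    variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = events & (times == t)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        observed_minus_expected += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)

    if variance == 0.0:
        # no event time where both groups are at risk: no information
        chi_square = 0.0
    else:
        chi_square = observed_minus_expected**2 / variance
    p_value = float(stats.chi2.sf(chi_square, df=1)) if variance > 0 else 1.0
    return LogrankResult(
        chi_square=float(chi_square),
        p_value=p_value,
        n1=len(group_a),
        n2=len(group_b),
    )


def write_logrank_table(results: dict, path) -> None:
    """Emit pairwise comparisons vs control: group, chi-square, p, code."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["group_id", "chi_square", "p_value", "significance"])
        for group_id, r in results.items():
            writer.writerow(
                [group_id, f"{r.chi_square:.4f}", f"{r.p_value:.4f}",
                 significance_code(r.p_value)]
            )


_SIGNIFICANCE_BANDS = (
    (0.001, "***"),  # extremely significant: P <= 0.001
    (0.01, "**"),    # very significant: 0.001 < P <= 0.01
    (0.05, "*"),     # significant: 0.01 < P <= 0.05
)


def significance_code(p: float) -> str:
    """Prism-style band code: ns, *, ** or *** with closed upper boundaries."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"p-value must be in [0, 1], got {p}")
    for bound, code in _SIGNIFICANCE_BANDS:
        if p <= bound:
            return code
    return "ns"
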