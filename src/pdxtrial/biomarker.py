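"""Serum lipase statistics: correlation with tumor volume, group comparisons.

For an acinar-cell tumor that secretes lipase, serum lipase tracks tumor
burden. Two summaries are computed: (1) an ordinary least-squares fit of
individual lipase values on tumor volume, pooled across groups at a single
draw day, reporting R^2; (2) per-group comparisons of on-treatment lipase
against the placebo arm. The between-group comparison uses Welch's
two-sample t-test by default, with an exact-style permutation test of the
mean difference available as an alternative. Both the day-15 values and the
pre/post deltas can be compared, since either reading of "on-treatment
lipase vs placebo" is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .trial_model import DomainError, PdxTrialError


@dataclass(frozen=True)
class LipasePair:
    animal_id: str
    volume_mm3: float
    lipase_u_per_l: float

    def __post_init__(self) -> None:
        if self.volume_mm3 < 0 or self.lipase_u_per_l < 0:
            raise DomainError("volume and lipase must be >= 0")


@dataclass(frozen=True)
class GroupComparison:
    mean_difference: float  # group mean minus placebo mean
    p_value: float
    n_group: int
    n_placebo: int
    low_n: bool  # flagged when either arm has n <= 3


def lipase_volume_fit(
    pairs: Sequence[LipasePair],
) -> tuple[float, float, float]:
    """OLS of lipase on tumor volume: (slope, intercept, r_squared)."""
    if len(pairs) < 3:
        raise PdxTrialError("need >= 3 lipase/volume pairs")
    volume = np.asarray([p.volume_mm3 for p in pairs], dtype=float)
    lipase = np.asarray([p.lipase_u_per_l for p in pairs], dtype=float)
    if np.ptp(volume) == 0:
        raise PdxTrialError("zero variance in tumor volume; fit undefined")
    if np.ptp(lipase) == 0:
        # flat response: the fit is the constant and explains nothing
        return 0.0, float(lipase[0]), 0.0
    fit = stats.linregress(volume, lipase)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def lipase_group_report(
    animals,
    placebo_group_id: str,
    draw_day: int = 15,
    predose_day: int = 1,
    method: str = "welch",
) -> list[dict]:
    """Per-group lipase summary rows versus the placebo arm.

    Each row carries the arm's n, mean pre-dose and draw-day lipase, and the
    draw-day difference and p-value against placebo (None for the placebo
    row itself and for arms too small to compare).
    """
    from .trial_model import group_animals

    def values(members, day):
        return [
            m.lipase_u_per_l
            for a in members
            for m in a.measurements
            if m.day == day and m.lipase_u_per_l is not None
        ]

    groups = group_animals(animals)
    if placebo_group_id not in groups:
        raise PdxTrialError(f"unknown placebo group id: {placebo_group_id}")
    placebo = values(groups[placebo_group_id], draw_day)
    rows = []
    for group_id, members in groups.items():
        day_values = values(members, draw_day)
        pre_values = values(members, predose_day)
        row = {
            "group_id": group_id,
            "n": len(day_values),
            "mean_predose": float(np.mean(pre_values)) if pre_values else None,
            "mean_day": float(np.mean(day_values)) if day_values else None,
            "difference_vs_placebo": None,
            "p_value": None,
            "low_n": None,
        }
        if group_id != placebo_group_id and len(day_values) >= 2 and len(placebo) >= 2:
            cmp = group_lipase_comparison(day_values, placebo, method=method)
            row.update(
                difference_vs_placebo=cmp.mean_difference,
                p_value=cmp.p_value,
                low_n=cmp.low_n,
            )
        rows.append(row)
    return rows


def write_biomarker_table(rows: Sequence[dict], path) -> None:
    """Emit the per-group lipase TSV produced by :func:`lipase_group_report`."""
    import csv
    from pathlib import Path

    def fmt(v, digits=1):
        return "" if v is None else f"{v:.{digits}f}"

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["group_id", "n", "mean_predose", "mean_day15",
             "difference_vs_placebo", "p_value"]
        )
        for r in rows:
            writer.writerow(
                [r["group_id"], r["n"], fmt(r["mean_predose"]), fmt(r["mean_day"]),
                 fmt(r["difference_vs_placebo"]), fmt(r["p_value"], 4)]
            )


def group_lipase_comparison(
    group_values: Sequence[float],
    placebo_values: Sequence[float],
    method: str = "welch",
    n_permutations: int = 10000,
    rng: Optional[np.random.Generator] = None,
) -> GroupComparison:
    """Two-sample comparison of a treatment arm's lipase against placebo.

    method "welch" is Welch's unequal-variance t-test (two-sided);
    "permutation" is a Monte Carlo permutation test of the mean difference.
    """
    a = np.asarray(group_values, dtype=float)
    b = np.asarray(placebo_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PdxTrialError("need n >= 2 per arm")
    diff = float(a.mean() - b.mean())
    if method == "welch":
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    elif method == "permutation":
        rng = rng if rng is not None else np.random.default_rng()
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            d = perm[: a.size].mean() - perm[a.size :].mean()
            if abs(d) >= abs(diff) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise DomainError(f"unknown method {method!r}")
    return GroupComparison(
        mean_difference=diff,
        p_value=p,
        n_group=int(a.size),
        n_placebo=int(b.size),
        low_n=bool(min(a.size, b.size) <= 3),
    )
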