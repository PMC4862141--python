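"""Seedable simulator for complete caliper-based efficacy-trial datasets.

The generator reproduces the statistical structure of a subcutaneous
xenograft efficacy study so that every analysis stage can be exercised and
verified end-to-end:

* baseline tumor volumes drawn uniformly on the eligibility range
  (default 75-245 mm^3) and allocated to groups by balanced snake
  randomization aiming at the target band of group means;
* exponential tumor growth (log-linear, the same law the endpoint
  interpolation assumes, which makes analytic oracles exact), modified
  during the treatment window by one of four response classes:
  ``none`` (vehicle), ``inhibition`` (growth rate reduced by a fraction f),
  ``regression`` (programmed shrinkage), and ``durable`` (growth arrested
  from the first dose onward, emulating a sustained responder);
* multiplicative lognormal caliper noise on volume (volume is cubic in the
  measured lengths, so measurement error is naturally multiplicative);
* twice-weekly measurement grid realized as alternating 3/4-day gaps
  (days 1, 4, 8, 11, ...), stopping at the first observation above the
  endpoint volume or at the last study day;
* body-weight trajectories around a ~20 g baseline with a per-dose
  fractional dip and exponential recovery (purely phenomenological);
* treatment-related deaths drawn per dose, non-treatment-related deaths as
  a constant daily hazard; and
* serum lipase at pre-dose and day 15 as a linear function of tumor volume
  plus Gaussian noise.

Everything is driven by one numpy Generator; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import dosing
from .trial_model import (
    Animal,
    DeathCause,
    DeathRecord,
    DomainError,
    Measurement,
    Regimen,
    Route,
    StudyDesign,
    write_deaths,
    write_measurements,
)

logger = logging.getLogger("pdxtrial")

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthParams:
    """Per-group tumor growth and response model.

    ``growth_rate_per_day`` is the natural-log exponential rate g; doubling
    time is ln(2)/g days. During the treatment window the rate becomes
    g*(1-f) under ``inhibition``, ``-shrink_rate_per_day`` under
    ``regression``, and 0 under ``durable`` (permanently, emulating a
    sustained response). With ``regrowth`` the rate returns to g after the
    window; otherwise the in-window rate persists.
    """

    growth_rate_per_day: float
    effect_model: str = "none"  # none | inhibition | regression | durable
    inhibition_fraction: float = 0.0
    shrink_rate_per_day: float = 0.0
    regrowth: bool = True
    noise_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.effect_model not in ("none", "inhibition", "regression", "durable"):
            raise DomainError(f"unknown effect model {self.effect_model!r}")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise DomainError("inhibition fraction must be in [0, 1]")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")


@dataclass(frozen=True)
class GroupSpec:
    group_id: str
    regimen: Regimen
    growth: GrowthParams
    n: int = 10
    tr_death_prob_per_dose: float = 0.0
    ntr_hazard_per_day: float = 0.0
    bw_dip_frac_per_dose: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.tr_death_prob_per_dose, self.ntr_hazard_per_day):
            if not 0.0 <= p <= 1.0:
                raise DomainError("probabilities must be in [0, 1]")
        if self.n < 1:
            raise DomainError("group size must be >= 1")


@dataclass
class SimConfig:
    design: StudyDesign
    groups: list[GroupSpec]
    seed: int = 0
    measurement_gaps: tuple[int, int] = (3, 4)  # twice weekly: days 1, 4, 8, 11, ...
    bw_baseline_mean_g: float = 20.0
    bw_baseline_sd_g: float = 1.2
    bw_recovery_tau_days: float = 5.0
    bw_noise_cv: float = 0.005
    lipase_alpha: float = 50.0   # U/L at zero tumor burden
    lipase_beta: float = 1.0     # U/L per mm^3
    lipase_sigma: float = 75.0   # residual SD, U/L
    lipase_n_per_group: int = 5  # animals bled per group
    lipase_days: tuple[int, ...] = (1, 15)


@dataclass
class SimulatedTrial:
    config: SimConfig
    animals: list[Animal]
    deaths: dict[str, DeathRecord]
    achieved_group_means: dict[str, float]

    @property
    def design(self) -> StudyDesign:
        return self.config.design

    @property
    def regimens(self) -> dict[str, Regimen]:
        return {g.group_id: g.regimen for g in self.config.groups}

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "measurements": out / "measurements.csv",
            "deaths": out / "deaths.csv",
            "provenance": out / "provenance.json",
        }
        write_measurements(self.animals, paths["measurements"])
        write_deaths(self.deaths.values(), paths["deaths"])
        provenance = asdict(self.config)
        for spec in provenance["groups"]:
            spec["regimen"]["route"] = spec["regimen"]["route"].value
        provenance["achieved_group_means_mm3"] = self.achieved_group_means
        paths["provenance"].write_text(
            json.dumps(provenance, indent=2, default=str), encoding="utf-8"
        )
        return paths


# ---------------------------------------------------------------------------
# Growth law
# ---------------------------------------------------------------------------

def measurement_grid(last_day: int, gaps: tuple[int, int] = (3, 4)) -> list[int]:
    """Twice-weekly measurement days 1, 4, 8, 11, ... up to last_day."""
    days = [1]
    i = 0
    while days[-1] + gaps[i % 2] <= last_day:
        days.append(days[-1] + gaps[i % 2])
        i += 1
    return days


def _rate_segments(
    params: GrowthParams, regimen: Optional[Regimen]
) -> list[tuple[float, float, float]]:
    """(start, end, rate) segments of the piecewise-constant log-growth rate."""
    g = params.growth_rate_per_day
    if regimen is None or params.effect_model == "none":
        return [(-math.inf, math.inf, g)]
    t0, t1 = dosing.treatment_window(regimen)
    if params.effect_model == "durable":
        # arrested from the first dose onward; regrowth does not apply
        return [(-math.inf, t0, g), (t0, math.inf, 0.0)]
    if params.effect_model == "inhibition":
        during = g * (1.0 - params.inhibition_fraction)
    else:  # regression
        during = -params.shrink_rate_per_day
    after = g if params.regrowth else during
    return [(-math.inf, t0, g), (t0, t1, during), (t1, math.inf, after)]


def true_log_volume(
    day: float,
    v0_mm3: float,
    params: GrowthParams,
    regimen: Optional[Regimen],
    baseline_day: float = 1.0,
) -> float:
    """ln V(day) for the noiseless growth law, with V(baseline_day) = v0."""
    log_v = math.log(v0_mm3)
    for start, end, rate in _rate_segments(params, regimen):
        lo = max(start, baseline_day)
        hi = min(end, day)
        if hi > lo:
            log_v += rate * (hi - lo)
    return log_v


def simulate_growth(
    v0_mm3: float,
    params: GrowthParams,
    design: StudyDesign,
    regimen: Optional[Regimen],
    rng: np.random.Generator,
    gaps: tuple[int, int] = (3, 4),
) -> "list[tuple[int, float]]":
    """Simulate one animal's measured (day, volume) series on the grid.

    The day-1 observation is the exact baseline; later observations carry
    multiplicative lognormal noise with coefficient of variation
    ``params.noise_cv`` (mean-one noise). The series stops with the first
    observation above the endpoint volume, or at the last study day.
    """
    if v0_mm3 <= 0:
        raise DomainError("baseline volume must be > 0")
    sigma = math.sqrt(math.log1p(params.noise_cv**2))
    points: list[tuple[int, float]] = []
    for day in measurement_grid(design.last_day, gaps):
        log_v = true_log_volume(day, v0_mm3, params, regimen)
        if day > 1 and sigma > 0:
            log_v += rng.normal(-sigma**2 / 2.0, sigma)
        volume = math.exp(log_v)
        points.append((day, volume))
        if volume > design.endpoint_volume_mm3:
            break
    return points


# ---------------------------------------------------------------------------
# Randomization
# ---------------------------------------------------------------------------

def randomize_groups(
    baselines: Sequence[float],
    k: int,
    design: StudyDesign,
    sizes: Optional[Sequence[int]] = None,
    max_passes: int = 20,
) -> tuple[list[list[int]], list[float]]:
    """Allocate baseline volumes to k groups balancing the group means.

    Deterministic snake allocation on volume-sorted animals, followed by
    local pair swaps that pull every group mean into the design's target
    band when feasible. Returns (allocation as index lists, achieved group
    means). When the band is infeasible for the given baselines a warning is
    logged and the best-achieved means are returned.
    """
    baselines = np.asarray(baselines, dtype=float)
    if np.any(baselines < design.baseline_min_mm3) or np.any(
        baselines > design.baseline_max_mm3
    ):
        raise DomainError("baseline volumes outside the eligibility range")
    sizes = list(sizes) if sizes is not None else None
    if sizes is None:
        if len(baselines) % k != 0:
            raise DomainError("baseline count not divisible into k equal groups")
        sizes = [len(baselines) // k] * k
    if sum(sizes) != len(baselines):
        raise DomainError("group sizes must sum to the number of baselines")

    order = np.argsort(baselines)[::-1]  # largest first
    groups: list[list[int]] = [[] for _ in range(k)]
    direction = 1
    g = 0
    for idx in order:
        while len(groups[g]) >= sizes[g]:
            g += direction
            if g == k or g < 0:
                direction *= -1
                g += direction
        groups[g].append(int(idx))
        g += direction
        if g == k or g < 0:
            direction *= -1
            g += direction

    lo, hi = design.group_mean_band_mm3

    def band_distance(mean: float) -> float:
        if mean < lo:
            return lo - mean
        if mean > hi:
            return mean - hi
        return 0.0

    means = [float(baselines[idx].mean()) for idx in (np.array(g) for g in groups)]
    for _ in range(max_passes):
        if all(band_distance(m) == 0 for m in means):
            break
        improved = False
        for a in range(k):
            for b in range(a + 1, k):
                for ia, i in enumerate(groups[a]):
                    for ib, j in enumerate(groups[b]):
                        delta = baselines[j] - baselines[i]
                        new_a = means[a] + delta / sizes[a]
                        new_b = means[b] - delta / sizes[b]
                        old_cost = band_distance(means[a]) + band_distance(means[b])
                        new_cost = band_distance(new_a) + band_distance(new_b)
                        if new_cost < old_cost - 1e-12:
                            groups[a][ia], groups[b][ib] = j, i
                            means[a], means[b] = new_a, new_b
                            improved = True
        if not improved:
            break

    if any(band_distance(m) > 0 for m in means):
        logger.warning(
            "group-mean band [%g, %g] infeasible for these baselines; "
            "achieved means %s",
            lo,
            hi,
            [round(m, 1) for m in means],
        )
    return groups, means


# ---------------------------------------------------------------------------
# Full-trial simulation
# ---------------------------------------------------------------------------

def _body_weight(
    day: int,
    baseline_g: float,
    dose_days: Sequence[int],
    dip_frac: float,
    tau: float,
    noise: float,
) -> float:
    # weights are taken pre-dose, so a dose-day measurement excludes that dose
    deficit = sum(
        dip_frac * math.exp(-(day - td) / tau) for td in dose_days if td < day
    )
    return baseline_g * (1.0 - min(deficit, 0.95)) * (1.0 + noise)


def _caliper_dims(volume_mm3: float, aspect: float = 1.3) -> tuple[float, float]:
    """Invert V = w^2 l / 2 at a fixed length/width aspect ratio."""
    width = (2.0 * volume_mm3 / aspect) ** (1.0 / 3.0)
    return width, aspect * width


def simulate_trial(config: SimConfig) -> SimulatedTrial:
    """Generate a complete, reproducible trial dataset from one seed."""
    rng = np.random.default_rng(config.seed)
    design = config.design

    total_n = sum(g.n for g in config.groups)
    baselines = rng.uniform(
        design.baseline_min_mm3, design.baseline_max_mm3, size=total_n
    )
    allocation, means = randomize_groups(
        baselines, len(config.groups), design, sizes=[g.n for g in config.groups]
    )
    achieved = {
        spec.group_id: mean for spec, mean in zip(config.groups, means)
    }

    animals: list[Animal] = []
    deaths: dict[str, DeathRecord] = {}
    for spec, indices in zip(config.groups, allocation):
        dose_days = dosing.schedule_days(spec.regimen)
        for j, idx in enumerate(indices):
            animal_id = f"{spec.group_id}-{j + 1:02d}"
            v0 = float(baselines[idx])
            points = simulate_growth(
                v0, spec.growth, design, spec.regimen, rng, config.measurement_gaps
            )

            # death processes: earliest of per-dose TR draw and daily NTR hazard
            tr_day: Optional[int] = None
            if spec.tr_death_prob_per_dose > 0:
                for td in dose_days:
                    if rng.random() < spec.tr_death_prob_per_dose:
                        tr_day = td + int(rng.integers(1, 5))
                        break
            ntr_day: Optional[int] = None
            if spec.ntr_hazard_per_day > 0:
                draw = int(rng.geometric(spec.ntr_hazard_per_day))
                if draw <= design.last_day:
                    ntr_day = max(draw, 2)
            death_day: Optional[int] = None
            death_cause: Optional[DeathCause] = None
            if tr_day is not None and (ntr_day is None or tr_day <= ntr_day):
                death_day = max(tr_day, 2)
                death_cause = (
                    DeathCause.treatment_evidence
                    if rng.random() < 0.5
                    else DeathCause.unknown
                )
            elif ntr_day is not None:
                death_day = ntr_day
                death_cause = (
                    DeathCause.accidental
                    if rng.random() < 0.5
                    else DeathCause.unrelated_evidence
                )

            exit_day = points[-1][0]
            reached = points[-1][1] > design.endpoint_volume_mm3
            if death_day is not None and (not reached or death_day <= exit_day):
                points = [p for p in points if p[0] < death_day] or points[:1]
                deaths[animal_id] = DeathRecord(
                    animal_id=animal_id, day=death_day, observed_cause=death_cause
                )

            bw_baseline = rng.normal(config.bw_baseline_mean_g, config.bw_baseline_sd_g)
            takes_lipase = j < config.lipase_n_per_group
            measurements = []
            for day, volume in points:
                width, length = _caliper_dims(volume)
                bw_noise = (
                    rng.normal(0.0, config.bw_noise_cv) if config.bw_noise_cv > 0 else 0.0
                )
                bw = _body_weight(
                    day,
                    bw_baseline,
                    dose_days,
                    spec.bw_dip_frac_per_dose,
                    config.bw_recovery_tau_days,
                    bw_noise,
                )
                lipase = None
                if takes_lipase and day in config.lipase_days:
                    lipase = max(
                        0.0,
                        config.lipase_alpha
                        + config.lipase_beta * volume
                        + rng.normal(0.0, config.lipase_sigma),
                    )
                measurements.append(
                    Measurement(
                        day=day,
                        width_mm=width,
                        length_mm=length,
                        body_weight_g=bw,
                        lipase_u_per_l=lipase,
                    ).canonicalized()
                )
            animals.append(
                Animal(
                    animal_id=animal_id,
                    group_id=spec.group_id,
                    measurements=measurements,
                    death=deaths.get(animal_id),
                )
            )

    return SimulatedTrial(
        config=config, animals=animals, deaths=deaths, achieved_group_means=achieved
    )


# ---------------------------------------------------------------------------
# Recovery / calibration experiments
# ---------------------------------------------------------------------------

def _arm_tte_results(
    rng: np.random.Generator,
    params: GrowthParams,
    regimen: Optional[Regimen],
    design: StudyDesign,
    n: int,
):
    from .endpoint_analysis import assign_tte
    from .volumetrics import GrowthCurve

    results = []
    for i in range(n):
        v0 = rng.uniform(design.baseline_min_mm3, design.baseline_max_mm3)
        points = simulate_growth(v0, params, design, regimen, rng)
        results.append(assign_tte(GrowthCurve(f"a{i}", points), design))
    return results


def tgd_recovery_experiment(
    seeds: Sequence[int],
    n_per_arm: int = 10,
    noise_cv: float = 0.10,
    doubling_days: float = 7.0,
) -> list[float]:
    """Estimated TGD per seed for a programmed full growth pause.

    Control arm grows exponentially (default doubling time 7 days); the
    treated arm is fully inhibited (f = 1) over a weekly-x3 course, i.e. a
    programmed 21-day delay. Each seed simulates both arms with noisy
    twice-weekly calipers and runs the TTE pipeline; the returned values are
    the estimated median-TTE differences. Their median should sit near the
    programmed 21 days.
    """
    design = StudyDesign()
    regimen = Regimen(
        "pause", 1.0, Route.ip, dosing.parse_schedule("qwk x 3"), first_dose_day=1
    )
    g = LN2 / doubling_days
    control = GrowthParams(growth_rate_per_day=g, noise_cv=noise_cv)
    treated = GrowthParams(
        growth_rate_per_day=g,
        effect_model="inhibition",
        inhibition_fraction=1.0,
        noise_cv=noise_cv,
    )
    from .endpoint_analysis import group_median_tte

    estimates = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        c = group_median_tte(_arm_tte_results(rng, control, None, design, n_per_arm))
        t = group_median_tte(_arm_tte_results(rng, treated, regimen, design, n_per_arm))
        estimates.append(t - c)
    return estimates


def null_logrank_calibration(
    seeds: Sequence[int],
    alpha: float = 0.05,
    n_per_arm: int = 10,
    noise_cv: float = 0.10,
    doubling_days: float = 7.0,
) -> float:
    """False-positive rate of the logrank test on identically grown arms.

    Both arms use the same untreated growth law; the returned fraction of
    seeds with p < alpha should be close to alpha for a calibrated test.
    """
    from .endpoint_analysis import group_median_tte  # noqa: F401  (keeps import local)
    from .survival_stats import logrank_two_group, survival_records

    design = StudyDesign()
    params = GrowthParams(growth_rate_per_day=LN2 / doubling_days, noise_cv=noise_cv)
    rejections = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        a = survival_records(_arm_tte_results(rng, params, None, design, n_per_arm), design)
        b = survival_records(_arm_tte_results(rng, params, None, design, n_per_arm), design)
        if logrank_two_group(a, b).p_value < alpha:
            rejections += 1
    return rejections / len(seeds)


# ---------------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------------

def _regimen(agent: str, dose: float, route: str, code: str) -> Regimen:
    return Regimen(
        agent=agent,
        dose_mg_per_kg=dose,
        route=Route(route),
        schedule=dosing.parse_schedule(code),
        first_dose_day=1,
    )


def default_sim_config(seed: int = 0) -> SimConfig:
    """Nine-arm trial emulating the study structure this package targets.

    One vehicle control and eight monotherapy arms of n = 10, covering the
    three observed response classes: transient inhibition with regrowth on
    drug withdrawal, intermediate response with slow regrowth, and a durable
    arrest lasting to study end. The control doubling time (14 days) puts
    the control median endpoint crossing near day 33. Per-dose body-weight
    dips, TR death probabilities and NTR hazards are set so group nadirs
    span roughly -0.1% to -15% and a realistic sprinkle of TR/NTR deaths
    occurs, including one overtly toxic arm.
    """
    g = LN2 / 14.0  # control doubling time 14 days

    def growth(**kw) -> GrowthParams:
        return GrowthParams(growth_rate_per_day=g, **kw)

    groups = [
        GroupSpec("G1", _regimen("vehicle", 0.0, "ip", "qwk x 3"), growth()),
        GroupSpec(
            "G2",
            _regimen("5-FU", 100.0, "ip", "qwk x 3"),
            growth(effect_model="inhibition", inhibition_fraction=0.25),
            tr_death_prob_per_dose=0.033,
            bw_dip_frac_per_dose=0.083,
        ),
        GroupSpec(
            "G3",
            _regimen("irinotecan", 100.0, "ip", "qwk x 3"),
            growth(effect_model="inhibition", inhibition_fraction=0.40),
            bw_dip_frac_per_dose=0.111,
        ),
        GroupSpec(
            "G4",
            _regimen("oxaliplatin", 10.0, "ip", "qwk x 3"),
            growth(effect_model="durable", regrowth=False),
            bw_dip_frac_per_dose=0.138,
        ),
        GroupSpec(
            "G5",
            _regimen("gemcitabine", 120.0, "ip", "q3d x 4"),
            growth(effect_model="inhibition", inhibition_fraction=0.45),
            tr_death_prob_per_dose=0.025,
            bw_dip_frac_per_dose=0.032,
        ),
        GroupSpec(
            "G6",
            _regimen("bevacizumab", 5.0, "ip", "biwk x 5"),
            growth(effect_model="inhibition", inhibition_fraction=1.0),
            ntr_hazard_per_day=0.0014,
            bw_dip_frac_per_dose=0.020,
        ),
        GroupSpec(
            "G7",
            _regimen("erlotinib", 80.0, "po", "qd x 15"),
            growth(effect_model="regression", shrink_rate_per_day=0.02),
            tr_death_prob_per_dose=0.013,
            ntr_hazard_per_day=0.0014,
            bw_dip_frac_per_dose=0.036,
        ),
        GroupSpec(
            "G8",
            _regimen("doxorubicin", 3.0, "iv", "qwk x 3"),
            growth(effect_model="regression", shrink_rate_per_day=0.03),
            bw_dip_frac_per_dose=0.072,
        ),
        GroupSpec(
            "G9",
            _regimen("imatinib", 100.0, "po", "qd x 28"),
            growth(effect_model="inhibition", inhibition_fraction=0.05),
            ntr_hazard_per_day=0.0014,
            bw_dip_frac_per_dose=0.0017,
        ),
    ]
    return SimConfig(design=StudyDesign(), groups=groups, seed=seed)
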