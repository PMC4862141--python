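# Methods

## The trial model

The package analyzes single-site subcutaneous xenograft efficacy studies of
the classical design: tumor-bearing mice are randomized to one control and
several treatment arms once tumors reach an eligibility window, calipered
twice weekly, and followed until the tumor reaches an endpoint volume or
the study ends. The units of analysis are:

* a **measurement** — one (study day, caliper width, caliper length, body
  weight, optional serum lipase) record per animal per measurement day.
  Day 1 is the randomization / first-dose day; the day-1 measurement is the
  pre-dose baseline. Caliper axes are canonicalized on ingest so that
  width ≤ length, because the volume formula `V = w²·l/2` (a prolate-
  ellipsoid approximation) is only well defined with `w` the smaller axis.
* a **death record** — day plus an observed cause category
  (`treatment_evidence`, `unrelated_evidence`, `unknown`, `accidental`)
  from which the TR/NTR classification is derived.
* a **study design** — the trial constants: endpoint volume (default
  800 mm³), last day (74), dosing volume (10 mL/kg), baseline eligibility
  range (75–245 mm³), target band of group-mean baselines (164–170 mm³),
  and the MTD limits (mean BW loss < 20 %, TR mortality ≤ 10 %, 14-day
  post-dose TR window).

## Time-to-endpoint

TTE is the estimated day the tumor crosses the endpoint volume, obtained by
inverting an OLS fit of log₁₀ volume on day over the *endpoint window*: the
first observation whose volume strictly exceeds the endpoint plus up to the
three observations immediately preceding it. With slope `m` and intercept
`b`, `TTE = (log₁₀(endpoint volume) − b)/m`. The crossing is deliberately
not clamped to the window's day span: with noisy flat-then-jump data the
regression can place it after the exceedance day, and the formula is
applied as written.

Assignment rules are total and mutually exclusive per animal: endpoint
reached → interpolated; otherwise TR death → day of death; NTR death →
excluded from analysis; otherwise (alive, under endpoint at study end) →
the last study day.

Degenerate cases, where the method is silent, are handled as follows and
always flagged on the result:

* fewer than two positive-volume observations available for the window →
  fall back to the day of first exceedance (the endpoint was factually
  attained; dropping the animal would bias TTE downward);
* non-positive fitted slope (possible with shrink-then-jump curves) → same
  fallback;
* zero or missing volumes inside the window are dropped before fitting
  (the log is undefined);
* windows with 2–3 points are used but flagged `short_window`.

Exact-at-endpoint observations (volume equal to the endpoint) are not
exceedances; strict inequality is used throughout.

Group medians use the standard even-n convention (mean of the central
pair). `TGD = T − C` and `%TGD = 100·(T − C)/C` compare each treated median
`T` with the control median `C`.

## Survival comparison

Each non-excluded animal contributes (TTE, event flag) to a two-group
logrank test against the control arm. Animals assigned the last study day
never experienced the event, so by default they enter censored
(`censor_last_day = True`); interpolated crossings and TR deaths are
events. The alternative all-events reading — feeding every assigned TTE as
an event — is available as a design switch because published tables built
from per-animal TTE lists do not always state the censoring convention.
This switch is the single most consequential interpretation in the package.

The statistic is the standard logrank: at each distinct event time, the
observed events in one group minus the hypergeometric expectation, with the
hypergeometric variance (ties pooled per time point);
`χ² = (ΣO − ΣE)²/ΣV`, `p` from the upper tail of χ²(1). Significance codes
follow the Prism bands with closed upper boundaries: `***` for p ≤ 0.001,
`**` for p ≤ 0.01, `*` for p ≤ 0.05, else `ns`.

Two calibration facts, measured by the test suite rather than assumed:

* the implementation agrees with an independent reference (lifelines) to
  machine precision on randomized instances, including ties and censoring;
* the asymptotic χ² approximation is slightly liberal at trial-sized
  samples: with 10 animals per arm, all events, the empirical size at
  nominal α = 0.05 is ≈ 6.5 % (identical in the reference implementation).
  At very small samples (3–4 per arm) the asymptotic p can differ from the
  exact permutation-null p by ~0.03–0.1, far more than Monte Carlo error in
  the permutation estimate; the corresponding acceptance check records this
  approximation gap.

## Toxicity and evaluability

Body weight is expressed as percent change from the day-1 baseline; the
group nadir is the minimum over days of the group-mean change (ties break
to the earliest day; means are taken over animals measured on that day). A
death is TR if there is treatment evidence, or if the cause is unknown and
the death falls within the dosing period or 14 days after the last dose;
unrelated or accidental deaths, and unknown deaths after the window, are
NTR. The MTD is exceeded if the group-mean BW loss reaches 20 % on any day
(loss strictly below 20 % is the acceptable region, so exactly −20.0 %
exceeds) or TR mortality exceeds 10 % of the initial group size (exactly
10 % is acceptable). A group exceeding the MTD is not evaluable for
efficacy. The TR-mortality denominator is the initial group size; reported
assessable n is initial n minus NTR deaths. Whether per-animal euthanasia
for weight loss uses the same 20 % bound as the group criterion is exposed
as `per_animal_bw_limit_pct` (default 20) without further claim.

## Dosing

Dose (mg/kg) is the product of formulation concentration (mg/mL) and the
fixed dosing volume (mL/kg); injection volume scales linearly with body
weight (0.2 mL for a 20 g mouse at 10 mL/kg). Schedules expand from
shorthand codes; `biwk` places two doses per 7-day block at offsets
{0, 3} (the within-week offsets are a convention and configurable). The
schedule's *treatment window* — first dose day through the end of the last
scheduled interval — is what the simulator uses as the drug-effect span, so
`qwk × 3` covers 21 days and `qd × 15` covers 15.

## The simulator and what it does (not) emulate

The generator's defaults reproduce the statistical structure of a nine-arm
study: one vehicle arm and eight monotherapies, n = 10 per arm, baselines
uniform on 75–245 mm³ allocated by deterministic snake randomization with
local swap repair toward the 164–170 mm³ group-mean band (with a uniform
baseline pool the cohort mean sits near 160 mm³, so the band is often
infeasible; the allocator then reports best-achieved means, which cluster
within a few mm³ of each other, and logs a warning).

Growth is exponential — deliberately, since the endpoint interpolation
itself assumes log-linear growth near the endpoint, which makes analytic
crossings available as exact oracles. The control doubling time is 14 days,
putting the control median crossing near day 33. Treatment effects are
piecewise modifications of the log-growth rate over the treatment window:
fractional inhibition `g·(1 − f)` (with regrowth at rate `g` after the
window), programmed shrinkage, or durable arrest from the first dose onward
(emulating a sustained responder whose median TTE is the day-74 sacrifice).
Arm parameters are set so the three response classes seen in such studies —
transient inhibition with regrowth, intermediate response, durable arrest —
are all represented, with one overtly toxic arm (daily dosing, ≈ −15 %
nadir, elevated TR-death risk).

Caliper noise is multiplicative lognormal on volume with CV 10 % (volume is
cubic in the measured lengths, so measurement error compounds
multiplicatively); the day-1 baseline is recorded exactly, which keeps
randomized baselines inside the eligibility range. Measurements follow the
twice-weekly grid (days 1, 4, 8, 11, …) and stop at the first observation
above the endpoint or at day 74. Body weight is a ~20 g baseline with a
per-dose fractional dip and 5-day exponential recovery, weighed pre-dose on
dosing days — a phenomenological model parameterized to produce group
nadirs from ≈ −0.1 % (vehicle, noise only) to ≈ −15 %. TR deaths are drawn
per dose, NTR deaths from a constant daily hazard; a death truncates the
measurement series. Serum lipase on the five bled animals per arm is
`α + β·V + ε` at pre-dose and day 15 (α = 50 U/L, β = 1 U/L/mm³,
σ = 75 U/L); σ was calibrated once so the pooled day-15 lipase-volume R²
centers near 0.69 (measured 0.69 ± 0.05 across seeds).

What the simulator does **not** emulate — and therefore what passing tests
do not establish about real data: Gompertzian deceleration at large tumor
burden, inter-animal growth-rate heterogeneity beyond the baseline spread,
dosing holidays/dose reductions after toxicity (dosing suspension is an
emitted flag only), caliper digitization and observer effects, and any
mechanistic pharmacology (effects are windows on the growth rate, not
concentration-response curves).

## Numerical and design choices

* OLS fits use the closed-form two-parameter solution in double precision;
  collinear input is recovered exactly.
* Carry-forward applies to the group mean as well as the median so the two
  summary curves stay consistent.
* Curve truncation uses a strict majority (6 of 10, not 5 of 10) at
  endpoint, or the day the MTD was exceeded, whichever is earlier.
* The logrank variance term skips event times where only one subject is at
  risk (the hypergeometric variance is undefined there); zero total
  variance yields χ² = 0, p = 1.
* Welch's t-test is the default for biomarker group comparisons, with a
  Monte Carlo permutation test as the alternative; both day-15 values and
  pre/post deltas can be compared since either reading of "on-treatment
  versus placebo" is defensible.
* Problem sizes in the verification experiments — 200 simulated trials for
  the growth-delay recovery (median recovered 21 ± 2 days for a programmed
  21-day pause) and 1000 for the null calibration — were chosen to bound
  the Monte Carlo error of each estimate well below the property's
  tolerance while keeping the whole suite fast.

## Known limitations

* Published chi-square/p values from any specific historical study are not
  reproducible without its per-animal TTEs; the test suite therefore
  verifies the statistics against independent oracles and calibration
  experiments instead of printed table values.
* The endpoint interpolation is only as good as the log-linear assumption
  over the last four observations; strongly decelerating growth near
  endpoint biases the crossing late.
* Real measurement days that drift off the twice-weekly grid are binned to
  the nearest grid day by the curve summaries; per-animal TTE regression
  uses the actual recorded days and is unaffected.
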