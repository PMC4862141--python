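# pdxtrial

Analysis of caliper-based preclinical efficacy trials in subcutaneous tumor
xenograft models (e.g. patient-derived xenografts, PDTX), together with a
seedable trial simulator used to verify every stage end-to-end.

Researchers running mouse efficacy studies measure tumors twice weekly with
calipers, euthanize each animal when its tumor reaches an endpoint volume
(here 800 mm³) or at the end of the study (day 74), and summarize efficacy
as *tumor growth delay*. This package implements that complete analysis:

* **Volumetrics** — tumor volume from caliper axes, `V = w²·l/2` (mm³, with
  `w ≤ l`), tumor weight under the 1 mg ≡ 1 mm³ assumption, and group
  growth-curve summaries with the carry-forward rule (an animal that exits
  at endpoint keeps contributing its final volume to later group medians)
  and >50 %-at-endpoint curve truncation.
* **Time-to-endpoint (TTE)** — for each animal, ordinary least squares of
  log₁₀ volume on study day over a short window (the first observation
  above the endpoint plus up to the three before it), then

  &nbsp;&nbsp;&nbsp;&nbsp;`TTE = (log₁₀(endpoint volume) − b) / m`

  with slope `m` and intercept `b`. Animals that never reach endpoint get
  `TTE = last day`; treatment-related (TR) deaths get the day of death;
  non-treatment-related (NTR) deaths are excluded.
* **Efficacy** — tumor growth delay `TGD = T − C` and
  `%TGD = 100·(T − C)/C`, where `T` and `C` are treated and control median
  TTEs, plus a two-group logrank test (hypergeometric observed-minus-
  expected, χ² with 1 df) with Prism-style significance codes
  (`ns`, `*`, `**`, `***`).
* **Toxicity** — body-weight nadir as percent change from day 1, TR/NTR
  death classification (unknown causes are TR during dosing or within 14
  days of the last dose), and the MTD rule: a group exceeding 20 % mean
  body-weight loss or 10 % TR mortality is not evaluable.
* **Dosing** — concentration × dosing-volume arithmetic
  (mg/mL × mL/kg → mg/kg), per-animal injection volumes, and schedule
  expansion (`qwk × 3`, `q3d × 4`, `biwk × 5`, `qd × N`).
* **Biomarker** — serum lipase vs tumor volume regression (R²) and
  treatment-vs-placebo comparisons (Welch's t-test or permutation).
* **Simulator** — a nine-arm synthetic study with balanced baseline
  randomization (75–245 mm³), exponential growth with treatment-effect
  windows (transient inhibition, regression, durable arrest), lognormal
  caliper noise, body-weight dips, TR/NTR deaths, and volume-linked lipase.

## Worked example

Simulate a trial and analyze it (the `pdxtrial` console script wraps the
same functions):

```sh
pdxtrial simulate --seed 1 --out demo/
# write demo/design.yaml with the endpoint/last-day and per-group regimens
pdxtrial analyze --measurements demo/measurements.csv --deaths demo/deaths.csv \
    --design demo/design.yaml --control G1 --out demo/out/
```

`demo/out/summary.tsv` for seed 1 (abridged):

```
group_id  agent        schedule  median_tte_days  tgd_days  chi_square  p_value  significance  bw_nadir_pct  tr  ntr  evaluable
G1        vehicle      qwk x 3   31.0                                                          -0.5          0   0    yes
G2        5-FU         qwk x 3   35.3             4.3       1.4558      0.2276   ns            -5.9          0   0    yes
G4        oxaliplatin  qwk x 3   74.0             43.0      21.8369     0.0000   ***           -9.6          0   0    yes
G5        gemcitabine  q3d x 4   35.7             4.7       0.5920      0.4416   ns            -5.1          2   0    ne
G7        erlotinib    qd x 15   50.9             19.9      9.9564      0.0016   **            -15.6         1   1    yes
```

Reading the rows: the vehicle arm's tumors crossed 800 mm³ at a median of
31.0 days. The durable-arrest arm (G4) never reached endpoint, so every
animal is assigned the day-74 sacrifice as its TTE — the largest possible
delay (TGD 43.0 days) and an extremely significant logrank split versus
control. G5 drew two treatment-related deaths out of ten (20 % TR
mortality, above the 10 % limit), so its efficacy row is marked `ne`
(not evaluable). G6/G7 show the assessable-n adjustment: one NTR death each
drops them to n = 9. Per-animal regression diagnostics are in `tte.tsv` and
the carry-forward group curves in `curves.tsv`.

The same analysis is available as a library call:

```python
from pdxtrial import synth_trial, analyze_trial

trial = synth_trial.simulate_trial(synth_trial.default_sim_config(seed=1))
result = analyze_trial(trial.animals, trial.deaths, trial.design,
                       trial.regimens, control_group_id="G1")
```

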