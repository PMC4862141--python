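import logging
import math

import pytest

from pdxtrial.dosing import parse_schedule
from pdxtrial.endpoint_analysis import TTEStatus, assign_tte
from pdxtrial.synth_trial import (
    GroupSpec,
    GrowthParams,
    default_sim_config,
    measurement_grid,
    randomize_groups,
    simulate_growth,
    simulate_trial,
    true_log_volume,
)
from pdxtrial.trial_model import DomainError, Regimen, Route
from pdxtrial.volumetrics import GrowthCurve

LN2 = math.log(2.0)


def _regimen(code="qwk x 3"):
    return Regimen("x", 10.0, Route.ip, parse_schedule(code), first_dose_day=1)


def test_measurement_grid_is_twice_weekly():
    grid = measurement_grid(22)
    assert grid == [1, 4, 8, 11, 15, 18, 22]
    assert measurement_grid(74)[-1] <= 74


class TestSimulateGrowth:
    def test_noiseless_exponential_recovers_analytic_crossing(self, design, rng):
        """Three doublings from 100 mm^3: crossing at day 22 (baseline day 1)."""
        params = GrowthParams(growth_rate_per_day=LN2 / 7, noise_cv=0.0)
        points = simulate_growth(100.0, params, design, None, rng)
        curve = GrowthCurve("a", points)
        r = assign_tte(curve, design)
        analytic = 1.0 + 7.0 * math.log2(800.0 / 100.0)
        assert r.status is TTEStatus.interpolated
        assert r.tte_days == pytest.approx(analytic, abs=1e-6)

    def test_durable_response_freezes_volume_until_study_end(self, design, rng):
        params = GrowthParams(
            growth_rate_per_day=LN2 / 7, effect_model="durable", regrowth=False,
            noise_cv=0.0,
        )
        points = simulate_growth(100.0, params, design, _regimen(), rng)
        volumes = [v for _, v in points]
        assert volumes == pytest.approx([100.0] * len(volumes))
        assert points[-1][0] == measurement_grid(design.last_day)[-1]
        assert assign_tte(GrowthCurve("a", points), design).status is (
            TTEStatus.assigned_last_day
        )

    def test_full_inhibition_delays_crossing_by_window_length(self, design, rng):
        # 21-day full pause (qwk x 3), regrowth afterwards
        control = GrowthParams(growth_rate_per_day=LN2 / 7, noise_cv=0.0)
        treated = GrowthParams(
            growth_rate_per_day=LN2 / 7, effect_model="inhibition",
            inhibition_fraction=1.0, noise_cv=0.0,
        )
        tte_c = assign_tte(
            GrowthCurve("c", simulate_growth(100.0, control, design, None, rng)), design
        ).tte_days
        tte_t = assign_tte(
            GrowthCurve("t", simulate_growth(100.0, treated, design, _regimen(), rng)),
            design,
        ).tte_days
        assert tte_t - tte_c == pytest.approx(21.0, abs=1e-6)

    def test_noise_free_law_matches_closed_form(self, design):
        params = GrowthParams(growth_rate_per_day=0.05, noise_cv=0.0)
        assert true_log_volume(15.0, 200.0, params, None) == pytest.approx(
            math.log(200.0) + 0.05 * 14.0
        )

    def test_invalid_baseline_rejected(self, design, rng):
        with pytest.raises(DomainError):
            simulate_growth(0.0, GrowthParams(0.05), design, None, rng)


class TestRandomizeGroups:
    def test_snake_allocation_balances_means(self, design, rng):
        baselines = rng.uniform(75, 245, 90)
        groups, means = randomize_groups(baselines, 9, design)
        assert sorted(i for g in groups for i in g) == list(range(90))
        assert max(means) - min(means) < 5.0

    def test_identical_baselines_give_equal_means(self, design):
        groups, means = randomize_groups([100.0] * 20, 4, design)
        assert means == [100.0] * 4

    def test_infeasible_band_warns_and_reports_best(self, design, caplog):
        with caplog.at_level(logging.WARNING, logger="pdxtrial"):
            _, means = randomize_groups([75.0] * 20, 2, design)
        assert "infeasible" in caplog.text
        assert means == [75.0, 75.0]

    def test_out_of_range_baseline_rejected(self, design):
        with pytest.raises(DomainError):
            randomize_groups([50.0] * 10, 2, design)


class TestSimulateTrial:
    def test_fixed_seed_gives_byte_identical_outputs(self, tmp_path):
        config = default_sim_config(seed=7)
        paths1 = simulate_trial(config).write(tmp_path / "run1")
        paths2 = simulate_trial(default_sim_config(seed=7)).write(tmp_path / "run2")
        for key in paths1:
            assert paths1[key].read_bytes() == paths2[key].read_bytes()

    def test_zero_death_rates_give_zero_deaths(self):
        config = default_sim_config(seed=3)
        config.groups = [
            GroupSpec(
                g.group_id, g.regimen, g.growth, n=g.n,
                tr_death_prob_per_dose=0.0, ntr_hazard_per_day=0.0,
                bw_dip_frac_per_dose=g.bw_dip_frac_per_dose,
            )
            for g in config.groups
        ]
        trial = simulate_trial(config)
        assert trial.deaths == {}

    def test_baselines_respect_eligibility_range(self, default_trial):
        from pdxtrial.volumetrics import caliper_volume

        design = default_trial.design
        for a in default_trial.animals:
            m = a.measurements[0]
            v0 = caliper_volume(m.width_mm, m.length_mm)
            assert design.baseline_min_mm3 - 1e-9 <= v0 <= design.baseline_max_mm3 + 1e-9

    def test_structure_matches_study_layout(self, default_trial):
        groups = {}
        for a in default_trial.animals:
            groups.setdefault(a.group_id, []).append(a)
        assert len(groups) == 9
        assert all(len(members) == 10 for members in groups.values())
        # lipase drawn pre-dose and day 15 on the bled animals
        bled = [
            a for a in default_trial.animals
            if any(m.lipase_u_per_l is not None for m in a.measurements)
        ]
        assert len(bled) == 9 * 5
        for a in bled:
            lipase_days = {m.day for m in a.measurements if m.lipase_u_per_l is not None}
            assert 1 in lipase_days

    def test_death_truncates_measurement_series(self, default_trial):
        by_id = {a.animal_id: a for a in default_trial.animals}
        assert default_trial.deaths  # default config produces some deaths
        for animal_id, record in default_trial.deaths.items():
            last_measured = by_id[animal_id].days[-1]
            assert last_measured < record.day or last_measured == 1
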