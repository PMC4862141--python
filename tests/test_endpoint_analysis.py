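import math

import pytest
from hypothesis import given, settings, strategies as st

from pdxtrial.endpoint_analysis import (
    InsufficientDataError,
    NonGrowingFitError,
    RegressionFit,
    SingularFitError,
    TTEStatus,
    assign_tte,
    fit_log_linear,
    group_median_tte,
    interpolate_tte,
    pct_tgd,
    select_endpoint_window,
    tgd,
)
from pdxtrial.trial_model import DeathCause, DeathClass, DeathRecord, DomainError, PdxTrialError
from pdxtrial.volumetrics import GrowthCurve


def _curve(points, animal_id="a1"):
    return GrowthCurve(animal_id=animal_id, points=points)


# Frozen oracle values for the flat-then-jump window [(0,100),(3,100),(6,100),(9,900)],
# computed with an independent least-squares routine (numpy.polyfit on log10 volumes).
ORACLE_SLOPE = 0.0954242509439324
ORACLE_INTERCEPT = 1.8091514981121357
ORACLE_TTE_800 = 11.463946303571865


class TestSelectEndpointWindow:
    def test_exactly_four_observations(self):
        pts = [(7, 100.0), (14, 200.0), (21, 400.0), (29, 884.0)]
        assert select_endpoint_window(_curve(pts), 800.0) == pts

    def test_window_slides_to_last_four(self):
        pts = [(1, 50.0), (4, 100.0), (8, 200.0), (11, 400.0), (15, 900.0), (18, 1200.0)]
        assert select_endpoint_window(_curve(pts), 800.0) == pts[1:5]

    def test_never_exceeding_curve_gives_empty_window(self):
        assert select_endpoint_window(_curve([(1, 100.0), (4, 700.0)]), 800.0) == []

    def test_exceedance_at_first_observation_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            select_endpoint_window(_curve([(1, 900.0), (4, 1000.0)]), 800.0)

    def test_exactly_endpoint_volume_is_not_an_exceedance(self):
        assert select_endpoint_window(_curve([(1, 100.0), (4, 800.0)]), 800.0) == []


class TestFitLogLinear:
    def test_exact_exponential_recovers_closed_form(self):
        days = [7, 14, 21, 29]
        pts = [(d, 50.0 * 2 ** (d / 7)) for d in days]
        fit = fit_log_linear(pts)
        assert fit.slope_m == pytest.approx(math.log10(2) / 7, abs=1e-12)
        assert fit.intercept_b == pytest.approx(math.log10(50), abs=1e-12)

    def test_matches_independent_least_squares_oracle(self):
        fit = fit_log_linear([(0, 100.0), (3, 100.0), (6, 100.0), (9, 900.0)])
        assert fit.slope_m == pytest.approx(ORACLE_SLOPE, abs=1e-12)
        assert fit.intercept_b == pytest.approx(ORACLE_INTERCEPT, abs=1e-12)

    def test_two_points_give_the_exact_line(self):
        fit = fit_log_linear([(0, 100.0), (10, 1000.0)])
        assert fit.slope_m == pytest.approx(0.1)
        assert fit.intercept_b == pytest.approx(2.0)

    def test_nonpositive_volume_is_domain_error(self):
        with pytest.raises(DomainError):
            fit_log_linear([(0, 0.0), (3, 100.0)])

    def test_equal_days_are_singular(self):
        with pytest.raises(SingularFitError):
            fit_log_linear([(3, 100.0), (3, 200.0)])


class TestInterpolateTTE:
    def test_exact_exponential_crossing(self):
        pts = [(d, 50.0 * 2 ** (d / 7)) for d in [7, 14, 21, 29]]
        fit = fit_log_linear(pts)
        # 50 * 2^(t/7) = 800 at t = 28
        assert interpolate_tte(fit, 800.0) == pytest.approx(28.0, abs=1e-9)

    def test_oracle_window_crossing(self):
        fit = fit_log_linear([(0, 100.0), (3, 100.0), (6, 100.0), (9, 900.0)])
        assert interpolate_tte(fit, 800.0) == pytest.approx(ORACLE_TTE_800, abs=1e-9)

    def test_crossing_may_lie_beyond_the_window(self):
        fit = fit_log_linear([(0, 100.0), (3, 100.0), (6, 100.0), (9, 900.0)])
        assert interpolate_tte(fit, 800.0) > 9

    def test_zero_slope_is_error(self):
        fit = RegressionFit(slope_m=0.0, intercept_b=2.0, n_points=2, window_days=(1, 4))
        with pytest.raises(NonGrowingFitError):
            interpolate_tte(fit, 800.0)


class TestAssignTTE:
    def test_never_reaching_endpoint_assigns_last_day(self, design):
        curve = _curve([(1, 100.0), (74, 700.0)])
        r = assign_tte(curve, design)
        assert (r.tte_days, r.status) == (74.0, TTEStatus.assigned_last_day)

    def test_tr_death_assigns_day_of_death(self, design):
        curve = _curve([(1, 100.0), (18, 300.0)])
        death = DeathRecord("a1", 21, DeathCause.treatment_evidence, DeathClass.TR)
        r = assign_tte(curve, design, death)
        assert (r.tte_days, r.status) == (21.0, TTEStatus.assigned_death_day)

    def test_ntr_death_excludes_animal(self, design):
        curve = _curve([(1, 100.0), (25, 300.0)])
        death = DeathRecord("a1", 30, DeathCause.accidental, DeathClass.NTR)
        r = assign_tte(curve, design, death)
        assert r.status is TTEStatus.excluded_ntr
        assert r.tte_days is None

    def test_endpoint_reached_is_interpolated_even_with_tr_death(self, design):
        pts = [(d, 50.0 * 2 ** (d / 7)) for d in [7, 14, 21, 29]]
        death = DeathRecord("a1", 29, DeathCause.treatment_evidence, DeathClass.TR)
        r = assign_tte(_curve(pts), design, death)
        assert r.status is TTEStatus.interpolated
        assert r.tte_days == pytest.approx(28.0, abs=1e-9)

    def test_nonpositive_slope_falls_back_to_exceedance_day(self, design):
        # shrink-then-jump: regression slope over the window is negative
        curve = _curve([(1, 790.0), (4, 200.0), (8, 100.0), (11, 810.0)])
        r = assign_tte(curve, design)
        assert r.status is TTEStatus.interpolated
        assert r.tte_days == 11.0
        assert "nonpositive_slope_fallback" in r.flags

    def test_short_window_is_flagged(self, design):
        curve = _curve([(1, 400.0), (4, 900.0)])
        r = assign_tte(curve, design)
        assert r.status is TTEStatus.interpolated
        assert "short_window" in r.flags

    def test_statuses_are_mutually_exclusive_and_total(self, design):
        cases = [
            (_curve([(1, 100.0), (4, 900.0)]), None),
            (_curve([(1, 100.0), (4, 200.0)]), None),
            (_curve([(1, 100.0)]), DeathRecord("a1", 5, DeathCause.unknown, DeathClass.TR)),
            (_curve([(1, 100.0)]), DeathRecord("a1", 5, DeathCause.accidental, DeathClass.NTR)),
        ]
        statuses = {assign_tte(c, design, d).status for c, d in cases}
        assert statuses == set(TTEStatus)


class TestGroupMedian:
    def test_odd_and_even_n(self):
        from pdxtrial.endpoint_analysis import TTEResult

        def res(t):
            return TTEResult("x", t, TTEStatus.interpolated)

        assert group_median_tte([res(30), res(32), res(40)]) == 32
        assert group_median_tte([res(30), res(32), res(40), res(74)]) == 36
        assert group_median_tte([res(74)] * 10) == 74

    def test_all_excluded_is_error(self):
        from pdxtrial.endpoint_analysis import TTEResult

        with pytest.raises(PdxTrialError):
            group_median_tte([TTEResult("x", None, TTEStatus.excluded_ntr)])


class TestTGD:
    def test_reported_style_arithmetic(self):
        assert tgd(40.8, 32.7) == pytest.approx(8.1)
        assert tgd(37.0, 37.0) == 0.0
        assert pct_tgd(37.0, 37.0) == 0.0
        assert pct_tgd(74.0, 32.7) == pytest.approx(126.299, abs=1e-3)

    def test_pct_tgd_requires_positive_control(self):
        with pytest.raises(DomainError):
            pct_tgd(10.0, 0.0)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

@given(
    v0=st.floats(20.0, 400.0),
    doubling=st.floats(3.0, 30.0),
    start=st.integers(1, 40),
)
@settings(max_examples=60, deadline=None)
def test_exact_exponential_tte_recovery(v0, doubling, start):
    """Noiseless exponential growth: interpolated TTE equals the analytic crossing."""
    k = math.log10(2) / doubling
    days = [start, start + 3, start + 7, start + 10, start + 14, start + 17, start + 21]
    endpoint = 800.0
    pts = [(d, v0 * 10 ** (k * d)) for d in days]
    curve = _curve(pts)
    if curve.first_exceedance_day(endpoint) is None:
        return
    try:
        window = select_endpoint_window(curve, endpoint)
    except InsufficientDataError:
        return
    if len(window) < 2:
        return
    tte = interpolate_tte(fit_log_linear(window), endpoint)
    analytic = (math.log10(endpoint) - math.log10(v0)) / k
    assert tte == pytest.approx(analytic, abs=1e-6)


@given(scale=st.floats(0.01, 100.0))
@settings(max_examples=40, deadline=None)
def test_tte_invariant_under_volume_rescaling(scale):
    pts = [(3, 120.0), (7, 260.0), (10, 530.0), (14, 950.0)]
    tte = interpolate_tte(fit_log_linear(pts), 800.0)
    scaled = [(d, v * scale) for d, v in pts]
    tte_scaled = interpolate_tte(fit_log_linear(scaled), 800.0 * scale)
    assert tte_scaled == pytest.approx(tte, rel=1e-9)


@given(shift=st.integers(1, 50))
@settings(max_examples=40, deadline=None)
def test_tte_shifts_with_measurement_days(shift):
    pts = [(3, 120.0), (7, 260.0), (10, 530.0), (14, 950.0)]
    tte = interpolate_tte(fit_log_linear(pts), 800.0)
    shifted = [(d + shift, v) for d, v in pts]
    tte_shifted = interpolate_tte(fit_log_linear(shifted), 800.0)
    assert tte_shifted == pytest.approx(tte + shift, rel=1e-9)
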