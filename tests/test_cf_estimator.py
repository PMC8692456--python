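"""The cumulative conversion-factor estimator and its hierarchical means."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leucarb.cf_estimator import (
    CumulativeSeries,
    CurveFit,
    IncubationTimeCourse,
    accumulate_curve,
    aggregate_depth,
    aggregate_sample,
    estimate_curve,
    fit_curve,
    round_half_away,
)
from leucarb.synthetic_data import IncubationSimParams, simulate_incubation


def tc(times, biomass, lir, **kw):
    defaults = dict(station="T", depth=100.0, curve_id="c1")
    defaults.update(kw)
    return IncubationTimeCourse(times=tuple(times), biomass=tuple(biomass),
                                lir=tuple(lir), **defaults)


class TestAccumulateCurve:
    def test_monotone_biomass_retains_all(self):
        series = accumulate_curve(tc([0, 1, 2, 3], [1, 2, 3, 4], [5, 5, 5, 5]))
        assert series.retained == (0, 1, 2, 3)
        assert series.excluded == ()

    def test_decline_excluded_running_reference(self):
        series = accumulate_curve(tc([0, 1, 2, 3], [10, 20, 15, 30], [5, 5, 5, 5]))
        assert series.retained == (0, 1, 3)
        assert [i for i, _ in series.excluded] == [2]

    def test_constant_lir_closed_form(self):
        # constant L over T days: cumulative = L * 24 * T / 1000 nmol/L
        L, T = 5.0, 3.0
        series = accumulate_curve(tc([0, 1, 2, 3], [1, 2, 3, 4], [L] * 4))
        assert series.cumulative_leucine[-1] == pytest.approx(L * 24 * T / 1000)

    def test_integration_continues_across_exclusions(self):
        full = accumulate_curve(tc([0, 1, 2, 3], [1, 2, 3, 4], [5, 5, 5, 5]))
        holed = accumulate_curve(tc([0, 1, 2, 3], [10, 20, 15, 30], [5, 5, 5, 5]))
        # last retained point carries the full integral up to day 3
        assert holed.cumulative_leucine[-1] == pytest.approx(
            full.cumulative_leucine[-1]
        )

    def test_unusable_when_fewer_than_three_retained(self):
        series = accumulate_curve(tc([0, 1, 2, 3], [10, 5, 4, 3], [5, 5, 5, 5]))
        assert not series.usable
        with pytest.raises(ValueError, match="retained"):
            fit_curve(series)


class TestFitCurve:
    def test_perfect_line(self):
        x = (0.0, 1.0, 2.0, 3.0)
        y = tuple(2.0 * xi + 5.0 for xi in x)
        series = CumulativeSeries(retained=(0, 1, 2, 3), cumulative_leucine=x,
                                  biomass=y, excluded=(), usable=True)
        fit = fit_curve(series)
        assert fit.ecf == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(5.0, rel=1e-12)
        assert fit.se == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value < 1e-10

    def test_four_point_hand_ols(self):
        # hand OLS: Sxy = 5.05, Sxx = 5 -> slope 1.01
        series = CumulativeSeries(retained=(0, 1, 2, 3),
                                  cumulative_leucine=(0.0, 1.0, 2.0, 3.0),
                                  biomass=(0.0, 1.1, 1.9, 3.1),
                                  excluded=(), usable=True)
        fit = fit_curve(series)
        assert fit.ecf == pytest.approx(1.01, rel=1e-12)
        assert fit.p_value < 0.01

    def test_constant_biomass_no_relationship(self):
        series = CumulativeSeries(retained=(0, 1, 2), cumulative_leucine=(0.0, 1.0, 2.0),
                                  biomass=(3.0, 3.0, 3.0), excluded=(), usable=True)
        fit = fit_curve(series)
        assert fit.ecf == 0.0
        assert fit.p_value == 1.0

    def test_zero_x_variance_rejected(self):
        series = CumulativeSeries(retained=(0, 1, 2), cumulative_leucine=(1.0, 1.0, 1.0),
                                  biomass=(1.0, 2.0, 3.0), excluded=(), usable=True)
        with pytest.raises(ValueError, match="variance"):
            fit_curve(series)


class TestEndToEndOracle:
    @given(
        st.floats(min_value=0.1, max_value=4.0),
        st.sampled_from([(), (3.0,), (2.0, 4.0), (3.0, 6.0)]),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_noise_free_recovery_any_cf_and_crash(self, true_cf, crashes):
        params = IncubationSimParams(true_cf=true_cf, crash_times=crashes,
                                     crash_fraction=0.6)
        fit = estimate_curve(simulate_incubation(params))
        assert fit.ecf == pytest.approx(true_cf, rel=1e-9)

    def test_units_identity_slope_scale(self):
        # doubling biomass units doubles the slope: ug/nmol == kg/mol exactly
        base = simulate_incubation(IncubationSimParams(true_cf=1.0))
        scaled = IncubationTimeCourse(
            station=base.station, depth=base.depth, curve_id=base.curve_id,
            times=base.times, biomass=tuple(2 * b for b in base.biomass),
            lir=base.lir,
        )
        assert estimate_curve(scaled).ecf == pytest.approx(2.0, rel=1e-9)


def fit(ecf, p):
    return CurveFit(ecf=ecf, se=0.1, p_value=p, n_points=4, intercept=0.0)


class TestAggregation:
    def test_sample_mean_filters_non_significant(self):
        fits = [fit(0.78, 0.0340), fit(2.40, 0.0020), fit(0.87, 0.2705)]
        agg = aggregate_sample(fits, alpha=0.1)
        assert agg.n == 2
        assert agg.mean_ecf == pytest.approx(1.59)

    def test_sample_mean_three_significant(self):
        fits = [fit(1.58, 0.0473), fit(0.96, 0.0033), fit(1.03, 0.0020)]
        agg = aggregate_sample(fits, alpha=0.1)
        assert agg.n == 3
        assert round_half_away(agg.mean_ecf) == pytest.approx(1.19)

    def test_single_significant_curve_flagged(self):
        agg = aggregate_sample([fit(2.12, 0.0378), fit(1.0, 0.5)], alpha=0.1)
        assert agg.mean_ecf == pytest.approx(2.12)
        assert agg.sem == 0.0 and agg.single

    def test_no_significant_curves_yields_no_estimate(self):
        agg = aggregate_sample([fit(1.0, 0.5), fit(2.0, 0.9)], alpha=0.1)
        assert not agg.has_estimate
        assert agg.mean_ecf is None and agg.n == 0

    def test_permutation_invariance_and_alpha_monotonicity(self):
        fits = [fit(1.0, 0.01), fit(2.0, 0.05), fit(3.0, 0.2)]
        a = aggregate_sample(fits, alpha=0.1)
        b = aggregate_sample(fits[::-1], alpha=0.1)
        assert a.mean_ecf == pytest.approx(b.mean_ecf)
        for lo, hi in [(0.02, 0.1), (0.1, 0.5)]:
            assert (aggregate_sample(fits, alpha=lo).n
                    <= aggregate_sample(fits, alpha=hi).n)

    def test_depth_mean_of_sample_means(self):
        s1 = aggregate_sample([fit(1.58, 0.04), fit(0.96, 0.003), fit(1.03, 0.002)])
        s2 = aggregate_sample([fit(0.78, 0.03), fit(2.40, 0.002), fit(0.87, 0.27)])
        dep = aggregate_depth([s1, s2])
        assert round_half_away(dep.mean_ecf) == pytest.approx(1.39)
        assert dep.n == 2

    def test_depth_single_sample_passthrough(self):
        s = aggregate_sample([fit(0.11, 0.0483), fit(0.09, 0.0075)])
        dep = aggregate_depth([s])
        assert dep.mean_ecf == pytest.approx(s.mean_ecf)

    def test_depth_identical_samples_zero_sem(self):
        s = aggregate_sample([fit(1.0, 0.01), fit(1.0, 0.02)])
        dep = aggregate_depth([s, s, s])
        assert dep.mean_ecf == pytest.approx(1.0)
        assert dep.sem == pytest.approx(0.0)

    def test_depth_rejects_empty(self):
        empty = aggregate_sample([fit(1.0, 0.9)])
        with pytest.raises(ValueError):
            aggregate_depth([empty])


@pytest.mark.parametrize("x,expected", [(1.385, 1.39), (0.105, 0.11), (-1.385, -1.39), (1.384, 1.38)])
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected


def test_time_course_validation():
    with pytest.raises(ValueError):
        tc([0, 1, 2], [1, 2, 3], [1, 1, 1])  # too few points
    with pytest.raises(ValueError):
        tc([0, 1, 1, 2], [1, 2, 3, 4], [1, 1, 1, 1])  # non-increasing times
    with pytest.raises(ValueError):
        tc([0, 1, 2, 3], [1, -2, 3, 4], [1, 1, 1, 1])  # negative biomass
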