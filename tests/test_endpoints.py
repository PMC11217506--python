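"""Survival endpoints, KM/logrank, nadir criterion, AUC with carry-forward.

The logrank implementation (lifelines) is cross-checked against a direct
evaluation of the Mantel-Cox formula written here as an oracle.
"""

import math

import numpy as np
import pytest

from preclin.io import SurvivalRecord, ValidationError
from preclin.endpoints import (
    auc_lvcf,
    cumulative_volume,
    km_estimate,
    logrank,
    nadir_response,
    time_to_threshold,
)
from preclin.simulate import CohortSpec, simulate_growth_curve

from conftest import make_curve


def rec(t, e, group="g", mouse="m"):
    return SurvivalRecord(mouse, group, t, e, 1000.0)


# --- direct Mantel-Cox formula oracle -------------------------------------

def logrank_oracle(times_a, events_a, times_b, events_b):
    """Chi-square from observed-vs-expected events over shared risk sets."""
    all_events = sorted(
        {t for t, e in zip(times_a, events_a) if e}
        | {t for t, e in zip(times_b, events_b) if e}
    )
    obs_a = exp_a = var = 0.0
    for t in all_events:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        n = n_a + n_b
        d_a = sum(1 for x, e in zip(times_a, events_a) if e and x == t)
        d_b = sum(1 for x, e in zip(times_b, events_b) if e and x == t)
        d = d_a + d_b
        if n == 0 or n_a == 0 and n_b == 0:
            continue
        obs_a += d_a
        exp_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return (obs_a - exp_a) ** 2 / var


class TestCumulativeVolume:
    def test_pointwise_sum_on_shared_days(self):
        p = make_curve([0, 5], [100, 600])
        s = make_curve([0, 5], [50, 500], tumor_site="secondary")
        c = cumulative_volume(p, s)
        assert list(c.days) == [0, 5]
        assert c.volumes == pytest.approx([150, 1100])

    def test_missing_secondary_is_identity(self):
        p = make_curve([0, 5], [100, 600])
        c = cumulative_volume(p, None)
        assert np.array_equal(c.volumes, p.volumes)

    def test_carry_forward_on_mismatched_days(self):
        p = make_curve([0, 5], [100, 600])
        s = make_curve([0, 8], [50, 700], tumor_site="secondary")
        c = cumulative_volume(p, s)
        assert c.volume_at(8) == pytest.approx(600 + 700)  # primary carried forward

    def test_days_before_first_measurement_contribute_zero(self):
        p = make_curve([0, 5], [100, 600])
        s = make_curve([5, 8], [50, 700], tumor_site="secondary", v_start=None)
        c = cumulative_volume(p, s)
        assert c.volume_at(0) == pytest.approx(100.0)

    def test_mismatched_mouse_ids_rejected(self):
        p = make_curve([0], [100], mouse_id="m1")
        s = make_curve([0], [50], mouse_id="m2", tumor_site="secondary")
        with pytest.raises(ValidationError):
            cumulative_volume(p, s)


class TestTimeToThreshold:
    def test_event_at_first_crossing_day(self):
        c = make_curve([0, 7, 10], [80, 400, 1200])
        r = time_to_threshold(c, 1000)
        assert r.event and r.time_days == 10

    def test_censored_at_last_observed_day(self):
        c = make_curve([0, 20, 50], [80, 200, 600])
        r = time_to_threshold(c, 1000)
        assert not r.event and r.time_days == 50

    def test_degenerate_crossing_at_first_post_ir_day(self):
        c = make_curve([0], [1200], v_start=1200.0)
        r = time_to_threshold(c, 1000)
        assert r.event and r.time_days == 0

    def test_threshold_monotonicity(self, rng):
        for _ in range(50):
            days = np.arange(0, 30, 3)
            vols = np.cumprod(rng.uniform(0.9, 1.6, size=days.size)) * 100
            c = make_curve(days, vols)
            lo = time_to_threshold(c, 500)
            hi = time_to_threshold(c, 1000)
            assert hi.time_days >= lo.time_days
            if hi.event:
                assert lo.event

    def test_closed_form_on_noise_free_exponential(self):
        g, v0, threshold = 0.2, 80.0, 1000.0
        spec = CohortSpec(
            n_mice=1, noise_cv=0.0, growth_rate=g, v0_mm3=v0,
            schedule_days=tuple(range(0, 61)), followup_end=60,
        )
        c = simulate_growth_curve("non_responder", spec, np.random.default_rng(0))
        r = time_to_threshold(c, threshold)
        assert r.event
        assert r.time_days == math.ceil(math.log(threshold / v0) / g)


class TestKaplanMeier:
    def test_hand_product_limit_no_censoring(self):
        km = km_estimate([rec(10, True), rec(20, True), rec(30, True)])
        # S drops to 2/3 at 10, 1/3 at 20, 0 at 30; median = 20
        assert km.median == 20
        surv = dict(zip(km.times, km.survival))
        assert surv[10.0] == pytest.approx(2 / 3)
        assert surv[20.0] == pytest.approx(1 / 3)
        assert surv[30.0] == pytest.approx(0.0)

    def test_all_censored_median_not_reached(self):
        km = km_estimate([rec(10, False), rec(20, False)])
        assert not km.median_reached
        assert np.all(km.survival == 1.0)

    def test_single_event_steps_to_zero(self):
        km = km_estimate([rec(15, True)])
        assert km.survival[-1] == 0.0
        assert km.median == 15

    def test_equals_empirical_survivor_without_censoring(self, rng):
        times = rng.integers(1, 40, size=25)
        km = km_estimate([rec(int(t), True, mouse=f"m{i}") for i, t in enumerate(times)])
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((times > t).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([])


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        a = [rec(t, True) for t in (5, 10, 15)]
        b = [rec(t, True) for t in (5, 10, 15)]
        stat, p = logrank(a, b)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        a = [rec(t, True) for t in (1, 2, 3)]
        b = [rec(t, True) for t in (31, 32, 33)]
        stat, p = logrank(a, b)
        assert p < 0.05
        oracle = logrank_oracle([1, 2, 3], [1] * 3, [31, 32, 33], [1] * 3)
        assert stat == pytest.approx(oracle, rel=1e-6)

    def test_agrees_with_direct_formula_on_random_instances(self, rng):
        for _ in range(25):
            na, nb = rng.integers(3, 12, size=2)
            ta = rng.integers(1, 30, size=na)
            tb = rng.integers(1, 30, size=nb)
            ea = rng.random(na) < 0.7
            eb = rng.random(nb) < 0.7
            if not (ea.any() or eb.any()):
                continue
            a = [rec(int(t), bool(e), mouse=f"a{i}") for i, (t, e) in enumerate(zip(ta, ea))]
            b = [rec(int(t), bool(e), mouse=f"b{i}") for i, (t, e) in enumerate(zip(tb, eb))]
            stat, _ = logrank(a, b)
            oracle = logrank_oracle(ta.tolist(), ea.tolist(), tb.tolist(), eb.tolist())
            assert stat == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_symmetric_under_group_swap(self, rng):
        a = [rec(int(t), True, mouse=f"a{i}") for i, t in enumerate(rng.integers(1, 20, 8))]
        b = [rec(int(t), True, mouse=f"b{i}") for i, t in enumerate(rng.integers(1, 20, 8))]
        assert logrank(a, b)[0] == pytest.approx(logrank(b, a)[0])

    def test_no_events_warns_and_returns_null(self):
        a, b = [rec(10, False)], [rec(12, False)]
        with pytest.warns(UserWarning):
            stat, p = logrank(a, b)
        assert (stat, p) == (0.0, 1.0)


class TestNadirResponse:
    def test_stated_rule(self):
        c = make_curve([0, 3, 7, 10], [100, 120, 50, 80])
        r = nadir_response(c)
        assert r.v_max == 120 and r.nadir == 50
        assert r.ratio == pytest.approx(50 / 120)
        assert r.responder

    def test_monotone_growth_is_non_responder(self):
        c = make_curve([0, 5, 10], [100, 150, 300])
        r = nadir_response(c)
        assert r.nadir == r.v_max == 100
        assert not r.responder

    def test_exact_half_is_responder(self):
        c = make_curve([0, 7], [100, 50])
        assert nadir_response(c).responder  # "50% or more decrease" is inclusive

    def test_fewer_than_two_points_unevaluable(self):
        assert nadir_response(make_curve([0], [100])) is None


class TestAUC:
    def test_constant_curve_is_rectangle(self):
        c = make_curve([0, 2, 5, 10], [100, 100, 100, 100])
        r = auc_lvcf(c, 10)
        assert r.auc == pytest.approx(1000.0)
        assert not r.extended

    def test_early_exit_extends_horizontally(self):
        c = make_curve([0, 5], [1, 100], v_start=1.0)
        r = auc_lvcf(c, 10)
        # trapezoid ~252.5 over [0,5], rectangle 500 over [5,10]
        assert r.auc == pytest.approx(np.trapezoid([1, 100], [0, 5]) + 500.0)
        assert r.extended

    def test_linear_growth_is_triangle_area(self):
        c = make_curve([0, 5, 10], [1, 50.5, 100], v_start=1.0)
        assert auc_lvcf(c, 10).auc == pytest.approx(np.trapezoid([1, 50.5, 100], [0, 5, 10]))

    def test_equals_plain_trapezoid_without_dropout(self, rng):
        days = np.arange(0, 31, 3)
        vols = rng.uniform(50, 900, size=days.size)
        c = make_curve(days, vols)
        assert auc_lvcf(c, 30).auc == pytest.approx(np.trapezoid(vols, days))

    def test_curve_beyond_study_end_clipped(self):
        c = make_curve([0, 10, 20], [100, 100, 300])
        r = auc_lvcf(c, 15)
        # value at day 15 interpolates to 200
        assert r.auc == pytest.approx(100 * 10 + (100 + 200) / 2 * 5)
        assert not r.extended

    def test_no_post_ir_measurements_rejected(self):
        c = make_curve([-3, -1], [50, 60], v_start=None)
        with pytest.raises(ValidationError):
            auc_lvcf(c, 10)
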