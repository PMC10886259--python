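"""Y90 fractionation, dosimetry, ICI pharmacodynamics and arm plans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y90ici import (
    ModelParameters,
    TreatmentPlan,
    build_arm_plan,
    dose_from_activity,
    ici_course,
    ici_multiplier,
    y90_schedule,
)
from y90ici.treatment import y90_decay_weights


class TestY90Schedule:
    @given(
        total=st.floats(0.0, 600.0),
        q=st.floats(0.0, 1.0),
        n_fractions=st.integers(1, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_physical_doses_sum_to_prescription(self, total, q, n_fractions):
        p = ModelParameters()
        events = y90_schedule(total, 0.0, q, p, n_fractions)
        assert sum(e.d_physical for e in events) == pytest.approx(total, rel=1e-9, abs=1e-9)
        assert sum(e.d_tumor for e in events) == pytest.approx(q * total, rel=1e-9, abs=1e-9)

    def test_first_day_fraction(self):
        """Day 1 carries 1-e^(-ln2/2.6) ~ 23.4% of the decay; at 400 Gy
        and q=0.12 the first effective tumor dose is ~11.2 Gy."""
        p = ModelParameters()
        events = y90_schedule(400.0, 0.0, 0.12, p)
        day1_frac = 1 - math.exp(-math.log(2) / 2.6)
        assert day1_frac == pytest.approx(0.2341, abs=2e-4)
        # renormalization over 26 fractions is a <0.1% correction
        assert events[0].d_physical == pytest.approx(400 * day1_frac, rel=1.2e-3)
        assert events[0].d_tumor == pytest.approx(11.24, abs=0.01)

    def test_26_fractions_capture_decay(self):
        lam = math.log(2) / 2.6
        assert 1 - math.exp(-lam * 26) == pytest.approx(0.999, abs=1e-3)
        w = y90_decay_weights(26, 2.6)
        assert w.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.diff(w) < 0)  # strictly decaying fractions

    def test_placebo_and_domain_errors(self):
        p = ModelParameters()
        events = y90_schedule(300.0, 0.0, 0.0, p)
        assert all(e.d_tumor == 0.0 for e in events)
        with pytest.raises(ValueError):
            y90_schedule(300.0, 0.0, 1.5, p)
        with pytest.raises(ValueError):
            y90_schedule(-1.0, 0.0, 0.1, p)


class TestDosimetry:
    def test_unit_activity_dose(self):
        """1 GBq decaying fully in 1 kg deposits ~48.1 Gy."""
        p = ModelParameters()
        assert dose_from_activity(0.0, 1.0, p) == 0.0
        assert dose_from_activity(1.0, 1.0, p) == pytest.approx(48.1, abs=0.1)

    def test_linearity_and_errors(self):
        p = ModelParameters()
        assert dose_from_activity(2.0, 1.0, p) == pytest.approx(
            2 * dose_from_activity(1.0, 1.0, p)
        )
        with pytest.raises(ValueError):
            dose_from_activity(1.0, 0.0, p)


class TestICIMultiplier:
    def test_reference_values(self, params):
        """delta=0.12, Cmax=10: multiplier 2.2 at dosing, 1.6 one
        half-life (21 d) later."""
        assert ici_multiplier(0.0, [0.0], 0.12, params) == pytest.approx(2.2)
        assert ici_multiplier(21.0, [0.0], 0.12, params) == pytest.approx(1.6)

    def test_no_drug_and_before_first_dose(self, params):
        assert ici_multiplier(5.0, [], 0.12, params) == 1.0
        assert ici_multiplier(5.0, [10.0], 0.12, params) == 1.0
        assert ici_multiplier(100.0, [0.0], 0.0, params) == 1.0

    def test_resets_at_each_administration(self, params):
        doses = [0.0, 14.0]
        just_before = ici_multiplier(13.999, doses, 0.12, params)
        at_dose = ici_multiplier(14.0, doses, 0.12, params)
        assert at_dose == pytest.approx(2.2)
        assert just_before < at_dose  # right-continuous jump upward

    def test_nonincreasing_between_doses_and_bounded_below(self, params):
        t = np.linspace(0.0, 13.99, 200)
        m = ici_multiplier(t, [0.0], 0.12, params)
        assert np.all(np.diff(m) < 0)
        assert np.all(m >= 1.0)


class TestArmPlans:
    def test_ici_course_length(self):
        """Every 14 days for 2 years: 53 administrations."""
        course = ici_course(0.0)
        assert len(course) == 53
        assert course[0] == 0.0 and course[-1] == 728.0

    def test_arm_timing(self, params):
        a = build_arm_plan("A", 400.0, 0.12, 60.0, 0.12, params, horizon=3650.0)
        b = build_arm_plan("B", 400.0, 0.12, 60.0, 0.12, params, horizon=3650.0)
        c = build_arm_plan("C", 400.0, 0.12, 60.0, 0.12, params, horizon=3650.0)
        assert a.radiation_events[0].time == 0.0 and a.ici_dose_times[0] == 0.0
        assert b.radiation_events[0].time == 0.0 and b.ici_dose_times[0] == 60.0
        assert c.ici_dose_times[0] == 0.0 and c.radiation_events[0].time == 60.0

    def test_monotherapies(self, params):
        y90 = build_arm_plan("Y90_mono", 400.0, 0.12, 0.0, 0.12, params, horizon=3650.0)
        ici = build_arm_plan("ICI_mono", 400.0, 0.12, 0.0, 0.12, params, horizon=3650.0)
        assert y90.ici_dose_times == ()
        assert len(y90.radiation_events) == 26
        assert ici.radiation_events == ()
        assert len(ici.ici_dose_times) == 53

    def test_zero_interval_collapses_sequential_arms_onto_concurrent(self, params):
        a = build_arm_plan("A", 400.0, 0.12, 0.0, 0.12, params, horizon=3650.0)
        for arm in ("B", "C"):
            other = build_arm_plan(arm, 400.0, 0.12, 0.0, 0.12, params, horizon=3650.0)
            assert other.radiation_events == a.radiation_events
            assert other.ici_dose_times == a.ici_dose_times

    def test_unknown_arm_rejected(self, params):
        with pytest.raises(ValueError, match="unknown arm"):
            build_arm_plan("D", 400.0, 0.12, 0.0, 0.12, params, horizon=100.0)

    def test_plan_json_roundtrip(self, params, tmp_path):
        plan = build_arm_plan("B", 350.0, 0.1, 45.0, 0.2, params, horizon=3000.0)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        assert TreatmentPlan.from_json(path) == plan
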