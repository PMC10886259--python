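"""Continuous dynamics, radiation events and the event-driven integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y90ici import (
    IntegrationError,
    ModelParameters,
    SystemState,
    apply_radiation_event,
    build_arm_plan,
    derivatives,
    simulate,
    simulate_cohort,
)
from y90ici.treatment import RadiationEvent, TreatmentPlan

NO_IMMUNE = ModelParameters(omega1=1e-300, omega2=1e-300, omega3=1e-300)


class TestDerivatives:
    def test_tumor_free_steady_state_is_stationary(self, params):
        """With no tumor and L = s/f every derivative vanishes."""
        L_star = params.s / params.f
        d = derivatives(SystemState(TI=0, TNI=0, I=0, L=L_star), params)
        assert np.allclose(d, 0.0, atol=1e-6)
        assert L_star == pytest.approx(4.4545e9, rel=1e-4)

    def test_no_lymphocytes_gives_pure_exponential_growth(self, params):
        state = SystemState(TI=1e10, TNI=0, I=0, L=0)
        d = derivatives(state, params)
        assert d[0] == pytest.approx(params.a * 1e10)
        assert d[1] == 0.0 and d[2] == 0.0
        assert d[3] == pytest.approx(params.s)

    def test_ici_multiplier_strengthens_kill(self, params):
        state = SystemState(TI=1e11, TNI=1e8, I=0, L=5e9)
        d1 = derivatives(state, params, 1.0)
        d2 = derivatives(state, params, 2.2)
        assert d2[0] < d1[0]  # stronger immune kill of targeted cells
        assert d2[1] < d1[1]

    def test_negative_state_rejected(self, params):
        with pytest.raises(ValueError):
            SystemState(TI=-1, TNI=0, I=0, L=0)
        state = SystemState(TI=1e10, TNI=0, I=0, L=1e9)
        with pytest.raises(ValueError, match="ici_multiplier"):
            derivatives(state, params, 0.5)


class TestRadiationEvent:
    def test_zero_dose_is_identity(self, params):
        state = SystemState(TI=1e10, TNI=1e7, I=1e5, L=5e9, t=3.0)
        out = apply_radiation_event(state, 0.0, 0.0, params)
        assert out == state

    def test_lq_survival_values(self, params):
        """2 Gy at alpha=0.148, alpha/beta=10: SF = exp(-0.148*2-0.0148*4)."""
        state = SystemState(TI=1e10, TNI=0, I=0, L=1e9)
        out = apply_radiation_event(state, 2.0, 1.0, params)
        sf = math.exp(-0.148 * 2 - 0.0148 * 4)
        assert sf == pytest.approx(0.7010, abs=2e-4)
        assert out.TI == pytest.approx(1e10 * sf)
        assert out.I == pytest.approx(1e10 * (1 - sf))
        assert out.L == pytest.approx(1e9 * math.exp(-0.737), rel=1e-9)
        assert math.exp(-0.737) == pytest.approx(0.4786, abs=2e-4)
        assert out.TNI == state.TNI  # non-targeted cells are never irradiated

    @given(
        d_tumor=st.floats(0, 60),
        d_lymph=st.floats(0, 20),
        ti=st.floats(1.0, 1e12),
        i0=st.floats(0.0, 1e12),
    )
    @settings(max_examples=100, deadline=None)
    def test_cell_conservation_at_event(self, d_tumor, d_lymph, ti, i0):
        """Radiation moves targeted cells to the inactivated pool exactly."""
        p = ModelParameters()
        state = SystemState(TI=ti, TNI=5e7, I=i0, L=1e9)
        out = apply_radiation_event(state, d_tumor, d_lymph, p)
        # exact up to round-off, whose scale is set by the larger pool
        tol = 1e-12 * (state.TI + state.I)
        assert out.TI + (out.I - state.I) == pytest.approx(state.TI, abs=tol, rel=1e-12)

    def test_kill_monotone_in_dose(self, params):
        state = SystemState(TI=1e10, TNI=0, I=0, L=1e9)
        doses = [0.5, 1.0, 2.0, 5.0, 10.0]
        outs = [apply_radiation_event(state, d, 0.0, params) for d in doses]
        ti = [o.TI for o in outs]
        inact = [o.I for o in outs]
        assert all(a > b for a, b in zip(ti, ti[1:]))
        assert all(a < b for a, b in zip(inact, inact[1:]))

    def test_negative_dose_rejected(self, params):
        state = SystemState(TI=1e10, TNI=0, I=0, L=1e9)
        with pytest.raises(ValueError):
            apply_radiation_event(state, -1.0, 0.0, params)


def _no_treatment_plan(horizon: float) -> TreatmentPlan:
    return TreatmentPlan(
        radiation_events=(), ici_dose_times=(), delta_durva=0.0,
        horizon=horizon, arm_label="Y90_mono",
    )


class TestIntegrator:
    def test_matches_exponential_closed_form(self):
        """Without immune interaction the tumor compartments are exact
        exponentials and L relaxes to s/f."""
        p = NO_IMMUNE
        init = np.array([[1e10], [1e7], [1e4], [1e9]])
        res = simulate_cohort(init, _no_treatment_plan(200.0), p, dt=0.25, record=True)
        t = res.times
        np.testing.assert_allclose(res.states[0, :, 0], 1e10 * np.exp(p.a * t), rtol=1e-6)
        np.testing.assert_allclose(res.states[1, :, 0], 1e7 * np.exp(p.a * t), rtol=1e-6)
        np.testing.assert_allclose(res.states[2, :, 0], 1e4 * np.exp(-p.r * t), rtol=1e-6)
        # dL/dt = s - f L  ->  L(t) = s/f + (L0 - s/f) e^(-f t)
        L_star = p.s / p.f
        np.testing.assert_allclose(
            res.states[3, :, 0], L_star + (1e9 - L_star) * np.exp(-p.f * t), rtol=1e-6
        )

    def test_doubling_time(self):
        """a = 0.01/d gives a doubling time of ln2/0.01 ~ 69.3 days."""
        res = simulate_cohort(
            np.array([[1e10], [0], [0], [0]]), _no_treatment_plan(69.25),
            NO_IMMUNE, dt=0.25, record=True,
        )
        t_double = np.interp(2e10, res.states[0, :, 0], res.times)
        assert t_double == pytest.approx(math.log(2) / 0.01, rel=1e-3)

    def test_zero_dose_event_is_no_op(self, params):
        init = np.array([[1e11], [1e8], [0], [5e9]])
        plan0 = _no_treatment_plan(100.0)
        plan1 = TreatmentPlan(
            radiation_events=(RadiationEvent(time=10.0, d_tumor=0.0, d_lymph=0.0),),
            ici_dose_times=(), delta_durva=0.0, horizon=100.0, arm_label="Y90_mono",
        )
        r0 = simulate_cohort(init, plan0, params, dt=0.25, record=True)
        r1 = simulate_cohort(init, plan1, params, dt=0.25, record=True)
        np.testing.assert_array_equal(r0.states, r1.states)

    def test_single_event_kill_decouples_from_growth(self):
        """With immune terms off and negligible growth, a 10 Gy event
        leaves TI(30)/T0 at the LQ surviving fraction."""
        p = ModelParameters(
            a=1e-12, omega1=1e-300, omega2=1e-300, omega3=1e-300
        )
        plan = TreatmentPlan(
            radiation_events=(RadiationEvent(time=0.0, d_tumor=10.0, d_lymph=0.0),),
            ici_dose_times=(), delta_durva=0.0, horizon=30.0, arm_label="Y90_mono",
        )
        init = np.array([[1e11], [0], [0], [1e9]])
        res = simulate_cohort(init, plan, p, dt=0.25, record=True)
        expected = math.exp(-0.148 * 10 - 0.0148 * 100)
        assert res.states[0, -1, 0] / 1e11 == pytest.approx(expected, rel=1e-9)

    def test_grid_refinement_stability(self, params):
        """Halving the step changes TI at 5 years by < 0.5%."""
        plan = build_arm_plan("A", 400.0, 0.12, 0.0, 0.12, params, horizon=1825.0)
        init = np.array([[1.07e11], [1.07e8], [0.0], [5.61e9]])
        fine = {}
        for dt in (0.25, 0.125):
            res = simulate_cohort(init, plan, params, dt=dt, horizon=1825.0)
            fine[dt] = res.final_state[0, 0]
        assert abs(fine[0.25] / fine[0.125] - 1) < 0.005

    def test_nonfinite_state_raises_naming_time(self, params):
        p = params.with_(a=15.0)  # unphysical growth -> overflow
        init = np.array([[1e300], [0], [0], [0]])
        with pytest.raises(IntegrationError, match="day"):
            simulate_cohort(init, _no_treatment_plan(200.0), p, dt=0.25)

    def test_event_off_grid_rejected(self, params):
        plan = TreatmentPlan(
            radiation_events=(RadiationEvent(time=0.1, d_tumor=1.0, d_lymph=0.0),),
            ici_dose_times=(), delta_durva=0.0, horizon=10.0, arm_label="Y90_mono",
        )
        with pytest.raises(ValueError, match="not a multiple"):
            simulate_cohort(np.array([[1e10], [0], [0], [0]]), plan, params, dt=0.25)

    def test_states_stay_nonnegative(self, params, small_cohort):
        from conftest import init_from_arrays

        plan = build_arm_plan("A", 500.0, 0.16, 0.0, 1.0, params, horizon=365.0)
        res = simulate_cohort(
            init_from_arrays(small_cohort), plan, params,
            q=small_cohort["q"], alpha_T=small_cohort["alpha_T"],
            delta_durva=0.16, dt=0.25, record=True,
        )
        assert np.all(res.states >= 0.0)
        assert np.all(np.isfinite(res.states))


class TestSinglePatientAPI:
    def test_trajectory_shape_and_monotone_times(self, params):
        state = SystemState(TI=1.07e11, TNI=1.07e8, I=0, L=5.61e9)
        plan = build_arm_plan("Y90_mono", 400.0, 0.0, 0.0, 0.12, params, horizon=100.0)
        traj = simulate(state, plan, params)
        assert len(traj.times) == len(traj.TI) == 101  # daily samples
        assert np.all(np.diff(traj.times) > 0)
        assert traj.TI[30] < traj.TI[0]  # ablation took effect

    def test_trajectory_csv_roundtrip(self, params, tmp_path):
        import pandas as pd

        state = SystemState(TI=1e11, TNI=1e8, I=0, L=5e9)
        plan = _no_treatment_plan(10.0)
        traj = simulate(state, plan, params)
        path = tmp_path / "traj.csv"
        traj.to_csv(path, patient_id=7, arm="A")
        df = pd.read_csv(path)
        assert list(df.columns) == ["time_d", "TI", "TNI", "I", "L", "patient_id", "arm"]
        np.testing.assert_allclose(df["TI"].to_numpy(), traj.TI)
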