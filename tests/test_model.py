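"""Circuit-model unit tests: elastance shape, valve law, ODE right-hand
side arithmetic, and the periodic-beat integrator's invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvcal import (
    BeatSeries,
    ModelConstants,
    ModelParameters,
    beat_summary,
    elastance,
    lv_pressure,
    rhs,
    simulate_to_steady_beat,
    valve_flow,
)
from pvcal.model import ContractError


@pytest.fixture
def params():
    return ModelParameters()


class TestElastance:
    def test_diastolic_baseline_and_peak(self, params, constants):
        assert elastance(0.0, params, constants) == pytest.approx(params.e_ed)
        assert elastance(params.t_s, params, constants) == pytest.approx(params.e_es)
        assert elastance(params.t_e, params, constants) == pytest.approx(params.e_ed)

    def test_cosine_ramp_midpoint(self, constants):
        # halfway up the rise the ramp sits at the mean of floor and peak
        p = ModelParameters(e_ed=0.146, e_es=4.85)
        assert elastance(p.t_s / 2, p, constants) == pytest.approx((0.146 + 4.85) / 2)

    @settings(max_examples=50, deadline=None)
    @given(t=st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    def test_periodic(self, t):
        p, c = ModelParameters(), ModelConstants()
        assert elastance(t, p, c) == pytest.approx(
            elastance(t + c.t_cycle, p, c), rel=1e-9, abs=1e-12
        )

    def test_continuous_at_knots(self, params, constants):
        for knot in (params.t_s, params.t_e):
            lo = elastance(knot - 1e-10, params, constants)
            hi = elastance(knot + 1e-10, params, constants)
            assert lo == pytest.approx(hi, abs=1e-6)

    def test_rejects_nonfinite_time(self, params, constants):
        with pytest.raises(ContractError):
            elastance(np.nan, params, constants)

    def test_vectorized(self, params, constants):
        t = np.linspace(0, constants.t_cycle, 20, endpoint=False)
        e = elastance(t, params, constants)
        assert e.shape == t.shape
        assert np.all(e >= params.e_ed - 1e-12)
        assert np.all(e <= params.e_es + 1e-12)


class TestLVPressureAndValves:
    def test_zero_at_dead_volume(self, params, constants):
        for t in (0.0, 0.02, 0.08):
            assert lv_pressure(params.v_lv_d, t, params, constants) == pytest.approx(0.0)

    def test_pressure_arithmetic(self, constants):
        # E = e_es at t = t_s; 4.42 * 20 µL above dead volume = 88.4 mmHg
        p = ModelParameters(e_es=4.42)
        assert lv_pressure(p.v_lv_d + 20.0, p.t_s, p, constants) == pytest.approx(88.4)

    def test_negative_below_dead_volume(self, constants):
        p = ModelParameters(e_es=1.0 + 1e-9, e_ed=1.0)
        assert lv_pressure(p.v_lv_d - 1.0, 0.0, p, constants) == pytest.approx(-1.0)

    def test_valve_forward_flow(self):
        assert valve_flow(10.0, 5.0, 5e-3) == pytest.approx(1000.0)

    @settings(max_examples=50, deadline=None)
    @given(
        up=st.floats(0.1, 200), dn=st.floats(0.1, 200), r=st.floats(1e-4, 1e-1)
    )
    def test_valve_never_negative(self, up, dn, r):
        assert valve_flow(up, dn, r) >= 0.0
        if up <= dn:
            assert valve_flow(up, dn, r) == 0.0

    def test_valve_rejects_nonpositive_resistance(self):
        with pytest.raises(ContractError):
            valve_flow(10.0, 5.0, 0.0)


class TestRHS:
    def test_isovolumic_phase(self, constants):
        # both valves closed: P_la < P_lv < P_ao freezes the volume
        p = ModelParameters()
        v = p.v_lv_d + 50.0 / p.e_ed  # P_lv = 50 at t = 0
        dv, _ = rhs(0.0, np.array([v, 80.0]), p, constants)
        assert dv == 0.0

    def test_volume_identity(self, constants):
        p = ModelParameters()
        for state in ([30.0, 80.0], [45.0, 60.0], [20.0, 95.0]):
            t = 0.03
            dv, _ = rhs(t, np.array(state), p, constants)
            p_lv = lv_pressure(state[0], t, p, constants)
            q_mv = valve_flow(constants.p_la, p_lv, p.r_mv)
            q_av = valve_flow(p_lv, state[1], p.r_av)
            assert dv == pytest.approx(q_mv - q_av)

    def test_hand_arithmetic_oracle(self, constants):
        # Construct E(t_s) = 4 so that P_lv = 4 * (30 - 5) = 100 mmHg;
        # Q_av = (100-80)/1e-3, Q_sys = (80-20)/0.268, dP_ao = (Q_av-Q_sys)/0.968
        p = ModelParameters(e_es=4.0, r_av=1e-3, r_art=0.268, c_ao=0.968, v_lv_d=5.0)
        dv, dp = rhs(p.t_s, np.array([30.0, 80.0]), p, constants)
        q_av = (100.0 - 80.0) / 1e-3
        q_sys = (80.0 - 20.0) / 0.268
        assert q_av == pytest.approx(20000.0)
        assert q_sys == pytest.approx(223.8806, rel=1e-5)
        assert dv == pytest.approx(-q_av)  # mitral closed
        assert dp == pytest.approx((q_av - q_sys) / 0.968, rel=1e-12)


class TestSteadyBeat:
    def test_diode_invariant_and_convergence(self, converged_beat):
        assert converged_beat.converged
        assert converged_beat.n_beats_to_converge <= 50
        assert converged_beat.convergence_metric < 1e-6
        assert converged_beat.q_mv.min() >= 0.0
        assert converged_beat.q_av.min() >= 0.0

    def test_flow_balance_over_beat(self, truth_params, constants):
        # at periodicity the mitral and aortic volume throughputs agree;
        # a fine grid keeps the quadrature error below the 1e-3 criterion
        beat = simulate_to_steady_beat(
            truth_params, constants, sampling_rate=5e4, tol=1e-8
        )
        v_in = np.trapezoid(beat.q_mv, beat.time)
        v_out = np.trapezoid(beat.q_av, beat.time)
        assert abs(v_in - v_out) / v_in < 1e-3

    def test_periodicity_restart(self, truth_params, constants, converged_beat):
        # restarting from the converged state changes the beat by < 10*tol
        with pytest.warns(RuntimeWarning):  # tol set unreachably tight
            restart = simulate_to_steady_beat(
                truth_params,
                constants,
                max_beats=2,
                tol=1e-12,
                initial_state=(converged_beat.v_lv[0], converged_beat.p_ao[0]),
            )
        assert restart.convergence_metric < 10 * 1e-6

    def test_step_halving(self, truth_params, constants):
        coarse = simulate_to_steady_beat(truth_params, constants, dt=4e-5, tol=1e-8)
        fine = simulate_to_steady_beat(truth_params, constants, dt=2e-5, tol=1e-8)
        for attr in ("v_lv", "p_lv", "p_ao"):
            a, b = getattr(coarse, attr), getattr(fine, attr)
            assert np.max(np.abs(a - b)) / np.max(np.abs(b)) < 1e-4

    def test_nonconvergence_warns(self, truth_params, constants):
        with pytest.warns(RuntimeWarning, match="did not reach periodicity"):
            beat = simulate_to_steady_beat(truth_params, constants, max_beats=2)
        assert not beat.converged

    def test_invalid_parameters_rejected(self, constants):
        with pytest.raises(ContractError):
            simulate_to_steady_beat(ModelParameters(e_es=0.1, e_ed=0.2), constants)


class TestBeatSummary:
    def test_matches_linear_scan(self, converged_beat):
        s = beat_summary(converged_beat)
        # independent brute-force scans
        mx = mn = converged_beat.p_lv[0]
        for v in converged_beat.p_lv:
            mx = v if v > mx else mx
            mn = v if v < mn else mn
        assert s["max_p_lv"] == pytest.approx(mx)
        assert s["min_p_lv"] == pytest.approx(mn)
        sv = max(converged_beat.v_lv) - min(converged_beat.v_lv)
        assert s["stroke_volume"] == pytest.approx(sv)

    def test_cardiac_output_arithmetic(self, constants):
        t = np.arange(55) / 500.0
        v = np.where(t < 0.05, 40.0, 15.0)  # stroke volume 25 µL
        flat = np.zeros_like(t)
        beat = BeatSeries(t, flat + 60, flat + 70, v, flat, flat, flat, 1, 0.0)
        s = beat_summary(beat)
        assert s["stroke_volume"] == pytest.approx(25.0)
        assert s["cardiac_output"] == pytest.approx(25.0 / 0.11, rel=1e-6)

    def test_constant_signal_zero_stroke(self):
        t = np.arange(10) / 500.0
        flat = np.full_like(t, 30.0)
        beat = BeatSeries(t, flat, flat, flat, flat, flat, flat, 1, 0.0)
        assert beat_summary(beat)["stroke_volume"] == 0.0
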