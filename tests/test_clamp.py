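import numpy as np
import pytest

import kvsim as kv
from kvsim.clamp import ClampProtocol, SolverOptions, gate_closed_form
from kvsim.clamp import _gates_analytic
from kvsim.models import GateState


class TestProtocol:
    def test_time_grid_spans_holding_and_step(self):
        proto = ClampProtocol(t_hold=100.0, t_step=500.0, dt_out=1.0)
        t = proto.time_grid()
        assert np.all(np.diff(t) > 0)
        assert t[0] == -100.0 and t[-1] == 500.0
        assert 0.0 in t

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            ClampProtocol(t_step=0.0)
        with pytest.raises(ValueError):
            ClampProtocol(dt_out=-1.0)
        with pytest.raises(ValueError):
            ClampProtocol(v_steps=())


class TestGateClosedForm:
    def test_initial_condition(self):
        assert gate_closed_form(0.8, 50.0, 0.2, 0.0) == pytest.approx(0.2)

    def test_fixed_point(self):
        t = np.linspace(0, 1e4, 50)
        np.testing.assert_allclose(gate_closed_form(0.6, 30.0, 0.6, t), 0.6)

    def test_one_time_constant_reaches_1_over_e(self):
        g = gate_closed_form(1.0, 120.0, 0.0, 120.0)
        assert g == pytest.approx(1.0 - np.exp(-1.0), rel=1e-14)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            gate_closed_form(0.5, 10.0, 0.1, -1.0)


class TestSimulateCurrent:
    def test_zero_conductance_gives_zero_trace(self):
        traces = kv.simulate_current("Kto", kv.KtoParams(Gto=0.0))
        assert all(np.all(tr.I == 0) for tr in traces)

    def test_step_to_reversal_potential_gives_zero_step_current(self):
        c = kv.ModelConstants()
        proto = ClampProtocol(v_steps=(c.E_K,), t_hold=100.0)
        tr = kv.simulate_current("Kslow", kv.KslowParams(), proto)[0]
        np.testing.assert_allclose(tr.step_window().I, 0.0, atol=1e-15)

    def test_holding_current_is_constant_with_steady_state_init(self, presets):
        proto = ClampProtocol(v_steps=(50.0,), t_hold=1000.0)
        for name, p in presets.items():
            tr = kv.simulate_current(None, p, proto)[0]
            hold = tr.I[tr.t < 0]
            assert np.max(np.abs(hold - hold[0])) < 1e-12

    def test_custom_gate_initialization_is_honoured(self):
        proto = ClampProtocol(v_steps=(50.0,), t_hold=0.0)
        opts = SolverOptions(init=GateState(0.0, 1.0))
        tr = kv.simulate_current("Kto", kv.load_preset("kto_wt"), proto, opts)[0]
        assert tr.I[0] == 0.0  # closed activation gate at step onset
        assert tr.I[5] > 0.0

    def test_gates_stay_in_unit_interval_on_all_trajectories(self, presets):
        proto = ClampProtocol()
        for p in presets.values():
            model = kv.model_for(p)
            g0 = model.steady_gates(proto.v_hold)
            t = proto.time_grid()
            for v in proto.v_steps:
                a, i = _gates_analytic(model, proto, v, g0, t)
                assert np.all((a >= 0) & (a <= 1))
                assert np.all((i >= 0) & (i <= 1))

    def test_kslow_wt_rise_and_decay_time_scales(self):
        # at +50 mV the trace rises on tau_a (~2 ms) and decays on tau_i
        p = kv.load_preset("kslow_wt")
        proto = ClampProtocol(v_steps=(50.0,), dt_out=0.25)
        tr = kv.simulate_current(None, p, proto)[0].step_window()
        c = kv.kslow_curves(50.0, p)
        t_pk, peak = kv.find_peak(tr)
        assert t_pk < 10 * float(c.tau_a)
        # once activation has settled, I is linear in the inactivation gate,
        # so the decay is exponential with tau_i toward the analytic asymptote
        I_inf = float(c.a_ss * c.i_ss) * p.Gr * (50.0 - kv.ModelConstants().E_K)
        idx = np.argmin(np.abs(tr.t - (t_pk + float(c.tau_i))))
        expected = I_inf + (peak - I_inf) * np.exp(-1.0)
        assert tr.I[idx] == pytest.approx(expected, rel=0.05)

    def test_ode_and_analytic_backends_agree(self):
        proto = ClampProtocol(v_steps=(-30.0, 50.0), t_hold=200.0)
        for name in ("kto_wt", "kslow_ko"):
            p = kv.load_preset(name)
            ana = kv.simulate_current(None, p, proto)
            ode = kv.simulate_current(None, p, proto, SolverOptions(method="ode"))
            for a, o in zip(ana, ode):
                scale = np.max(np.abs(a.I))
                assert np.max(np.abs(a.I - o.I)) / scale < 1e-4


class TestIksum:
    def test_superposition_of_components(self):
        p_to, p_sl = kv.load_preset("kto_wt"), kv.load_preset("kslow_wt")
        proto = ClampProtocol(v_steps=(0.0, 50.0), t_hold=100.0)
        total = kv.simulate_iksum(p_to, p_sl, a_kss=2.0, proto=proto)
        kto = kv.simulate_current(None, p_to, proto)
        kslow = kv.simulate_current(None, p_sl, proto)
        for ts, ta, tb in zip(total, kto, kslow):
            expected = ta.I + tb.I + 2.0 * (ts.t >= 0)
            np.testing.assert_array_equal(ts.I, expected)

    def test_degenerates_to_kto_when_other_components_vanish(self):
        p_to = kv.load_preset("kto_wt")
        p_sl = kv.KslowParams(Gr=0.0)
        proto = ClampProtocol(v_steps=(50.0,), t_hold=100.0)
        total = kv.simulate_iksum(p_to, p_sl, a_kss=0.0, proto=proto)[0]
        kto = kv.simulate_current(None, p_to, proto)[0]
        np.testing.assert_array_equal(total.I, kto.I)

    def test_late_plateau_equals_offset_plus_residual_kslow(self):
        # by 4.5 s the Kto component has fully decayed; the remaining current
        # is A_Kss plus the analytic I_Kslow residual
        p_to, p_sl = kv.load_preset("kto_wt"), kv.load_preset("kslow_wt")
        proto = ClampProtocol(v_steps=(50.0,))
        tr = kv.simulate_iksum(p_to, p_sl, a_kss=2.0, proto=proto)[0]
        model = kv.KslowModel(p_sl)
        c = model.curves(50.0)
        g0 = model.steady_gates(proto.v_hold)
        a = gate_closed_form(float(c.a_ss), float(c.tau_a), g0.a, 4500.0)
        i = gate_closed_form(float(c.i_ss), float(c.tau_i), g0.i, 4500.0)
        residual = model.current(GateState(float(a), float(i)), 50.0)
        assert tr.I[-1] == pytest.approx(2.0 + residual, abs=1e-3)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            kv.simulate_iksum(kv.KtoParams(), kv.KslowParams(), a_kss=-1.0)


class TestCharacteristicCurves:
    def test_iv_peaks_scale_linearly_with_conductance(self):
        proto = ClampProtocol(t_hold=0.0)
        p = kv.load_preset("kslow_wt")
        full = kv.iv_peak_curve(None, p, proto)
        half = kv.iv_peak_curve(None, p.replace(Gr=p.Gr / 2), proto)
        np.testing.assert_allclose(
            half["peak_pApf"], full["peak_pApf"] / 2, rtol=1e-12)

    def test_single_step_yields_single_row(self):
        proto = ClampProtocol(v_steps=(50.0,), t_hold=0.0)
        df = kv.iv_peak_curve("Kto", kv.KtoParams(), proto)
        assert len(df) == 1 and df["v_step_mv"][0] == 50.0

    def test_kto_tau_curve_matches_fitted_decay(self):
        # the analytic 1/(alpha_i+beta_i) agrees with a mono-exponential fit
        # of the simulated decay to within 1%
        p = kv.load_preset("kto_wt")
        proto = ClampProtocol(v_steps=(50.0,), t_hold=0.0)
        tr = kv.simulate_current(None, p, proto)[0]
        fitted = kv.fit_monoexp(tr).tau
        analytic = kv.tau_voltage_curve("Kto", p, [50.0])["tau_ms"][0]
        assert fitted == pytest.approx(analytic, rel=0.01)

    def test_kslow_tau_curve_ko_exceeds_wt_everywhere(self):
        V = np.arange(-60.0, 51.0, 10.0)
        wt = kv.tau_voltage_curve("Kslow", kv.load_preset("kslow_wt"), V)
        ko = kv.tau_voltage_curve("Kslow", kv.load_preset("kslow_ko"), V)
        assert np.all(ko["tau_ms"].to_numpy() > wt["tau_ms"].to_numpy())

    def test_ssi_midpoint_and_wt_value_at_holding(self):
        p = kv.load_preset("kslow_wt")
        assert kv.ssi_curve("Kslow", p, [-p.x3])["i_ss"][0] == pytest.approx(0.5)
        # frozen scalar: 1/(1+e^{(-70+54.3)/12.4})
        assert kv.ssi_curve("Kslow", p, [-70.0])["i_ss"][0] == pytest.approx(
            0.78008, abs=1e-4)

    @pytest.mark.parametrize(
        "name", ["kto_wt", "kto_ko", "kslow_wt", "kslow_ko"])
    def test_ssi_monotone_decreasing_over_step_range(self, name, presets):
        V = np.arange(-60.0, 51.0, 10.0)
        p = presets[name]
        vals = kv.ssi_curve(p.kind, p, V)["i_ss"].to_numpy()
        assert np.all(np.diff(vals) < 0)
        assert np.all((vals > 0) & (vals < 1))
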