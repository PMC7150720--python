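"""Unit tests for the lumped circulation, elastance drive and PV metrics."""

import numpy as np
import pytest

from cardiolab import hemodynamics as hd
from cardiolab import myofilament as mf
from cardiolab.exceptions import (
    ConfigurationError,
    ModelFailureError,
    NotConvergedError,
    ProtocolError,
)


def flat_force(period=600.0, dt=1.0, level=0.0):
    t = np.arange(0.0, period, dt)
    return mf.ForceTrace(t=t, F_active=np.full_like(t, level),
                         atp_flux=np.zeros_like(t))


class TestElastanceDrive:
    def test_zero_force_gives_minimum_elastance(self):
        drive = hd.tension_to_elastance(flat_force(), 0.08, 2.5, 1.0)
        tt = np.linspace(0.0, 1800.0, 500)
        assert np.allclose(drive(tt), 0.08)

    def test_single_peak_near_force_peak(self, force_traces):
        """The WT elastance waveform peaks once per beat, shortly after the
        force peak (pressure-development lag)."""
        f = force_traces["WT"]
        drive = hd.tension_to_elastance(f, 0.08, 2.5,
                                        float(f.F_active.max()))
        e = drive(f.t)
        peaks = np.nonzero((e[1:-1] > e[:-2]) & (e[1:-1] >= e[2:]) &
                           (e[1:-1] > 0.5 * e.max()))[0]
        assert len(peaks) == 1
        t_epk = f.t[1 + peaks[0]]
        t_fpk = f.t[np.argmax(f.F_active)]
        # the lag integrates over the force plateau, so the elastance peak
        # trails the (early) force maximum by up to the plateau duration
        assert 0.0 <= t_epk - t_fpk <= 350.0

    def test_mutant_excursion_smaller(self, force_traces, wt_calibration):
        params, _, f_ref = wt_calibration
        exc = {}
        for cond, f in force_traces.items():
            drive = hd.tension_to_elastance(f, params.Emin_LV,
                                            params.Emax_LV, f_ref)
            exc[cond] = drive.E.max() - drive.E.min()
        assert exc["WT"] > exc["WT_E299V"] > exc["E299V"]

    def test_nonperiodic_trace_rejected(self):
        t = np.arange(0.0, 600.0, 1.0)
        f = mf.ForceTrace(t=t, F_active=np.linspace(0.0, 0.5, len(t)),
                          atp_flux=np.zeros_like(t))
        with pytest.raises(ProtocolError):
            hd.tension_to_elastance(f, 0.08, 2.5, 1.0)


class TestCirculationDynamics:
    def test_constant_elastance_reaches_equilibrium(self):
        """With no elastance variation the loop relaxes to a stationary
        state with (near-)zero net flows."""
        params = hd.CirculationParameters()
        run = hd.run_circulation(params, lambda t: np.full_like(t, 0.3),
                                 lambda t: np.full_like(t, 0.2),
                                 n_beats=100)
        v_late = run.volumes[-2400:]          # final 0.6 s
        assert np.abs(np.diff(v_late, axis=0)).max() < 1e-4

    def test_volume_conservation(self, force_traces, wt_calibration):
        """Total blood volume is conserved to < 1e-6 relative over 60 s."""
        params, state, f_ref = wt_calibration
        lv = hd.tension_to_elastance(force_traces["WT"], params.Emin_LV,
                                     params.Emax_LV, f_ref)
        rv = hd.tension_to_elastance(force_traces["WT"], params.Emin_RV,
                                     params.Emax_RV, f_ref)
        st = hd.CirculationState(state.volumes.copy(), 0.0)
        total0 = st.total_volume
        run = hd.run_circulation(params, lv, rv, n_beats=100, state=st)
        drift = abs(run.volumes[-1].sum() - total0) / total0
        assert drift < 1e-6

    def test_valve_diode_contract(self, force_traces, wt_calibration):
        """Flow through a closed valve is zero; open-valve flow is forward."""
        params, state, f_ref = wt_calibration
        lv_d = hd.tension_to_elastance(force_traces["WT"], params.Emin_LV,
                                       params.Emax_LV, f_ref)
        p = hd.CirculationState(state.volumes.copy(), 0.0).pressures(
            params, lv_d(0.0), 0.1)
        q = hd._flows(p, params)
        # diode indices: 0 MI, 1 AO, 4 TR, 5 PU
        for k, (up, dn) in zip((0, 1, 4, 5),
                               (((1, 0)), (0, 4), (3, 2), (2, 6))):
            if p[up] <= p[dn]:
                assert q[k] == 0.0
            else:
                assert q[k] >= 0.0

    def test_negative_volume_raises(self):
        params = hd.CirculationParameters()
        state = hd.CirculationState(
            np.array([12.0, 5.0, 12.0, 5.0, 10.0, 50.0, 10.0, 10.0]))
        with pytest.raises(ModelFailureError):
            for _ in range(100):
                state = hd.step_circulation(state, 10.0, 5.0, params,
                                            dt=50.0)

    def test_bad_parameters_rejected(self):
        p = hd.CirculationParameters(Emax_LV=0.05, Emin_LV=0.08)
        with pytest.raises(ConfigurationError):
            p.validate()


class TestPVMetrics:
    def test_rectangle_stroke_work(self):
        """A rectangular loop P in [10,110], V in [60,120] has SW exactly
        (110-10)*(120-60) = 6000 mmHg*mL."""
        v = np.array([120.0, 60.0, 60.0, 120.0])
        p = np.array([10.0, 10.0, 110.0, 110.0])
        assert hd.shoelace_area(v, p) == pytest.approx(6000.0, abs=1e-9)

    def test_ef_identity(self, pump_results):
        met = pump_results["WT"]["metrics"]
        assert met["EF_pct"] == pytest.approx(
            100.0 * met["SV_mL"] / met["EDV_mL"], rel=1e-12)

    def test_sw_integrators_agree(self, pump_results):
        """Shoelace loop area vs time-parametrized -∮P dV within 0.5%."""
        run = pump_results["WT"]["run"]
        vlv, plv = run.lv_loop(-1)
        t = np.arange(len(vlv)) * hd.DT_CIRC
        sw_shoelace = hd.shoelace_area(vlv, plv)
        sw_time = hd.stroke_work_time_integral(t, vlv, plv)
        assert sw_shoelace == pytest.approx(sw_time, rel=0.005)

    def test_loop_orientation_counterclockwise(self, pump_results):
        """A pumping beat traverses the V-P loop counter-clockwise
        (positive signed shoelace area)."""
        vlv, plv = pump_results["WT"]["run"].lv_loop(-1)
        signed = 0.5 * (np.dot(vlv, np.roll(plv, -1)) -
                        np.dot(plv, np.roll(vlv, -1)))
        assert signed > 0

    def test_unsettled_run_rejected(self, force_traces):
        params = hd.CirculationParameters()
        f = force_traces["WT"]
        f_ref = float(f.F_active.max())
        lv = hd.tension_to_elastance(f, params.Emin_LV, params.Emax_LV,
                                     f_ref)
        rv = hd.tension_to_elastance(f, params.Emin_RV, params.Emax_RV,
                                     f_ref)
        run = hd.run_circulation(params, lv, rv, n_beats=3)
        with pytest.raises(NotConvergedError):
            hd.pv_metrics(run)

    def test_metric_invariants(self, pump_results):
        for cond, res in pump_results.items():
            m = res["metrics"]
            assert 0.0 <= m["EF_pct"] <= 100.0
            assert m["SW_mmHg_mL"] >= 0.0
            assert m["SV_mL"] <= m["EDV_mL"]
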