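"""Shared fixtures: expensive steady-state simulations computed once."""

import numpy as np
import pytest

from cardiolab import hemodynamics as hd
from cardiolab import myofilament as mf
from cardiolab import protocols as pr
from cardiolab import tissue as ts
from cardiolab.ionic_cell import CELL_TYPES, CONDITIONS


@pytest.fixture(scope="session")
def steady_traces():
    """Steady-state paced traces (BCL 600 ms, 50 beats) for the 3x3 grid of
    mutation conditions and transmural cell types."""
    out = {}
    for cond in CONDITIONS:
        for ct in CELL_TYPES:
            out[(cond, ct)] = pr.pace_to_steady_state(ct, cond)
    return out


@pytest.fixture(scope="session")
def force_traces(steady_traces):
    """Myofilament force responses driven by the endocardial steady-state
    calcium transient of each condition (one pacing period)."""
    out = {}
    for cond in CONDITIONS:
        tr = steady_traces[(cond, "endo")]
        m = tr.t >= tr.stim_times[-1]
        out[cond] = mf.force_response(tr.t[m], tr.Ca_i[m], n_repeats=5)
    return out


@pytest.fixture(scope="session")
def calibrated_D():
    """Diffusion coefficient calibrated so the WT planar CV is 70 cm/s."""
    return ts.calibrate_diffusion()


@pytest.fixture(scope="session")
def wt_calibration(force_traces):
    """Frozen wild-type circulation calibration (params, state, F_ref)."""
    return hd.calibrate_circulation(force_traces["WT"])


@pytest.fixture(scope="session")
def pump_results(wt_calibration):
    """Settled closed-loop metrics and sinus pressure fluctuation per
    condition, with the circulation frozen at the WT calibration."""
    from cardiolab.cli_reporting import _pump_chain
    out = {}
    for cond in CONDITIONS:
        metrics, run, force, _ = _pump_chain(cond, n_beats=25,
                                             calibration=wt_calibration)
        out[cond] = {"metrics": metrics, "run": run, "force": force}
    return out


@pytest.fixture(scope="session")
def ring_runs(calibrated_D):
    """Sustained ring reentry (25 cm, 2.5 s) per condition, with calcium."""
    out = {}
    for cond in CONDITIONS:
        ring = ts.make_ring(cond, circumference=25.0, D=calibrated_D)
        out[cond] = ts.initiate_ring_reentry(ring, duration=2500.0,
                                             record_ca=True)
    return out


@pytest.fixture(scope="session")
def restitution_scans():
    """Dynamic-restitution curves for every condition and cell type over
    the study's BCL range (400 down to 200 ms)."""
    out = {}
    for cond in CONDITIONS:
        for ct in CELL_TYPES:
            out[(cond, ct)] = pr.dynamic_restitution(ct, cond)
    return out


def triangle_ap(duration=200.0, v_rest=-85.0, v_peak=35.0, dt=0.1,
                tail=100.0):
    """Synthetic triangular action potential: instant upstroke, linear
    repolarization reaching v_rest exactly at ``duration`` after upstroke."""
    t_up = 10.0
    t = np.arange(0.0, t_up + duration + tail, dt)
    v = np.full_like(t, v_rest)
    on = t >= t_up
    frac = np.clip((t[on] - t_up) / duration, 0.0, 1.0)
    v[on] = v_peak + (v_rest - v_peak) * frac
    return t, v
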