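"""Closed-loop lumped-parameter circulation with tension-driven ventricles.

Eight compartments — LV, LA, RV, RA, systemic artery (SA), systemic vein
(SV), pulmonary artery (PA), pulmonary vein (PV) — joined by resistances,
with diode valves (mitral MI, aortic AO, tricuspid TR, pulmonary PU) guarding
the ventricular inlets/outlets:

    LA -MI-> LV -AO-> SA -> SV -> RA -TR-> RV -PU-> PA -> PV -> LA

Vascular and atrial compartments are passive compliances (P = V/C); the
ventricles are time-varying elastances P = E(t)·(V − V0).  E(t) is driven by
the normalized myofilament active force of the underlying cell-level
simulation:

    E(t) = E_min + (E_max − E_min) · F_active(t) / F_ref

with F_ref frozen once at wild-type calibration, so mutation conditions
differ *only* through their force waveforms.  This varying-elastance chamber
is the package's organ-level contraction surrogate: organ-scale absolute
values for mutants are therefore trend/ordering quantities, while the
wild-type operating point is calibrated to stroke volume 59 mL and ejection
fraction 54% at 100 bpm and then held fixed.

Explicit Euler at dt = 0.25 ms conserves total blood volume to round-off
(every flow leaves one compartment and enters exactly one other).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    ConfigurationError,
    ModelFailureError,
    NotConvergedError,
    ProtocolError,
)

COMPARTMENTS = ("LV", "LA", "RV", "RA", "SA", "SV", "PA", "PV")
VALVES = ("MI", "AO", "TR", "PU")

DT_CIRC = 0.25     # ms
BCL_SINUS = 600.0  # ms (100 bpm)

#: Wild-type calibration anchors (stroke volume mL, ejection fraction %)
SV_TARGET = 59.0
EF_TARGET = 54.0


@dataclass
class CirculationParameters:
    """Compliances (mL/mmHg), resistances (mmHg·ms/mL) and ventricular
    elastance bounds (mmHg/mL)."""

    # passive compartments
    C_SA: float = 1.6
    C_SV: float = 60.0
    C_PA: float = 4.0
    C_PV: float = 12.0
    C_LA: float = 15.0
    C_RA: float = 15.0
    # resistances
    R_MI: float = 5.0
    R_AO: float = 8.0
    R_SYS: float = 1000.0
    R_SV: float = 30.0
    R_TR: float = 5.0
    R_PU: float = 8.0
    R_PUL: float = 100.0
    R_PV: float = 30.0
    # ventricles
    Emax_LV: float = 2.5
    Emin_LV: float = 0.08
    V0_LV: float = 10.0
    Emax_RV: float = 0.6
    Emin_RV: float = 0.045
    V0_RV: float = 10.0

    def validate(self):
        for name, v in self.__dict__.items():
            if name.startswith(("C_", "R_")) and v <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.Emax_LV <= self.Emin_LV or self.Emax_RV <= self.Emin_RV:
            raise ConfigurationError("Emax must exceed Emin")


@dataclass
class CirculationState:
    """Volumes (mL) of the eight compartments at one instant."""

    volumes: np.ndarray
    t: float = 0.0

    @classmethod
    def default(cls) -> "CirculationState":
        # LV, LA, RV, RA, SA, SV, PA, PV
        return cls(np.array([130.0, 70.0, 130.0, 70.0,
                             140.0, 420.0, 45.0, 95.0]), 0.0)

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def pressures(self, params: CirculationParameters,
                  e_lv: float, e_rv: float) -> np.ndarray:
        v = self.volumes
        return np.array([
            e_lv * (v[0] - params.V0_LV),
            v[1] / params.C_LA,
            e_rv * (v[2] - params.V0_RV),
            v[3] / params.C_RA,
            v[4] / params.C_SA,
            v[5] / params.C_SV,
            v[6] / params.C_PA,
            v[7] / params.C_PV,
        ])

    def valve_states(self, params, e_lv, e_rv) -> dict:
        p = self.pressures(params, e_lv, e_rv)
        return {"MI": p[1] > p[0], "AO": p[0] > p[4],
                "TR": p[3] > p[2], "PU": p[2] > p[6]}


class ElastanceDrive:
    """Periodic elastance waveform from a normalized force trace."""

    def __init__(self, t: np.ndarray, E: np.ndarray):
        self.t = np.asarray(t, float)
        self.E = np.asarray(E, float)
        self.period = float(self.t[-1] - self.t[0] +
                            (self.t[1] - self.t[0]))
        if np.any(self.E <= 0):
            raise ConfigurationError("elastance must be positive")

    def __call__(self, t):
        tau = np.mod(t - self.t[0], self.period) + self.t[0]
        return np.interp(tau, self.t, self.E)


#: time constants (ms) of organ-level pressure dynamics: the 0D chamber
#: responds to the cell tension through an asymmetric first-order lag —
#: pressure development is slow (isovolumic pressure rise takes ~0.1 s in
#: the human LV) while relaxation is fast.  Brief twitches therefore
#: translate into disproportionately weak chamber contraction, as in the
#: full organ, without compromising diastolic filling.
TAU_ACT_RISE = 100.0
TAU_ACT_FALL = 25.0


def tension_to_elastance(force_trace, Emin: float, Emax: float,
                         F_ref: float, periodicity_tol: float = 0.05,
                         tau_rise: float = TAU_ACT_RISE,
                         tau_fall: float = TAU_ACT_FALL) -> ElastanceDrive:
    """Map a one-period active-force trace onto an elastance waveform.

    E(t) = Emin + (Emax - Emin) * a(t), where a(t) is F(t)/F_ref passed
    through the asymmetric pressure-development lag (set both taus to 0 for
    the instantaneous mapping).  F_ref is the frozen wild-type reference
    peak of the lagged activation.  The trace must be periodic: its
    endpoints must agree to ``periodicity_tol`` of its excursion.
    """
    t = np.asarray(force_trace.t, float)
    f = np.asarray(force_trace.F_active, float)
    if F_ref <= 0:
        raise ConfigurationError("F_ref must be positive")
    excursion = max(float(f.max() - f.min()), 1e-12)
    if abs(f[0] - f[-1]) > periodicity_tol * excursion + 1e-9:
        raise ProtocolError(
            "force trace is not periodic over the pacing period")
    act = lagged_activation(t, np.clip(f, 0.0, None),
                            tau_rise, tau_fall) / F_ref
    act = np.clip(act, 0.0, None)
    return ElastanceDrive(t, Emin + (Emax - Emin) * act)


def lagged_activation(t: np.ndarray, f: np.ndarray,
                      tau_rise: float = TAU_ACT_RISE,
                      tau_fall: float = TAU_ACT_FALL,
                      n_periods: int = 4) -> np.ndarray:
    """Asymmetric first-order lag of a periodic waveform over one period.

    da/dt = (f - a)/tau, with tau = tau_rise while tension exceeds the
    lagged activation (contraction) and tau_fall otherwise (relaxation).
    Integrated over ``n_periods`` repeats so the output is the periodic
    steady state; zero taus return the input unchanged.
    """
    if tau_rise <= 0 and tau_fall <= 0:
        return np.asarray(f, float).copy()
    f = np.asarray(f, float)
    a = 0.0
    out = np.empty_like(f)
    dts = np.diff(np.asarray(t, float))
    dts = np.append(dts, dts[-1])
    for _ in range(n_periods):
        for i in range(len(f)):
            tau = tau_rise if f[i] > a else tau_fall
            a += dts[i] * (f[i] - a) / max(tau, dts[i])
            out[i] = a
    return out


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _flows(p, params):
    q = np.empty(8)
    q[0] = max(p[1] - p[0], 0.0) / params.R_MI    # LA -> LV
    q[1] = max(p[0] - p[4], 0.0) / params.R_AO    # LV -> SA
    q[2] = (p[4] - p[5]) / params.R_SYS           # SA -> SV
    q[3] = (p[5] - p[3]) / params.R_SV            # SV -> RA
    q[4] = max(p[3] - p[2], 0.0) / params.R_TR    # RA -> RV
    q[5] = max(p[2] - p[6], 0.0) / params.R_PU    # RV -> PA
    q[6] = (p[6] - p[7]) / params.R_PUL           # PA -> PV
    q[7] = (p[7] - p[1]) / params.R_PV            # PV -> LA
    return q


def step_circulation(state: CirculationState, E_lv: float, E_rv: float,
                     params: CirculationParameters,
                     dt: float = DT_CIRC) -> CirculationState:
    """Advance the compliance–resistance network one explicit-Euler step.

    Valves switch on instantaneous pressure gradients (diode contract:
    zero flow closed, forward flow open).
    """
    p = state.pressures(params, E_lv, E_rv)
    q = _flows(p, params)
    dv = np.array([
        q[0] - q[1],   # LV
        q[7] - q[0],   # LA
        q[4] - q[5],   # RV
        q[3] - q[4],   # RA
        q[1] - q[2],   # SA
        q[2] - q[3],   # SV
        q[5] - q[6],   # PA
        q[6] - q[7],   # PV
    ])
    v_new = state.volumes + dt * dv
    if np.any(v_new <= 0):
        bad = COMPARTMENTS[int(np.argmin(v_new))]
        raise ModelFailureError(
            f"negative volume in {bad} at t = {state.t + dt:.1f} ms",
            state=CirculationState(v_new, state.t + dt))
    return CirculationState(v_new, state.t + dt)


@dataclass
class CirculationRun:
    """Time series of a closed-loop run."""

    t: np.ndarray
    volumes: np.ndarray    # (nt, 8)
    pressures: np.ndarray  # (nt, 8)
    bcl: float
    params: CirculationParameters

    def lv_loop(self, beat: int = -1):
        """(V, P) points of the LV over one beat."""
        per = self.bcl
        nb = int(round((self.t[-1] + (self.t[1] - self.t[0])) / per))
        b = range(nb)[beat]
        m = (self.t >= b * per) & (self.t < (b + 1) * per)
        return self.volumes[m, 0], self.pressures[m, 0]


def run_circulation(params: CirculationParameters, lv_drive, rv_drive,
                    n_beats: int, bcl: float = BCL_SINUS,
                    dt: float = DT_CIRC,
                    state: CirculationState | None = None,
                    record: bool = True) -> CirculationRun:
    """Run ``n_beats`` pacing periods of the closed loop."""
    params.validate()
    if state is None:
        state = CirculationState.default()
    nsteps = int(round(n_beats * bcl / dt))
    ts = np.arange(nsteps) * dt
    elv = np.asarray(lv_drive(ts), float)
    erv = np.asarray(rv_drive(ts), float)
    if np.any(elv <= 0) or np.any(erv <= 0):
        raise ConfigurationError("elastance drive must be positive")
    vols = np.empty((nsteps, 8)) if record else None
    pres = np.empty((nsteps, 8)) if record else None
    v = state.volumes.copy()
    t = state.t
    for k in range(nsteps):
        st = CirculationState(v, t)
        p = st.pressures(params, elv[k], erv[k])
        q = _flows(p, params)
        if record:
            vols[k] = v
            pres[k] = p
        v = v + dt * np.array([
            q[0] - q[1], q[7] - q[0], q[4] - q[5], q[3] - q[4],
            q[1] - q[2], q[2] - q[3], q[5] - q[6], q[6] - q[7]])
        t += dt
        if np.any(v <= 0):
            bad = COMPARTMENTS[int(np.argmin(v))]
            raise ModelFailureError(
                f"negative volume in {bad} at t = {t:.1f} ms",
                state=CirculationState(v, t))
    state.volumes[:] = v
    state.t = t
    return CirculationRun(t=ts, volumes=vols, pressures=pres, bcl=bcl,
                          params=params)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class PVLoopMetrics:
    """Pumping metrics of one settled beat."""

    EDV: float             # mL
    ESV: float             # mL
    SV: float              # mL
    EF: float              # %
    SW: float              # mmHg·mL
    CO: float              # mL/min
    peak_LVP: float        # mmHg
    atp_rate: float = float("nan")   # s^-1
    sw_per_atp: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.EF <= 100.0):
            raise ConfigurationError("EF outside [0, 100]%")
        if self.SV > self.EDV + 1e-9:
            raise ConfigurationError("SV cannot exceed EDV")


def shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute polygon area of a closed loop given vertex series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) -
                           np.dot(y, np.roll(x, -1))))


def stroke_work_time_integral(t, v, p) -> float:
    """SW as the time-parametrized integral -∮ P dV (trapezoid oracle)."""
    dv = np.gradient(np.asarray(v, float), np.asarray(t, float))
    return float(abs(np.trapezoid(np.asarray(p, float) * dv, t)))


def pv_metrics(run: CirculationRun, force_trace=None,
               settle_tol: float = 0.01) -> PVLoopMetrics:
    """Metrics from the final beat of a run with >= 3 settled beats.

    Raises NotConvergedError if beat-to-beat stroke volume still drifts by
    more than ``settle_tol`` (relative, with a 0.1 mL absolute floor for
    near-zero-output runs whose slow volume redistribution never meets a
    relative criterion).
    """
    per = run.bcl
    n_beats = int(round((run.t[-1] + (run.t[1] - run.t[0])) / per))
    if n_beats < 3:
        raise NotConvergedError("need >= 3 beats for settled metrics")
    svs = []
    for b in (n_beats - 2, n_beats - 1):
        m = (run.t >= b * per) & (run.t < (b + 1) * per)
        vlv = run.volumes[m, 0]
        svs.append(vlv.max() - vlv.min())
    drift = abs(svs[-1] - svs[-2])
    if drift > max(settle_tol * max(svs[-1], 1e-9), 0.1):
        raise NotConvergedError(
            f"stroke volume still drifting ({svs[-2]:.2f} -> "
            f"{svs[-1]:.2f} mL)")
    m = (run.t >= (n_beats - 1) * per) & (run.t < n_beats * per)
    vlv = run.volumes[m, 0]
    plv = run.pressures[m, 0]
    edv = float(vlv.max())
    esv = float(vlv.min())
    sv = edv - esv
    sw = shoelace_area(vlv, plv)
    atp = force_trace.atp_rate() if force_trace is not None else float("nan")
    return PVLoopMetrics(
        EDV=edv, ESV=esv, SV=sv, EF=100.0 * sv / edv, SW=sw,
        CO=sv * 60000.0 / per, peak_LVP=float(plv.max()),
        atp_rate=atp,
        sw_per_atp=(sw / atp if atp and np.isfinite(atp) and atp > 0
                    else float("nan")))


def pressure_fluctuation(run: CirculationRun, tail_beats: int = 3) -> float:
    """Peak-to-trough LV pressure excursion over the final beats (mmHg)."""
    per = run.bcl
    t0 = run.t[-1] - tail_beats * per
    m = run.t >= t0
    p = run.pressures[m, 0]
    return float(p.max() - p.min())


# ---------------------------------------------------------------------------
# Wild-type calibration
# ---------------------------------------------------------------------------

def calibrate_circulation(wt_force_trace,
                          params: CirculationParameters | None = None,
                          bcl: float = BCL_SINUS,
                          sv_target: float = SV_TARGET,
                          ef_target: float = EF_TARGET,
                          n_iter: int = 24):
    """One-time wild-type calibration of the closed loop.

    Two-knob damped fixed point: total stressed volume is shifted through the
    venous reservoir to reach the target EDV (= SV/EF), and Emax_LV is scaled
    to reach the target ESV.  Returns (params, state, F_ref) with the
    circulation then frozen for mutant runs.
    """
    params = replace(params) if params is not None else CirculationParameters()
    f_ref = float(np.max(lagged_activation(
        np.asarray(wt_force_trace.t, float),
        np.clip(np.asarray(wt_force_trace.F_active, float), 0.0, None))))
    if f_ref <= 0:
        raise ConfigurationError("wild-type force trace has no contraction")
    edv_target = sv_target / (ef_target / 100.0)
    esv_target = edv_target - sv_target
    state = CirculationState.default()
    for _ in range(n_iter):
        lv = tension_to_elastance(wt_force_trace, params.Emin_LV,
                                  params.Emax_LV, f_ref)
        rv = tension_to_elastance(wt_force_trace, params.Emin_RV,
                                  params.Emax_RV, f_ref)
        run = run_circulation(params, lv, rv, n_beats=8, bcl=bcl,
                              state=state)
        per = bcl
        m = run.t >= run.t[-1] - per
        vlv = run.volumes[m, 0]
        edv, esv = float(vlv.max()), float(vlv.min())
        # preload: move volume in/out of the venous reservoir
        state.volumes[5] = max(state.volumes[5] + 1.5 * (edv_target - edv),
                               20.0)
        # contractility: scale Emax toward the ESV target
        scale = (esv - params.V0_LV) / max(esv_target - params.V0_LV, 1.0)
        params.Emax_LV *= float(np.clip(scale, 0.5, 2.0)) ** 0.8
    return params, state, f_ref
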