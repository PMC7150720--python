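"""Single-cell pacing protocols.

Steady-state pacing at a fixed basic cycle length (BCL), APD measurement at a
configurable repolarization fraction, dynamic restitution scans and alternans
detection.  The dynamic protocol paces each BCL to approximate steady state
(default 30 equilibration beats), measures the following beats, and carries
the cell state to the next, shorter BCL — the standard decremental protocol
for APD-restitution (APDr) curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import ionic_cell as ic
from .exceptions import (
    CaptureError,
    ConfigurationError,
    InsufficientDataError,
    UnrepolarizedBeatError,
)

#: default pacing configuration
DEFAULT_BCL = 600.0         # ms
DEFAULT_N_BEATS = 50        # beats to approximate single-cell steady state
DEFAULT_DT = 0.02           # ms
ALTERNANS_THRESHOLD = 2.0   # ms APD difference
ALTERNANS_MIN_BEATS = 4     # consecutive beats required
UPSTROKE_THRESHOLD = -20.0  # mV, used for capture counting


@dataclass
class PacedTrace:
    """Recorded tail of a constant-BCL pacing run."""

    t: np.ndarray            # ms, absolute time
    V: np.ndarray            # mV
    Ca_i: np.ndarray         # mM
    I_K1: np.ndarray         # pA/pF
    stim_times: np.ndarray   # ms, stimuli within the recorded window
    BCL: float
    n_beats: int             # total beats paced
    cell_type: str = ""
    condition: str = ""
    dt: float = DEFAULT_DT
    final_state: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.V) == len(self.Ca_i) == len(self.I_K1) == n):
            raise ConfigurationError("trace series lengths differ")
        if len(self.stim_times) > 1:
            gaps = np.diff(self.stim_times)
            if np.any(gaps <= 0) or np.any(np.abs(gaps - self.BCL) > 1e-6):
                raise ConfigurationError(
                    "stimulus times must increase with spacing = BCL")

    @property
    def n_recorded_beats(self) -> int:
        return len(self.stim_times)

    def beat_window(self, beat_index: int):
        """Time slice [stim, next stim) of one recorded beat."""
        idx = range(len(self.stim_times))[beat_index]
        t0 = self.stim_times[idx]
        t1 = (self.stim_times[idx + 1] if idx + 1 < len(self.stim_times)
              else self.t[-1] + self.dt)
        m = (self.t >= t0) & (self.t < t1)
        return self.t[m], self.V[m], m

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"t_ms": self.t, "V_mV": self.V,
                             "Ca_i_mM": self.Ca_i, "I_K1_pA_pF": self.I_K1})


@dataclass
class RestitutionCurve:
    """(BCL, DI, APD) records of a restitution protocol with slope estimates.

    ``apd_sequences`` keeps the raw post-equilibration APD sequence per BCL so
    alternans can be assessed; ``records`` holds one row per measured APD
    branch (two rows for an alternating BCL).  DI is BCL minus the preceding
    APD.  Slopes are d(APD)/d(DI) central differences on the per-BCL mean
    curve.
    """

    bcl: np.ndarray
    di: np.ndarray
    apd: np.ndarray
    protocol: str = "dynamic"
    apd_sequences: dict = field(default_factory=dict)
    truncated_at: float | None = None   # first BCL with capture loss, if any
    cell_type: str = ""
    condition: str = ""

    def __post_init__(self):
        order = np.argsort(self.bcl)[::-1]
        self.bcl = np.asarray(self.bcl, float)[order]
        self.di = np.asarray(self.di, float)[order]
        self.apd = np.asarray(self.apd, float)[order]

    def slopes(self) -> np.ndarray:
        """Central-difference d(APD)/d(DI) on the per-BCL mean curve."""
        bcl_u = np.unique(self.bcl)[::-1]
        apd_m = np.array([self.apd[self.bcl == b].mean() for b in bcl_u])
        di_m = np.array([self.di[self.bcl == b].mean() for b in bcl_u])
        if len(bcl_u) < 3:
            raise InsufficientDataError("need >= 3 BCL levels for slopes")
        return np.gradient(apd_m, di_m)

    @property
    def max_slope(self) -> float:
        return float(np.max(self.slopes()))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"BCL_ms": self.bcl, "DI_ms": self.di,
                             "APD_ms": self.apd})


# ---------------------------------------------------------------------------
# APD measurement
# ---------------------------------------------------------------------------

def apd_from_series(t: np.ndarray, v: np.ndarray,
                    repol_fraction: float = 0.9,
                    min_upstroke_rate: float = 5.0) -> float:
    """APD of a single action potential given as (t, V) samples.

    Measured from the maximum-dV/dt upstroke to the linearly interpolated
    crossing of the level ``V_dia + (1 - repol_fraction)*(V_peak - V_dia)``
    where V_dia is the pre-stimulus diastolic potential.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if len(t) < 4:
        raise InsufficientDataError("too few samples for APD measurement")
    dv = np.diff(v) / np.diff(t)
    iup = int(np.argmax(dv))
    if dv[iup] < min_upstroke_rate:
        raise CaptureError("no upstroke in beat window")
    # pre-stimulus diastolic reference: the window opens at the stimulus,
    # so the first sample still sits at the diastolic potential
    v_dia = v[0]
    v_peak = float(np.max(v[iup:]))
    level = v_dia + (1.0 - repol_fraction) * (v_peak - v_dia)
    seg = v[iup:]
    below = np.nonzero((seg[:-1] > level) & (seg[1:] <= level))[0]
    if len(below) == 0:
        raise UnrepolarizedBeatError(
            f"beat not repolarized to {100*repol_fraction:.0f}% "
            "before the window end")
    i = iup + below[0]
    t_cross = t[i] + (t[i + 1] - t[i]) * (v[i] - level) / (v[i] - v[i + 1])
    return float(t_cross - t[iup])


def measure_apd(trace: PacedTrace, beat_index: int = -1,
                repol_fraction: float = 0.9) -> float:
    """APD of one recorded beat of a paced trace (linear-interpolated
    crossing at the stated repolarization fraction)."""
    tt, vv, _ = trace.beat_window(beat_index)
    return apd_from_series(tt, vv, repol_fraction)


def _count_upstrokes(t, v, threshold=UPSTROKE_THRESHOLD):
    above = v >= threshold
    return int(np.sum(~above[:-1] & above[1:]))


# ---------------------------------------------------------------------------
# Pacing
# ---------------------------------------------------------------------------

def pace_to_steady_state(cell_type: str, cond, BCL: float = DEFAULT_BCL,
                         n_beats: int = DEFAULT_N_BEATS,
                         dt: float = DEFAULT_DT,
                         record_beats: int = 2,
                         record_stride: int = 2,
                         initial_state: np.ndarray | None = None,
                         verify_capture: bool = True) -> PacedTrace:
    """Pace one cell at a fixed BCL and return the recorded final beats.

    The stimulus is a 1-ms, -52 pA/pF square pulse at the start of each
    cycle.  1:1 capture over the recorded window is verified (one upstroke
    per stimulus) unless ``verify_capture`` is disabled.
    """
    if n_beats < 2:
        raise ConfigurationError("n_beats must be >= 2")
    if BCL <= 0:
        raise ConfigurationError("BCL must be positive")
    c = ic.condition(cond)
    state, params = ic.make_cell(cell_type, c)
    y = state.y if initial_state is None else np.array(initial_state, float)
    tabs = ic.get_tables(dt)
    record_beats = min(record_beats, n_beats)
    t, v, ca, ik1, y = ic._pace_run(
        y, params.ct_code, params.G_Ks, params.G_to, c.variant,
        BCL, n_beats, dt, params.stim_amplitude, params.stim_duration,
        n_beats - record_beats, record_stride, *tabs)
    if len(t) == 0 or not np.all(np.isfinite(v)):
        raise CaptureError("pacing run diverged", beat_index=None)
    stim_times = np.arange(n_beats - record_beats, n_beats) * BCL
    trace = PacedTrace(t=t, V=v, Ca_i=ca, I_K1=ik1, stim_times=stim_times,
                       BCL=BCL, n_beats=n_beats, cell_type=cell_type,
                       condition=c.label, dt=dt, final_state=y)
    if verify_capture:
        n_up = _count_upstrokes(t, v)
        if n_up != len(stim_times):
            # locate the first beat without an upstroke
            bad = None
            for k in range(len(stim_times)):
                tt, vv, _ = trace.beat_window(k)
                if _count_upstrokes(tt, vv) != 1:
                    bad = n_beats - record_beats + k
                    break
            raise CaptureError(
                f"loss of 1:1 capture ({n_up} upstrokes for "
                f"{len(stim_times)} stimuli)", beat_index=bad)
    return trace


def peak_ik1(trace: PacedTrace, beat_index: int = -1) -> float:
    """Maximum I_K1 (pA/pF) over one recorded beat's time course."""
    idx = range(len(trace.stim_times))[beat_index]
    t0 = trace.stim_times[idx]
    t1 = t0 + trace.BCL
    m = (trace.t >= t0) & (trace.t < t1)
    return float(np.max(trace.I_K1[m]))


# ---------------------------------------------------------------------------
# Restitution and alternans
# ---------------------------------------------------------------------------

def dynamic_restitution(cell_type: str, cond,
                        BCL_start: float = 400.0, BCL_stop: float = 200.0,
                        BCL_step: float = 10.0,
                        beats_per_BCL: int = 30, measured_beats: int = 8,
                        dt: float = DEFAULT_DT,
                        threshold: float = ALTERNANS_THRESHOLD
                        ) -> RestitutionCurve:
    """Decremental dynamic restitution scan.

    Each BCL is paced ``beats_per_BCL`` equilibration beats followed by
    ``measured_beats`` measured beats; the state carries over between BCLs.
    The curve truncates (``truncated_at``) at the first BCL where 1:1 capture
    or full repolarization fails.
    """
    if BCL_start <= BCL_stop:
        raise ConfigurationError("BCL_start must exceed BCL_stop")
    c = ic.condition(cond)
    state, params = ic.make_cell(cell_type, c)
    # settle at the starting BCL first; a cell that cannot hold 1:1 capture
    # even there yields an empty curve truncated at the start
    try:
        pre = pace_to_steady_state(cell_type, c, BCL=BCL_start,
                                   n_beats=DEFAULT_N_BEATS, dt=dt)
    except CaptureError:
        return RestitutionCurve(
            bcl=np.array([]), di=np.array([]), apd=np.array([]),
            protocol="dynamic", apd_sequences={}, truncated_at=BCL_start,
            cell_type=cell_type, condition=c.label)
    y = pre.final_state
    tabs = ic.get_tables(dt)

    bcls, dis, apds = [], [], []
    sequences: dict[float, np.ndarray] = {}
    truncated_at = None
    for bcl in np.arange(BCL_start, BCL_stop - 1e-9, -BCL_step):
        nb = beats_per_BCL + measured_beats
        t, v, ca, ik1, y = ic._pace_run(
            y, params.ct_code, params.G_Ks, params.G_to, c.variant,
            bcl, nb, dt, -52.0, 1.0, beats_per_BCL, 2, *tabs)
        if len(t) == 0 or not np.all(np.isfinite(v)):
            truncated_at = bcl
            break
        stim_times = np.arange(beats_per_BCL, nb) * bcl
        seq = []
        ok = True
        for st in stim_times:
            m = (t >= st) & (t < st + bcl)
            try:
                seq.append(apd_from_series(t[m], v[m]))
            except (UnrepolarizedBeatError, CaptureError,
                    InsufficientDataError):
                ok = False
                break
        if not ok or len(seq) < ALTERNANS_MIN_BEATS:
            truncated_at = bcl
            break
        seq = np.array(seq)
        sequences[float(bcl)] = seq
        # one record per branch: two if alternating, else the mean
        tail = seq[-ALTERNANS_MIN_BEATS:]
        d = np.diff(tail)
        alternating = np.all(np.abs(d) > threshold) and np.all(
            d[:-1] * d[1:] < 0)
        if alternating:
            for a_prev, a in zip(tail[-3:-1], tail[-2:]):
                bcls.append(bcl)
                dis.append(bcl - a_prev)
                apds.append(a)
        else:
            a = float(seq[-2:].mean())
            bcls.append(bcl)
            dis.append(bcl - a)
            apds.append(a)
    return RestitutionCurve(
        bcl=np.array(bcls), di=np.array(dis), apd=np.array(apds),
        protocol="dynamic", apd_sequences=sequences,
        truncated_at=truncated_at, cell_type=cell_type, condition=c.label)


def s1s2_restitution(cell_type: str, cond, S1_BCL: float = 600.0,
                     n_S1: int = 20,
                     S2_intervals=np.arange(1000.0, 200.0, -50.0),
                     dt: float = DEFAULT_DT) -> RestitutionCurve:
    """S1-S2 (standard) restitution: a premature S2 after an S1 train.

    Provided for completeness; the dynamic protocol is the primary one.
    """
    c = ic.condition(cond)
    state, params = ic.make_cell(cell_type, c)
    tabs = ic.get_tables(dt)
    base = pace_to_steady_state(cell_type, c, BCL=S1_BCL, n_beats=n_S1, dt=dt)
    apd1 = measure_apd(base, -1)
    bcls, dis, apds = [], [], []
    for s2 in S2_intervals:
        y = base.final_state.copy()
        t, v, ca, ik1, y = ic._pace_run(
            y, params.ct_code, params.G_Ks, params.G_to, c.variant,
            s2, 2, dt, -52.0, 1.0, 1, 2, *tabs)
        st = np.array([s2])
        m = (t >= s2)
        try:
            a = apd_from_series(t[m], v[m])
        except (UnrepolarizedBeatError, CaptureError):
            continue
        bcls.append(s2)
        dis.append(s2 - apd1)
        apds.append(a)
    return RestitutionCurve(bcl=np.array(bcls), di=np.array(dis),
                            apd=np.array(apds), protocol="S1S2",
                            cell_type=cell_type, condition=c.label)


def detect_alternans(apd_sequences: dict,
                     threshold: float = ALTERNANS_THRESHOLD,
                     min_beats: int = ALTERNANS_MIN_BEATS) -> float | None:
    """Largest BCL with sustained APD alternans, or None.

    Alternans: consecutive APDs differing by more than ``threshold`` ms with
    alternating sign over at least ``min_beats`` beats (after whatever
    equilibration discard the caller applied).
    """
    onset = None
    for bcl, seq in apd_sequences.items():
        seq = np.asarray(seq, float)
        if len(seq) < min_beats:
            raise InsufficientDataError(
                f"need >= {min_beats} APDs per BCL (got {len(seq)} "
                f"at BCL {bcl})")
        tail = seq[-min_beats:]
        d = np.diff(tail)
        if np.all(np.abs(d) > threshold) and np.all(d[:-1] * d[1:] < 0):
            if onset is None or bcl > onset:
                onset = float(bcl)
    return onset
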