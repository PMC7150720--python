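"""Calcium-driven cross-bridge mechanics (Rice-type approximate model).

A cytosolic calcium transient activates regulatory units (troponin/
tropomyosin) whose permissive fraction gates a three-state cross-bridge
cycle::

    N  <->  P  <->  XB_PreR  <->  XB_PostR
                       \\____________/
                        g_xb (ATP-consuming detachment back to P)

``N``/``P`` are nonpermissive/permissive regulatory-unit fractions;
``XB_PreR`` is the strongly bound, pre-rotation (stiffness-bearing) state and
``XB_PostR`` the post-rotation, force-generating state.  The N->P rate scales
with troponin-bound calcium to a high cooperative power (Hill-type exponent
7.5 on each side of the permissivity); it is implemented with the smooth
saturating permissivity ``permtot = sqrt(1/(1 + (perm50/TCa)^15))`` whose
two square-root halves are the T^±7.5 cooperative factors, with the inverse
capped for numerical sanity.

Mean cross-bridge strains x_PreR and x_PostR relax toward their
isosarcometric fixed point (0 and x0); normalized active force is

    F = SOVF_thick(SL) * (XB_PreR*x_PreR + XB_PostR*x_PostR) / (x0 * XB_PostR_max)

so that optimal conditions (full single overlap, saturating calcium,
steady-state cycling) give F = 1.  ATP consumption is the detachment flux
g_xb * XB_PostR, reported beat-averaged per second.

Operation is isosarcometric (fixed sarcomere length, default 2.2 µm): the
coupling from electrophysiology to mechanics is one-way, so no shortening
feedback is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    NumericalStateError,
)

# ---------------------------------------------------------------------------
# Parameters (rates in ms^-1, lengths in µm, Ca in mM)
# ---------------------------------------------------------------------------

F_APP = 0.5      # P -> XB_PreR attachment
G_APP = 0.07     # XB_PreR -> P detachment
H_F = 2.0        # XB_PreR -> XB_PostR rotation (forward)
H_B = 0.4        # XB_PostR -> XB_PreR rotation (backward)
G_XB = 0.07      # XB_PostR -> P ATP-consuming detachment
K_NP = 0.5       # nonpermissive -> permissive base rate
K_PN = 0.05      # permissive -> nonpermissive base rate
PERM50 = 0.5     # half-activation of the regulatory permissivity
N_PERM = 15.0    # cooperativity (2 x 7.5)
INPRMT_CAP = 100.0

# Troponin calcium kinetics.  The on-rate is the usual 50 µM^-1 s^-1; the
# off-rates set an apparent Kd of 0.6 µM (no bound cross-bridges) falling to
# 0.25 µM under full cross-bridge feedback.  This places the 0.2-1.1 µM
# systolic transients of the ionic model across the regulatory switch's
# dynamic range (graded partial activation for the weakest transients) while
# keeping the ~0.1 µM diastolic level below the deactivation point so every
# twitch relaxes.
K_ON = 50.0      # troponin Ca on-rate, mM^-1 ms^-1
K_OFF_L = 0.03    # off-rate (ms^-1), no strongly bound cross-bridges
K_OFF_H = 0.0125  # off-rate (ms^-1), full cross-bridge feedback

X0 = 0.007       # µm, power-stroke size
PHI_STRAIN = 0.05

LEN_THICK = 1.65   # µm
LEN_HBARE = 0.1    # µm
LEN_THIN = 1.2     # µm
SL_DEFAULT = 2.2   # µm


def sovf_thick(sl: float) -> float:
    """Single-overlap fraction of the thick filament at sarcomere length sl."""
    sovr_ze = min(LEN_THICK / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - LEN_THIN), LEN_HBARE / 2.0)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    return 2.0 * len_sovr / (LEN_THICK - LEN_HBARE)


def _cycle_steady_state(fapp=F_APP, gapp=G_APP, hf=H_F, hb=H_B, gxb=G_XB):
    """Steady-state occupancies of the P/PreR/PostR cycle at full
    permissivity (the 'optimal conditions' normalization anchor)."""
    A = np.array([
        [-fapp, gapp, gxb],
        [fapp, -(gapp + hf), hb],
        [1.0, 1.0, 1.0],
    ])
    b = np.array([0.0, 0.0, 1.0])
    p, pre, post = np.linalg.solve(A, b)
    return float(pre), float(post)


XB_PRER_MAX, XB_POSTR_MAX = _cycle_steady_state()


@dataclass
class MyofilamentState:
    """Regulatory-unit and cross-bridge state of one half-sarcomere."""

    N_xb: float = 0.99       # nonpermissive fraction
    P_xb: float = 0.01       # permissive (unbound) fraction
    XB_PreR: float = 0.0     # strongly bound, pre-rotation
    XB_PostR: float = 0.0    # strongly bound, post-rotation
    xXB_PreR: float = 0.0    # mean strain (µm)
    xXB_PostR: float = X0    # mean strain (µm)
    TCa_Tot: float = 0.0     # troponin-bound Ca fraction
    SL: float = SL_DEFAULT   # sarcomere length (µm)

    def fractions(self):
        return np.array([self.N_xb, self.P_xb, self.XB_PreR, self.XB_PostR])

    def validate(self, tol: float = 1e-6):
        fr = self.fractions()
        if np.any(fr < -tol) or np.any(fr > 1.0 + tol):
            raise NumericalStateError("cross-bridge fraction outside [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-6:
            raise NumericalStateError(
                f"regulatory/cross-bridge fractions not conserved "
                f"(sum = {fr.sum():.8f})")
        if not 0.0 <= self.TCa_Tot <= 1.0:
            raise NumericalStateError("TCa_Tot outside [0, 1]")

    def as_vector(self) -> np.ndarray:
        return np.array([self.N_xb, self.P_xb, self.XB_PreR, self.XB_PostR,
                         self.xXB_PreR, self.xXB_PostR, self.TCa_Tot])

    @classmethod
    def from_vector(cls, y, SL: float = SL_DEFAULT) -> "MyofilamentState":
        return cls(N_xb=y[0], P_xb=y[1], XB_PreR=y[2], XB_PostR=y[3],
                   xXB_PreR=y[4], xXB_PostR=y[5], TCa_Tot=y[6], SL=SL)


@dataclass
class ForceTrace:
    """Normalized active force and instantaneous ATP flux over time."""

    t: np.ndarray          # ms
    F_active: np.ndarray   # dimensionless, 1 = optimal-conditions maximum
    atp_flux: np.ndarray   # s^-1, instantaneous g_xb * XB_PostR
    XB_PostR: np.ndarray = field(default=None)

    def __post_init__(self):
        if np.any(self.F_active < -1e-9):
            raise NumericalStateError("active force must be non-negative")

    def atp_rate(self) -> float:
        """Trace-averaged ATP turnover (s^-1)."""
        return float(np.mean(self.atp_flux))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"t_ms": self.t, "F_active": self.F_active,
                             "atp_flux_per_s": self.atp_flux})


# ---------------------------------------------------------------------------
# Integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _myo_step(y, ca, dt, gxb_scale, koff_l, koff_h):
    """Advance the 7-component myofilament vector one step in place.

    Operator split: exact 2-state exchange for N<->P, explicit Euler for the
    bound-state cycle and strains, exact exponential for troponin Ca.
    Both substeps conserve N + P + XB_PreR + XB_PostR to round-off.
    """
    n = y[0]; p = y[1]; pre = y[2]; post = y[3]
    x1 = y[4]; x2 = y[5]; tca = y[6]

    gxb = G_XB * gxb_scale

    # permissivity from troponin-bound calcium (T^+7.5 / T^-7.5 cooperativity)
    t_eff = tca if tca > 1e-8 else 1e-8
    permtot = math.sqrt(1.0 / (1.0 + (PERM50 / t_eff) ** N_PERM))
    inprmt = 1.0 / permtot
    if inprmt > INPRMT_CAP:
        inprmt = INPRMT_CAP
    kf = K_NP * permtot
    kb = K_PN * inprmt

    # exact relaxation of the N<->P exchange (conserves n + p)
    tot = n + p
    pss = kf * tot / (kf + kb)
    e = math.exp(-(kf + kb) * dt)
    p = pss + (p - pss) * e
    n = tot - p

    # cross-bridge cycle (fluxes sum to zero)
    dp = G_APP * pre + gxb * post - F_APP * p
    dpre = F_APP * p - (G_APP + H_F) * pre + H_B * post
    dpost = H_F * pre - (H_B + gxb) * post
    p += dt * dp
    pre += dt * dpre
    post += dt * dpost

    # mean strains relax toward the isosarcometric fixed point (0, x0)
    duty_pre = XB_PRER_MAX
    duty_post = XB_POSTR_MAX
    dx1 = (PHI_STRAIN / duty_pre) * (-F_APP * x1 + H_B * (x2 - X0 - x1))
    dx2 = (PHI_STRAIN / duty_post) * (H_F * (x1 + X0 - x2))
    x1 += dt * dx1
    x2 += dt * dx2

    # troponin calcium with cross-bridge-dependent off-rate
    w = (pre + post) / (XB_PRER_MAX + XB_POSTR_MAX)
    if w > 1.0:
        w = 1.0
    koff = koff_l * (1.0 - w) + koff_h * w
    a = K_ON * ca + koff
    tca_ss = K_ON * ca / a
    tca = tca_ss + (tca - tca_ss) * math.exp(-a * dt)

    y[0] = n; y[1] = p; y[2] = pre; y[3] = post
    y[4] = x1; y[5] = x2; y[6] = tca
    return gxb * post


@njit(cache=True)
def _myo_run(ca_series, dt, sl, gxb_scale, koff_l, koff_h, y):
    """Integrate along a calcium series; returns (F, atp_flux, xb_postr)."""
    nsteps = ca_series.shape[0]
    f_out = np.empty(nsteps)
    atp_out = np.empty(nsteps)
    post_out = np.empty(nsteps)
    # single-overlap factor is constant at fixed SL
    sovr_ze = min(LEN_THICK / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - LEN_THIN), LEN_HBARE / 2.0)
    sovf = 2.0 * max(sovr_ze - sovr_cle, 0.0) / (LEN_THICK - LEN_HBARE)
    for i in range(nsteps):
        flux = _myo_step(y, ca_series[i], dt, gxb_scale, koff_l, koff_h)
        f_out[i] = sovf * (y[2] * y[4] + y[3] * y[5]) / (X0 * XB_POSTR_MAX)
        atp_out[i] = flux * 1000.0  # ms^-1 -> s^-1
        post_out[i] = y[3]
    return f_out, atp_out, post_out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def step_myofilament(state: MyofilamentState, Ca_i: float,
                     dt: float = 0.02) -> MyofilamentState:
    """Advance the myofilament state one time step under cytosolic Ca_i (mM)."""
    if Ca_i < 0:
        raise ConfigurationError("Ca_i must be non-negative")
    if dt <= 0 or dt > 0.1:
        raise ConfigurationError("dt outside the stable range (0, 0.1] ms")
    y = state.as_vector()
    _myo_step(y, float(Ca_i), dt, 1.0, K_OFF_L, K_OFF_H)
    new = MyofilamentState.from_vector(y, SL=state.SL)
    new.validate(tol=1e-3)
    return new


def active_force(state: MyofilamentState) -> float:
    """Normalized active force of one state (1 = optimal-conditions max)."""
    return (sovf_thick(state.SL) *
            (state.XB_PreR * state.xXB_PreR +
             state.XB_PostR * state.xXB_PostR) / (X0 * XB_POSTR_MAX))


def force_response(t: np.ndarray, ca: np.ndarray,
                   SL: float = SL_DEFAULT, dt: float = 0.02,
                   gxb_scale: float = 1.0,
                   state: MyofilamentState | None = None,
                   n_repeats: int = 1,
                   koff_l: float | None = None,
                   koff_h: float | None = None) -> ForceTrace:
    """Drive the cross-bridge model with a calcium transient.

    ``(t, ca)`` is resampled onto a uniform dt grid; ``n_repeats`` repeats the
    transient periodically (for pacing trains) before recording the last
    period.
    """
    t = np.asarray(t, float)
    ca = np.asarray(ca, float)
    if len(t) < 2 or len(t) != len(ca):
        raise InsufficientDataError("calcium series too short or mismatched")
    if np.any(ca < 0):
        raise ConfigurationError("calcium must be non-negative")
    period = t[-1] - t[0]
    tu = np.arange(0.0, period, dt)
    cau = np.interp(tu, t - t[0], ca)
    kl = K_OFF_L if koff_l is None else float(koff_l)
    kh = K_OFF_H if koff_h is None else float(koff_h)
    y = (state.as_vector() if state is not None
         else MyofilamentState().as_vector())
    for _ in range(max(n_repeats - 1, 0)):
        _myo_run(cau, dt, SL, gxb_scale, kl, kh, y)
    f, atp, post = _myo_run(cau, dt, SL, gxb_scale, kl, kh, y)
    return ForceTrace(t=tu, F_active=np.maximum(f, 0.0), atp_flux=atp,
                      XB_PostR=post)


def atp_rate(trace, dt: float | None = None) -> float:
    """Beat-averaged ATP turnover (s^-1) of a force trace or state sequence.

    The rate is the time average of the ATP-consuming detachment flux
    g_xb * XB_PostR over the trace.
    """
    if isinstance(trace, ForceTrace):
        if len(trace.t) == 0:
            raise InsufficientDataError("empty force trace")
        return trace.atp_rate()
    states = list(trace)
    if not states:
        raise InsufficientDataError("empty state trace")
    post = np.array([s.XB_PostR for s in states])
    return float(np.mean(G_XB * post) * 1000.0)
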