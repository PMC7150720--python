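"""Human ventricular myocyte electrophysiology.

Implements the ten Tusscher–Panfilov (2006) human ventricular ionic model with
three inward-rectifier (I_K1) formulations describing increasing expression of
the Kir2.1 E299V gain-of-function mutation:

* ``WT`` — wild type,
* ``WT_E299V`` — heterozygous expression,
* ``E299V`` — pure mutant, in which inward rectification is lost and I_K1
  becomes quasi-ohmic at depolarized potentials.

The mutation changes nothing but the I_K1 current–voltage relation.  Three
transmural cell types (endocardial, midmyocardial, epicardial) differ in their
transient-outward conductance/kinetics (base model) and in the slow
delayed-rectifier conductance G_Ks (endo/epi 0.392 × 1.3 mS/µF, mid
0.073 mS/µF).

The membrane equation is ``dV/dt = -(I_ion + I_stim)/C_m`` with I_ion the sum
of twelve sarcolemmal currents; intracellular Na+, K+ and the three-compartment
Ca2+ system (cytosol, subspace, SR with CICR release) are integrated alongside.
Gating variables use Rush–Larsen exponential updates; voltage-dependent rate
expressions are tabulated on a 0.05 mV grid with linear interpolation for
speed, and an untabulated right-hand side is kept for reference integrations
and current breakdowns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .exceptions import ConfigurationError, DivergenceError, NumericalStateError

# ---------------------------------------------------------------------------
# Physical constants and base-model parameters (ten Tusscher–Panfilov 2006)
# ---------------------------------------------------------------------------

R_GAS = 8314.472      # mJ/(mol*K)
TEMP = 310.0          # K
FARADAY = 96485.3415  # C/mol
RTONF = R_GAS * TEMP / FARADAY  # mV

KO = 5.4     # mM
CAO = 2.0    # mM
NAO = 140.0  # mM

VC = 0.016404     # cytosolic volume (units of the base model)
VSR = 0.001094
VSS = 0.00005468
CAPACITANCE = 0.185  # µF

BUFC, KBUFC = 0.2, 0.001
BUFSR, KBUFSR = 10.0, 0.3
BUFSS, KBUFSS = 0.4, 0.00025

VMAXUP, KUP = 0.006375, 0.00025
VREL = 0.102
K1P, K2P, K3, K4 = 0.15, 0.045, 0.060, 0.005
EC_SR, MAXSR, MINSR = 1.5, 2.5, 1.0
VLEAK, VXFER = 0.00036, 0.0038

G_NA = 14.838
G_K1_NATIVE = 5.405
G_KR = 0.153
G_CAL = 0.00003980
P_NAK, KM_K, KM_NA = 2.724, 1.0, 40.0
K_NACA, KM_NAI, KM_CA, K_SAT, ALPHA_NACA, GAMMA_NACA = (
    1000.0, 87.5, 1.38, 0.1, 2.5, 0.35)
G_PCA, K_PCA = 0.1238, 0.0005
G_PK = 0.0146
G_BNA, G_BCA = 0.00029, 0.000592
P_KNA = 0.03

# Transmural cell types --------------------------------------------------

CELL_TYPES = ("endo", "mid", "epi")
_CT_CODE = {"endo": 0, "mid": 1, "epi": 2}

# G_Ks overrides used throughout this study (mS/µF): endo/epi boosted 1.3x
# over the base 0.392; mid reduced to 0.073.
GKS_BY_TYPE = {"endo": 0.392 * 1.3, "mid": 0.073, "epi": 0.392 * 1.3}
GTO_BY_TYPE = {"endo": 0.073, "mid": 0.294, "epi": 0.294}

# Mutation conditions ----------------------------------------------------

CONDITIONS = ("WT", "WT_E299V", "E299V")

#: Printed coefficient sets of the three I_K1 formulations.  The flattened
#: typesetting of the source expressions is ambiguous in how the trailing
#: constant groups with the exponential; both readings are implemented (see
#: ``ik1_current``) and the package default per condition was fixed once by
#: comparing simulated peak I_K1 and APD against the reported values.
IK1_COEFFICIENTS = {
    "WT": dict(a=0.24731, s=0.0, b=0.86426, c=0.0904, d=-0.06519),
    "WT_E299V": dict(a=0.11905, s=2.4, b=0.04092, c=0.01732, d=-0.36212),
    "E299V": dict(a=0.06634, s=6.5, q=-2.44009e-4, d=-0.51383),
}

# Integer codes for the I_K1 variants used inside kernels.
IK1_NATIVE = 0        # base-model inward rectifier
IK1_WT_FIT_A = 1      # WT fit, trailing constant inside the exponent
IK1_WT_FIT_B = 2      # WT fit, trailing constant additive outside the fraction
IK1_HET_FIT_A = 3
IK1_HET_FIT_B = 4
IK1_E299V_QUAD = 5

#: Functional form used for each condition.  Chosen once by grouping
#: calibration against the reported peak I_K1 (1.9 / ~2.3 / >4 pA/pF) and the
#: steady-state APDs; see docs/methods.md.
CONDITION_VARIANTS = {
    "WT": IK1_WT_FIT_B,
    "WT_E299V": IK1_HET_FIT_B,
    "E299V": IK1_E299V_QUAD,
}

# State vector layout ----------------------------------------------------

STATE_NAMES = (
    "V", "Na_i", "K_i", "Ca_i", "Ca_ss", "Ca_SR",
    "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fcass", "Rbar",
)
N_STATE = len(STATE_NAMES)
GATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
              "fcass", "Rbar")

# Resting initial conditions of the base model.
_Y0 = np.array([
    -86.2,      # V
    7.67,       # Na_i
    138.3,      # K_i
    0.00007,    # Ca_i
    0.00007,    # Ca_ss
    1.3,        # Ca_SR
    0.0, 0.75, 0.75,   # m h j
    0.0, 1.0, 0.0,     # xr1 xr2 xs
    0.0, 1.0,          # r s
    0.0, 1.0, 1.0,     # d f f2
    1.0,               # fcass
    1.0,               # Rbar
])

CURRENT_NAMES = ("I_Na", "I_K1", "I_to", "I_Kr", "I_Ks", "I_CaL", "I_NaCa",
                 "I_NaK", "I_pCa", "I_pK", "I_bCa", "I_bNa")


# ---------------------------------------------------------------------------
# Gating-rate expressions (single source of truth: used directly by the
# reference right-hand side and sampled onto lookup tables by the stepper)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gate_inf_tau(gate: int, v: float):
    """Return (y_inf, tau) for voltage-gated variable ``gate`` at potential v.

    Gate row indices: 0 m, 1 h, 2 j, 3 xr1, 4 xr2, 5 xs, 6 r, 7 s (epi/mid),
    8 s (endo), 9 d, 10 f, 11 f2.
    """
    if gate == 0:  # m
        inf = 1.0 / (1.0 + math.exp((-56.86 - v) / 9.03)) ** 2
        am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
        bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + \
            0.1 / (1.0 + math.exp((v - 50.0) / 200.0))
        return inf, am * bm
    elif gate == 1:  # h
        inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
        if v >= -40.0:
            ah = 0.0
            bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        else:
            ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
            bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
        return inf, 1.0 / (ah + bh)
    elif gate == 2:  # j
        inf = 1.0 / (1.0 + math.exp((v + 71.55) / 7.43)) ** 2
        if v >= -40.0:
            aj = 0.0
            bj = 0.6 * math.exp(0.057 * v) / \
                (1.0 + math.exp(-0.1 * (v + 32.0)))
        else:
            aj = ((-2.5428e4 * math.exp(0.2444 * v) -
                   6.948e-6 * math.exp(-0.04391 * v)) * (v + 37.78) /
                  (1.0 + math.exp(0.311 * (v + 79.23))))
            bj = 0.02424 * math.exp(-0.01052 * v) / \
                (1.0 + math.exp(-0.1378 * (v + 40.14)))
        return inf, 1.0 / (aj + bj)
    elif gate == 3:  # xr1
        inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
        a = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
        b = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
        return inf, a * b
    elif gate == 4:  # xr2
        inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
        a = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
        b = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
        return inf, a * b
    elif gate == 5:  # xs
        inf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
        a = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - v) / 6.0))
        b = 1.0 / (1.0 + math.exp((v - 35.0) / 15.0))
        return inf, a * b + 80.0
    elif gate == 6:  # r
        inf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
        tau = 9.5 * math.exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
        return inf, tau
    elif gate == 7:  # s, epicardial / midmyocardial kinetics
        inf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
        tau = (85.0 * math.exp(-(v + 45.0) ** 2 / 320.0) +
               5.0 / (1.0 + math.exp((v - 20.0) / 5.0)) + 3.0)
        return inf, tau
    elif gate == 8:  # s, endocardial kinetics
        inf = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
        tau = 1000.0 * math.exp(-(v + 67.0) ** 2 / 1000.0) + 8.0
        return inf, tau
    elif gate == 9:  # d
        inf = 1.0 / (1.0 + math.exp((-8.0 - v) / 7.5))
        ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
        gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
        return inf, ad * bd + gd
    elif gate == 10:  # f
        inf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
        tau = (1102.5 * math.exp(-(v + 27.0) ** 2 / 225.0) +
               200.0 / (1.0 + math.exp((13.0 - v) / 10.0)) +
               180.0 / (1.0 + math.exp((v + 30.0) / 10.0)) + 20.0)
        return inf, tau
    else:  # f2
        inf = 0.67 / (1.0 + math.exp((v + 35.0) / 7.0)) + 0.33
        tau = (562.0 * math.exp(-(v + 27.0) ** 2 / 240.0) +
               31.0 / (1.0 + math.exp((25.0 - v) / 10.0)) +
               80.0 / (1.0 + math.exp((v + 30.0) / 10.0)))
        return inf, tau


@njit(cache=True)
def _ik1_of_x(variant: int, x: float) -> float:
    """I_K1 (pA/pF) as a function of the driving force x = V - E_K."""
    if variant == IK1_NATIVE:
        ak1 = 0.1 / (1.0 + math.exp(0.06 * (x - 200.0)))
        bk1 = ((3.0 * math.exp(0.0002 * (x + 100.0)) +
                math.exp(0.1 * (x - 10.0))) /
               (1.0 + math.exp(-0.5 * x)))
        xk1 = ak1 / (ak1 + bk1)
        return G_K1_NATIVE * math.sqrt(KO / 5.4) * xk1 * x
    elif variant == IK1_WT_FIT_A:
        return 0.24731 * x / (0.86426 + math.exp(0.0904 * x - 0.06519))
    elif variant == IK1_WT_FIT_B:
        return 0.24731 * x / (0.86426 + math.exp(0.0904 * x)) - 0.06519
    elif variant == IK1_HET_FIT_A:
        return (0.11905 * (x + 2.4) /
                (0.04092 + math.exp(0.01732 * x - 0.36212)))
    elif variant == IK1_HET_FIT_B:
        return (0.11905 * (x + 2.4) /
                (0.04092 + math.exp(0.01732 * x)) - 0.36212)
    else:  # IK1_E299V_QUAD: rectification lost, quasi-ohmic with curvature
        return 0.06634 * (x + 6.5) - 2.44009e-4 * x * x - 0.51383


# ---------------------------------------------------------------------------
# Reference right-hand side (direct evaluation, no tables)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_and_currents(y, ct_code, gks, gto, ik1_variant, istim, dy, cur):
    """Evaluate the full ODE right-hand side and the current breakdown.

    ``cur`` layout: 12 membrane currents (CURRENT_NAMES order), then
    I_ion, I_leak, I_up, I_rel, E_K, E_Na, E_Ca (19 slots).
    """
    v = y[0]
    nai = y[1]
    ki = y[2]
    cai = y[3]
    cass = y[4]
    casr = y[5]
    m = y[6]; h = y[7]; jj = y[8]
    xr1 = y[9]; xr2 = y[10]; xs = y[11]
    r = y[12]; s = y[13]
    d = y[14]; f = y[15]; f2 = y[16]
    fcass = y[17]; rbar = y[18]

    ek = RTONF * math.log(KO / ki)
    ena = RTONF * math.log(NAO / nai)
    eks = RTONF * math.log((KO + P_KNA * NAO) / (ki + P_KNA * nai))
    eca = 0.5 * RTONF * math.log(CAO / cai)

    ina = G_NA * m ** 3 * h * jj * (v - ena)
    ik1 = _ik1_of_x(ik1_variant, v - ek)
    ito = gto * r * s * (v - ek)
    ikr = G_KR * math.sqrt(KO / 5.4) * xr1 * xr2 * (v - ek)
    iks = gks * xs * xs * (v - eks)

    vf_rt = (v - 15.0) * FARADAY / (R_GAS * TEMP)
    if abs(vf_rt) < 1e-7:
        ical = (G_CAL * d * f * f2 * fcass * 2.0 * FARADAY *
                (0.25 * cass - CAO))
    else:
        e2 = math.exp(2.0 * vf_rt)
        ical = (G_CAL * d * f * f2 * fcass * 4.0 * (v - 15.0) *
                FARADAY ** 2 / (R_GAS * TEMP) *
                (0.25 * cass * e2 - CAO) / (e2 - 1.0))

    vfrt = v * FARADAY / (R_GAS * TEMP)
    eg = math.exp(GAMMA_NACA * vfrt)
    eg1 = math.exp((GAMMA_NACA - 1.0) * vfrt)
    inaca = (K_NACA * (eg * nai ** 3 * CAO - eg1 * NAO ** 3 * cai * ALPHA_NACA) /
             ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO) *
              (1.0 + K_SAT * eg1)))
    inak = (P_NAK * KO / (KO + KM_K) * nai / (nai + KM_NA) /
            (1.0 + 0.1245 * math.exp(-0.1 * vfrt) +
             0.0353 * math.exp(-vfrt)))
    ipca = G_PCA * cai / (cai + K_PCA)
    ipk = G_PK * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    ibna = G_BNA * (v - ena)
    ibca = G_BCA * (v - eca)

    iion = (ina + ik1 + ito + ikr + iks + ical + inaca + inak +
            ipca + ipk + ibca + ibna)

    # SR calcium handling
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC_SR / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    o_rel = k1 * cass * cass * rbar / (K3 + k1 * cass * cass)
    irel = VREL * o_rel * (casr - cass)
    ileak = VLEAK * (casr - cai)
    iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
    ixfer = VXFER * (cass - cai)

    dy[0] = -(iion + istim)
    dy[1] = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * CAPACITANCE / (VC * FARADAY)
    dy[2] = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk + istim) * \
        CAPACITANCE / (VC * FARADAY)

    bufci = 1.0 / (1.0 + BUFC * KBUFC / (cai + KBUFC) ** 2)
    dy[3] = bufci * ((ileak - iup) * VSR / VC + ixfer -
                     (ibca + ipca - 2.0 * inaca) * CAPACITANCE /
                     (2.0 * VC * FARADAY))
    bufss = 1.0 / (1.0 + BUFSS * KBUFSS / (cass + KBUFSS) ** 2)
    dy[4] = bufss * (-ical * CAPACITANCE / (2.0 * VSS * FARADAY) +
                     irel * VSR / VSS - ixfer * VC / VSS)
    bufsr = 1.0 / (1.0 + BUFSR * KBUFSR / (casr + KBUFSR) ** 2)
    dy[5] = bufsr * (iup - irel - ileak)

    # voltage gates
    s_gate_row = 8 if ct_code == 0 else 7
    gate_rows = (0, 1, 2, 3, 4, 5, 6, s_gate_row, 9, 10, 11)
    for k in range(11):
        inf, tau = _gate_inf_tau(gate_rows[k], v)
        dy[6 + k] = (inf - y[6 + k]) / tau
    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
    dy[17] = (fcass_inf - fcass) / tau_fcass
    dy[18] = -k2 * cass * rbar + K4 * (1.0 - rbar)

    cur[0] = ina; cur[1] = ik1; cur[2] = ito; cur[3] = ikr
    cur[4] = iks; cur[5] = ical; cur[6] = inaca; cur[7] = inak
    cur[8] = ipca; cur[9] = ipk; cur[10] = ibca; cur[11] = ibna
    cur[12] = iion
    cur[13] = ileak; cur[14] = iup; cur[15] = irel
    cur[16] = ek; cur[17] = ena; cur[18] = eca


# ---------------------------------------------------------------------------
# Tabulated Rush–Larsen stepper
# ---------------------------------------------------------------------------

VT_MIN, VT_MAX, VT_STEP = -150.0, 100.0, 0.05
XT_MIN, XT_MAX, XT_STEP = -90.0, 230.0, 0.05


def _build_tables(dt: float):
    """Precompute voltage-dependent factors on a uniform grid for one dt.

    Returns (INF, RLF, CF, IK1T) where INF/RLF hold steady states and
    Rush–Larsen factors exp(-dt/tau) for the 12 voltage gates (two s-gate
    kinetics as separate rows), CF holds current prefactors and IK1T the six
    I_K1 variants as functions of V - E_K.
    """
    nv = int(round((VT_MAX - VT_MIN) / VT_STEP)) + 1
    vgrid = VT_MIN + VT_STEP * np.arange(nv)
    INF = np.empty((12, nv))
    RLF = np.empty((12, nv))
    for g in range(12):
        for i, v in enumerate(vgrid):
            inf, tau = _gate_inf_tau(g, v)
            INF[g, i] = inf
            RLF[g, i] = math.exp(-dt / tau)
    CF = np.empty((6, nv))
    for i, v in enumerate(vgrid):
        vfrt = v * FARADAY / (R_GAS * TEMP)
        vf_rt = (v - 15.0) * FARADAY / (R_GAS * TEMP)
        if abs(vf_rt) < 1e-9:
            e2 = 1.0
            pref = 2.0 * FARADAY
        else:
            e2 = math.exp(2.0 * vf_rt)
            pref = 4.0 * (v - 15.0) * FARADAY ** 2 / (R_GAS * TEMP) / (e2 - 1.0)
        CF[0, i] = e2
        CF[1, i] = pref
        CF[2, i] = math.exp(GAMMA_NACA * vfrt)
        CF[3, i] = math.exp((GAMMA_NACA - 1.0) * vfrt)
        CF[4, i] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * vfrt) +
                          0.0353 * math.exp(-vfrt))
        CF[5, i] = 1.0 / (1.0 + math.exp((25.0 - v) / 5.98))
    nx = int(round((XT_MAX - XT_MIN) / XT_STEP)) + 1
    xgrid = XT_MIN + XT_STEP * np.arange(nx)
    IK1T = np.empty((6, nx))
    for var in range(6):
        for i, x in enumerate(xgrid):
            IK1T[var, i] = _ik1_of_x(var, x)
    return INF, RLF, CF, IK1T


_TABLE_CACHE: dict[float, tuple] = {}


def get_tables(dt: float):
    key = round(dt, 12)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _build_tables(dt)
    return _TABLE_CACHE[key]


@njit(cache=True)
def _advance_nodes(Y, ct, gks, gto, ik1v, istim, dt, INF, RLF, CF, IK1T):
    """Advance every node (column of Y) one time step in place.

    Returns the node-wise I_K1 of the step (pA/pF) for peak tracking.
    """
    n = Y.shape[1]
    ik1_out = np.empty(n)
    for i in range(n):
        v = Y[0, i]
        # table position for voltage
        fv = (v - VT_MIN) / VT_STEP
        iv = int(fv)
        if iv < 0:
            iv = 0; fv = 0.0
        elif iv > INF.shape[1] - 2:
            iv = INF.shape[1] - 2; fv = float(INF.shape[1] - 2)
        wv = fv - iv

        # Rush-Larsen updates for the 11 voltage gates of this cell type
        s_row = 8 if ct[i] == 0 else 7
        # gate state indices 6..16 map to rows (0..6, s_row, 9, 10, 11)
        for k in range(11):
            if k < 7:
                g = k
            elif k == 7:
                g = s_row
            else:
                g = k + 1
            inf = INF[g, iv] + wv * (INF[g, iv + 1] - INF[g, iv])
            rl = RLF[g, iv] + wv * (RLF[g, iv + 1] - RLF[g, iv])
            Y[6 + k, i] = inf + (Y[6 + k, i] - inf) * rl

        nai = Y[1, i]; ki = Y[2, i]
        cai = Y[3, i]; cass = Y[4, i]; casr = Y[5, i]
        m = Y[6, i]; h = Y[7, i]; jj = Y[8, i]
        xr1 = Y[9, i]; xr2 = Y[10, i]; xs = Y[11, i]
        r = Y[12, i]; s = Y[13, i]
        d = Y[14, i]; f = Y[15, i]; f2 = Y[16, i]
        fcass = Y[17, i]; rbar = Y[18, i]

        ek = RTONF * math.log(KO / ki)
        ena = RTONF * math.log(NAO / nai)
        eks = RTONF * math.log((KO + P_KNA * NAO) / (ki + P_KNA * nai))
        eca = 0.5 * RTONF * math.log(CAO / cai)

        ina = G_NA * m ** 3 * h * jj * (v - ena)

        x = v - ek
        fx = (x - XT_MIN) / XT_STEP
        ix = int(fx)
        if ix < 0:
            ix = 0; fx = 0.0
        elif ix > IK1T.shape[1] - 2:
            ix = IK1T.shape[1] - 2; fx = float(IK1T.shape[1] - 2)
        wx = fx - ix
        var = ik1v[i]
        ik1 = IK1T[var, ix] + wx * (IK1T[var, ix + 1] - IK1T[var, ix])

        ito = gto[i] * r * s * x
        ikr = G_KR * xr1 * xr2 * x  # sqrt(Ko/5.4) = 1 at Ko = 5.4
        iks = gks[i] * xs * xs * (v - eks)

        e2 = CF[0, iv] + wv * (CF[0, iv + 1] - CF[0, iv])
        pref = CF[1, iv] + wv * (CF[1, iv + 1] - CF[1, iv])
        ical = G_CAL * d * f * f2 * fcass * pref * (0.25 * cass * e2 - CAO)

        eg = CF[2, iv] + wv * (CF[2, iv + 1] - CF[2, iv])
        eg1 = CF[3, iv] + wv * (CF[3, iv + 1] - CF[3, iv])
        inaca = (K_NACA * (eg * nai ** 3 * CAO -
                           eg1 * NAO ** 3 * cai * ALPHA_NACA) /
                 ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO) *
                  (1.0 + K_SAT * eg1)))
        fnak = CF[4, iv] + wv * (CF[4, iv + 1] - CF[4, iv])
        inak = P_NAK * KO / (KO + KM_K) * nai / (nai + KM_NA) * fnak
        ipca = G_PCA * cai / (cai + K_PCA)
        fpk = CF[5, iv] + wv * (CF[5, iv + 1] - CF[5, iv])
        ipk = G_PK * x * fpk
        ibna = G_BNA * (v - ena)
        ibca = G_BCA * (v - eca)

        iion = (ina + ik1 + ito + ikr + iks + ical + inaca + inak +
                ipca + ipk + ibca + ibna)

        kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC_SR / casr) ** 2)
        k1 = K1P / kcasr
        k2 = K2P * kcasr
        o_rel = k1 * cass * cass * rbar / (K3 + k1 * cass * cass)
        irel = VREL * o_rel * (casr - cass)
        ileak = VLEAK * (casr - cai)
        iup = VMAXUP / (1.0 + (KUP / cai) ** 2)
        ixfer = VXFER * (cass - cai)

        # fcass gate (calcium-dependent; exact exponential update)
        fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
        tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0
        Y[17, i] = fcass_inf + (fcass - fcass_inf) * math.exp(-dt / tau_fcass)
        Y[18, i] = rbar + dt * (-k2 * cass * rbar + K4 * (1.0 - rbar))

        bufci = 1.0 / (1.0 + BUFC * KBUFC / (cai + KBUFC) ** 2)
        Y[3, i] = cai + dt * bufci * (
            (ileak - iup) * VSR / VC + ixfer -
            (ibca + ipca - 2.0 * inaca) * CAPACITANCE / (2.0 * VC * FARADAY))
        bufss = 1.0 / (1.0 + BUFSS * KBUFSS / (cass + KBUFSS) ** 2)
        Y[4, i] = cass + dt * bufss * (
            -ical * CAPACITANCE / (2.0 * VSS * FARADAY) +
            irel * VSR / VSS - ixfer * VC / VSS)
        bufsr = 1.0 / (1.0 + BUFSR * KBUFSR / (casr + KBUFSR) ** 2)
        Y[5, i] = casr + dt * bufsr * (iup - irel - ileak)

        Y[1, i] = nai + dt * (-(ina + ibna + 3.0 * inak + 3.0 * inaca) *
                              CAPACITANCE / (VC * FARADAY))
        Y[2, i] = ki + dt * (-(ik1 + ito + ikr + iks - 2.0 * inak + ipk +
                               istim[i]) * CAPACITANCE / (VC * FARADAY))

        Y[0, i] = v + dt * (-(iion + istim[i]))
        ik1_out[i] = ik1
    return ik1_out


@njit(cache=True)
def _pace_run(y, ct_code, gks, gto, ik1v, bcl, n_beats, dt,
              stim_amp, stim_dur, rec_start_beat, rec_stride,
              INF, RLF, CF, IK1T):
    """Pace a single cell for ``n_beats`` at cycle length ``bcl``.

    Records t, V, Ca_i and I_K1 every ``rec_stride`` steps starting at beat
    ``rec_start_beat``.  Returns (t, V, Cai, IK1, apds_placeholder, y).
    """
    steps_per_beat = int(round(bcl / dt))
    stim_steps = int(round(stim_dur / dt))
    total_steps = steps_per_beat * n_beats
    rec_from = steps_per_beat * rec_start_beat
    n_rec = (total_steps - rec_from) // rec_stride + 1
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    ca_out = np.empty(n_rec)
    ik1_out = np.empty(n_rec)

    Y = y.reshape(N_STATE, 1)
    ct = np.empty(1, np.int64); ct[0] = ct_code
    gks_a = np.empty(1); gks_a[0] = gks
    gto_a = np.empty(1); gto_a[0] = gto
    v_arr = np.empty(1, np.int64); v_arr[0] = ik1v
    istim = np.zeros(1)

    k = 0
    for step in range(total_steps):
        in_beat = step % steps_per_beat
        istim[0] = stim_amp if in_beat < stim_steps else 0.0
        ik1_now = _advance_nodes(Y, ct, gks_a, gto_a, v_arr, istim, dt,
                                 INF, RLF, CF, IK1T)
        if step >= rec_from and (step - rec_from) % rec_stride == 0:
            t_out[k] = (step + 1) * dt
            v_out[k] = Y[0, 0]
            ca_out[k] = Y[3, 0]
            ik1_out[k] = ik1_now[0]
            k += 1
        if not np.isfinite(Y[0, 0]) or Y[0, 0] < -150.0 or Y[0, 0] > 100.0:
            # signal divergence through a NaN sentinel in the trace
            t_out[k - 1 if k > 0 else 0] = np.nan
            break
    return t_out[:k], v_out[:k], ca_out[:k], ik1_out[:k], y


# ---------------------------------------------------------------------------
# Public domain types and API
# ---------------------------------------------------------------------------

@dataclass
class MutationCondition:
    """Selector for the Kir2.1 E299V expression level.

    Binds one of the three I_K1 current–voltage formulations; nothing else in
    the model changes between conditions.
    """

    label: str
    coefficients: dict = field(default_factory=dict)
    variant: int = -1

    def __post_init__(self):
        if self.label not in CONDITIONS:
            raise ConfigurationError(
                f"unknown mutation condition {self.label!r}; "
                f"expected one of {CONDITIONS}")
        if not self.coefficients:
            self.coefficients = dict(IK1_COEFFICIENTS[self.label])
        if self.variant < 0:
            self.variant = CONDITION_VARIANTS[self.label]


def condition(label: str | MutationCondition) -> MutationCondition:
    """Coerce a label or MutationCondition to a MutationCondition."""
    if isinstance(label, MutationCondition):
        return label
    return MutationCondition(str(label))


@dataclass
class IonicParameters:
    """Cell-type specific parameters layered on the base model."""

    cell_type: str
    G_Ks: float   # mS/µF
    G_to: float   # mS/µF
    C_m: float = CAPACITANCE
    stim_amplitude: float = -52.0  # pA/pF
    stim_duration: float = 1.0     # ms

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ConfigurationError(
                f"unknown cell type {self.cell_type!r}; "
                f"expected one of {CELL_TYPES}")
        if self.G_Ks < 0 or self.G_to < 0:
            raise ConfigurationError("conductances must be non-negative")

    @property
    def ct_code(self) -> int:
        return _CT_CODE[self.cell_type]


@dataclass
class CellState:
    """Full state of one myocyte at one instant."""

    y: np.ndarray          # length-19 state vector (STATE_NAMES order)
    t: float = 0.0         # ms

    @property
    def V(self) -> float:
        return float(self.y[0])

    @property
    def Ca_i(self) -> float:
        return float(self.y[3])

    @property
    def Ca_ss(self) -> float:
        return float(self.y[4])

    @property
    def Ca_SR(self) -> float:
        return float(self.y[5])

    @property
    def Na_i(self) -> float:
        return float(self.y[1])

    @property
    def K_i(self) -> float:
        return float(self.y[2])

    @property
    def gates(self) -> dict:
        return {name: float(self.y[6 + k]) for k, name in enumerate(GATE_NAMES)}

    def validate(self):
        if not np.all(np.isfinite(self.y)):
            bad = STATE_NAMES[int(np.argmin(np.isfinite(self.y)))]
            raise NumericalStateError(f"non-finite state entry: {bad}")
        if not (-120.0 <= self.V <= 80.0):
            raise NumericalStateError(f"V out of range: {self.V} mV")
        gates = self.y[6:]
        if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
            raise NumericalStateError("gating variable outside [0, 1]")
        if np.any(self.y[1:6] <= 0):
            raise NumericalStateError("non-positive concentration")

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), self.t)


@dataclass
class CurrentBreakdown:
    """All membrane currents (pA/pF), SR fluxes (mM/ms) and reversal
    potentials (mV) at one state."""

    currents: dict
    I_ion: float
    I_leak: float
    I_up: float
    I_rel: float
    E_K: float
    E_Na: float
    E_Ca: float


def make_cell(cell_type: str, cond: str | MutationCondition = "WT"
              ) -> tuple[CellState, IonicParameters]:
    """Build the resting state and parameter set for one transmural cell type.

    G_Ks is 0.392 × 1.3 mS/µF for endocardial and epicardial cells and
    0.073 mS/µF for the midmyocardial cell; G_to follows the base model.
    """
    if cell_type not in CELL_TYPES:
        raise ConfigurationError(
            f"unknown cell type {cell_type!r}; expected one of {CELL_TYPES}")
    condition(cond)  # validate label
    params = IonicParameters(cell_type=cell_type,
                             G_Ks=GKS_BY_TYPE[cell_type],
                             G_to=GTO_BY_TYPE[cell_type])
    return CellState(_Y0.copy(), 0.0), params


def ik1_current(V: float, E_K: float, cond: str | MutationCondition) -> float:
    """Inward-rectifier current density (pA/pF) at potential V.

    Evaluates the condition's I_K1 formulation at driving force V - E_K.
    """
    c = condition(cond)
    return float(_ik1_of_x(c.variant, float(V) - float(E_K)))


def compute_currents(state: CellState, params: IonicParameters,
                     cond: str | MutationCondition,
                     I_stim: float = 0.0) -> CurrentBreakdown:
    """Evaluate every membrane current, the SR fluxes and the reversal
    potentials at the given state (direct evaluation, no lookup tables)."""
    state.validate()
    c = condition(cond)
    dy = np.empty(N_STATE)
    cur = np.empty(19)
    _rhs_and_currents(state.y, params.ct_code, params.G_Ks, params.G_to,
                      c.variant, I_stim, dy, cur)
    currents = {name: float(cur[i]) for i, name in enumerate(CURRENT_NAMES)}
    return CurrentBreakdown(
        currents=currents, I_ion=float(cur[12]),
        I_leak=float(cur[13]), I_up=float(cur[14]), I_rel=float(cur[15]),
        E_K=float(cur[16]), E_Na=float(cur[17]), E_Ca=float(cur[18]))


def rhs(y: np.ndarray, params: IonicParameters,
        cond: str | MutationCondition, I_stim: float = 0.0) -> np.ndarray:
    """Plain ODE right-hand side dy/dt for reference integrations."""
    c = condition(cond)
    dy = np.empty(N_STATE)
    cur = np.empty(19)
    _rhs_and_currents(np.asarray(y, dtype=float), params.ct_code, params.G_Ks,
                      params.G_to, c.variant, I_stim, dy, cur)
    return dy


def step_cell(state: CellState, params: IonicParameters,
              cond: str | MutationCondition, I_stim: float = 0.0,
              dt: float = 0.02) -> CellState:
    """Advance one cell one time step (Rush–Larsen gates, explicit Euler for
    V and concentrations).  Deterministic for fixed inputs."""
    if dt <= 0 or dt > 0.1:
        raise ConfigurationError(
            f"dt = {dt} ms outside the admissible range (0, 0.1] ms")
    c = condition(cond)
    INF, RLF, CF, IK1T = get_tables(dt)
    Y = state.y.reshape(N_STATE, 1).copy()
    ct = np.array([params.ct_code], dtype=np.int64)
    _advance_nodes(Y, ct, np.array([params.G_Ks]), np.array([params.G_to]),
                   np.array([c.variant], dtype=np.int64),
                   np.array([float(I_stim)]), dt, INF, RLF, CF, IK1T)
    ynew = Y[:, 0]
    if not np.all(np.isfinite(ynew)):
        bad = STATE_NAMES[int(np.argmax(~np.isfinite(ynew)))]
        raise DivergenceError(f"integration diverged in {bad}", variable=bad)
    if ynew[0] < -150.0 or ynew[0] > 100.0:
        raise DivergenceError(
            f"membrane potential out of range: {ynew[0]:.1f} mV", variable="V")
    return CellState(ynew, state.t + dt)


def resting_potential_oracle(params: IonicParameters,
                             cond: str | MutationCondition,
                             v_lo: float = -95.0, v_hi: float = -60.0,
                             n: int = 3501) -> float:
    """Brute-force scan for the resting potential: the root of the quasi
    steady-state current-balance I_ion(V) = 0 nearest E_K, with gates at
    their steady state for each V and concentrations held at rest."""
    c = condition(cond)
    vs = np.linspace(v_lo, v_hi, n)
    iion = np.empty(n)
    y = _Y0.copy()
    dy = np.empty(N_STATE)
    cur = np.empty(19)
    for i, v in enumerate(vs):
        y[0] = v
        # gates at steady state for this V
        s_row = 8 if params.ct_code == 0 else 7
        rows = (0, 1, 2, 3, 4, 5, 6, s_row, 9, 10, 11)
        for k in range(11):
            inf, _ = _gate_inf_tau(rows[k], v)
            y[6 + k] = inf
        _rhs_and_currents(y, params.ct_code, params.G_Ks, params.G_to,
                          c.variant, 0.0, dy, cur)
        iion[i] = cur[12]
    sign_change = np.nonzero(np.diff(np.sign(iion)))[0]
    if len(sign_change) == 0:
        raise NumericalStateError("no current-balance root in scan window")
    i = sign_change[0]
    # linear interpolation of the crossing
    f0, f1 = iion[i], iion[i + 1]
    return float(vs[i] + (vs[i + 1] - vs[i]) * (-f0) / (f1 - f0))
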