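"""Fixed-step RK4 integration kernel.

Hot loop of the simulator, written against flat float64 arrays so it can be
JIT-compiled with numba when available; falls back to pure Python (slow but
identical numerics) otherwise.  The public API lives in
:mod:`ecpella.sim_engine` — nothing here is part of the package surface.

Parameter vector layout (``CP_*`` indices) and the chamber matrix layout
(rows LA, LV, RA, RV; columns ``CH_*``) are fixed and shared with the
packing helpers in :mod:`ecpella.sim_engine`.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


# circuit-parameter vector indices
(CP_R_MV, CP_R_AV, CP_R_TV, CP_R_PAV,
 CP_R_SZ0, CP_R_PZ0,
 CP_R_SA, CP_R_SC, CP_R_SV, CP_R_PA, CP_R_PC, CP_R_PV,
 CP_C_SA, CP_C_SC, CP_C_SV, CP_C_PA, CP_C_PC, CP_C_PV,
 CP_B_MV, CP_B_AV, CP_B_TV, CP_B_PAV,
 CP_T_CYCLE, CP_FLOOR) = range(24)
N_CP = 24

# chamber matrix columns
CH_EES, CH_EMIN, CH_V0, CH_ALPHA, CH_BETA, CH_ONSET, CH_DUR = range(7)

# output record columns
REC_COLUMNS = ("t",
               "LAP", "LVP", "RAP", "RVP",
               "SAP", "SCP", "SVP", "PAP", "PCP", "PVP",
               "V_LA", "V_LV", "V_RA", "V_RV",
               "Q_impella", "Q_vaecmo", "suction", "Q_AV", "V_total")
N_REC = len(REC_COLUMNS)

# double-Hill activation shape (keep in sync with model_core)
HILL_S1 = 0.303
HILL_M1 = 1.9
HILL_S2 = 0.508
HILL_M2 = 21.9


def _hill_norm() -> float:
    x = np.linspace(0.0, 1.0, 20001)
    h1 = (x / HILL_S1) ** HILL_M1
    h2 = (x / HILL_S2) ** HILL_M2
    return float(np.max((h1 / (1.0 + h1)) / (1.0 + h2)))


HILL_NORM = _hill_norm()

PRESSURE_BLOWUP = 500.0  # mmHg; |P| beyond this aborts the run


@njit(cache=True)
def _activation(phase, onset, dur):
    s = (phase - onset) % 1.0
    if s >= dur:
        return 0.0
    x = s / dur
    if x <= 0.0:
        return 0.0
    h1 = (x / HILL_S1) ** HILL_M1
    h2 = (x / HILL_S2) ** HILL_M2
    return (h1 / (1.0 + h1)) / (1.0 + h2) / HILL_NORM


@njit(cache=True)
def _chamber_p(v, a, ees, v0, alpha, beta):
    return a * ees * (v - v0) + (1.0 - a) * alpha * math.expm1(beta * v)


@njit(cache=True)
def _pressures(V, tc, cp, ch, P):
    # chambers: LA, LV, RA, RV
    for k in range(4):
        a = _activation(tc, ch[k, CH_ONSET], ch[k, CH_DUR])
        P[k] = _chamber_p(V[k], a, ch[k, CH_EES], ch[k, CH_V0],
                          ch[k, CH_ALPHA], ch[k, CH_BETA])
    P[4] = V[4] / cp[CP_C_SA]
    P[5] = V[5] / cp[CP_C_SC]
    P[6] = V[6] / cp[CP_C_SV]
    P[7] = V[7] / cp[CP_C_PA]
    P[8] = V[8] / cp[CP_C_PC]
    P[9] = V[9] / cp[CP_C_PV]


@njit(cache=True)
def _guard(v, floor):
    if v >= floor:
        return 1.0
    if v <= 0.0:
        return 0.0
    return v / floor


@njit(cache=True)
def _q_valve(dp, r, b):
    if dp <= 0.0:
        return 0.0
    return (-r + math.sqrt(r * r + 4.0 * b * dp)) / (2.0 * b)


@njit(cache=True)
def _q_res(p_from, p_to, r, v_from, v_to, floor):
    q = (p_from - p_to) / r
    if q >= 0.0:
        return q * _guard(v_from, floor)
    return q * _guard(v_to, floor)


@njit(cache=True)
def _rhs(V, tc, cp, ch, q_imp, q_ec, P, dV):
    """Fills dV (mL/s); returns aortic-valve flow for recording."""
    _pressures(V, tc, cp, ch, P)
    fl = cp[CP_FLOOR]
    lap, lvp, rap, rvp = P[0], P[1], P[2], P[3]
    sap, scp, svp, pap, pcp, pvp = P[4], P[5], P[6], P[7], P[8], P[9]

    q_mv = _q_valve(lap - lvp, cp[CP_R_MV], cp[CP_B_MV]) * _guard(V[0], fl)
    q_av = _q_valve(lvp - sap, cp[CP_R_AV] + cp[CP_R_SZ0], cp[CP_B_AV]) * _guard(V[1], fl)
    q_tv = _q_valve(rap - rvp, cp[CP_R_TV], cp[CP_B_TV]) * _guard(V[2], fl)
    q_pav = _q_valve(rvp - pap, cp[CP_R_PAV] + cp[CP_R_PZ0], cp[CP_B_PAV]) * _guard(V[3], fl)

    q_sa = _q_res(sap, scp, cp[CP_R_SA], V[4], V[5], fl)
    q_sc = _q_res(scp, svp, cp[CP_R_SC], V[5], V[6], fl)
    q_sv = _q_res(svp, rap, cp[CP_R_SV], V[6], V[2], fl)
    q_pa = _q_res(pap, pcp, cp[CP_R_PA], V[7], V[8], fl)
    q_pc = _q_res(pcp, pvp, cp[CP_R_PC], V[8], V[9], fl)
    q_pv = _q_res(pvp, lap, cp[CP_R_PV], V[9], V[0], fl)

    qi = q_imp * _guard(V[1], fl)
    qe = q_ec * _guard(V[6], fl)

    dV[0] = q_pv - q_mv
    dV[1] = q_mv - q_av - qi
    dV[2] = q_sv - q_tv
    dV[3] = q_tv - q_pav
    dV[4] = q_av + qi + qe - q_sa
    dV[5] = q_sa - q_sc
    dV[6] = q_sc - q_sv - qe
    dV[7] = q_pav - q_pa
    dV[8] = q_pa - q_pc
    dV[9] = q_pc - q_pv
    return q_av


@njit(cache=True)
def _impella_nominal(head, a, b, c):
    if a <= 0.0:
        return 0.0
    h = head if head > 0.0 else 0.0
    if h >= a:
        return 0.0
    if c == 0.0:
        return (a - h) / b
    return (-b + math.sqrt(b * b + 4.0 * c * (a - h))) / (2.0 * c)


@njit(cache=True)
def run_segment(V, t0, n_steps, dt, cp, ch,
                hq_a, hq_b, hq_c, q_ec_lpm, limiter_gain,
                dec, out):
    """Integrate `n_steps` RK4 steps; record every `dec`-th step into `out`.

    Device flows are resolved once per step from the pre-step state and held
    constant across the four RK4 stages.  Returns (n_recorded, status, t_end)
    with status 0 = ok, 1 = pressure blow-up.
    """
    T = cp[CP_T_CYCLE]
    P = np.empty(10)
    Pw = np.empty(10)
    k1 = np.empty(10)
    k2 = np.empty(10)
    k3 = np.empty(10)
    k4 = np.empty(10)
    Vw = np.empty(10)
    q_ec = q_ec_lpm * 1000.0 / 60.0
    j = 0
    t = t0
    for i in range(n_steps):
        t = t0 + i * dt
        tc = (t / T) % 1.0
        _pressures(V, tc, cp, ch, P)
        lap = P[0]
        head = P[4] - P[1]  # SAP - LVP
        q_nom = _impella_nominal(head, hq_a, hq_b, hq_c)
        suction = 0.0
        q_imp_lpm = q_nom
        if lap <= 0.0:
            suction = 1.0
            if lap < 0.0:
                q_imp_lpm = q_nom + limiter_gain * lap
                if q_imp_lpm < 0.0:
                    q_imp_lpm = 0.0
        q_imp = q_imp_lpm * 1000.0 / 60.0

        if i % dec == 0:
            q_av = _rhs(V, tc, cp, ch, q_imp, q_ec, Pw, k1)
            out[j, 0] = t
            for m in range(10):
                out[j, 1 + m] = P[m]
            for m in range(4):
                out[j, 11 + m] = V[m]
            out[j, 15] = q_imp_lpm * _guard(V[1], cp[CP_FLOOR])
            out[j, 16] = q_ec_lpm * _guard(V[6], cp[CP_FLOOR])
            out[j, 17] = suction
            out[j, 18] = q_av
            vtot = 0.0
            for m in range(10):
                vtot += V[m]
            out[j, 19] = vtot
            j += 1
            for m in range(10):
                if abs(P[m]) > PRESSURE_BLOWUP:
                    return j, 1, t

        # RK4 with frozen device flows
        _rhs(V, tc, cp, ch, q_imp, q_ec, Pw, k1)
        tc2 = ((t + 0.5 * dt) / T) % 1.0
        for m in range(10):
            Vw[m] = V[m] + 0.5 * dt * k1[m]
        _rhs(Vw, tc2, cp, ch, q_imp, q_ec, Pw, k2)
        for m in range(10):
            Vw[m] = V[m] + 0.5 * dt * k2[m]
        _rhs(Vw, tc2, cp, ch, q_imp, q_ec, Pw, k3)
        tc3 = ((t + dt) / T) % 1.0
        for m in range(10):
            Vw[m] = V[m] + dt * k3[m]
        _rhs(Vw, tc3, cp, ch, q_imp, q_ec, Pw, k4)
        for m in range(10):
            V[m] += dt / 6.0 * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])

    return j, 0, t0 + n_steps * dt


@njit(cache=True)
def sample_state(V, t, cp, ch, hq_a, hq_b, hq_c, q_ec_lpm, limiter_gain, out_row):
    """Record a single sample (same columns as run_segment) without stepping."""
    T = cp[CP_T_CYCLE]
    P = np.empty(10)
    dV = np.empty(10)
    tc = (t / T) % 1.0
    _pressures(V, tc, cp, ch, P)
    lap = P[0]
    head = P[4] - P[1]
    q_nom = _impella_nominal(head, hq_a, hq_b, hq_c)
    suction = 0.0
    q_imp_lpm = q_nom
    if lap <= 0.0:
        suction = 1.0
        if lap < 0.0:
            q_imp_lpm = max(0.0, q_nom + limiter_gain * lap)
    q_imp = q_imp_lpm * 1000.0 / 60.0
    q_ec = q_ec_lpm * 1000.0 / 60.0
    q_av = _rhs(V, tc, cp, ch, q_imp, q_ec, P, dV)
    out_row[0] = t
    _pressures(V, tc, cp, ch, P)
    for m in range(10):
        out_row[1 + m] = P[m]
    for m in range(4):
        out_row[11 + m] = V[m]
    out_row[15] = q_imp_lpm * _guard(V[1], cp[CP_FLOOR])
    out_row[16] = q_ec_lpm * _guard(V[6], cp[CP_FLOOR])
    out_row[17] = suction
    out_row[18] = q_av
    vtot = 0.0
    for m in range(10):
        vtot += V[m]
    out_row[19] = vtot
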