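"""Closed-loop lumped-parameter circulation model.

The circulation is a ten-compartment closed loop: four cardiac chambers
(LA, LV, RA, RV) described by time-varying elastances with unidirectional
Bernoulli valves, and two 5-element resistance–capacitance networks for the
systemic and pulmonary vascular beds.  Compartment volumes are the state;
pressures follow from elastance/compliance relations and flows from the
resistive/orifice elements, so the loop conserves volume exactly.

Mechanical-support flows (Impella: LV -> systemic artery; VA-ECMO: systemic
vein -> systemic artery) enter the volume balance as externally resolved
source/sink terms, see :mod:`ecpella.mcs_devices`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np

from . import units

__all__ = [
    "CircuitParams",
    "ChamberParams",
    "SimState",
    "ScenarioPreset",
    "activation",
    "elastance_waveform",
    "chamber_pressure",
    "valve_flow",
    "compartment_pressures",
    "circulation_rhs",
    "CHAMBER_ORDER",
    "STATE_ORDER",
    "PRESSURE_ORDER",
]

# State vector layout (indices into SimState.as_array()).
STATE_ORDER = ("V_LA", "V_LV", "V_RA", "V_RV",
               "V_SA", "V_SC", "V_SV", "V_PA", "V_PC", "V_PV")
CHAMBER_ORDER = ("LA", "LV", "RA", "RV")
PRESSURE_ORDER = ("LAP", "LVP", "RAP", "RVP",
                  "SAP", "SCP", "SVP", "PAP", "PCP", "PVP")

# Double-Hill activation shape constants (dimensionless, on the local
# normalized activation time x in [0, 1)).  The product of an ascending and
# a descending Hill function gives a smooth C1 twitch; the normalization
# constant below rescales its peak to exactly 1.
_HILL_S1 = 0.303
_HILL_M1 = 1.9
_HILL_S2 = 0.508
_HILL_M2 = 21.9


def _hill_raw(x: np.ndarray | float):
    h1 = (x / _HILL_S1) ** _HILL_M1
    h2 = (x / _HILL_S2) ** _HILL_M2
    return (h1 / (1.0 + h1)) * (1.0 / (1.0 + h2))


_HILL_NORM: float = float(np.max(_hill_raw(np.linspace(0.0, 1.0, 20001))))


@dataclass(frozen=True)
class ChamberParams:
    """Elastance and pressure-volume constants of one cardiac chamber.

    Activation timing is expressed as fractions of the cardiac cycle with
    phase 0 at ventricular activation onset; atrial onsets are late in the
    cycle so the atrial kick precedes the next ventricular systole.
    """

    role: str                      # one of CHAMBER_ORDER
    E_es: float                    # end-systolic elastance, mmHg/mL
    E_min: float                   # minimal (diastolic) elastance, mmHg/mL
    V0: float                      # ESPVR volume intercept, mL
    edpvr_alpha: float             # EDPVR scale, mmHg
    edpvr_beta: float              # EDPVR exponent, 1/mL
    t_activation_onset: float      # fraction of cycle
    t_activation_duration: float   # fraction of cycle

    def __post_init__(self) -> None:
        if self.role not in CHAMBER_ORDER:
            raise ValueError(f"unknown chamber role {self.role!r}")
        if not (self.E_es >= self.E_min > 0.0):
            raise ValueError(
                f"{self.role}: requires E_es >= E_min > 0, "
                f"got E_es={self.E_es}, E_min={self.E_min}")
        if self.edpvr_alpha < 0.0 or self.edpvr_beta <= 0.0:
            raise ValueError(f"{self.role}: EDPVR constants must be positive")
        if not (0.0 < self.t_activation_duration < 1.0):
            raise ValueError(f"{self.role}: activation duration must be in (0,1)")

    def edpvr_pressure(self, volume: float) -> float:
        """End-diastolic pressure at `volume` (passes through the origin)."""
        return self.edpvr_alpha * math.expm1(self.edpvr_beta * volume)

    def espvr_pressure(self, volume: float) -> float:
        """End-systolic pressure at `volume` (linear ESPVR)."""
        return self.E_es * (volume - self.V0)


@dataclass(frozen=True)
class CircuitParams:
    """Every resistive/capacitive constant of the closed loop.

    Resistances in mmHg·s/mL, compliances in mL/mmHg, valve areas in cm²,
    heart rate in beats/min, total stressed volume in mL, blood density in
    g/mL.
    """

    R_MV: float
    R_AV: float
    R_TV: float
    R_PAV: float
    R_SZ0: float
    R_PZ0: float
    R_SA: float
    R_SC: float
    R_SV: float
    R_PA: float
    R_PC: float
    R_PV: float
    C_SA: float
    C_SC: float
    C_SV: float
    C_PA: float
    C_PC: float
    C_PV: float
    A_MV: float
    A_AV: float
    A_TV: float
    A_PAV: float
    HR: float
    V_total: float
    rho: float = 1.05

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"CircuitParams.{name} must be strictly positive")

    @property
    def cycle_length(self) -> float:
        """Cardiac cycle length in seconds."""
        return 60.0 / self.HR

    @property
    def svr_wood_units(self) -> float:
        """Systemic vascular resistance in WU, clinical definition:
        mean-gradient resistances (artery + capillary + vein), excluding the
        characteristic impedance, which only carries the pulsatile drop."""
        return units.internal_to_wood_units(self.R_SA + self.R_SC + self.R_SV)

    @property
    def pvr_wood_units(self) -> float:
        """Pulmonary vascular resistance in WU (clinical definition, cf. SVR)."""
        return units.internal_to_wood_units(self.R_PA + self.R_PC + self.R_PV)


@dataclass
class SimState:
    """Instantaneous compartment volumes (mL) at time t (s)."""

    V_LA: float
    V_LV: float
    V_RA: float
    V_RV: float
    V_SA: float
    V_SC: float
    V_SV: float
    V_PA: float
    V_PC: float
    V_PV: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_ORDER], dtype=float)

    @classmethod
    def from_array(cls, v: np.ndarray, t: float = 0.0) -> "SimState":
        return cls(*(float(x) for x in v), t=t)

    @property
    def total_volume(self) -> float:
        return float(sum(getattr(self, n) for n in STATE_ORDER))


@dataclass(frozen=True)
class ScenarioPreset:
    """Headline scenario knobs applied on top of the full default parameter set."""

    name: str                      # NORMAL, LVF, BVF or BVF_PH
    LV_Ees: float                  # mmHg/mL
    RV_Ees: float                  # mmHg/mL
    PVR_WU: float                  # Wood units
    SVR_WU: float                  # Wood units

    @property
    def Zc_scale(self) -> float:
        """Pulmonary characteristic impedance scales linearly with PVR."""
        return self.PVR_WU / 0.8


def activation(t_cycle: float, chamber: ChamberParams) -> float:
    """Normalized activation a(t) in [0, 1] at cycle phase `t_cycle`.

    Double-Hill twitch confined to the chamber's activation window; zero
    elsewhere.  Phase is wrapped modulo 1, so any real argument is valid.
    """
    phase = (t_cycle - chamber.t_activation_onset) % 1.0
    if phase >= chamber.t_activation_duration:
        return 0.0
    x = phase / chamber.t_activation_duration
    return float(_hill_raw(x)) / _HILL_NORM


def elastance_waveform(t_cycle: float, chamber: ChamberParams) -> float:
    """Instantaneous elastance E(t) = E_min + a(t)·(E_es − E_min), mmHg/mL."""
    a = activation(t_cycle, chamber)
    return chamber.E_min + a * (chamber.E_es - chamber.E_min)


def chamber_pressure(V: float, e_t: float, chamber: ChamberParams) -> float:
    """Chamber pressure from the activation-weighted ESPVR/EDPVR blend.

    ``P = a·E_es·(V − V0) + (1 − a)·P_ed(V)`` with
    ``a = (e_t − E_min)/(E_es − E_min)``; at full activation this is the
    ESPVR line, at zero activation the exponential EDPVR.  Transiently
    negative pressures are permitted (e.g. during suction).
    """
    if chamber.E_es == chamber.E_min:
        a = 1.0
    else:
        a = (e_t - chamber.E_min) / (chamber.E_es - chamber.E_min)
    return a * chamber.espvr_pressure(V) + (1.0 - a) * chamber.edpvr_pressure(V)


def valve_flow(P_up: float, P_down: float, A: float, R_valve: float,
               rho: float = 1.05) -> float:
    """Unidirectional orifice flow (mL/s) through a cardiac valve.

    Solves ``dP = R·Q + B·Q²`` for Q ≥ 0, with the Bernoulli coefficient
    ``B = rho/(2·(k·A)²)`` where k absorbs the mmHg/CGS conversion (see
    :func:`ecpella.units.bernoulli_coefficient`).  Returns 0 for any
    non-positive gradient.
    """
    dp = P_up - P_down
    if dp <= 0.0:
        return 0.0
    if A <= 0.0:
        raise ValueError("valve orifice area must be positive")
    b = units.bernoulli_coefficient(A, rho)
    if b < 1e-15:
        return dp / R_valve
    # positive root of B·Q² + R·Q − dp = 0
    return (-R_valve + math.sqrt(R_valve * R_valve + 4.0 * b * dp)) / (2.0 * b)


def compartment_pressures(state: SimState, params: CircuitParams,
                          chambers: Mapping[str, ChamberParams],
                          t: float | None = None) -> Dict[str, float]:
    """All ten compartment pressures (mmHg) at simulation time `t`.

    Chamber pressures use the time-varying elastance blend; vascular
    pressures are linear, ``P_X = V_X / C_X``.
    """
    if t is None:
        t = state.t
    t_cycle = (t / params.cycle_length) % 1.0
    p: Dict[str, float] = {}
    for role, pname, vname in (("LA", "LAP", "V_LA"), ("LV", "LVP", "V_LV"),
                               ("RA", "RAP", "V_RA"), ("RV", "RVP", "V_RV")):
        ch = chambers[role]
        e_t = elastance_waveform(t_cycle, ch)
        p[pname] = chamber_pressure(getattr(state, vname), e_t, ch)
    p["SAP"] = state.V_SA / params.C_SA
    p["SCP"] = state.V_SC / params.C_SC
    p["SVP"] = state.V_SV / params.C_SV
    p["PAP"] = state.V_PA / params.C_PA
    p["PCP"] = state.V_PC / params.C_PC
    p["PVP"] = state.V_PV / params.C_PV
    return p


def _outflow_guard(V: float, floor: float) -> float:
    """Linear throttle of outflows as a compartment approaches emptiness."""
    if V >= floor:
        return 1.0
    if V <= 0.0:
        return 0.0
    return V / floor


def _resistive_flow(p_from: float, p_to: float, r: float,
                    v_from: float, v_to: float, floor: float) -> float:
    """Bidirectional resistive flow, throttled on its source side."""
    q = (p_from - p_to) / r
    if q >= 0.0:
        return q * _outflow_guard(v_from, floor)
    return q * _outflow_guard(v_to, floor)


def circulation_rhs(state: SimState, params: CircuitParams,
                    chambers: Mapping[str, ChamberParams],
                    q_impella_mls: float = 0.0, q_vaecmo_mls: float = 0.0,
                    t: float | None = None,
                    volume_floor: float = 1.0) -> Tuple[np.ndarray, Dict[str, float]]:
    """Time derivative of all compartment volumes (mL/s).

    Device flows must already be resolved (mL/s): Impella withdraws from the
    LV and returns to the systemic artery; VA-ECMO withdraws from the
    systemic vein and returns to the systemic artery.  Every flow appears in
    exactly one inflow and one outflow term, so the derivatives sum to zero
    identically.  Returns ``(dV, flows)`` with the named element flows for
    diagnostics.
    """
    if t is None:
        t = state.t
    p = compartment_pressures(state, params, chambers, t)
    fl = volume_floor

    q_mv = valve_flow(p["LAP"], p["LVP"], params.A_MV, params.R_MV,
                      params.rho) * _outflow_guard(state.V_LA, fl)
    # characteristic impedances sit in series with the semilunar valves
    q_av = valve_flow(p["LVP"], p["SAP"], params.A_AV, params.R_AV + params.R_SZ0,
                      params.rho) * _outflow_guard(state.V_LV, fl)
    q_tv = valve_flow(p["RAP"], p["RVP"], params.A_TV, params.R_TV,
                      params.rho) * _outflow_guard(state.V_RA, fl)
    q_pav = valve_flow(p["RVP"], p["PAP"], params.A_PAV, params.R_PAV + params.R_PZ0,
                       params.rho) * _outflow_guard(state.V_RV, fl)

    q_sa = _resistive_flow(p["SAP"], p["SCP"], params.R_SA, state.V_SA, state.V_SC, fl)
    q_sc = _resistive_flow(p["SCP"], p["SVP"], params.R_SC, state.V_SC, state.V_SV, fl)
    q_sv = _resistive_flow(p["SVP"], p["RAP"], params.R_SV, state.V_SV, state.V_RA, fl)
    q_pa = _resistive_flow(p["PAP"], p["PCP"], params.R_PA, state.V_PA, state.V_PC, fl)
    q_pc = _resistive_flow(p["PCP"], p["PVP"], params.R_PC, state.V_PC, state.V_PV, fl)
    q_pv = _resistive_flow(p["PVP"], p["LAP"], params.R_PV, state.V_PV, state.V_LA, fl)

    q_imp = q_impella_mls * _outflow_guard(state.V_LV, fl)
    q_ec = q_vaecmo_mls * _outflow_guard(state.V_SV, fl)

    dV = np.array([
        q_pv - q_mv,                    # V_LA
        q_mv - q_av - q_imp,            # V_LV
        q_sv - q_tv,                    # V_RA
        q_tv - q_pav,                   # V_RV
        q_av + q_imp + q_ec - q_sa,     # V_SA
        q_sa - q_sc,                    # V_SC
        q_sc - q_sv - q_ec,             # V_SV
        q_pav - q_pa,                   # V_PA
        q_pa - q_pc,                    # V_PC
        q_pc - q_pv,                    # V_PV
    ])
    flows = {"Q_MV": q_mv, "Q_AV": q_av, "Q_TV": q_tv, "Q_PAV": q_pav,
             "Q_SA": q_sa, "Q_SC": q_sc, "Q_SV": q_sv,
             "Q_PA": q_pa, "Q_PC": q_pc, "Q_PV": q_pv,
             "Q_impella": q_imp, "Q_vaecmo": q_ec}
    return dV, flows
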