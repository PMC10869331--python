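"""Unit conversions used throughout the simulator.

Internal working units are mmHg, mL and seconds.  Vascular resistances are
quoted clinically in Wood units (1 WU = 1 mmHg·min/L) and pump flows in
L/min; everything is converted here, in one place.
"""

from __future__ import annotations

#: 1 Wood unit expressed in internal resistance units (mmHg·s/mL).
#: 1 mmHg·min/L = 60 s / 1000 mL = 0.06 mmHg·s/mL.
WU_TO_MMHG_S_PER_ML = 60.0 / 1000.0

#: 1 mmHg in CGS pressure units (dyn/cm^2); used by the Bernoulli orifice law.
MMHG_TO_DYN_PER_CM2 = 1333.22

#: O2 carrying capacity of haemoglobin (mL O2 per g Hb), Hufner's constant.
HUFNER_ML_O2_PER_G_HB = 1.34


def wood_units_to_internal(r_wu: float) -> float:
    """Convert a resistance from Wood units to mmHg·s/mL."""
    return r_wu * WU_TO_MMHG_S_PER_ML


def internal_to_wood_units(r: float) -> float:
    """Convert a resistance from mmHg·s/mL to Wood units."""
    return r / WU_TO_MMHG_S_PER_ML


def lpm_to_mls(q_lpm: float) -> float:
    """Convert a flow from L/min to mL/s."""
    return q_lpm * 1000.0 / 60.0


def mls_to_lpm(q_mls: float) -> float:
    """Convert a flow from mL/s to L/min."""
    return q_mls * 60.0 / 1000.0


def bernoulli_coefficient(area_cm2: float, rho_g_per_ml: float) -> float:
    """Quadratic loss coefficient B (mmHg·s²/mL²) of an orifice.

    The orifice relation is ``dP = R·Q + B·Q²`` with Q in mL/s.  From
    Bernoulli, ``dP = rho/2 · (Q/A)²`` in CGS units; dividing by
    :data:`MMHG_TO_DYN_PER_CM2` converts the pressure to mmHg.
    """
    return rho_g_per_ml / (2.0 * area_cm2 * area_cm2 * MMHG_TO_DYN_PER_CM2)
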