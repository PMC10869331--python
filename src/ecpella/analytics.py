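"""Per-beat haemodynamic indices: PV loops, stroke work, PVA, flows, DO2.

Stroke work is the shoelace area of the sampled pressure-volume loop.
Pressure-volume area adds the potential-energy triangle between the linear
end-systolic and the exponential end-diastolic pressure-volume relations,
trapezoid-integrated on a fine volume grid.  Global oxygen delivery sums
the native-lung pathway (CO + Impella flow at arterial saturation) and the
fully saturated VA-ECMO pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .mcs_devices import DeviceSettings, effective_sao2
from .model_core import ChamberParams
from .sim_engine import TimeSeries

__all__ = ["PVLoop", "BeatSummary", "stroke_work", "pressure_volume_area",
           "beat_summary", "global_do2", "loops_from_beat"]

_PE_GRID_STEP = 0.1  # mL, trapezoid grid for the potential-energy integral


@dataclass
class PVLoop:
    """Ordered (volume, pressure) samples of one beat for one ventricle."""

    volume: np.ndarray        # mL
    pressure: np.ndarray      # mmHg
    ventricle: str            # "LV" or "RV"

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.volume.shape != self.pressure.shape or self.volume.ndim != 1:
            raise ValueError("volume and pressure must be 1-D arrays of equal length")
        if self.ventricle not in ("LV", "RV"):
            raise ValueError("ventricle must be 'LV' or 'RV'")

    @property
    def n_points(self) -> int:
        return len(self.volume)

    def closed(self) -> "PVLoop":
        """A closed copy: the first point appended as the final one.

        The shoelace rule wraps the final edge either way, so this changes
        nothing for an already-closed loop; for a beat cut from a still
        drifting (non-converged) run it makes the sampled polygon explicit.
        """
        if self.is_closed():
            return self
        return PVLoop(np.append(self.volume, self.volume[0]),
                      np.append(self.pressure, self.pressure[0]),
                      self.ventricle)

    def is_closed(self, rtol: float = 3.0) -> bool:
        """Closed if first and last points are within `rtol` sample-travels
        (or within 2 % of the loop's excursion, whichever is larger — the
        latter covers quasi-static loops whose per-sample travel is tiny)."""
        if self.n_points < 3:
            return False
        dv = np.abs(np.diff(self.volume)).max()
        dp = np.abs(np.diff(self.pressure)).max()
        # absolute floors (0.5 mL / 0.5 mmHg) admit the slowly creeping
        # quasi-static loops seen under suction, where the per-beat drift is
        # comparable to the (tiny) loop excursion itself
        tol_v = max(rtol * dv, 0.02 * np.ptp(self.volume), 0.5)
        tol_p = max(rtol * dp, 0.02 * np.ptp(self.pressure), 0.5)
        return (abs(self.volume[0] - self.volume[-1]) <= tol_v
                and abs(self.pressure[0] - self.pressure[-1]) <= tol_p)


@dataclass
class BeatSummary:
    """Steady-state indices of one beat under one device setting."""

    CO: float                   # L/min, native trans-aortic-valve output
    total_systemic_flow: float  # L/min = CO + Impella + VA-ECMO
    mean_AP: float              # mmHg
    mean_RAP: float             # mmHg
    mean_LAP: float             # mmHg
    LVEDP: float                # mmHg
    SW_LV: float                # mmHg·mL
    SW_RV: float                # mmHg·mL
    PVA_LV: float               # mmHg·mL
    PVA_RV: float               # mmHg·mL
    suction: bool
    Q_impella: float            # L/min
    Q_vaecmo: float             # L/min


def stroke_work(loop: PVLoop) -> float:
    """Loop area |∮ P dV| (mmHg·mL) by the shoelace rule; requires a closed loop."""
    if not loop.is_closed():
        raise ValueError("PV loop is not closed")
    v, p = loop.volume, loop.pressure
    # shoelace over the closed polygon (wraps the final edge)
    area = 0.5 * np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p)
    return float(abs(area))


def pressure_volume_area(loop: PVLoop, chamber: ChamberParams) -> float:
    """PVA = stroke work + potential energy (mmHg·mL).

    The potential energy is the region bounded by the ESPVR above, the EDPVR
    below, from V0 to the end-systolic volume; integrated with the trapezoid
    rule at 0.1 mL resolution.  If the end-systolic volume does not exceed
    V0 the potential energy is zero (with a warning-level note via return).
    """
    sw = stroke_work(loop)
    v_es = float(np.min(loop.volume))
    if v_es <= chamber.V0:
        return sw
    grid = np.arange(chamber.V0, v_es + _PE_GRID_STEP, _PE_GRID_STEP)
    grid[-1] = min(grid[-1], v_es)
    espvr = chamber.E_es * (grid - chamber.V0)
    edpvr = chamber.edpvr_alpha * np.expm1(chamber.edpvr_beta * grid)
    integrand = np.clip(espvr - edpvr, 0.0, None)
    pe = float(np.trapezoid(integrand, grid))
    return sw + pe


def loops_from_beat(beat: TimeSeries) -> dict[str, PVLoop]:
    """Extract the LV and RV pressure-volume loops from one beat window."""
    return {
        "LV": PVLoop(beat.column("V_LV"), beat.column("LVP"), "LV"),
        "RV": PVLoop(beat.column("V_RV"), beat.column("RVP"), "RV"),
    }


def beat_summary(beat: TimeSeries, settings: DeviceSettings,
                 chambers=None) -> BeatSummary:
    """Summarize one complete beat.

    CO is the time-average of the trans-aortic-valve flow (Impella excluded,
    making zero CO under total support literal); mean pressures are plain
    time-averages; LVEDP is the LV pressure at maximal LV volume; suction is
    true if LAP reached 0 mmHg at any sample.
    """
    co = units.mls_to_lpm(float(np.mean(beat.column("Q_AV"))))
    q_imp = float(np.mean(beat.column("Q_impella")))
    q_ec = float(np.mean(beat.column("Q_vaecmo")))
    vlv = beat.column("V_LV")
    lvp = beat.column("LVP")
    # beats cut from a not-yet-converged window may drift open; summaries
    # are still produced (the cell carries its convergence flag)
    loops = {k: lp.closed() for k, lp in loops_from_beat(beat).items()}
    if chambers is not None:
        pva_lv = pressure_volume_area(loops["LV"], chambers["LV"])
        pva_rv = pressure_volume_area(loops["RV"], chambers["RV"])
    else:
        pva_lv = float("nan")
        pva_rv = float("nan")
    return BeatSummary(
        CO=co,
        total_systemic_flow=co + q_imp + q_ec,
        mean_AP=float(np.mean(beat.column("SAP"))),
        mean_RAP=float(np.mean(beat.column("RAP"))),
        mean_LAP=float(np.mean(beat.column("LAP"))),
        LVEDP=float(lvp[int(np.argmax(vlv))]),
        SW_LV=stroke_work(loops["LV"]),
        SW_RV=stroke_work(loops["RV"]),
        PVA_LV=pva_lv,
        PVA_RV=pva_rv,
        suction=bool(np.any(beat.column("suction") > 0)
                     | np.any(beat.column("LAP") <= 0.0)),
        Q_impella=q_imp,
        Q_vaecmo=q_ec,
    )


def global_do2(Hb: float, SaO2: float, CO: float,
               Q_impella: float, Q_vaecmo: float) -> float:
    """Global oxygen delivery (mL O2/min).

    ``DO2 = 1.34 · 10 · Hb · SaO2 · (CO + Q_impella)
           + 1.34 · 10 · Hb · 1.0 · Q_vaecmo``
    with Hb in g/dL and flows in L/min; the factor 10 converts g/dL to g/L.
    The VA-ECMO pathway is fully oxygenated (saturation 1.0).
    """
    for name, v in (("Hb", Hb), ("CO", CO),
                    ("Q_impella", Q_impella), ("Q_vaecmo", Q_vaecmo)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if not 0.0 <= SaO2 <= 1.0:
        raise ValueError(f"SaO2 must be in [0, 1], got {SaO2}")
    k = units.HUFNER_ML_O2_PER_G_HB * 10.0 * Hb
    return k * SaO2 * (CO + Q_impella) + k * 1.0 * Q_vaecmo


def do2_for_settings(summary: BeatSummary, settings: DeviceSettings) -> float:
    """DO2 for a summarized beat under given device/oxygenation settings."""
    return global_do2(settings.Hb, effective_sao2(settings),
                      summary.CO, summary.Q_impella, summary.Q_vaecmo)
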