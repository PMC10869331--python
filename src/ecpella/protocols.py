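"""The four published protocol sweeps, end to end.

Each protocol sweeps VA-ECMO flow (0-5 L/min in 0.5 steps; protocol 4 caps
at 4 L/min) against the in-run Impella staircase P0-P9.  One simulation is
run per ECMO flow: a device-free settling segment at P0 followed by one
segment per level, exactly the published in-run design.  Per-cell summaries
are extracted from the steady-state window ending 2 s before each level
change.

Protocols: 1 = LVF, 2 = BVF, 3 = BVF with pulmonary hypertension,
4 = BVF and BVF_PH with the oxygenation scenario (Hb 10 g/dL, native
SaO2 40 % vs VV-ECMO 80 %) and global DO2 appended per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .analytics import beat_summary, global_do2
from .mcs_devices import DeviceSettings, HQCurve, effective_sao2
from .presets import Scenario, get_scenario, initial_state
from .sim_engine import (ProtocolSchedule, build_protocol_schedule, config_hash,
                         extract_steady_snapshots, run_simulation,
                         DEFAULT_SETTLE_INITIAL, DEFAULT_SETTLE_PER_LEVEL,
                         DEFAULT_DT)

__all__ = ["SweepResult", "run_protocol", "run_sweep", "max_impella_flow",
           "PROTOCOL_SCENARIOS", "ecmo_grid"]

PROTOCOL_SCENARIOS: Dict[int, List[str]] = {
    1: ["LVF"],
    2: ["BVF"],
    3: ["BVF_PH"],
    4: ["BVF", "BVF_PH"],
}

SUMMARY_COLUMNS = ["scenario", "vaecmo_flow", "impella_level",
                   "CO", "total_systemic_flow", "mean_AP", "mean_RAP",
                   "mean_LAP", "LVEDP", "SW_LV", "SW_RV", "PVA_LV", "PVA_RV",
                   "suction", "Q_impella", "Q_vaecmo", "converged"]


@dataclass
class SweepResult:
    """Complete grid of per-setting beat summaries for one protocol."""

    protocol: int
    scenarios: List[str]
    table: pd.DataFrame                      # one row per (scenario, ecmo, level)
    provenance: Dict[str, object] = field(default_factory=dict)

    def grid_shape(self, scenario: str) -> tuple:
        sub = self.table[self.table["scenario"] == scenario]
        return (sub["vaecmo_flow"].nunique(), sub["impella_level"].nunique())


def ecmo_grid(protocol: int) -> List[float]:
    """The protocol's VA-ECMO axis (L/min)."""
    top = 4.0 if protocol == 4 else 5.0
    return [round(0.5 * i, 1) for i in range(int(top / 0.5) + 1)]


def run_sweep(scenario: Scenario,
              ecmo_flows: Sequence[float],
              settle_initial: float = DEFAULT_SETTLE_INITIAL,
              settle_per_level: float = DEFAULT_SETTLE_PER_LEVEL,
              dt: float = DEFAULT_DT,
              hq_curve: Optional[HQCurve] = None,
              device_template: Optional[DeviceSettings] = None,
              extend_until_converged: int = 2) -> pd.DataFrame:
    """Run the Impella staircase once per ECMO flow and summarize every cell.

    If any segment's steady-state window fails the 1 % beat-to-beat
    convergence check, the whole run is retried with doubled settling times,
    up to `extend_until_converged` times.
    """
    if hq_curve is None:
        hq_curve = HQCurve.default()
    if device_template is None:
        device_template = DeviceSettings()
    rows = []
    for ecmo in ecmo_flows:
        s_init, s_level = settle_initial, settle_per_level
        for attempt in range(extend_until_converged + 1):
            sched = build_protocol_schedule(ecmo, s_init, s_level,
                                            device_template=device_template, dt=dt)
            st = initial_state(scenario)
            ts = run_simulation(scenario.params, scenario.chambers, sched, st,
                                hq_curve=hq_curve,
                                limiter_gain=scenario.devices["limiter_gain"],
                                volume_floor=scenario.engine["volume_floor"],
                                decimation=scenario.engine["decimation"])
            snaps = extract_steady_snapshots(ts, sched,
                                             scenario.params.cycle_length)
            if all(s.converged for s in snaps) or attempt == extend_until_converged:
                break
            s_init, s_level = 2.0 * s_init, 2.0 * s_level
        for snap in snaps:
            summ = beat_summary(snap.window, snap.settings, scenario.chambers)
            rows.append({"scenario": scenario.preset.name,
                         "vaecmo_flow": ecmo,
                         "impella_level": snap.settings.impella_level,
                         "converged": snap.converged,
                         **{k: getattr(summ, k) for k in
                            ("CO", "total_systemic_flow", "mean_AP", "mean_RAP",
                             "mean_LAP", "LVEDP", "SW_LV", "SW_RV",
                             "PVA_LV", "PVA_RV", "suction",
                             "Q_impella", "Q_vaecmo")}})
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def run_protocol(n: int,
                 settle_initial: float = DEFAULT_SETTLE_INITIAL,
                 settle_per_level: float = DEFAULT_SETTLE_PER_LEVEL,
                 dt: float = DEFAULT_DT,
                 hq_curve: Optional[HQCurve] = None) -> SweepResult:
    """Run one of the four published protocol sweeps.

    Defaults reproduce the published schedule (100 s settling + 50 s per
    level = 550 s per ECMO flow); pass reduced settling for desk-scale runs.
    """
    if n not in PROTOCOL_SCENARIOS:
        raise ValueError(f"protocol must be 1-4, got {n!r}")
    flows = ecmo_grid(n)
    tables = []
    scenarios = PROTOCOL_SCENARIOS[n]
    for name in scenarios:
        scenario = get_scenario(name)
        if n == 4:
            template = DeviceSettings(Hb=10.0, SaO2_native=0.40, SaO2_vv=0.80)
        else:
            template = DeviceSettings()
        table = run_sweep(scenario, flows, settle_initial, settle_per_level,
                          dt=dt, hq_curve=hq_curve, device_template=template)
        if n == 4:
            # DO2 per cell, with and without VV-ECMO oxygenation
            for vv, col in ((False, "DO2_native"), (True, "DO2_vv")):
                sett = DeviceSettings(Hb=10.0, SaO2_native=0.40, SaO2_vv=0.80,
                                      vvecmo_on=vv)
                sao2 = effective_sao2(sett)
                table[col] = [
                    global_do2(sett.Hb, sao2, r.CO, r.Q_impella, r.Q_vaecmo)
                    for r in table.itertuples()]
        tables.append(table)
    table = pd.concat(tables, ignore_index=True)
    prov = {"protocol": n,
            "settle_initial": settle_initial,
            "settle_per_level": settle_per_level,
            "dt": dt,
            "hash": config_hash({"protocol": n, "settle": [settle_initial,
                                                           settle_per_level],
                                 "dt": dt, "scenarios": scenarios})}
    return SweepResult(protocol=n, scenarios=scenarios, table=table,
                       provenance=prov)


def max_impella_flow(result: SweepResult,
                     scenario: Optional[str] = None) -> pd.Series:
    """Per-ECMO-flow maximum steady Impella flow (L/min) across levels P0-P9."""
    t = result.table
    if scenario is not None:
        t = t[t["scenario"] == scenario]
    return t.groupby("vaecmo_flow")["Q_impella"].max()
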