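"""Scenario presets: full parameter files and their resolution to model objects.

Four presets ship with the package (normal.yaml, lvf.yaml, bvf.yaml,
bvf_ph.yaml).  The headline scenario values — ventricular end-systolic
elastances, SVR/PVR in Wood units and heart rate — follow the published
cardiogenic-shock settings; every other circuit constant is a documented
physiologically standard default, calibrated so the NORMAL preset produces a
sane resting circulation (CO 4-6 L/min, mean arterial pressure 70-110 mmHg).

Total vascular resistances are specified in Wood units and split across the
individual elements by fixed fractions (characteristic impedance about 5 %
of the total), so the pulmonary characteristic impedance scales linearly
with PVR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict

import yaml

from . import units
from .model_core import (ChamberParams, CircuitParams, ScenarioPreset,
                         SimState, CHAMBER_ORDER)

__all__ = ["PRESET_NAMES", "SCHEMA_VERSION", "load_preset_dict",
           "build_scenario", "initial_state", "Scenario"]

PRESET_NAMES = ("NORMAL", "LVF", "BVF", "BVF_PH")
SCHEMA_VERSION = 1

_RESISTANCE_SPLIT_KEYS = {
    "svr_split": ("SA", "SC", "SV"),
    "pvr_split": ("PA", "PC", "PV"),
}


@dataclass
class Scenario:
    """A fully resolved simulation scenario."""

    preset: ScenarioPreset
    params: CircuitParams
    chambers: Dict[str, ChamberParams]
    engine: Dict[str, float]
    devices: Dict[str, float]
    raw: dict = field(repr=False, default_factory=dict)


def _preset_path(name: str) -> Path:
    fname = name.lower() + ".yaml"
    return resources.files("ecpella._data") / fname  # type: ignore[return-value]


def load_preset_dict(name_or_path: str | Path) -> dict:
    """Load a preset by name (NORMAL/LVF/BVF/BVF_PH) or from a YAML path."""
    if isinstance(name_or_path, str) and name_or_path.upper() in PRESET_NAMES:
        with resources.as_file(_preset_path(name_or_path.upper())) as p:
            text = p.read_text(encoding="utf-8")
    else:
        text = Path(name_or_path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    version = cfg.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported preset schema_version {version!r}")
    return cfg


def build_scenario(cfg: dict) -> Scenario:
    """Resolve a preset dictionary into validated model parameter objects."""
    circ = cfg["circuit"]
    heart = cfg["heart"]

    for split_key, elements in _RESISTANCE_SPLIT_KEYS.items():
        split = circ[split_key]
        total = sum(split[e] for e in elements)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{split_key} fractions must sum to 1, got {total}")

    svr = units.wood_units_to_internal(circ["SVR_WU"])
    pvr = units.wood_units_to_internal(circ["PVR_WU"])
    ss, ps = circ["svr_split"], circ["pvr_split"]
    valves = circ["valves"]
    comp = circ["compliances"]

    # characteristic impedances are not part of the clinically defined
    # (mean-pressure-gradient) resistances; they scale linearly with them
    params = CircuitParams(
        R_MV=valves["R_MV"], R_AV=valves["R_AV"],
        R_TV=valves["R_TV"], R_PAV=valves["R_PAV"],
        R_SZ0=circ["zc_fraction_systemic"] * svr,
        R_PZ0=circ["zc_fraction_pulmonary"] * pvr,
        R_SA=ss["SA"] * svr, R_SC=ss["SC"] * svr, R_SV=ss["SV"] * svr,
        R_PA=ps["PA"] * pvr, R_PC=ps["PC"] * pvr, R_PV=ps["PV"] * pvr,
        C_SA=comp["C_SA"], C_SC=comp["C_SC"], C_SV=comp["C_SV"],
        C_PA=comp["C_PA"], C_PC=comp["C_PC"], C_PV=comp["C_PV"],
        A_MV=valves["A_MV"], A_AV=valves["A_AV"],
        A_TV=valves["A_TV"], A_PAV=valves["A_PAV"],
        HR=heart["HR"], V_total=circ["V_total"], rho=circ.get("rho", 1.05),
    )

    chambers: Dict[str, ChamberParams] = {}
    for role in CHAMBER_ORDER:
        c = heart[role]
        chambers[role] = ChamberParams(
            role=role, E_es=c["E_es"], E_min=c["E_min"], V0=c["V0"],
            edpvr_alpha=c["edpvr_alpha"], edpvr_beta=c["edpvr_beta"],
            t_activation_onset=c["t_activation_onset"],
            t_activation_duration=c["t_activation_duration"],
        )
    # atrial activation must precede ventricular onset within the cycle
    for atr, ven in (("LA", "LV"), ("RA", "RV")):
        a, v = chambers[atr], chambers[ven]
        atr_peak_phase = (a.t_activation_onset + 0.45 * a.t_activation_duration) % 1.0
        if not atr_peak_phase > v.t_activation_onset + v.t_activation_duration:
            raise ValueError(f"{atr} activation must precede {ven} activation")

    preset = ScenarioPreset(
        name=cfg["name"],
        LV_Ees=chambers["LV"].E_es, RV_Ees=chambers["RV"].E_es,
        PVR_WU=circ["PVR_WU"], SVR_WU=circ["SVR_WU"],
    )

    engine = dict(cfg.get("engine", {}))
    engine.setdefault("dt", 0.0002)
    engine.setdefault("decimation", 5)
    engine.setdefault("volume_floor", 1.0)
    devices = dict(cfg.get("devices", {}))
    devices.setdefault("limiter_gain", 1.0)

    return Scenario(preset=preset, params=params, chambers=chambers,
                    engine=engine, devices=devices, raw=cfg)


def get_scenario(name_or_path: str | Path) -> Scenario:
    """Convenience: load and resolve in one call."""
    return build_scenario(load_preset_dict(name_or_path))


def initial_state(scenario: Scenario) -> SimState:
    """Starting volumes: chambers at their configured end-diastolic estimates,
    the rest of the stressed volume split across the vascular compartments in
    proportion to compliance (uniform initial filling pressure)."""
    cfg = scenario.raw.get("initial", {})
    params = scenario.params
    v_ch = {f"V_{r}": float(cfg.get(f"V_{r}", 0.0)) for r in CHAMBER_ORDER}
    if not all(v > 0 for v in v_ch.values()):
        raise ValueError("preset must provide positive initial chamber volumes")
    remaining = params.V_total - sum(v_ch.values())
    if remaining <= 0:
        raise ValueError("initial chamber volumes exceed V_total")
    comps = {"V_SA": params.C_SA, "V_SC": params.C_SC, "V_SV": params.C_SV,
             "V_PA": params.C_PA, "V_PC": params.C_PC, "V_PV": params.C_PV}
    c_sum = sum(comps.values())
    vols = dict(v_ch)
    for k, c in comps.items():
        vols[k] = remaining * c / c_sum
    return SimState(**vols, t=0.0)
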