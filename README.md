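# ecpella

Closed-loop lumped-parameter (0-D) simulator of severe heart failure under
combined mechanical circulatory support: VA-ECMO plus an Impella
percutaneous LV pump ("ECPELLA"), with optional VV-ECMO oxygenation.

The model couples four time-varying-elastance cardiac chambers through
unidirectional Bernoulli valves with 5-element resistance–capacitance
systemic and pulmonary vascular networks (ten volume states, exactly
volume-conserving). Devices are resolved every integration step:

* **Impella** — head–capacity (H–Q) pump: flow at level P0–P9 solves a
  per-level quadratic in the head (systemic arterial minus LV pressure),
  with a suction limiter that throttles flow once left atrial pressure
  reaches 0 mmHg;
* **VA-ECMO** — ideal constant-flow pump, systemic vein → systemic artery;
* **VV-ECMO** — raises the arterial O2 saturation of native-lung output.

Built-in analyses: pressure–volume loops, stroke work (SW), pressure–volume
area (PVA), cardiac output / total systemic flow, LVEDP, suction status and
global oxygen delivery (DO2). Four scenario presets ship as YAML
(`NORMAL`, `LVF`, `BVF`, `BVF_PH`) together with a replaceable H–Q
coefficient table.

## Quick start

```python
from ecpella import (get_scenario, initial_state, build_protocol_schedule,
                     run_simulation, extract_steady_snapshots, beat_summary)

sc = get_scenario("BVF_PH")
sched = build_protocol_schedule(vaecmo_flow=2.0,        # L/min
                                settle_initial=10.0,     # s (default 100)
                                settle_per_level=10.0)   # s (default 50)
ts = run_simulation(sc.params, sc.chambers, sched, initial_state(sc))
snaps = extract_steady_snapshots(ts, sched, sc.params.cycle_length)
print(beat_summary(snaps[-1].window, snaps[-1].settings, sc.chambers))
```

## CLI

```bash
ecpella simulate CONFIG.yaml --out results/       # single run -> CSV + JSON
ecpella sweep --protocol 3 --settle-initial 10 --settle-level 10 --out results/
ecpella do2 --hb 10 --sao2 0.8 --co 3 --vaecmo 4  # -> 857.60
ecpella validate CONFIG.yaml
```

`sweep --protocol N` reproduces the four published sweeps: 1 = LVF,
2 = BVF, 3 = BVF + pulmonary hypertension, 4 = the oxygenation scenario
(BVF and BVF_PH, ECMO capped at 4 L/min, DO2 with/without VV-ECMO appended
per cell). Default settling matches the published schedule (100 s + 9×50 s
= 550 s per ECMO flow at a 0.2 ms fixed step); the options above scale it
down for desk runs. Output is a tidy CSV, one row per
(scenario, VA-ECMO flow, Impella level).

A run configuration is a small YAML document:

```yaml
scenario: BVF_PH          # preset name or path to a preset YAML
overrides:
  heart: {HR: 70.0}       # any preset key can be overridden
schedule: {settle_initial: 10.0, settle_per_level: 10.0, levels: [1,2,3]}
devices: {vaecmo_flow: 2.0}
```

## Layout

```
src/ecpella/
  model_core.py   chambers, valves, vascular network, volume-conserving RHS
  mcs_devices.py  Impella H-Q pump + suction limiter, VA-/VV-ECMO
  sim_engine.py   fixed-step RK4 engine, schedules, beats, steady windows
  _kernel.py      numba-compiled hot loop (pure-Python fallback)
  analytics.py    PV loops, SW, PVA, beat summaries, global DO2
  protocols.py    the four published sweeps, tidy result tables
  presets.py      scenario presets (YAML) -> validated parameter objects
  io_cli.py       config schema, serialization, test fixtures
  cli.py          click command-line interface
  _data/          normal/lvf/bvf/bvf_ph.yaml, hq_default.csv
```

All scenario-defining published values (ventricular end-systolic
elastances, SVR/PVR in Wood units, HR 80 bpm, Hb, SaO2, device ranges) are
wired into the presets; every unprinted circuit constant is a documented,
calibrated default in the same files and can be overridden per run.
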