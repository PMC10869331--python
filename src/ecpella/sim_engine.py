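"""Fixed-step simulation engine: schedules, integration, beat segmentation.

The engine integrates the closed-loop model with classical RK4 at a fixed
0.2 ms step (configurable), switching device settings at the boundaries of a
:class:`ProtocolSchedule`.  Output is decimated (default: every 5th step,
i.e. 1 ms sampling) into a :class:`TimeSeries`.  Everything is fully
deterministic — there is no randomness anywhere in the engine.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernel, units
from ._kernel import N_CP, N_REC, REC_COLUMNS
from .mcs_devices import DeviceSettings, HQCurve
from .model_core import ChamberParams, CircuitParams, SimState, CHAMBER_ORDER

__all__ = ["ProtocolSchedule", "TimeSeries", "SegmentSnapshot",
           "run_simulation", "build_protocol_schedule",
           "extract_steady_snapshots", "segment_beats", "SimulationError"]

DEFAULT_DT = 0.0002           # s, the fundamental sampling time
DEFAULT_DECIMATION = 5        # store every 5th step -> 1 ms output
DEFAULT_SETTLE_INITIAL = 100.0
DEFAULT_SETTLE_PER_LEVEL = 50.0


class SimulationError(RuntimeError):
    """Raised on numerical blow-up or an invalid schedule."""


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered device-setting segments integrated back to back."""

    segments: Tuple[Tuple[float, DeviceSettings], ...]
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        for duration, _ in self.segments:
            if duration <= 0.0:
                raise ValueError("segment durations must be positive")
        # an empty segment tuple is allowed: zero-duration run (initial sample only)

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.segments))

    def boundaries(self) -> List[float]:
        """Cumulative segment end times (s)."""
        ends, t = [], 0.0
        for d, _ in self.segments:
            t += d
            ends.append(t)
        return ends


@dataclass
class TimeSeries:
    """Decimated simulation output.

    ``data`` has one row per sample with columns :data:`REC_COLUMNS`
    (time, the ten pressures, four chamber volumes, device flows in L/min,
    suction flag, aortic-valve flow in mL/s and total volume).
    ``segment_index`` maps every sample to its schedule segment.
    """

    data: np.ndarray
    segment_index: np.ndarray
    schedule: ProtocolSchedule
    final_state: SimState
    dt_sample: float

    _col: Dict[str, int] = field(default_factory=lambda: {
        c: i for i, c in enumerate(REC_COLUMNS)}, repr=False)

    def __len__(self) -> int:
        return self.data.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self._col[name]]

    @property
    def t(self) -> np.ndarray:
        return self.column("t")

    def window(self, i0: int, i1: int) -> "TimeSeries":
        """A contiguous sample slice sharing this series' metadata."""
        return TimeSeries(self.data[i0:i1], self.segment_index[i0:i1],
                          self.schedule, self.final_state, self.dt_sample)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(REC_COLUMNS))
        df["segment"] = self.segment_index
        return df


def pack_circuit(params: CircuitParams, volume_floor: float = 1.0) -> np.ndarray:
    """Flatten CircuitParams into the kernel's parameter vector."""
    cp = np.empty(N_CP)
    k = _kernel
    cp[k.CP_R_MV] = params.R_MV
    cp[k.CP_R_AV] = params.R_AV
    cp[k.CP_R_TV] = params.R_TV
    cp[k.CP_R_PAV] = params.R_PAV
    cp[k.CP_R_SZ0] = params.R_SZ0
    cp[k.CP_R_PZ0] = params.R_PZ0
    cp[k.CP_R_SA] = params.R_SA
    cp[k.CP_R_SC] = params.R_SC
    cp[k.CP_R_SV] = params.R_SV
    cp[k.CP_R_PA] = params.R_PA
    cp[k.CP_R_PC] = params.R_PC
    cp[k.CP_R_PV] = params.R_PV
    cp[k.CP_C_SA] = params.C_SA
    cp[k.CP_C_SC] = params.C_SC
    cp[k.CP_C_SV] = params.C_SV
    cp[k.CP_C_PA] = params.C_PA
    cp[k.CP_C_PC] = params.C_PC
    cp[k.CP_C_PV] = params.C_PV
    cp[k.CP_B_MV] = units.bernoulli_coefficient(params.A_MV, params.rho)
    cp[k.CP_B_AV] = units.bernoulli_coefficient(params.A_AV, params.rho)
    cp[k.CP_B_TV] = units.bernoulli_coefficient(params.A_TV, params.rho)
    cp[k.CP_B_PAV] = units.bernoulli_coefficient(params.A_PAV, params.rho)
    cp[k.CP_T_CYCLE] = params.cycle_length
    cp[k.CP_FLOOR] = volume_floor
    return cp


def pack_chambers(chambers: Mapping[str, ChamberParams]) -> np.ndarray:
    """Flatten the four chambers into the kernel's (4, 7) matrix."""
    ch = np.empty((4, 7))
    k = _kernel
    for i, role in enumerate(CHAMBER_ORDER):
        c = chambers[role]
        ch[i, k.CH_EES] = c.E_es
        ch[i, k.CH_EMIN] = c.E_min
        ch[i, k.CH_V0] = c.V0
        ch[i, k.CH_ALPHA] = c.edpvr_alpha
        ch[i, k.CH_BETA] = c.edpvr_beta
        ch[i, k.CH_ONSET] = c.t_activation_onset
        ch[i, k.CH_DUR] = c.t_activation_duration
    return ch


def run_simulation(params: CircuitParams,
                   chambers: Mapping[str, ChamberParams],
                   schedule: ProtocolSchedule,
                   initial: SimState,
                   hq_curve: HQCurve | None = None,
                   limiter_gain: float = 1.0,
                   volume_floor: float = 1.0,
                   decimation: int = DEFAULT_DECIMATION) -> TimeSeries:
    """Integrate the model through every schedule segment.

    Raises :class:`SimulationError` on pressure blow-up (|P| > 500 mmHg) or
    if the initial volumes do not sum to ``params.V_total``.
    """
    if hq_curve is None:
        hq_curve = HQCurve.default()
    v0 = initial.as_array()
    if abs(v0.sum() - params.V_total) > 1e-6 * params.V_total:
        raise SimulationError(
            f"initial volumes sum to {v0.sum():.3f} mL, expected "
            f"V_total = {params.V_total:.3f} mL")

    cp = pack_circuit(params, volume_floor)
    ch = pack_chambers(chambers)
    dt = schedule.dt

    blocks: List[np.ndarray] = []
    seg_idx: List[np.ndarray] = []
    V = v0.copy()
    t = initial.t
    last_dev = (0.0, 0.0, 0.0, 0.0, 0.0)
    for s, (duration, dev) in enumerate(schedule.segments):
        n_steps = int(round(duration / dt))
        a, b, c = hq_curve.coefficients(dev.impella_level)
        out = np.empty((max(1, -(-n_steps // decimation)), N_REC))
        n_rec, status, t_end = _kernel.run_segment(
            V, t, n_steps, dt, cp, ch, a, b, c,
            dev.vaecmo_flow, limiter_gain, decimation, out)
        blocks.append(out[:n_rec])
        seg_idx.append(np.full(n_rec, s, dtype=np.int64))
        last_dev = (a, b, c, dev.vaecmo_flow, limiter_gain)
        if status != 0:
            bad = out[n_rec - 1]
            raise SimulationError(
                f"pressure blow-up in segment {s} at t = {bad[0]:.4f} s "
                f"(|P| > {_kernel.PRESSURE_BLOWUP:.0f} mmHg)")
        t = t_end

    # terminal sample so the series covers [t0, t0 + total_duration]
    row = np.empty(N_REC)
    _kernel.sample_state(V, t, cp, ch, *last_dev, row)
    blocks.append(row[None, :])
    seg_idx.append(np.array([max(0, len(schedule.segments) - 1)], dtype=np.int64))

    data = np.concatenate(blocks, axis=0) if blocks else np.empty((0, N_REC))
    return TimeSeries(data=data,
                      segment_index=np.concatenate(seg_idx),
                      schedule=schedule,
                      final_state=SimState.from_array(V, t=t),
                      dt_sample=dt * decimation)


def build_protocol_schedule(vaecmo_flow: float,
                            settle_initial: float = DEFAULT_SETTLE_INITIAL,
                            settle_per_level: float = DEFAULT_SETTLE_PER_LEVEL,
                            levels: Sequence[int] = tuple(range(1, 10)),
                            device_template: DeviceSettings | None = None,
                            dt: float = DEFAULT_DT) -> ProtocolSchedule:
    """The in-run Impella staircase: a device-free settling segment at P0,
    then one segment per support level.  Defaults (100 s + 9 x 50 s) give the
    550 s protocol duration."""
    if settle_initial <= 0.0 or settle_per_level <= 0.0:
        raise ValueError("settle times must be positive")
    if device_template is None:
        device_template = DeviceSettings()
    segs = [(settle_initial,
             replace(device_template, vaecmo_flow=vaecmo_flow, impella_level=0))]
    for lev in levels:
        segs.append((settle_per_level,
                     replace(device_template, vaecmo_flow=vaecmo_flow,
                             impella_level=int(lev))))
    return ProtocolSchedule(segments=tuple(segs), dt=dt)


@dataclass
class SegmentSnapshot:
    """Steady-state extraction window of one schedule segment."""

    segment: int
    settings: DeviceSettings
    window: TimeSeries            # integer number of complete beats
    n_beats: int
    converged: bool               # beat-to-beat mean SAP within 1 %


def extract_steady_snapshots(ts: TimeSeries, schedule: ProtocolSchedule,
                             cycle_length: float,
                             lead_time: float = 2.0,
                             window_beats: int = 2,
                             sap_tolerance: float = 0.01) -> List[SegmentSnapshot]:
    """One summary window per segment, ending `lead_time` s before the next
    device alteration and spanning `window_beats` complete beats aligned to
    ventricular activation onset."""
    T = cycle_length
    dt_s = ts.dt_sample
    t0 = float(ts.t[0])
    snaps: List[SegmentSnapshot] = []
    seg_start = t0
    for s, (duration, dev) in enumerate(schedule.segments):
        seg_end = seg_start + duration
        if duration < window_beats * T + lead_time:
            raise SimulationError(
                f"segment {s} too short for steady-state extraction: needs "
                f">= {window_beats * T + lead_time:.2f} s, has {duration:.2f} s")
        # last beat boundary at or before (seg_end - lead_time)
        k_end = int(np.floor((seg_end - lead_time) / T + 1e-9))
        w_start, w_end = (k_end - window_beats) * T, k_end * T
        i0 = int(round((w_start - t0) / dt_s))
        i1 = int(round((w_end - t0) / dt_s)) + 1
        win = ts.window(i0, i1)
        sap = win.column("SAP")
        spb = int(round(T / dt_s))
        beat_means = [float(np.mean(sap[b * spb:(b + 1) * spb]))
                      for b in range(window_beats)]
        ref = max(abs(m) for m in beat_means) or 1.0
        converged = (max(beat_means) - min(beat_means)) / ref <= sap_tolerance
        snaps.append(SegmentSnapshot(segment=s, settings=dev, window=win,
                                     n_beats=window_beats, converged=converged))
        seg_start = seg_end
    return snaps


def segment_beats(ts: TimeSeries, HR: float) -> List[TimeSeries]:
    """Cut a series into complete beats at ventricular-activation-onset
    phases (t = k·60/HR); every beat has the same sample count."""
    T = 60.0 / HR
    dt_s = ts.dt_sample
    spb = int(round(T / dt_s))
    if abs(spb * dt_s - T) > 1e-9 * T:
        raise ValueError("cycle length must be an integer number of samples")
    t = ts.t
    if len(t) == 0:
        return []
    k0 = int(np.ceil(t[0] / T - 1e-9))
    i0 = int(round((k0 * T - t[0]) / dt_s))
    beats = []
    while i0 + spb < len(t):
        beats.append(ts.window(i0, i0 + spb + 1))
        i0 += spb
    return beats


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
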