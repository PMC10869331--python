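"""Mechanical circulatory support devices.

Impella is a head-capacity (H-Q) pump: at rotational-speed level P0-P9 its
delivered flow is the root of a per-level quadratic in the head, the
pressure gradient between the systemic artery and the LV.  A suction
limiter throttles that flow when left atrial pressure falls below zero.
VA-ECMO is an ideal constant-flow pump from the systemic vein to the
systemic artery, and VV-ECMO acts purely on arterial oxygen saturation.

The shipped default H-Q coefficient table (presets/hq_default.csv) is a
transparent, replaceable quadratic fit of an Impella-CP-class pump: zero-flow
head rises monotonically with level and the top level delivers about
3.7 L/min at zero head.  Users with manufacturer data can load their own
table via :meth:`HQCurve.from_csv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Tuple

from . import units

__all__ = ["DeviceSettings", "HQCurve", "impella_flow", "suction_limiter",
           "vaecmo_flows", "effective_sao2", "IMPELLA_LEVELS"]

IMPELLA_LEVELS = tuple(f"P{i}" for i in range(10))


def _parse_level(level: int | str) -> int:
    if isinstance(level, str):
        s = level.strip().upper()
        if s.startswith("P"):
            s = s[1:]
        if not s.isdigit():
            raise ValueError(f"unknown Impella level {level!r}")
        level = int(s)
    if not 0 <= level <= 9:
        raise ValueError(f"Impella level must be P0..P9, got {level!r}")
    return level


@dataclass(frozen=True)
class DeviceSettings:
    """Settings of all support devices plus the oxygen-carriage inputs."""

    vaecmo_flow: float = 0.0       # L/min
    impella_level: int = 0         # 0..9 (P0..P9)
    vvecmo_on: bool = False
    Hb: float = 10.0               # g/dL
    SaO2_native: float = 0.40      # fraction
    SaO2_vv: float = 0.80          # fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "impella_level", _parse_level(self.impella_level))
        if self.vaecmo_flow < 0.0:
            raise ValueError("vaecmo_flow must be >= 0")
        if self.Hb < 0.0:
            raise ValueError("Hb must be >= 0")
        for name in ("SaO2_native", "SaO2_vv"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


class HQCurve:
    """Per-level quadratic head-capacity coefficients.

    Each level P stores (a, b, c) of ``head = a − b·Q − c·Q²`` with head in
    mmHg and Q in L/min; a is the shut-off (zero-flow) head.  The P0 row is
    implicit: the pump is off and delivers no flow.
    """

    def __init__(self, coefficients: Dict[int, Tuple[float, float, float]]):
        self._coef: Dict[int, Tuple[float, float, float]] = {0: (0.0, 0.0, 0.0)}
        for level, (a, b, c) in sorted(coefficients.items()):
            level = _parse_level(level)
            if level == 0:
                continue
            if a <= 0.0 or b < 0.0 or c < 0.0 or (b == 0.0 and c == 0.0):
                raise ValueError(f"level P{level}: head must strictly decrease in flow")
            self._coef[level] = (float(a), float(b), float(c))
        if set(self._coef) != set(range(10)):
            missing = sorted(set(range(1, 10)) - set(self._coef))
            raise ValueError(f"H-Q table incomplete, missing levels {missing}")
        heads = [self._coef[k][0] for k in range(1, 10)]
        if any(h2 < h1 for h1, h2 in zip(heads, heads[1:])):
            raise ValueError("shut-off head must be non-decreasing in level")

    def coefficients(self, level: int | str) -> Tuple[float, float, float]:
        return self._coef[_parse_level(level)]

    def shutoff_head(self, level: int | str) -> float:
        """Head at which the level's flow is exactly zero (mmHg)."""
        return self._coef[_parse_level(level)][0]

    def max_flow(self, level: int | str) -> float:
        """Flow at zero head (L/min); the curve is clamped here for negative heads."""
        a, b, c = self._coef[_parse_level(level)]
        return _solve_quadratic(a, b, c, 0.0)

    @classmethod
    def from_csv(cls, path: str | Path) -> "HQCurve":
        """Load a table with columns level,a,b,c (one row per P1..P9)."""
        coef: Dict[int, Tuple[float, float, float]] = {}
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline().strip().lower().split(",")
            if header[:4] != ["level", "a", "b", "c"]:
                raise ValueError(f"{path}: expected header level,a,b,c")
            for line in fh:
                if not line.strip():
                    continue
                lev, a, b, c = line.strip().split(",")[:4]
                coef[_parse_level(lev)] = (float(a), float(b), float(c))
        return cls(coef)

    @classmethod
    def default(cls) -> "HQCurve":
        """The packaged Impella-CP-class coefficient table."""
        with resources.as_file(
                resources.files("ecpella._data") / "hq_default.csv") as p:
            return cls.from_csv(p)


def _solve_quadratic(a: float, b: float, c: float, head: float) -> float:
    """Positive root Q of ``c·Q² + b·Q + (head − a) = 0``."""
    if head >= a:
        return 0.0
    if c == 0.0:
        return (a - head) / b
    disc = b * b + 4.0 * c * (a - head)
    return (-b + math.sqrt(disc)) / (2.0 * c)


def impella_flow(level: int | str, head: float, curve: HQCurve) -> float:
    """Nominal Impella flow (L/min) at `head` = SAP − LVP (mmHg).

    Zero at or above the shut-off head; for negative heads the flow is
    clamped at the level's zero-head maximum (the pump cannot out-run its
    own capacity).
    """
    level = _parse_level(level)
    if level == 0:
        return 0.0
    a, b, c = curve.coefficients(level)
    return _solve_quadratic(a, b, c, max(head, 0.0))


def suction_limiter(LAP: float, Q_nominal: float,
                    limiter_gain: float = 1.0) -> Tuple[float, bool]:
    """Throttle Impella flow on LV suction.

    Suction is flagged once LAP reaches 0 mmHg; below zero the nominal flow
    is reduced by ``limiter_gain`` (L/min per mmHg) times the depth of the
    negative excursion, clamped at zero.  Continuous in LAP.
    """
    if Q_nominal < 0.0:
        raise ValueError("Q_nominal must be >= 0")
    if LAP > 0.0:
        return Q_nominal, False
    if LAP == 0.0:
        return Q_nominal, True
    return max(0.0, Q_nominal - limiter_gain * (-LAP)), True


def vaecmo_flows(settings: DeviceSettings) -> Tuple[float, float]:
    """(drain from systemic vein, return to systemic artery) in mL/s.

    Ideal continuous-flow pump: drain equals return, no recirculation.
    """
    q = units.lpm_to_mls(settings.vaecmo_flow)
    return q, q


def effective_sao2(settings: DeviceSettings) -> float:
    """Arterial O2 saturation of native-lung output, raised by VV-ECMO if on."""
    return settings.SaO2_vv if settings.vvecmo_on else settings.SaO2_native
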