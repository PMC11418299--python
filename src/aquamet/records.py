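"""Core records shared across the pipeline: fish metadata, respirometry
protocol timing, raw O2 traces and fitted measurement cycles.

Units are fixed package-wide: time in seconds since the end of the exhaustive
chase, dissolved O2 in mg l-1, volumes in litres, body mass in kg, and
mass-specific oxygen uptake (mdot) in mg O2 kg-1 min-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASE_FLUSH = "flush"
PHASE_MEASURE = "measure"

#: mg O2 kg-1 min-1 -> mg O2 kg-1 h-1
PER_MIN_TO_PER_H = 60.0


def per_minute_to_per_hour(mdot_per_min: float) -> float:
    """Convert an uptake rate from mg O2 kg-1 min-1 (the canonical unit used
    throughout this package, matching how results are usually plotted) to
    mg O2 kg-1 h-1."""
    return mdot_per_min * PER_MIN_TO_PER_H


@dataclass(frozen=True)
class FishRecord:
    """Identity and geometry of one fish in a respirometer.

    ``fish_volume`` defaults to the body mass in kg under the 1 kg = 1 l
    convention for fish tissue density.
    """

    fish_id: str
    sex: str  # "female" | "male"
    treatment: str  # "sham" | "ligated"
    body_mass: float  # kg
    fork_length: float = float("nan")  # cm
    respirometer_volume: float = 54.5  # l
    fish_volume: float | None = None  # l; None -> body mass in kg

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError(f"body_mass must be positive, got {self.body_mass}")
        if self.fish_volume is None:
            object.__setattr__(self, "fish_volume", float(self.body_mass))
        if not self.respirometer_volume > self.fish_volume > 0:
            raise ValueError(
                "invalid geometry: need respirometer_volume > fish_volume > 0, "
                f"got v_R={self.respirometer_volume}, v_F={self.fish_volume}"
            )

    @property
    def effective_volume(self) -> float:
        """Water volume actually holding dissolved O2: v_R - v_F (l)."""
        return self.respirometer_volume - self.fish_volume


@dataclass(frozen=True)
class RespirometryProtocol:
    """Intermittent-flow schedule: a first post-chase measurement, then
    alternating flush / sealed-measure cycles.

    All durations in minutes.  ``flush_length + measure_length`` must equal
    ``cycle_length``.  The first measurement begins at time zero (end of
    chase) and is typically shorter (4-6 min) than the overnight measure
    phases.
    """

    cycle_length: float = 15.0
    flush_length: float = 9.0
    measure_length: float = 6.0
    first_measure_length: float = 4.0
    sample_rate: float = 1.0  # Hz
    total_duration_h: float = 20.1
    o2_saturation: float = 10.78  # mg l-1, air-saturated freshwater at 12 degC
    o2_saturation_floor: float = 80.0  # % air saturation
    flush_tau_s: float = 120.0  # re-oxygenation time constant

    def __post_init__(self):
        if abs(self.flush_length + self.measure_length - self.cycle_length) > 1e-9:
            raise ValueError(
                "flush_length + measure_length must equal cycle_length "
                f"({self.flush_length} + {self.measure_length} != {self.cycle_length})"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0 < self.o2_saturation_floor < 100:
            raise ValueError("o2_saturation_floor must be in (0, 100)")

    @property
    def n_cycles(self) -> int:
        """Number of full flush+measure cycles after the first measurement."""
        remaining = self.total_duration_h * 60.0 - self.first_measure_length
        return int(remaining // self.cycle_length)

    @property
    def floor_mg_l(self) -> float:
        return self.o2_saturation * self.o2_saturation_floor / 100.0


@dataclass
class O2Trace:
    """Timestamped dissolved-O2 series for one fish with phase labels.

    ``time`` is strictly increasing, in seconds since chase end; ``phase``
    holds ``"flush"`` / ``"measure"`` labels forming contiguous alternating
    blocks.
    """

    time: np.ndarray  # s
    o2: np.ndarray  # mg l-1
    phase: np.ndarray  # str array
    temperature: np.ndarray  # degC

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not (len(self.time) == len(self.o2) == len(self.phase) == len(self.temperature)):
            raise ValueError("all trace columns must have equal length")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "o2_mg_per_l": self.o2,
                "phase": self.phase.astype(str),
                "temp_c": self.temperature,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "O2Trace":
        return cls(
            time=frame["time_s"].to_numpy(float),
            o2=frame["o2_mg_per_l"].to_numpy(float),
            phase=frame["phase"].to_numpy(object),
            temperature=frame["temp_c"].to_numpy(float),
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "O2Trace":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class MeasureCycle:
    """One sealed measurement window with its fitted O2 decline.

    ``slope`` is the OLS slope of o2 on time (mg l-1 s-1, negative when the
    fish consumes oxygen); ``mdot`` the derived mass-specific uptake.  A cycle
    is ``valid`` when its regression is acceptably linear (r2 above threshold)
    and negative.
    """

    cycle_index: int
    t_start: float  # s
    t_end: float  # s
    slope: float  # mg l-1 s-1
    r2: float
    mdot: float  # mg O2 kg-1 min-1
    valid: bool
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def cycles_to_frame(cycles: list[MeasureCycle]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cycle_index": [c.cycle_index for c in cycles],
            "t_start": [c.t_start for c in cycles],
            "t_end": [c.t_end for c in cycles],
            "slope": [c.slope for c in cycles],
            "r2": [c.r2 for c in cycles],
            "mdot": [c.mdot for c in cycles],
            "valid": [c.valid for c in cycles],
        }
    )
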