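"""Non-respirometry endpoints: somatic organ indices, percent compact
myocardium, venous PvO2 plateau reads, and critical thermal maximum (CTmax)
from a constant-rate warming ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BLOOD_TIME_POINTS = ("0", "15", "60", "rest", "ctmax")


@dataclass(frozen=True)
class MorphometricRecord:
    """Organ and body masses for one fish.  Wet masses in g, dried ventricle
    layers (compact / spongy myocardium) in mg."""

    body_mass: float  # g
    ventricle_mass: float = float("nan")
    liver_mass: float = float("nan")
    spleen_mass: float = float("nan")
    gonad_mass: float = float("nan")
    compact_dry_mass: float = float("nan")  # mg
    spongy_dry_mass: float = float("nan")  # mg

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")

    @property
    def rvm(self) -> float:
        """Relative ventricular mass (%)."""
        return organ_index(self.ventricle_mass, self.body_mass)

    @property
    def hsi(self) -> float:
        """Hepatosomatic index (%)."""
        return organ_index(self.liver_mass, self.body_mass)

    @property
    def ssi(self) -> float:
        """Splenosomatic index (%)."""
        return organ_index(self.spleen_mass, self.body_mass)

    @property
    def gsi(self) -> float:
        """Gonadal size index (%)."""
        return organ_index(self.gonad_mass, self.body_mass)

    @property
    def percent_compact_myocardium(self) -> float:
        return percent_compact(self.compact_dry_mass, self.spongy_dry_mass)


@dataclass
class ThermalTrial:
    """One acute warming trial: temperature ramped at a constant rate from
    ``start_temp`` until loss of equilibrium at ``t_loe`` minutes.

    ``ctmax = start_temp + ramp_rate * t_loe`` by construction; an optional
    logged temperature series takes precedence when supplied.
    """

    start_temp: float  # degC
    ramp_rate: float  # degC min-1
    t_loe: float | None  # min; None -> censored trial
    temperature_log: tuple[np.ndarray, np.ndarray] | None = None  # (t_min, temp)

    @property
    def ctmax(self) -> float:
        return ctmax_from_ramp(self)


@dataclass
class PlateauResult:
    value: float  # Torr (nan when not plateaued)
    plateaued: bool
    tail_slope: float  # Torr min-1 over the tail window


def organ_index(organ_mass: float, body_mass: float) -> float:
    """Somatic index: organ mass as a percentage of body mass.

    Both masses must be in the same unit; the ratio is scale invariant.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    if organ_mass < 0:
        raise ValueError("organ_mass must be non-negative")
    return organ_mass / body_mass * 100.0


def percent_compact(compact_dry_mass: float, spongy_dry_mass: float) -> float:
    """Percentage compact myocardium: compact / (compact + spongy) x 100.

    The two layers of the fish ventricle are weighed after drying; the outer
    compact layer is the coronary-perfused one.
    """
    if compact_dry_mass < 0 or spongy_dry_mass < 0:
        raise ValueError("masses must be non-negative")
    total = compact_dry_mass + spongy_dry_mass
    if total <= 0:
        raise ValueError("total ventricular mass must be positive")
    return compact_dry_mass / total * 100.0


def pvo2_plateau(
    time_s: np.ndarray,
    po2: np.ndarray,
    tail_window_s: float = 30.0,
    slope_tol: float = 0.5,  # Torr min-1
    min_duration_s: float = 180.0,
) -> PlateauResult:
    """Estimate the venous PO2 plateau of a sealed sensor-chamber series.

    The reading equilibrates over ~3 min; the plateau is taken as the mean of
    the final ``tail_window_s`` seconds, accepted only when the absolute OLS
    slope over that tail is below ``slope_tol`` — otherwise the series is
    flagged non-plateaued and the value is NaN.
    """
    time_s = np.asarray(time_s, dtype=float)
    po2 = np.asarray(po2, dtype=float)
    if len(time_s) != len(po2):
        raise ValueError("time and po2 must have equal length")
    span = time_s[-1] - time_s[0] if len(time_s) else 0.0
    if span < tail_window_s:
        raise ValueError(
            f"series spans {span:.1f} s, shorter than the {tail_window_s:.0f} s tail window"
        )
    if span < min_duration_s:
        raise ValueError(
            f"series spans {span:.1f} s; at least {min_duration_s:.0f} s required "
            "for a plateau estimate"
        )
    tail = time_s >= time_s[-1] - tail_window_s
    t_tail, y_tail = time_s[tail], po2[tail]
    tc = t_tail - t_tail.mean()
    denom = np.dot(tc, tc)
    slope_per_s = np.dot(tc, y_tail - y_tail.mean()) / denom if denom > 0 else 0.0
    tail_slope = slope_per_s * 60.0
    if abs(tail_slope) < slope_tol:
        return PlateauResult(float(y_tail.mean()), True, float(tail_slope))
    return PlateauResult(float("nan"), False, float(tail_slope))


def ctmax_from_ramp(
    trial: ThermalTrial,
    log_tolerance: float = 0.5,
) -> float:
    """CTmax: temperature at loss of equilibrium under the constant ramp.

    Computed as ``start_temp + ramp_rate * t_loe``.  When the trial carries a
    logged temperature series, the logged temperature at ``t_loe`` takes
    precedence; a disagreement larger than ``log_tolerance`` degC between the
    logged and computed value raises a warning flag via ``UserWarning``.
    """
    if trial.t_loe is None:
        raise ValueError("censored trial: t_loe not recorded")
    computed = trial.start_temp + trial.ramp_rate * trial.t_loe
    if trial.temperature_log is not None:
        t_log, temp_log = trial.temperature_log
        logged = float(np.interp(trial.t_loe, np.asarray(t_log, float), np.asarray(temp_log, float)))
        if abs(logged - computed) > log_tolerance:
            import warnings

            warnings.warn(
                f"logged CTmax {logged:.2f} degC differs from ramp-computed "
                f"{computed:.2f} degC by more than {log_tolerance} degC",
                UserWarning,
                stacklevel=2,
            )
        return logged
    return float(computed)
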