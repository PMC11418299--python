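"""Synthetic experiment generator with known ground truth.

Every downstream stage of the pipeline (trace processing, metabolic metrics,
endpoint arithmetic, statistics) is testable against cohorts produced here:
intermittent-flow O2 traces for fish recovering from exhaustive exercise,
five-point venous blood panels, organ masses, and acute thermal-ramp trials,
for a two-treatment (sham vs coronary-ligated) by two-sex design.

The recovery model is a single exponential: oxygen uptake decays from the
maximum metabolic rate (MMR) reached during the post-chase measurement toward
the resting rate (RMR) with rate constant ``k_recovery``, so the excess
post-exercise oxygen consumption has the closed form (MMR - RMR) / k — used
as an analytic oracle in the tests.  Within each measurement cycle the
programmed consumption is held constant at the recovery curve evaluated at
the start of that cycle's sealed phase (cycle-level discretization), which
makes noiseless traces exactly invertible by the processing stage.

Overnight "resting" cycles are jittered by a multiplicative spontaneous-
activity factor exp(cv * |Z|) >= 1: activity can only elevate uptake above
rest, which is precisely why resting metabolism is estimated by a low
quantile downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .endpoints import BLOOD_TIME_POINTS, ThermalTrial
from .records import (
    PHASE_FLUSH,
    PHASE_MEASURE,
    FishRecord,
    O2Trace,
    RespirometryProtocol,
)

TREATMENTS = ("sham", "ligated")
SEXES = ("female", "male")

BLOOD_ANALYTES = (
    "pvo2",
    "lactate",
    "glucose",
    "potassium",
    "sodium",
    "cortisol",
    "haematocrit",
)
#: analytes generated on the log10 scale (right-skewed in real panels)
LOG_ANALYTES = frozenset({"cortisol", "glucose"})


@dataclass(frozen=True)
class TraceTruth:
    """Ground-truth parameters behind one fish's O2 trace."""

    rmr_true: float  # mg O2 kg-1 min-1
    mmr_true: float  # mg O2 kg-1 min-1
    k_recovery: float = 0.05  # min-1
    noise_sd: float = 0.005  # mg l-1 additive sensor noise per sample
    drift: float = 0.0  # mg l-1 h-1 linear sensor drift
    activity_cv: float = 0.05  # log-scale spontaneous-activity jitter

    def __post_init__(self):
        if not (self.mmr_true > self.rmr_true > 0):
            raise ValueError(
                f"need mmr_true > rmr_true > 0, got {self.mmr_true}, {self.rmr_true}"
            )
        if self.k_recovery <= 0:
            raise ValueError("k_recovery must be positive")
        if self.noise_sd < 0 or self.activity_cv < 0:
            raise ValueError("noise_sd and activity_cv must be non-negative")


@dataclass(frozen=True)
class ThermalTrialTruth:
    """Truth for one acute warming trial."""

    ctmax_true: float  # degC
    start_temp: float = 12.0  # degC
    ramp_rate: float = 0.1  # degC min-1

    def __post_init__(self):
        if self.ctmax_true <= self.start_temp:
            raise ValueError("ctmax_true must exceed start_temp")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be positive")


def simulate_recovery_mdot(truth: TraceTruth, t_min):
    """Oxygen uptake (mg O2 kg-1 min-1) ``t_min`` minutes after exhaustion.

    ``rmr + (mmr - rmr) * exp(-k t)``: monotonically non-increasing, equal to
    MMR at t = 0 and approaching RMR asymptotically.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since exhaustion must be non-negative")
    out = truth.rmr_true + (truth.mmr_true - truth.rmr_true) * np.exp(
        -truth.k_recovery * t
    )
    return out if out.ndim else float(out)


def _phase_plan(protocol: RespirometryProtocol):
    """Ordered (phase, start_s, duration_s, cycle_index) tuples.

    Cycle indices number the *measurement* phases: 0 is the first post-chase
    measurement, 1..n the overnight cycles.  Flush phases carry the index of
    the following measurement.
    """
    plan = []
    t = 0.0
    plan.append((PHASE_MEASURE, t, protocol.first_measure_length * 60.0, 0))
    t += protocol.first_measure_length * 60.0
    for c in range(1, protocol.n_cycles + 1):
        plan.append((PHASE_FLUSH, t, protocol.flush_length * 60.0, c))
        t += protocol.flush_length * 60.0
        plan.append((PHASE_MEASURE, t, protocol.measure_length * 60.0, c))
        t += protocol.measure_length * 60.0
    return plan


def simulate_trace(
    fish: FishRecord,
    truth: TraceTruth,
    protocol: RespirometryProtocol | None = None,
    seed: int | np.random.SeedSequence = 0,
    temperature: float = 12.0,
    return_truth: bool = False,
):
    """Simulate one fish's intermittent-flow O2 trace.

    During each sealed measurement phase the O2 concentration declines
    linearly at ``mdot_c * m / (v_R - v_F)`` (per-minute rate converted to
    per-second), where ``mdot_c`` is the recovery curve at the phase start
    times the cycle's activity factor; flush phases re-approach air
    saturation exponentially.  Additive Gaussian sensor noise and optional
    linear drift are applied to the whole series.  The programmed (pre-noise)
    concentration never falls below the protocol's saturation floor — the
    decline is clamped there and the cycle flagged.

    With ``return_truth=True`` also returns a DataFrame of per-cycle
    programmed uptake rates (the generator's ground truth).
    """
    protocol = protocol or RespirometryProtocol()
    rng = np.random.default_rng(seed)
    plan = _phase_plan(protocol)
    n_cycles = protocol.n_cycles
    # activity factors: first (post-chase) measurement is un-jittered
    factors = np.ones(n_cycles + 1)
    if truth.activity_cv > 0:
        factors[1:] = np.exp(
            truth.activity_cv * np.abs(rng.standard_normal(n_cycles))
        )

    dt = 1.0 / protocol.sample_rate
    vol = fish.effective_volume
    floor = protocol.floor_mg_l
    sat = protocol.o2_saturation

    times, o2s, phases = [], [], []
    truth_rows = []
    o2_now = sat
    for kind, start, dur, cyc in plan:
        n = int(round(dur * protocol.sample_rate))
        t_local = np.arange(n) * dt
        t_abs = start + t_local
        if kind == PHASE_MEASURE:
            mdot_c = factors[cyc] * simulate_recovery_mdot(truth, start / 60.0)
            slope = mdot_c * fish.body_mass / vol / 60.0  # mg l-1 s-1 decline
            seg = o2_now - slope * t_local
            clamped = seg < floor
            seg = np.maximum(seg, floor)
            truth_rows.append(
                {
                    "cycle_index": cyc,
                    "t_start": start,
                    "t_end": start + dur,
                    "mdot_programmed": mdot_c,
                    "slope_programmed": -slope,
                    "clamped": bool(clamped.any()),
                }
            )
        else:
            seg = sat - (sat - o2_now) * np.exp(-t_local / protocol.flush_tau_s)
        times.append(t_abs)
        o2s.append(seg)
        phases.append(np.full(n, kind, dtype=object))
        o2_now = seg[-1] if n else o2_now

    time = np.concatenate(times)
    o2 = np.concatenate(o2s)
    o2 = o2 + truth.drift * time / 3600.0
    if truth.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, truth.noise_sd, size=len(o2))
    trace = O2Trace(
        time=time,
        o2=o2,
        phase=np.concatenate(phases),
        temperature=np.full(len(time), float(temperature)),
    )
    if return_truth:
        return trace, pd.DataFrame(truth_rows)
    return trace


def simulate_thermal_trial(
    truth: ThermalTrialTruth, log_interval_min: float = 1.0
) -> ThermalTrial:
    """Simulate one warming trial: loss of equilibrium occurs exactly where
    the ramp reaches ``ctmax_true``, i.e. ``t_loe = (ctmax - start) / rate``.
    """
    t_loe = (truth.ctmax_true - truth.start_temp) / truth.ramp_rate
    t_log = np.arange(0.0, t_loe + log_interval_min, log_interval_min)
    t_log = t_log[t_log <= t_loe]
    if t_log[-1] < t_loe:
        t_log = np.append(t_log, t_loe)
    temp_log = truth.start_temp + truth.ramp_rate * t_log
    return ThermalTrial(
        start_temp=truth.start_temp,
        ramp_rate=truth.ramp_rate,
        t_loe=t_loe,
        temperature_log=(t_log, temp_log),
    )


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellTruth:
    """Ground-truth metabolic means for one treatment x sex cell, with
    between-fish standard deviations."""

    rmr: float
    mmr: float
    k_recovery: float = 0.05
    rmr_sd: float = 0.0
    mmr_sd: float = 0.0
    noise_sd: float = 0.005
    activity_cv: float = 0.05
    drift: float = 0.0

    def __post_init__(self):
        if not (self.mmr > self.rmr > 0):
            raise ValueError("need mmr > rmr > 0")
        if min(self.rmr_sd, self.mmr_sd, self.noise_sd, self.activity_cv) < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class CohortConfig:
    """Everything needed to draw a complete synthetic experiment.

    ``group_effects`` must contain a :class:`CellTruth` for every
    (treatment, sex) cell; blood-panel means are keyed by
    (analyte, treatment, sex, time_point) with per-analyte residual sds
    (log10-scale for the analytes in :data:`LOG_ANALYTES`); morphometric
    means are somatic indices in percent.  All randomness flows from
    ``seed``.
    """

    n_per_cell: int = 5
    group_effects: Mapping = field(default_factory=dict)
    blood_means: Mapping = field(default_factory=dict)
    blood_sds: Mapping = field(default_factory=dict)
    morph_means: Mapping = field(default_factory=dict)
    morph_sds: Mapping = field(default_factory=dict)
    ctmax_means: Mapping = field(default_factory=dict)
    ctmax_sd: float = 0.8
    ctmax_start_temp: float = 12.0
    ctmax_ramp_rate: float = 0.1
    body_mass_mean: float = 2.2  # kg
    body_mass_sd: float = 0.0
    fork_length_mean: float = 55.7  # cm
    fork_length_sd: float = 0.0
    respirometer_volume: float = 54.5  # l
    protocol: RespirometryProtocol = field(default_factory=RespirometryProtocol)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be at least 1")
        for cell in [(t, s) for t in TREATMENTS for s in SEXES]:
            if cell not in self.group_effects:
                raise ValueError(f"missing CellTruth for cell {cell}")
        for sd_map in (self.blood_sds, self.morph_sds):
            for k, v in sd_map.items():
                if v < 0:
                    raise ValueError(f"negative sd for {k}")


@dataclass
class CohortData:
    """One simulated experiment: records, traces and endpoint tables."""

    fish: list[FishRecord]
    truths: dict[str, TraceTruth]
    traces: dict[str, O2Trace]
    blood: pd.DataFrame
    morphometrics: pd.DataFrame
    thermal: dict[str, ThermalTrial]
    config: CohortConfig

    @property
    def fish_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": [f.fish_id for f in self.fish],
                "sex": [f.sex for f in self.fish],
                "treatment": [f.treatment for f in self.fish],
                "body_mass_kg": [f.body_mass for f in self.fish],
                "fork_length_cm": [f.fork_length for f in self.fish],
                "respirometer_volume_l": [f.respirometer_volume for f in self.fish],
                "fish_volume_l": [f.fish_volume for f in self.fish],
            }
        )

    @property
    def thermal_frame(self) -> pd.DataFrame:
        rows = []
        for fid, tr in self.thermal.items():
            rows.append(
                {
                    "fish_id": fid,
                    "start_temp": tr.start_temp,
                    "ramp_rate": tr.ramp_rate,
                    "t_loe_min": tr.t_loe,
                    "ctmax": tr.ctmax,
                }
            )
        return pd.DataFrame(rows)


def _truncated_normal(rng, mean, sd, low, n=None):
    """Normal draw re-sampled above ``low`` (keeps invariants like mmr > rmr
    without distorting the mean when the bound is far in the tail)."""
    x = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = x <= low
        if not np.any(bad):
            return x
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
    return np.maximum(x, low)


def simulate_cohort(config: CohortConfig, include_traces: bool = True) -> CohortData:
    """Draw a full cohort.  Deterministic for a fixed config (incl. seed)."""
    root = np.random.SeedSequence(config.seed)
    cells = [(t, s) for t in TREATMENTS for s in SEXES]
    cell_seeds = dict(zip(cells, root.spawn(len(cells))))

    fish_list: list[FishRecord] = []
    truths: dict[str, TraceTruth] = {}
    traces: dict[str, O2Trace] = {}
    blood_rows = []
    morph_rows = []
    thermal: dict[str, ThermalTrial] = {}

    for treatment, sex in cells:
        cell = config.group_effects[(treatment, sex)]
        cell_ss = cell_seeds[(treatment, sex)]
        fish_seeds = cell_ss.spawn(config.n_per_cell)
        for i, fseed in enumerate(fish_seeds):
            rng = np.random.default_rng(fseed)
            fid = f"{treatment[:3]}-{sex[0]}-{i + 1:02d}"
            mass = float(
                _truncated_normal(rng, config.body_mass_mean, config.body_mass_sd, 0.5)
            )
            flen = float(rng.normal(config.fork_length_mean, config.fork_length_sd))
            fish = FishRecord(
                fish_id=fid,
                sex=sex,
                treatment=treatment,
                body_mass=mass,
                fork_length=flen,
                respirometer_volume=config.respirometer_volume,
            )
            rmr_i = float(_truncated_normal(rng, cell.rmr, cell.rmr_sd, 0.2))
            mmr_i = float(_truncated_normal(rng, cell.mmr, cell.mmr_sd, rmr_i + 1.0))
            truth = TraceTruth(
                rmr_true=rmr_i,
                mmr_true=mmr_i,
                k_recovery=cell.k_recovery,
                noise_sd=cell.noise_sd,
                drift=cell.drift,
                activity_cv=cell.activity_cv,
            )
            fish_list.append(fish)
            truths[fid] = truth
            if include_traces:
                traces[fid] = simulate_trace(
                    fish, truth, config.protocol, seed=rng.integers(2**31)
                )

            # blood panels at the five study time points
            for tp in BLOOD_TIME_POINTS:
                row = {"fish_id": fid, "treatment": treatment, "sex": sex, "time_point": tp}
                for analyte in BLOOD_ANALYTES:
                    mean = config.blood_means.get((analyte, treatment, sex, tp))
                    if mean is None:
                        row[analyte] = np.nan
                        continue
                    sd = config.blood_sds.get(analyte, 0.0)
                    if analyte in LOG_ANALYTES:
                        row[analyte] = float(10 ** rng.normal(np.log10(mean), sd))
                    else:
                        row[analyte] = float(rng.normal(mean, sd))
                blood_rows.append(row)

            # organ masses from somatic-index truths (% of body mass)
            body_g = mass * 1000.0
            idx = {}
            for name in ("rvm", "hsi", "ssi", "gsi", "pct_compact"):
                mean = config.morph_means.get((name, treatment, sex))
                sd = config.morph_sds.get(name, 0.0)
                idx[name] = float(rng.normal(mean, sd)) if mean is not None else np.nan
            ventricle_g = idx["rvm"] / 100.0 * body_g
            dry_ventricle_mg = ventricle_g * 1000.0 * 0.15  # ~15% dry yield
            morph_rows.append(
                {
                    "fish_id": fid,
                    "treatment": treatment,
                    "sex": sex,
                    "body_mass_g": body_g,
                    "ventricle_mass_g": ventricle_g,
                    "liver_mass_g": idx["hsi"] / 100.0 * body_g,
                    "spleen_mass_g": idx["ssi"] / 100.0 * body_g,
                    "gonad_mass_g": idx["gsi"] / 100.0 * body_g,
                    "compact_dry_mg": idx["pct_compact"] / 100.0 * dry_ventricle_mg,
                    "spongy_dry_mg": (1 - idx["pct_compact"] / 100.0) * dry_ventricle_mg,
                }
            )

            ct_mean = config.ctmax_means.get(treatment)
            if ct_mean is not None:
                ct_true = float(
                    _truncated_normal(
                        rng, ct_mean, config.ctmax_sd, config.ctmax_start_temp + 1.0
                    )
                )
                thermal[fid] = simulate_thermal_trial(
                    ThermalTrialTruth(
                        ctmax_true=ct_true,
                        start_temp=config.ctmax_start_temp,
                        ramp_rate=config.ctmax_ramp_rate,
                    )
                )

    return CohortData(
        fish=fish_list,
        truths=truths,
        traces=traces,
        blood=pd.DataFrame(blood_rows),
        morphometrics=pd.DataFrame(morph_rows),
        thermal=thermal,
        config=config,
    )


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write a cohort as tidy CSVs plus a ground-truth YAML sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    cohort.fish_frame.to_csv(outdir / "fish.csv", index=False)
    cohort.blood.to_csv(outdir / "blood.csv", index=False)
    cohort.morphometrics.to_csv(outdir / "morphometrics.csv", index=False)
    cohort.thermal_frame.to_csv(outdir / "thermal.csv", index=False)
    for fid, trace in cohort.traces.items():
        trace.write_csv(outdir / "traces" / f"{fid}.csv")
    truth_doc = {
        "seed": cohort.config.seed,
        "fish": {
            fid: {
                "rmr_true": t.rmr_true,
                "mmr_true": t.mmr_true,
                "k_recovery": t.k_recovery,
                "noise_sd": t.noise_sd,
                "drift": t.drift,
                "activity_cv": t.activity_cv,
            }
            for fid, t in cohort.truths.items()
        },
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_doc, fh, sort_keys=True)


def serialize_cohort(cohort: CohortData) -> bytes:
    """Byte-stable serialization of the endpoint tables (determinism checks)."""
    buf = io.StringIO()
    for frame in (
        cohort.fish_frame,
        cohort.blood,
        cohort.morphometrics,
        cohort.thermal_frame,
    ):
        frame.to_csv(buf, index=False)
    for fid in sorted(cohort.traces):
        cohort.traces[fid].to_frame().to_csv(buf, index=False)
    return buf.getvalue().encode()


# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------


def default_cohort_config(seed: int = 0, n_per_cell: int = 5) -> CohortConfig:
    """Cohort configured to the study conditions of the coronary-ligation
    experiment this package models.

    Group resting rates are the published sham / ligated RMRs (2.96 and
    2.92 mg O2 kg-1 min-1); sham MMR is 11.94 with the ligated group 16%
    lower; CTmax means 26.9 / 25.8 degC; venous PO2 and the few blood values
    reported in the study text are used where available.  Quantities the
    study does not report numerically (sex-specific MMR offsets, most blood
    and organ means) are synthetic fillers chosen to be physiologically
    plausible for maturing coho salmon — see docs/methods.md.
    """
    sham_rmr, lig_rmr = 2.96, 2.92
    sham_mmr = 11.94
    lig_mmr = sham_mmr * (1 - 0.16)
    # small sex offset (females lower), preserving the treatment-level means
    dm = 0.5

    def cell(rmr, mmr):
        return CellTruth(rmr=rmr, mmr=mmr, rmr_sd=0.35, mmr_sd=2.0)

    group_effects = {
        ("sham", "female"): cell(sham_rmr - 0.1, sham_mmr - dm),
        ("sham", "male"): cell(sham_rmr + 0.1, sham_mmr + dm),
        ("ligated", "female"): cell(lig_rmr - 0.1, lig_mmr - dm),
        ("ligated", "male"): cell(lig_rmr + 0.1, lig_mmr + dm),
    }

    # blood-panel means by (analyte, treatment, sex, time point); values
    # printed in the study where available, plausible fillers elsewhere
    pvo2 = {
        "sham": {"0": 25.2, "15": 35.7, "60": 34.5, "rest": 33.9, "ctmax": 12.0},
        "ligated": {"0": 21.3, "15": 23.0, "60": 33.1, "rest": 31.0, "ctmax": 14.6},
    }
    lactate = {
        "sham": {"0": 9.0, "15": 13.0, "60": 16.1, "rest": 0.9, "ctmax": 14.0},
        "ligated": {"0": 10.0, "15": 15.0, "60": 19.5, "rest": 3.3, "ctmax": 12.9},
    }
    potassium = {"0": 3.4, "15": 3.3, "60": 3.2, "rest": 3.0, "ctmax": 5.0}
    sodium_f, sodium_m = 146.0, 152.0
    glucose = {"female": 5.2, "male": 6.0}
    cortisol = {"female": 420.0, "male": 160.0}
    haematocrit = {"0": 55.0, "15": 50.0, "60": 48.0, "rest": 45.0, "ctmax": 55.0}

    blood_means = {}
    for tr in TREATMENTS:
        for sx in SEXES:
            for tp in BLOOD_TIME_POINTS:
                blood_means[("pvo2", tr, sx, tp)] = pvo2[tr][tp]
                blood_means[("lactate", tr, sx, tp)] = lactate[tr][tp]
                blood_means[("potassium", tr, sx, tp)] = potassium[tp]
                blood_means[("sodium", tr, sx, tp)] = (
                    sodium_f if sx == "female" else sodium_m
                )
                glu = glucose[sx] + (1.0 if (sx == "male" and tp == "60") else 0.0)
                blood_means[("glucose", tr, sx, tp)] = glu
                cort = cortisol[sx] * (1.6 if tp == "ctmax" else 1.0)
                blood_means[("cortisol", tr, sx, tp)] = cort
                blood_means[("haematocrit", tr, sx, tp)] = haematocrit[tp]

    blood_sds = {
        "pvo2": 4.0,
        "lactate": 2.0,
        "glucose": 0.05,  # log10 scale
        "potassium": 0.4,
        "sodium": 3.0,
        "cortisol": 0.15,  # log10 scale
        "haematocrit": 5.0,
    }

    morph_means = {}
    rvm = {("sham", "female"): 0.115, ("sham", "male"): 0.135,
           ("ligated", "female"): 0.125, ("ligated", "male"): 0.145}
    hsi = {("sham", "female"): 1.8, ("sham", "male"): 1.2,
           ("ligated", "female"): 2.0, ("ligated", "male"): 1.4}
    gsi = {"female": 8.0, "male": 3.5}
    ssi = {"female": 0.18, "male": 0.22}
    pct_compact = {"sham": 29.0, "ligated": 31.2}
    for tr in TREATMENTS:
        for sx in SEXES:
            morph_means[("rvm", tr, sx)] = rvm[(tr, sx)]
            morph_means[("hsi", tr, sx)] = hsi[(tr, sx)]
            morph_means[("gsi", tr, sx)] = gsi[sx]
            morph_means[("ssi", tr, sx)] = ssi[sx]
            morph_means[("pct_compact", tr, sx)] = pct_compact[tr]
    morph_sds = {"rvm": 0.012, "hsi": 0.25, "gsi": 1.2, "ssi": 0.04, "pct_compact": 3.5}

    return CohortConfig(
        n_per_cell=n_per_cell,
        group_effects=group_effects,
        blood_means=blood_means,
        blood_sds=blood_sds,
        morph_means=morph_means,
        morph_sds=morph_sds,
        ctmax_means={"sham": 26.9, "ligated": 25.8},
        ctmax_sd=0.8,
        body_mass_sd=0.25,
        fork_length_sd=5.3,
        seed=seed,
    )


def zero_noise_config(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with every source of variation switched off —
    endpoints then equal their cell means exactly."""
    ge = {
        k: replace(v, rmr_sd=0.0, mmr_sd=0.0, noise_sd=0.0, activity_cv=0.0)
        for k, v in config.group_effects.items()
    }
    return replace(
        config,
        group_effects=ge,
        blood_sds={k: 0.0 for k in config.blood_sds},
        morph_sds={k: 0.0 for k in config.morph_sds},
        ctmax_sd=0.0,
        body_mass_sd=0.0,
        fork_length_sd=0.0,
    )
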