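"""End-to-end orchestration: simulate -> process -> summarize -> infer.

One :class:`RunConfig` (typically loaded from YAML) drives a deterministic
run that leaves behind tidy cohort CSVs, a per-fish metabolic summary table,
endpoint tables, a machine-readable statistics JSON and a text report with a
provenance block (config hash, seed, package versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .endpoints import organ_index, percent_compact
from .metrics import summarize_fish
from .records import FishRecord, O2Trace, RespirometryProtocol, cycles_to_frame
from .traces import process_trace
from .stats import (
    EndpointTable,
    StatResult,
    apply_gate,
    factorial_anova,
    format_stat_result,
    group_summary,
    one_way_anova,
    repeated_measures_lmm,
    tukey_contrasts,
)
from .synthetic import default_cohort_config, simulate_cohort, write_cohort


@dataclass
class Thresholds:
    """Analysis thresholds; defaults are the published ones."""

    r2_min_cycles: float = 0.90
    r2_min_mmr: float = 0.95
    window_min: float = 180.0  # s
    window_step: float = 1.0  # s
    rmr_quantile: float = 0.10
    min_cycles: int = 60
    alpha: float = 0.05
    min_cell_for_sex: int = 5  # below this, sex is dropped as a factor

    def __post_init__(self):
        if not 0 < self.rmr_quantile < 1:
            raise ValueError("rmr_quantile must be in (0, 1)")
        if not (0 < self.r2_min_cycles < 1 and 0 < self.r2_min_mmr < 1):
            raise ValueError("r2 thresholds must be in (0, 1)")
        if self.window_min <= 0 or self.window_step <= 0:
            raise ValueError("window parameters must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class RunConfig:
    mode: str = "full"  # simulate | analyze | full
    outdir: str = "aquamet_run"
    seed: int = 0
    n_per_cell: int = 5
    protocol: RespirometryProtocol = field(default_factory=RespirometryProtocol)
    thresholds: Thresholds = field(default_factory=Thresholds)
    lmm_endpoints: tuple[str, ...] = ("pvo2",)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = dict(doc)
        if "protocol" in kwargs:
            kwargs["protocol"] = RespirometryProtocol(**kwargs["protocol"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "lmm_endpoints" in kwargs:
            kwargs["lmm_endpoints"] = tuple(kwargs["lmm_endpoints"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lmm_endpoints"] = list(self.lmm_endpoints)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded,
        so identical analyses hash identically wherever they are written)."""
        d = self.to_dict()
        d.pop("outdir", None)
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stat_to_dict(res: StatResult) -> dict:
    d = {
        "model": res.model,
        "anova_type": res.anova_type,
        "transform": res.transform,
        "alpha": res.alpha,
        "flags": list(res.flags),
        "terms": [
            {
                "term": t.term,
                "statistic": t.statistic,
                "df_num": t.df_num,
                "df_den": None if not np.isfinite(t.df_den) else t.df_den,
                "p": t.p,
                "kind": t.kind,
            }
            for t in res.terms
        ],
    }
    if res.contrasts is not None:
        d["contrasts"] = res.contrasts.to_dict(orient="records")
    if res.letters is not None:
        d["letters"] = res.letters
    return d


def _analyze_endpoint(df: pd.DataFrame, endpoint: str, thresholds: Thresholds) -> StatResult:
    """Gate -> transform -> factorial ANOVA, with the small-cell guard: when
    any treatment x sex cell is smaller than ``min_cell_for_sex`` the sex
    factor is dropped and a one-way treatment ANOVA is used."""
    table = EndpointTable(df, endpoint)
    table, gate = apply_gate(table, alpha=thresholds.alpha)
    cell_n = df.groupby(["treatment", "sex"], observed=True)["value"].count()
    complete = len(cell_n) == df["treatment"].nunique() * df["sex"].nunique()
    if complete and (cell_n >= thresholds.min_cell_for_sex).all():
        res = factorial_anova(table, alpha=thresholds.alpha)
    else:
        res = one_way_anova(table, alpha=thresholds.alpha)
        res.flags = res.flags + ("sex excluded: small cells",)
    res.flags = res.flags + (
        f"gate: shapiro p={gate.shapiro_p:.3g}, transform={gate.transform}",
    )
    return res


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the run directory.

    ``simulate`` writes a synthetic cohort; ``analyze`` consumes a cohort
    directory (written by simulate or supplied externally in the same
    layout); ``full`` chains the two, with analyze reading the simulated
    files back from disk so the staged and end-to-end paths are identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_dir = outdir / "cohort"
    if config.mode not in ("simulate", "analyze", "full"):
        raise ValueError(f"unknown mode {config.mode!r}")

    if config.mode in ("simulate", "full"):
        cc = default_cohort_config(seed=config.seed, n_per_cell=config.n_per_cell)
        cc = dataclasses.replace(cc, protocol=config.protocol)
        cohort = simulate_cohort(cc)
        write_cohort(cohort, cohort_dir)
    if config.mode == "simulate":
        _write_provenance(outdir, config)
        return outdir

    # ----- analyze -----
    required = ["fish.csv", "blood.csv", "morphometrics.csv", "thermal.csv"]
    missing = [f for f in required if not (cohort_dir / f).exists()]
    if missing or not (cohort_dir / "traces").is_dir():
        missing = missing + ([] if (cohort_dir / "traces").is_dir() else ["traces/"])
        raise FileNotFoundError(
            f"analyze mode: missing artifacts in {cohort_dir}: {', '.join(missing)}"
        )
    th = config.thresholds
    fish_meta = pd.read_csv(cohort_dir / "fish.csv")
    blood = pd.read_csv(cohort_dir / "blood.csv")
    morph = pd.read_csv(cohort_dir / "morphometrics.csv")
    thermal = pd.read_csv(cohort_dir / "thermal.csv")

    rows = []
    for rec in fish_meta.itertuples():
        fish = FishRecord(
            fish_id=rec.fish_id,
            sex=rec.sex,
            treatment=rec.treatment,
            body_mass=rec.body_mass_kg,
            fork_length=rec.fork_length_cm,
            respirometer_volume=rec.respirometer_volume_l,
            fish_volume=rec.fish_volume_l,
        )
        trace = O2Trace.read_csv(cohort_dir / "traces" / f"{rec.fish_id}.csv")
        cyc = process_trace(trace, fish, config.protocol, r2_min=th.r2_min_cycles)
        (outdir / "cycles").mkdir(exist_ok=True)
        cycles_to_frame(cyc).to_csv(outdir / "cycles" / f"{rec.fish_id}.csv", index=False)
        s = summarize_fish(
            trace,
            fish,
            config.protocol,
            r2_min_cycles=th.r2_min_cycles,
            r2_min_mmr=th.r2_min_mmr,
            window_min=th.window_min,
            window_step=th.window_step,
            rmr_quantile=th.rmr_quantile,
            min_cycles=th.min_cycles,
        )
        rows.append(
            {
                "fish_id": s.fish_id,
                "treatment": rec.treatment,
                "sex": rec.sex,
                "rmr": s.rmr,
                "mmr": s.mmr,
                "aas": s.aas,
                "fas": s.fas,
                "epoc": s.epoc,
                "epoc_duration": s.epoc_duration,
                "n_valid_cycles": s.n_valid_cycles,
                "flags": ";".join(s.flags),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "metabolic_summary.csv", index=False)

    # somatic indices from organ masses
    morph_idx = morph.assign(
        rvm=[organ_index(v, b) for v, b in zip(morph.ventricle_mass_g, morph.body_mass_g)],
        hsi=[organ_index(v, b) for v, b in zip(morph.liver_mass_g, morph.body_mass_g)],
        ssi=[organ_index(v, b) for v, b in zip(morph.spleen_mass_g, morph.body_mass_g)],
        gsi=[organ_index(v, b) for v, b in zip(morph.gonad_mass_g, morph.body_mass_g)],
        pct_compact=[
            percent_compact(c, sp)
            for c, sp in zip(morph.compact_dry_mg, morph.spongy_dry_mg)
        ],
    )
    morph_idx.to_csv(outdir / "somatic_indices.csv", index=False)

    stats_out: dict[str, dict] = {}
    report_blocks: list[str] = []

    for endpoint in ("rmr", "mmr", "aas", "fas", "epoc", "epoc_duration"):
        df = summary.rename(columns={endpoint: "value"})[
            ["fish_id", "treatment", "sex", "value"]
        ].dropna()
        if df["value"].nunique() < 3:
            continue
        res = _analyze_endpoint(df, endpoint, th)
        stats_out[endpoint] = _stat_to_dict(res)
        report_blocks.append(format_stat_result(endpoint, res))

    for name, col in (("rvm", "rvm"), ("hsi", "hsi"), ("ssi", "ssi"),
                      ("gsi", "gsi"), ("pct_compact", "pct_compact")):
        df = morph_idx.rename(columns={col: "value"})[
            ["fish_id", "treatment", "sex", "value"]
        ].dropna()
        if df["value"].nunique() < 3:
            continue
        res = _analyze_endpoint(df, name, th)
        stats_out[name] = _stat_to_dict(res)
        report_blocks.append(format_stat_result(name, res))

    ct = thermal.merge(fish_meta[["fish_id", "treatment", "sex"]], on="fish_id")
    if len(ct) >= 6:
        df = ct.rename(columns={"ctmax": "value"})[["fish_id", "treatment", "sex", "value"]]
        res = _analyze_endpoint(df, "ctmax", th)
        stats_out["ctmax"] = _stat_to_dict(res)
        report_blocks.append(format_stat_result("ctmax", res))

    for analyte in config.lmm_endpoints:
        df = blood.rename(columns={analyte: "value"})[
            ["fish_id", "treatment", "sex", "time_point", "value"]
        ].dropna()
        if df.empty:
            continue
        table = EndpointTable(df, analyte)
        table, gate = apply_gate(table, alpha=th.alpha)
        res = repeated_measures_lmm(table, alpha=th.alpha)
        res = tukey_contrasts(res, "time_point", data=table.data)
        res.flags = res.flags + (
            f"gate: shapiro p={gate.shapiro_p:.3g}, transform={gate.transform}",
        )
        stats_out[f"{analyte}_recovery"] = _stat_to_dict(res)
        report_blocks.append(format_stat_result(f"{analyte}_recovery", res))

    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, sort_keys=True)

    tab = group_summary(
        summary.melt(
            id_vars=["treatment", "sex"],
            value_vars=["rmr", "mmr", "aas", "fas", "epoc", "epoc_duration"],
            var_name="metric",
        ).dropna(subset=["value"]),
        by=("metric", "treatment"),
    )
    tab.to_csv(outdir / "group_summary.csv", index=False)

    _write_provenance(outdir, config)
    report = [
        "aquamet pipeline report",
        "=======================",
        _provenance_text(config),
        "",
        "Group means (mean ± s.e.m.):",
        tab.to_string(index=False),
        "",
    ] + report_blocks
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return outdir


def _provenance_text(config: RunConfig) -> str:
    import scipy
    import statsmodels

    return (
        f"seed: {config.seed} | config sha256: {config.config_hash} | "
        f"aquamet {__version__} | numpy {np.__version__} | pandas {pd.__version__} | "
        f"scipy {scipy.__version__} | statsmodels {statsmodels.__version__}"
    )


def _write_provenance(outdir: Path, config: RunConfig) -> None:
    doc = {"config": config.to_dict(), "config_hash": config.config_hash,
           "aquamet_version": __version__}
    with open(outdir / "run.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
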