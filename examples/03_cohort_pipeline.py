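"""A full simulated experiment: two surgical treatments x two sexes, traces
through statistics, driven by one config.  Uses a shortened 3-h protocol so
the example runs in seconds; the defaults reproduce the ~20 h study schedule.

Run:  python examples/03_cohort_pipeline.py
"""

import json
import tempfile
from pathlib import Path

from aquamet import RunConfig, Thresholds, run_pipeline
from aquamet.records import RespirometryProtocol

outdir = Path(tempfile.mkdtemp()) / "demo_run"
config = RunConfig(
    mode="full",
    outdir=str(outdir),
    seed=7,
    n_per_cell=4,
    protocol=RespirometryProtocol(
        cycle_length=10.0, flush_length=6.0, measure_length=4.0,
        first_measure_length=4.0, total_duration_h=3.0,
    ),
    thresholds=Thresholds(min_cycles=10, min_cell_for_sex=2),
)
run_pipeline(config)

print(f"run directory: {outdir}")
print("outputs:", ", ".join(sorted(p.name for p in outdir.iterdir())))
print()

stats = json.loads((outdir / "stats.json").read_text())
mmr = stats["mmr"]
print("MMR, treatment x sex ANOVA "
      f"(type {mmr['anova_type']}, transform {mmr['transform']}):")
for t in mmr["terms"]:
    if t["kind"] == "F":
        print(f"  {t['term']:<14} F = {t['statistic']:7.3f}  p = {t['p']:.4f}")
print()
pv = stats["pvo2_recovery"]
print(f"venous PO2 recovery, mixed model: {pv['model']}")
for t in pv["terms"]:
    if t["kind"] == "chi2":
        print(f"  {t['term']:<24} chi2 = {t['statistic']:8.3f}  p = {t['p']:.4f}")
print("  Tukey letters across time points:", pv.get("letters"))
print()
print("A treatment term with p < 0.05 on MMR mirrors the design's headline")
print("effect: blocking coronary blood flow lowers maximum aerobic capacity.")
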