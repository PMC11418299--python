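# aquamet

Intermittent-flow respirometry analysis for whole-animal fish physiology:
from raw dissolved-O2 traces to resting and maximum metabolic rate, aerobic
scope, post-exercise oxygen consumption, thermal tolerance and blood or
morphometric endpoints, through the staged statistical workflow used in
comparative ecophysiology.  It was built around a coronary-ligation
experiment in maturing coho salmon (*Oncorhynchus kisutch*) — does blocking
the heart's arterial oxygen supply impair aerobic performance, and does it
do so differently in females and males? — but every stage is generic for
chase-protocol respirometry of fishes.

Because studies of this kind rarely deposit raw traces, the package ships a
first-class synthetic cohort generator with known ground truth (exponential
post-exhaustion recovery, spontaneous-activity jitter, sensor noise, blood
panels, organ masses, thermal ramps), so the whole pipeline is testable and
its calibration demonstrable.

## The quantities at the core

For a fish of mass *m* (kg) in a respirometer of volume *v*<sub>R</sub> (l),
each sealed measurement cycle yields

&nbsp;&nbsp;&nbsp;&nbsp;*Ṁ*<sub>O2</sub> = |ΔO₂| · (*v*<sub>R</sub> − *v*<sub>F</sub>) / *m*&nbsp;&nbsp;&nbsp;[mg O₂ kg⁻¹ min⁻¹]

with *v*<sub>F</sub> the fish volume (1 kg ≡ 1 l).  From the validated
cycles (negative slope, r² > 0.90):

* **MMR** — steepest ≥180 s sliding window (1-s steps, r² > 0.95) of the
  first post-exhaustion measurement;
* **RMR** — 0.10 quantile of all validated cycle uptakes (≥60 required);
* **AAS = MMR − RMR**, **FAS = MMR / RMR** — absolute and factorial aerobic
  scope;
* **EPOC** — area between a monotone cubic interpolant of the recovery
  curve and the RMR line, from MMR until uptake returns to RMR;
* **CTmax** — temperature at loss of equilibrium under a 0.1 °C min⁻¹ ramp;
* **PvO₂** — venous oxygen tension read as a sensor-chamber plateau.

Inference mirrors the field's staging: Shapiro–Wilk/Levene gates with a
log10 fallback, treatment × sex ANOVA (type III, sum-to-zero coding) with a
non-significant interaction dropped to a type II additive fit,
repeated-measures linear mixed models with a per-fish random intercept and
BIC-selected fixed effects, and Tukey-HSD contrasts with compact letter
displays.  See `docs/methods.md` for every convention and its rationale.

## A worked example

`examples/01_single_fish_metrics.py` simulates a ~20 h record for one
exhausted 2.2 kg fish (true RMR 2.96, true MMR 11.94 mg O₂ kg⁻¹ min⁻¹) and
runs the full per-fish pipeline:

```
trace: 72240 samples over 20.1 h, 81 measurement cycles
RMR  =  2.984 mg O2 kg-1 min-1   (true 2.96)
MMR  = 11.945 mg O2 kg-1 min-1   (true 11.94)
AAS  =  8.961 mg O2 kg-1 min-1   (= MMR - RMR)
FAS  =  4.003                    (= MMR / RMR)
EPOC =  215.9 mg O2 kg-1 over 296 min (closed-form generator value 179.6)
validated cycles: 81
```

The estimators recover the programmed rates to well under 1%; EPOC exceeds
the noiseless closed form `(MMR−RMR)/k = 179.6` because spontaneous
overnight activity keeps measured uptake slightly above rest, exactly as in
real records.  `examples/02_thermal_and_blood_endpoints.py` covers CTmax,
PvO₂ plateaus and somatic indices; `examples/03_cohort_pipeline.py` runs a
four-cell cohort end to end and prints the ANOVA / mixed-model output.

The same pipeline is scriptable from the shell:

```bash
aquamet full --seed 7 --out demo_run          # simulate + analyse
aquamet report demo_run                       # print the text report
```

All tabular outputs are CSV, statistics land in `stats.json`, and every run
records seed, config hash and package versions.

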