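"""Non-respirometry endpoints: critical thermal maximum from a warming ramp,
a venous PO2 plateau read from a sensor-chamber series, and somatic indices.

Run:  python examples/02_thermal_and_blood_endpoints.py
"""

import numpy as np

from aquamet import (
    ctmax_from_ramp,
    organ_index,
    percent_compact,
    pvo2_plateau,
    simulate_thermal_trial,
)
from aquamet.synthetic import ThermalTrialTruth

# --- CTmax: 0.1 degC/min ramp from 12 degC until loss of equilibrium -------
trial = simulate_thermal_trial(ThermalTrialTruth(ctmax_true=26.9))
print(f"loss of equilibrium after {trial.t_loe:.0f} min "
      f"-> CTmax = {ctmax_from_ramp(trial):.1f} degC")

# --- venous PO2: sealed chamber equilibrates over ~3 min -------------------
rng = np.random.default_rng(7)
t = np.arange(0.0, 181.0)                      # 1 Hz, 3 min
series = 23.0 - (23.0 - 5.0) * np.exp(-t / 30.0) + rng.normal(0, 0.3, len(t))
res = pvo2_plateau(t, series)
print(f"PvO2 plateau = {res.value:.1f} Torr "
      f"(tail slope {res.tail_slope:+.2f} Torr/min, plateaued={res.plateaued})")

# --- somatic indices -------------------------------------------------------
print(f"relative ventricular mass: {organ_index(2.9, 2200.0):.3f} % of body mass")
print(f"percent compact myocardium: {percent_compact(31.2, 68.8):.1f} % "
      f"(coronary-perfused outer layer of the ventricle)")
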