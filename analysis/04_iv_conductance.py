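#!/usr/bin/env python
"""Unitary i-V relation and slope conductance in symmetric Cs+.

Simulates unitary current amplitudes at six holding potentials from the
248 pS / 0 mV-reversal line (6 replicates per voltage, 0.2 pA noise) and
refits by ordinary least squares, as done for pooled single-channel
amplitude data.  Writes results/iv_points.csv and results/iv_fit.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ip3rkit import params
from ip3rkit.fits import fit_linear_iv

OUT = Path(__file__).resolve().parents[1] / "results"
VOLTAGES = np.array([-40.0, -30.0, -20.0, 20.0, 30.0, 40.0])

gamma = params.get_params("conductance")["gamma_ps"] / 1000.0  # pA/mV
rng = np.random.default_rng(3)
v = np.repeat(VOLTAGES, 6)
i = gamma * v + rng.normal(0.0, 0.2, v.size)
fit = fit_linear_iv((v, i))

OUT.mkdir(exist_ok=True)
pd.DataFrame({"voltage_mV": v, "current_pA": i}).to_csv(
    OUT / "iv_points.csv", index=False
)
payload = {
    "conductance_pS": fit["conductance_pS"],
    "conductance_se_pS": fit.se["conductance_pS"],
    "reversal_mV": fit["reversal_mV"],
    "generating_pS": gamma * 1000.0,
}
(OUT / "iv_fit.json").write_text(json.dumps(payload, indent=2))
print(
    f"slope conductance {fit['conductance_pS']:.1f} +/- "
    f"{fit.se['conductance_pS']:.1f} pS (generator {gamma * 1000:.0f} pS), "
    f"reversal {fit['reversal_mV']:+.2f} mV"
)
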