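#!/usr/bin/env python
"""Ca2+ puff kinetics and frequency, WT vs D2594K linescans.

Synthesizes confocal linescans for both genotypes, detects puffs at the
5.5 SD criterion, and tabulates the kinetic attributes (FDHM, time to
peak, 20-80% rise, 80-20% decay) and the per-cell event frequency.  The
mutant's ~3.5x longer FDHM and ~2.5x higher frequency reproduce its
subcellular gain-of-function signature.
Writes results/puff_kinetics.csv and results/puff_events_<genotype>.csv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ip3rkit import io as kio, params
from ip3rkit.puffs import PuffGenSpec, detect_puffs, puff_frequency, synthesize_linescan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
warnings.simplefilter("ignore", UserWarning)

rows = []
for genotype, n_cells, seed in (("wt", 24, 90), ("d2594k", 24, 91)):
    entry = params.get_params(f"{genotype}_puffs")
    spec = PuffGenSpec(
        rate=entry["rate"],
        amplitude=2.0,
        rise_time=entry["rise_time"],
        decay_tau=entry["decay_tau"],
        noise_sd=20.0,
        baseline_f0=100.0,
    )
    image, truth = synthesize_linescan(
        spec, n_cells=n_cells, rng=np.random.default_rng(seed)
    )
    events = detect_puffs(image, k_sd=5.5)
    kio.write_puff_events_csv(events, OUT / f"puff_events_{genotype}.csv")
    usable = [e for e in events if not (e.censored or e.overlap)]
    freq = puff_frequency(events, n_cells, spec.duration)
    rows.append(
        {
            "genotype": genotype,
            "generator_rate_hz": spec.rate,
            "n_true": len(truth),
            "n_detected": len(events),
            "frequency_hz_per_cell": freq,
            "fdhm_s": np.mean([e.fdhm for e in usable]),
            "time_to_peak_s": np.mean([e.time_to_peak for e in usable]),
            "rise_20_80_s": np.mean([e.rise_20_80 for e in usable]),
            "decay_80_20_s": np.mean([e.decay_80_20 for e in usable]),
            "amplitude_dff": np.mean([e.amplitude for e in usable]),
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "puff_kinetics.csv", index=False)
print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
wt, kk = df.iloc[0], df.iloc[1]
print(
    f"\nD2594K vs WT: FDHM {kk.fdhm_s / wt.fdhm_s:.1f}x longer, "
    f"frequency {kk.frequency_hz_per_cell / wt.frequency_hz_per_cell:.1f}x higher."
)
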