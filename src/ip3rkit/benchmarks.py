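"""End-to-end parameter-recovery experiments.

Each function generates synthetic data from a named parameter set in the
registry, runs the corresponding analysis pipeline, and returns the
recovered quantity.  These are the package's main results: because the
generators are parameterized from published WT / D2594K estimates, the
recovered values should land on those estimates within the sampling noise
of the stated study conditions.

All randomness derives from the caller's integer seed through
``numpy.random.SeedSequence`` so every experiment is reproducible.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import params
from .bilayersim import SimConfig, render_trace, simulate_train
from .fits import dose_response_pipeline, fit_biphasic_hill, fit_linear_iv, fit_mot_edf
from .gating import biphasic_po, hill_po, mot_edf_model, rates_from_po
from .plateassay import atp_dose_response, synthesize_well
from .puffs import PuffGenSpec, detect_puffs, puff_frequency, synthesize_linescan

__all__ = [
    "recover_atp_ec50",
    "recover_iv_conductance",
    "recover_ip3_ec50",
    "recover_biphasic_ca",
    "recover_puff_fdhm",
    "recover_puff_frequency",
    "recover_mot_va50",
]

MOT_S = 8e-3  # mean open time used by the bilayer simulator (s)
IP3_LEVELS = np.logspace(math.log10(30e-9), math.log10(10e-6), 7)
ATP_LEVELS = np.logspace(math.log10(0.3e-6), math.log10(100e-6), 8)
CA_LEVELS = np.logspace(math.log10(10e-9), math.log10(10e-6), 12)
IV_VOLTAGES = np.array([-40.0, -30.0, -20.0, 20.0, 30.0, 40.0])


def recover_atp_ec50(genotype: str = "wt", seed: int = 1) -> tuple[float, int]:
    """Plate-assay Hill EC50 (uM) from synthetic ATP dose-response wells.

    8 log-spaced ATP levels (0.3-100 uM), 6 replicate wells per level,
    additive noise of 5% of the baseline fluorescence.  Returns (EC50 in
    uM, number of wells).
    """
    hill = params.get_model(f"{genotype.lower()}_atp")
    root = np.random.SeedSequence([seed, 101])
    f0, noise_frac, n_rep = 100.0, 0.05, 6
    children = root.spawn(len(ATP_LEVELS) * n_rep)
    wells = []
    k = 0
    for atp in ATP_LEVELS:
        for _ in range(n_rep):
            wells.append(
                synthesize_well(
                    atp, hill, noise_sd=noise_frac * f0, f0=f0,
                    rng=np.random.default_rng(children[k]),
                )
            )
            k += 1
    _, fit = atp_dose_response(wells)
    return fit["ec50"] * 1e6, len(wells)


def recover_iv_conductance(
    seed: int = 3, n_rep: int = 6
) -> tuple[float, int]:
    """Slope conductance (pS) from noisy unitary-current amplitudes.

    ``n_rep`` replicate amplitudes per voltage at -40..+40 mV (matching
    the pooled n per point of the source data), 0.2 pA Gaussian noise on a
    248 pS / 0 mV-reversal line.
    """
    gamma = params.get_params("conductance")["gamma_ps"] / 1000.0  # pA/mV
    rng = np.random.default_rng(np.random.SeedSequence([seed, 103]))
    v = np.repeat(IV_VOLTAGES, n_rep)
    i = gamma * v + rng.normal(0.0, 0.2, size=v.size)
    fit = fit_linear_iv((v, i))
    return fit["conductance_pS"], v.size


def recover_ip3_ec50(
    genotype: str = "wt",
    seed: int = 1,
    record_s: float = 60.0,
    n_records: int = 3,
) -> tuple[float, int]:
    """EC50 (nM) from the full simulate -> idealize -> nPo -> Hill chain.

    Single-channel records at 7 IP3 levels (30 nM - 10 uM), equilibrium Po
    from the genotype's Hill curve, MOT 8 ms, rendered at +30 mV / 248 pS
    with 2 kHz filtering and 20 kHz sampling, then half-amplitude
    idealization with 300 us dead time and a Hill fit to the pooled nPo.
    Record length defaults to 1 min (a scaled-down stand-in for the >3 min
    records of full experiments).
    """
    hill = params.get_model(f"{genotype.lower()}_ip3")
    root = np.random.SeedSequence([seed, 104])
    children = iter(root.spawn(len(IP3_LEVELS) * n_records * 2))
    traces_by_condition: dict[float, list] = {}
    config = SimConfig(duration=record_s, em=30.0)
    for ip3 in IP3_LEVELS:
        po = hill_po(float(ip3), hill)
        opening, closing = rates_from_po(po, MOT_S)
        traces = []
        for _ in range(n_records):
            train = simulate_train(opening, closing, record_s, seed=next(children))
            trace = render_trace(
                [train], config, rng=np.random.default_rng(next(children))
            )
            traces.append(trace)
        traces_by_condition[float(ip3)] = traces
    _, fit = dose_response_pipeline(
        traces_by_condition,
        unitary=config.unitary_current,
        baseline=0.0,
        fit="hill",
    )
    return fit["ec50"] * 1e9, len(IP3_LEVELS) * n_records


def recover_biphasic_ca(
    genotype: str = "wt", seed: int = 7, noise_frac: float = 0.03
) -> tuple[float, float, int]:
    """(EC50_act nM, IC50_inh nM) from a biphasic-Hill fit to noisy nPo.

    12 log-spaced cytosolic Ca2+ levels (10 nM - 10 uM), multiplicative
    Gaussian noise of 3%.  The known relative noise supplies the fit
    weights (1/y_err^2), which keeps the low-Po limbs informative.
    """
    model = params.get_model(f"{genotype.lower()}_cyto_ca")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 106]))
    y = biphasic_po(CA_LEVELS, model)
    y = y * (1.0 + rng.normal(0.0, noise_frac, size=y.size))
    fit = fit_biphasic_hill((CA_LEVELS, y), y_err=noise_frac * np.abs(y))
    return fit["ec50_act"] * 1e9, fit["ic50_inh"] * 1e9, len(CA_LEVELS)


def recover_puff_fdhm(
    genotype: str = "wt", seed: int = 9, min_events: int = 60,
    event_rate: float = 0.02,
) -> tuple[float, int]:
    """Mean detected FDHM (s) on synthetic linescans of one genotype.

    Generator kinetics come from the registry (rise/decay chosen through
    the closed-form identities to carry the genotype's published half
    duration); event amplitude is 10x the background noise SD; detection
    at 5.5 SD.  Enough 120-s linescan is synthesized to expect >=
    ``min_events`` puffs.  The genotype enters through the event kinetics;
    the generation density is kept sparse (``event_rate`` per cell, spread
    over as many cells as needed) so that kinetic measurements come from
    isolated events — overlapping time courses measure neither event's
    true kinetics.  Right-censored or overlap-split detections are
    likewise excluded from the average.
    """
    entry = params.get_params(f"{genotype.lower()}_puffs")
    spec = PuffGenSpec(
        rate=event_rate,
        amplitude=2.0,  # 10x the 0.2 Delta-F/F0 background SD
        rise_time=entry["rise_time"],
        decay_tau=entry["decay_tau"],
        noise_sd=20.0,
        baseline_f0=100.0,
    )
    n_cells = int(math.ceil(1.3 * min_events / (spec.rate * spec.duration)))
    image, _ = synthesize_linescan(
        spec, n_cells=n_cells,
        rng=np.random.default_rng(np.random.SeedSequence([seed, 108])),
    )
    events = [
        e for e in detect_puffs(image, k_sd=5.5)
        if not (e.censored or e.overlap)
    ]
    if not events:
        raise RuntimeError("no puffs detected")
    return float(np.mean([e.fdhm for e in events])), len(events)


def recover_puff_frequency(
    seed: int = 12, n_cells: int = 64, genotype: str = "d2594k"
) -> tuple[float, int]:
    """Detected per-cell puff frequency (Hz) at the genotype's event rate.

    64 cells x 120 s by default, amplitude 10x background SD, detection at
    5.5 SD; frequency is detected events / (cells * duration).
    """
    entry = params.get_params(f"{genotype.lower()}_puffs")
    spec = PuffGenSpec(
        rate=entry["rate"],
        amplitude=2.0,
        rise_time=entry["rise_time"],
        decay_tau=entry["decay_tau"],
        noise_sd=20.0,
        baseline_f0=100.0,
    )
    image, _ = synthesize_linescan(
        spec, n_cells=n_cells,
        rng=np.random.default_rng(np.random.SeedSequence([seed, 110])),
    )
    events = detect_puffs(image, k_sd=5.5)
    return puff_frequency(events, n_cells, spec.duration), len(events)


def recover_mot_va50(seed: int = 11, noise_frac: float = 0.05) -> tuple[float, int]:
    """Va50 (mV) refit from noisy samples of the feedthrough MOT curve.

    12 EDF values in [60, 260] mV, 5% multiplicative Gaussian noise,
    double-Hill refit with the baseline fixed at 1.
    """
    model = params.get_model("wt_mot_edf")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 111]))
    edf_mv = np.linspace(60.0, 260.0, 12)
    y = mot_edf_model(edf_mv, model)
    y = y * (1.0 + rng.normal(0.0, noise_frac, size=y.size))
    fit = fit_mot_edf((edf_mv, y))
    return fit["va50"], len(edf_mv)
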