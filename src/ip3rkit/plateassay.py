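"""Synthetic plate-reader ATP dose-response assay.

Emulates fluorescence-plate recordings of global Ca2+ transients evoked by
extracellular ATP: each well trace is a baseline followed, at stimulus
time t = 0, by a transient

    F(t) = F0 * [1 + A * (1 - exp(-t/rise_tau)) * exp(-t/decay_tau)]

whose driving amplitude ``A`` follows a Hill function of the ATP
concentration.  Traces are sampled every 2 or 4 s with additive Gaussian
noise.  ``max_dff`` extracts the maximal Delta-F/F0 against the
pre-stimulus baseline, and ``atp_dose_response`` pools replicate wells per
ATP level and fits the Hill concentration-response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fits import FitResult, fit_hill
from .gating import HillParams, hill_po

__all__ = [
    "WellTrace",
    "synthesize_well",
    "max_dff",
    "peak_response_factor",
    "atp_dose_response",
]

DEFAULT_PRE_S = 20.0  # s of pre-stimulus baseline
DEFAULT_POST_S = 100.0  # s recorded after the stimulus


@dataclass
class WellTrace:
    """One well's fluorescence time series (a.u.)."""

    samples: np.ndarray
    dt: float  # s, 2 or 4
    atp: float  # mol/L
    genotype: str = ""
    n_pre: int = 0  # samples before the stimulus

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt not in (2.0, 4.0):
            raise ValueError("dt must be 2 or 4 s")
        if np.any(self.samples <= 0):
            raise ValueError("fluorescence samples must be positive")


def peak_response_factor(rise_tau: float, decay_tau: float) -> float:
    """Peak of ``(1 - exp(-t/a)) * exp(-t/b)``, attained at
    ``t* = a ln(1 + b/a)``.

    The measured maximal Delta-F/F0 equals the Hill driving amplitude
    times this factor.
    """
    a, b = rise_tau, decay_tau
    t_star = a * math.log(1.0 + b / a)
    return (1.0 - math.exp(-t_star / a)) * math.exp(-t_star / b)


def synthesize_well(
    atp: float,
    hill: HillParams,
    rise_tau: float = 5.0,
    decay_tau: float = 30.0,
    noise_sd: float = 5.0,
    dt: float = 2.0,
    f0: float = 100.0,
    pre_s: float = DEFAULT_PRE_S,
    post_s: float = DEFAULT_POST_S,
    genotype: str = "",
    rng=None,
    seed=None,
) -> WellTrace:
    """One synthetic well trace at the given ATP concentration.

    ``hill`` is the Delta-F/F0 amplitude ceiling curve (``pmax`` in
    Delta-F/F0 units); ``noise_sd`` is the additive Gaussian noise in the
    same arbitrary units as ``f0``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    amp = hill_po(atp, hill) if atp > 0 else 0.0
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    t = np.arange(n_post) * dt
    resp = amp * (1.0 - np.exp(-t / rise_tau)) * np.exp(-t / decay_tau)
    f = f0 * np.concatenate([np.ones(n_pre), 1.0 + resp])
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    f = np.maximum(f, 1e-6)  # fluorescence cannot go negative
    return WellTrace(samples=f, dt=dt, atp=atp, genotype=genotype, n_pre=n_pre)


def max_dff(trace: WellTrace) -> float:
    """Maximal Delta-F/F0 of a well trace.

    F0 is the mean of the pre-stimulus window (>= 5 samples required);
    the statistic is invariant to scaling the whole trace.
    """
    if trace.n_pre < 5:
        raise ValueError("need >= 5 pre-stimulus samples to estimate F0")
    f0 = float(trace.samples[: trace.n_pre].mean())
    if f0 <= 0:
        raise ValueError("non-positive baseline fluorescence")
    return float((trace.samples - f0).max() / f0)


def atp_dose_response(
    wells: Sequence[WellTrace],
) -> tuple[pd.DataFrame, FitResult]:
    """Pool wells by ATP level and fit the Hill concentration-response.

    Returns the per-level table (mean +/- SE of maximal Delta-F/F0) and
    the Hill fit.  Requires >= 4 ATP levels with >= 2 replicates each.
    """
    if not wells:
        raise ValueError("no wells supplied")
    groups: dict[float, list[float]] = {}
    for w in wells:
        groups.setdefault(w.atp, []).append(max_dff(w))
    if len(groups) < 4:
        raise ValueError(
            f"{len(groups)} ATP level(s) is too few for a Hill fit (need >= 4)"
        )
    rows = []
    for atp in sorted(groups):
        vals = np.asarray(groups[atp])
        if len(vals) < 2:
            raise ValueError(f"ATP level {atp} has fewer than 2 replicates")
        rows.append(
            {
                "x": atp,
                "y": float(vals.mean()),
                "y_err": float(vals.std(ddof=1) / math.sqrt(len(vals))),
                "n": len(vals),
            }
        )
    table = pd.DataFrame(rows)
    fit = fit_hill((table["x"].to_numpy(), table["y"].to_numpy()))
    return table, fit
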