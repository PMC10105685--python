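"""Parametric ligand dependence of IP3R1 gating, and Nernst/driving-force
arithmetic.

This module is the generative heart shared by the bilayer simulator and the
curve fitters:

* Hill dependence of open probability on an activating ligand (IP3, ATP):
  ``Po = Pmax / (1 + (EC50/L)^h)``.
* Biphasic (bell-shaped) dependence on cytosolic Ca2+, the product of an
  activating and an inhibiting Hill term:
  ``Po = Pmax * [1+(EC50/Ca)^ha]^-1 * [1+(Ca/IC50)^hi]^-1``.
* Ca2+ Nernst potential ``E_Ca = (RT/2F) ln([Ca]cis/[Ca]trans)`` and the
  electrochemical driving force ``EDF = Em - E_Ca`` (positive EDF drives
  trans->cis, i.e. lumen-to-cytosol, Ca2+ flux; the trans/luminal side
  carries the applied voltage with cis at ground).
* The "feedthrough" double-Hill model of normalized mean open time versus
  EDF, ``MOT = 1 + Range * [1+(Va50/EDF)^Ha]^-1 * [1+(EDF/Vi50)^Hi]^-1``,
  pinned to the baseline value 1 for EDF <= 0 where lumen-to-cytosol flux
  is absent and the printed expression is undefined for non-integer
  exponents.
* ``rates_from_po``, mapping an equilibrium (Po, mean open time) target
  onto two-state opening/closing rates for the stochastic simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "R_GAS",
    "FARADAY",
    "CA_VALENCE",
    "HillParams",
    "BiphasicHillParams",
    "FeedthroughMotParams",
    "IonConditions",
    "LigandSurface",
    "hill_po",
    "biphasic_po",
    "nernst_eca",
    "edf",
    "mot_edf_model",
    "rates_from_po",
]

R_GAS = 8.314  # J / (K mol)
FARADAY = 96485.0  # C / mol
CA_VALENCE = 2


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")


@dataclass(frozen=True)
class HillParams:
    """Hill activation curve: ceiling ``pmax``, midpoint ``ec50`` (mol/L),
    slope ``h``."""

    pmax: float
    ec50: float
    h: float

    def __post_init__(self) -> None:
        _require_finite(pmax=self.pmax, ec50=self.ec50, h=self.h)
        if not (0 < self.pmax <= 1.0 or self.pmax > 0):
            raise ValueError("pmax must be > 0")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")


@dataclass(frozen=True)
class BiphasicHillParams:
    """Bell-shaped Ca2+ dependence: activation (ec50_act, h_act) times
    inhibition (ic50_inh, h_inh), scaled by ``pmax``."""

    pmax: float
    ec50_act: float
    h_act: float
    ic50_inh: float
    h_inh: float

    def __post_init__(self) -> None:
        _require_finite(
            pmax=self.pmax,
            ec50_act=self.ec50_act,
            h_act=self.h_act,
            ic50_inh=self.ic50_inh,
            h_inh=self.h_inh,
        )
        if self.ec50_act <= 0 or self.ic50_inh <= 0:
            raise ValueError("ec50_act and ic50_inh must be > 0")
        if self.h_act <= 0 or self.h_inh <= 0:
            raise ValueError("Hill exponents must be > 0")


@dataclass(frozen=True)
class FeedthroughMotParams:
    """Double-Hill model of normalized mean open time versus EDF (mV)."""

    range: float
    va50: float  # mV
    ha: float
    vi50: float  # mV
    hi: float

    def __post_init__(self) -> None:
        _require_finite(
            range=self.range, va50=self.va50, ha=self.ha,
            vi50=self.vi50, hi=self.hi,
        )
        if self.range <= 0:
            raise ValueError("range must be > 0")
        if self.va50 <= 0 or self.vi50 <= 0:
            raise ValueError("va50 and vi50 must be > 0")


@dataclass(frozen=True)
class IonConditions:
    """Membrane potential and cis/trans Ca2+ for Nernst arithmetic.

    ``em`` is the applied potential on the trans (luminal) side, cis at
    ground, in mV.  Concentrations are free Ca2+ in mol/L.
    """

    em: float  # mV
    ca_cis: float  # mol/L
    ca_trans: float  # mol/L
    temperature: float = 295.15  # K (22 degC)

    def __post_init__(self) -> None:
        _require_finite(
            em=self.em, ca_cis=self.ca_cis, ca_trans=self.ca_trans,
            temperature=self.temperature,
        )
        if self.ca_cis <= 0 or self.ca_trans <= 0:
            raise ValueError("cis/trans Ca2+ must be > 0 for a Nernst potential")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def hill_po(ligand, params: HillParams):
    """Open probability from a Hill activation curve.

    Accepts scalar or array ligand concentration (mol/L, >= 0).
    ``hill_po(0) == 0``; saturates at ``pmax``.
    """
    ligand_arr = np.asarray(ligand, dtype=float)
    if np.any(ligand_arr < 0) or not np.all(np.isfinite(ligand_arr)):
        raise ValueError("ligand must be finite and >= 0")
    lh = np.power(ligand_arr, params.h)
    out = params.pmax * lh / (lh + params.ec50 ** params.h)
    return out if out.ndim else float(out)


def biphasic_po(ca, params: BiphasicHillParams):
    """Bell-shaped open probability versus cytosolic Ca2+ (mol/L).

    Vanishes at 0 and at saturating Ca2+; unimodal in between.
    """
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr < 0) or not np.all(np.isfinite(ca_arr)):
        raise ValueError("ca must be finite and >= 0")
    act_h = np.power(ca_arr, params.h_act)
    act = act_h / (act_h + params.ec50_act ** params.h_act)
    inh = 1.0 / (1.0 + np.power(ca_arr / params.ic50_inh, params.h_inh))
    out = params.pmax * act * inh
    return out if out.ndim else float(out)


def biphasic_peak(
    params: BiphasicHillParams,
    lo: float = 1e-9,
    hi: float = 1e-2,
    pts_per_decade: int = 1000,
) -> Tuple[float, float]:
    """Location and value of the biphasic maximum by dense log-grid search."""
    n = int(round(math.log10(hi / lo) * pts_per_decade)) + 1
    grid = np.logspace(math.log10(lo), math.log10(hi), n)
    vals = biphasic_po(grid, params)
    k = int(np.argmax(vals))
    return float(grid[k]), float(vals[k])


def nernst_eca(cond: IonConditions) -> float:
    """Ca2+ Nernst potential in mV for the cis/trans gradient.

    ``E_Ca = (RT / zF) ln([Ca]cis / [Ca]trans)`` with z = 2.
    """
    volts = (
        R_GAS * cond.temperature / (CA_VALENCE * FARADAY)
    ) * math.log(cond.ca_cis / cond.ca_trans)
    return volts * 1000.0


def edf(cond: IonConditions) -> float:
    """Electrochemical Ca2+ driving force ``Em - E_Ca`` in mV.

    Positive values drive trans-to-cis (lumen-to-cytosol) Ca2+ flux.
    """
    return cond.em - nernst_eca(cond)


def mot_edf_model(edf_mv, params: FeedthroughMotParams):
    """Normalized mean open time as a double-Hill function of EDF (mV).

    Baseline 1 for EDF <= 0 (no lumen-to-cytosol flux); bounded above by
    ``1 + range``.  Continuous at EDF -> 0+.
    """
    e = np.asarray(edf_mv, dtype=float)
    out = np.ones_like(e)
    pos = e > 0
    if np.any(pos):
        ep = e[pos]
        act = 1.0 / (1.0 + np.power(params.va50 / ep, params.ha))
        inh = 1.0 / (1.0 + np.power(ep / params.vi50, params.hi))
        out[pos] = 1.0 + params.range * act * inh
    return out if out.ndim else float(out)


def rates_from_po(po: float, mot: float) -> Tuple[float, float]:
    """Two-state (C<->O) rates from equilibrium Po and mean open time.

    closing = 1/MOT; opening = Po / ((1-Po) * MOT), so that the implied
    equilibrium open fraction opening/(opening+closing) equals ``po``.
    """
    if not (0.0 < po < 1.0):
        raise ValueError(f"po must lie strictly in (0, 1), got {po}")
    if not (mot > 0 and math.isfinite(mot)):
        raise ValueError(f"mot must be finite and > 0, got {mot}")
    closing = 1.0 / mot
    opening = po / ((1.0 - po) * mot)
    return opening, closing


@dataclass(frozen=True)
class LigandSurface:
    """Joint Po surface over (IP3, cytosolic Ca2+).

    The per-axis dose-response data constrain each ligand axis at fixed
    co-ligands; no joint equation is implied by them.  The simulator's
    modelling choice here is a separable product

        Po(IP3, Ca) = pmax * f_IP3(IP3) * f_Ca(Ca)

    with ``f_IP3`` a unit-ceiling Hill factor and ``f_Ca`` the biphasic
    factor normalized so its peak equals 1.  Per-axis fits never depend on
    this composition rule.
    """

    pmax: float
    ip3: HillParams
    ca: BiphasicHillParams

    def po(self, ip3: float, ca: float) -> float:
        f_ip3 = hill_po(ip3, HillParams(1.0, self.ip3.ec50, self.ip3.h))
        _, peak = biphasic_peak(self.ca)
        f_ca = biphasic_po(ca, self.ca) / peak
        return float(self.pmax * f_ip3 * f_ca)
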