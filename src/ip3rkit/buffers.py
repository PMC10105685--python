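"""Total/free Ca2+ interconversion in multi-chelator solutions.

Recording solutions in bilayer and imaging experiments set the free Ca2+
concentration with mixtures of high-affinity chelators (EGTA, BAPTA,
dibromo-BAPTA).  At equilibrium a single-metal system obeys the mass
conservation

    Ca_total = Ca_free + sum_i  T_i * Ca_free / (Ca_free + Kd_i)

where ``T_i`` is the total concentration of chelator *i* and ``Kd_i`` its
apparent Ca2+ dissociation constant at the working pH, temperature and
ionic strength.  The forward map (free from total) requires a root solve;
the inverse (total needed for a target free level) is closed-form.

Apparent Kd values are condition dependent.  The shipped table
(:data:`CHELATOR_KD`) holds values appropriate for pH 7.4, ~22 degC,
~0.1 M ionic strength, frozen for reproducibility; override per
:class:`ChelatorSpec` when other conditions apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from scipy.optimize import brentq

__all__ = [
    "CHELATOR_KD",
    "ChelatorSpec",
    "BufferSystem",
    "free_ca",
    "total_ca_for_free",
]

#: Apparent Ca2+ dissociation constants (mol/L) at pH 7.4, ~22 degC,
#: ~0.1 M ionic strength.  Frozen defaults; real experiments should supply
#: constants matched to their exact solution composition.
CHELATOR_KD: dict[str, float] = {
    "egta": 150e-9,
    "bapta": 220e-9,
    "dibromo-bapta": 1.6e-6,
}


@dataclass(frozen=True)
class ChelatorSpec:
    """One chelator species: total concentration and apparent Ca2+ Kd."""

    name: str
    total_conc: float  # mol/L
    kd_ca: float  # mol/L

    def __post_init__(self) -> None:
        if not (math.isfinite(self.total_conc) and math.isfinite(self.kd_ca)):
            raise ValueError("chelator concentrations must be finite")
        if self.total_conc < 0:
            raise ValueError(f"total_conc must be >= 0, got {self.total_conc}")
        if self.kd_ca <= 0:
            raise ValueError(f"kd_ca must be > 0, got {self.kd_ca}")

    @classmethod
    def from_table(cls, name: str, total_conc: float) -> "ChelatorSpec":
        """Build a spec using the shipped apparent-Kd table."""
        key = name.lower()
        if key not in CHELATOR_KD:
            raise KeyError(
                f"unknown chelator {name!r}; known: {sorted(CHELATOR_KD)}"
            )
        return cls(name=key, total_conc=total_conc, kd_ca=CHELATOR_KD[key])


@dataclass(frozen=True)
class BufferSystem:
    """A chelator mixture with a stated total Ca2+ content.

    pH and temperature are carried as metadata only: they are assumed to be
    already folded into each chelator's apparent Kd.
    """

    chelators: tuple[ChelatorSpec, ...]
    total_ca: float  # mol/L
    ph: float = 7.4
    temperature: float = 295.15  # K

    def __init__(
        self,
        chelators: Sequence[ChelatorSpec] = (),
        total_ca: float = 0.0,
        ph: float = 7.4,
        temperature: float = 295.15,
    ) -> None:
        object.__setattr__(self, "chelators", tuple(chelators))
        object.__setattr__(self, "total_ca", float(total_ca))
        object.__setattr__(self, "ph", float(ph))
        object.__setattr__(self, "temperature", float(temperature))
        if not math.isfinite(self.total_ca):
            raise ValueError("total_ca must be finite")
        if self.total_ca < 0:
            raise ValueError(f"total_ca must be >= 0, got {self.total_ca}")
        names = [c.name for c in self.chelators]
        if len(set(names)) != len(names):
            raise ValueError(f"chelator names must be unique, got {names}")

    def bound_ca(self, free: float) -> float:
        """Chelator-bound Ca2+ at a given free concentration."""
        return sum(
            c.total_conc * free / (free + c.kd_ca) for c in self.chelators
        )

    def with_total_ca(self, total_ca: float) -> "BufferSystem":
        return replace(self, total_ca=total_ca)


def free_ca(system: BufferSystem, rtol: float = 1e-12) -> float:
    """Free Ca2+ concentration (mol/L) of a buffer system.

    Solves the conservation equation by bracketed root finding on
    ``[0, total_ca]``.  The conservation function is strictly monotone in
    the free concentration, so the root is unique.
    """
    total = system.total_ca
    if total == 0.0:
        return 0.0
    if not system.chelators:
        return total

    def residual(c: float) -> float:
        return c + system.bound_ca(c) - total

    # residual(0) = -total < 0; residual(total) = bound(total) >= 0.
    # xtol far below any physical concentration so that heavily buffered
    # systems (free << 1 pM) still resolve relative to rtol
    return float(
        brentq(residual, 0.0, total, rtol=rtol, xtol=1e-30, maxiter=300)
    )


def total_ca_for_free(system: BufferSystem, target_free: float) -> float:
    """Total Ca2+ (mol/L) needed to reach ``target_free`` in this mixture.

    Closed form: ``total = free * (1 + sum_i T_i / (free + Kd_i))``.
    ``system.total_ca`` is ignored.
    """
    if not math.isfinite(target_free):
        raise ValueError("target_free must be finite")
    if target_free < 0:
        raise ValueError(f"target_free must be >= 0, got {target_free}")
    if target_free == 0.0:
        return 0.0
    return target_free + system.bound_ca(target_free)
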