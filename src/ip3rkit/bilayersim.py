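"""Synthetic planar-bilayer experiments with known gating ground truth.

Pipeline: two-state (closed <-> open) Markov gating with exponential dwell
times -> per-channel open/closed event trains -> summed unitary currents
rendered at the digitizer rate -> Gaussian low-pass filter (matched -3 dB
corner to the recording chain's analog filter) -> additive Gaussian noise.

Conventions follow bilayer practice: the trans (luminal) side carries the
applied potential with cis at ground, and positive current (upward
deflections) is trans-to-cis cation flux, so openings at positive
potentials deflect upward.  Default acquisition settings are 20 kHz
sampling, 2 kHz corner, 248 pS unitary conductance in symmetric Cs+.

The default noise amplitude (0.8 pA RMS before filtering, ~0.37 pA after)
keeps the half-amplitude threshold at +30 mV (3.7 pA, about 10 post-filter
noise SDs away) essentially free of false crossings; it is configurable.
Flicker noise, baseline drift and capacitive transients are not
modelled; add them to ``CurrentTrace.samples`` directly for robustness
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .gating import LigandSurface, rates_from_po

__all__ = [
    "SimConfig",
    "EventTrain",
    "CurrentTrace",
    "filter_sigma_samples",
    "simulate_train",
    "render_trace",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and rendering settings for one synthetic bilayer record."""

    duration: float  # s
    n_channels: int = 1
    sample_rate: float = 20_000.0  # Hz
    filter_corner: Optional[float] = 2_000.0  # Hz; None disables filtering
    conductance: float = 248.0  # pS
    reversal: float = 0.0  # mV
    em: float = 30.0  # mV, applied on trans side
    noise_sd: float = 0.8  # pA, pre-filter RMS
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.filter_corner is not None and self.sample_rate < 2 * self.filter_corner:
            raise ValueError("sample_rate must be >= 2 * filter_corner")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def unitary_current(self) -> float:
        """Open-level unitary current in pA: conductance * (Em - Erev) / 1000."""
        return self.conductance * (self.em - self.reversal) / 1000.0


@dataclass
class EventTrain:
    """Alternating open/closed dwell sequence for one channel over [0, T].

    ``states`` holds 0 (closed) / 1 (open); ``durations`` are seconds.
    Events are contiguous, non-overlapping and strictly alternating.
    """

    states: np.ndarray
    durations: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.states) != len(self.durations):
            raise ValueError("states and durations must have equal length")
        if len(self.states) > 1 and np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("states must alternate")

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.durations)[:-1]))

    @property
    def open_fraction(self) -> float:
        return float(self.durations[self.states == 1].sum() / self.duration)

    def open_intervals(self) -> np.ndarray:
        """(n, 2) array of open (start, stop) times in seconds."""
        starts = self.starts
        sel = self.states == 1
        return np.column_stack((starts[sel], starts[sel] + self.durations[sel]))


@dataclass
class CurrentTrace:
    """A rendered current record plus its provenance metadata."""

    samples: np.ndarray
    sample_rate: float
    config: Optional[SimConfig] = None
    ligands: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def filter_sigma_samples(sample_rate: float, corner: float) -> float:
    """Gaussian-kernel sigma (in samples) giving -3 dB at ``corner`` Hz.

    A Gaussian impulse response with time-domain sigma ``s`` has
    ``|H(f)| = exp(-2 pi^2 s^2 f^2)``; solving ``|H(fc)| = 1/sqrt(2)``
    gives ``s = sqrt(ln 2) / (2 pi fc)`` seconds.
    """
    return math.sqrt(math.log(2.0)) / (2.0 * math.pi * corner) * sample_rate


def simulate_train(
    opening_rate: float,
    closing_rate: float,
    duration: float,
    seed=None,
) -> EventTrain:
    """Two-state Markov gating: exponential dwells, equilibrium start state.

    ``seed`` may be an int, a SeedSequence, or a Generator; the same seed
    reproduces the same train bit-for-bit.
    """
    if opening_rate <= 0 or closing_rate <= 0:
        raise ValueError("rates must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    po_eq = opening_rate / (opening_rate + closing_rate)
    state = int(rng.random() < po_eq)

    mean_dwell = (po_eq / closing_rate) + ((1 - po_eq) / opening_rate)
    # chunked sampling until the record is covered
    states: list[np.ndarray] = []
    durations: list[np.ndarray] = []
    covered = 0.0
    s = state
    while covered < duration:
        n = max(16, int(2 * (duration - covered) / mean_dwell) + 16)
        # dwell in state s has rate = exit rate of s
        seq_states = np.empty(n, dtype=np.int8)
        seq_states[0::2] = s
        seq_states[1::2] = 1 - s
        rates = np.where(seq_states == 1, closing_rate, opening_rate)
        dwells = rng.exponential(1.0 / rates)
        states.append(seq_states)
        durations.append(dwells)
        covered += float(dwells.sum())
        s = int(seq_states[-1] == 0)  # next chunk starts in the other state

    st = np.concatenate(states)
    du = np.concatenate(durations)
    ends = np.cumsum(du)
    last = int(np.searchsorted(ends, duration))
    st, du = st[: last + 1], du[: last + 1].copy()
    du[-1] -= ends[last] - duration  # truncate final dwell at T
    return EventTrain(st, du, duration)


def render_trace(
    trains: Sequence[EventTrain],
    config: SimConfig,
    rng=None,
) -> CurrentTrace:
    """Render event trains into a filtered, noisy current record (pA)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    fs = config.sample_rate
    open_count = np.zeros(n, dtype=float)
    for train in trains:
        for start, stop in train.open_intervals():
            i0 = int(round(start * fs))
            i1 = int(round(stop * fs))
            open_count[i0 : min(i1, n)] += 1.0
    x = open_count * config.unitary_current
    if config.filter_corner is not None:
        sigma = filter_sigma_samples(fs, config.filter_corner)
        x = gaussian_filter1d(x, sigma, mode="nearest")
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=n)
    return CurrentTrace(samples=x, sample_rate=fs, config=config)


def simulate_experiment(
    ligands: dict,
    surface,
    mot: float,
    config: SimConfig,
):
    """Full synthetic experiment: ligand conditions -> Po -> gating -> trace.

    ``surface`` is either a :class:`~ip3rkit.gating.LigandSurface` (Po from
    the joint IP3 x Ca product surface) or a callable mapping the ligand
    dict to an equilibrium Po.  Returns ``(CurrentTrace, [EventTrain, ...])``
    with the trace metadata recording the ligand conditions.
    """
    if isinstance(surface, LigandSurface):
        po = surface.po(ligands.get("ip3", 0.0), ligands.get("ca_cis", 0.0))
    else:
        po = float(surface(ligands))
    if not (0.0 < po < 1.0):
        raise ValueError(
            f"surface gives Po={po} for ligands {ligands}; need 0 < Po < 1"
        )
    opening, closing = rates_from_po(po, mot)
    root = np.random.SeedSequence(config.seed)
    train_seeds = root.spawn(config.n_channels + 1)
    trains = [
        simulate_train(opening, closing, config.duration, seed=s)
        for s in train_seeds[:-1]
    ]
    trace = render_trace(
        trains, config, rng=np.random.default_rng(train_seeds[-1])
    )
    trace.ligands = dict(ligands)
    return trace, trains
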