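"""Half-amplitude idealization and single-channel gating statistics.

A current record is reduced to a sequence of discrete conductance-level
events by the half-amplitude threshold-crossing technique: a sample sits at
level ``k`` when the baseline-subtracted current exceeds ``(k - 1/2)``
unitary amplitudes.  Events briefer than the dead time (default 300 us)
are censored, their duration merged into the flanking events.  From the
idealized record the module derives nPo, mean open/closed times, event
counts, channel-count estimates (maximum stacking level, corroborated by
the mode count of the all-points amplitude histogram), and
maximum-likelihood exponential dwell-time fits.

Records shorter than 3 minutes trigger a warning (not an error): open
probability is conventionally measured from idealized records longer than
3 min.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import chi2

from .bilayersim import CurrentTrace

__all__ = [
    "DEFAULT_DEAD_TIME",
    "MIN_RECORD_S",
    "Idealization",
    "ChannelStats",
    "idealize_trace",
    "apply_dead_time",
    "estimate_n_channels",
    "amplitude_histogram_modes",
    "channel_stats",
    "fit_dwell_mixture",
]

DEFAULT_DEAD_TIME = 300e-6  # s; events briefer than this are censored
MIN_RECORD_S = 180.0  # conventional minimum record length for Po estimates
_EPS = 1e-12


@dataclass
class Idealization:
    """Contiguous, non-overlapping level events covering a whole record.

    Durations are stored as integer sample counts so that total duration is
    conserved exactly through censoring; second-valued views are derived.
    """

    levels: np.ndarray  # int level per event, >= 0
    n_samples: np.ndarray  # int samples per event
    sample_rate: float
    unitary_amplitude: float
    baseline: float
    dead_time: float = 0.0  # s; dead time already applied (0 = none)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.n_samples = np.asarray(self.n_samples, dtype=np.int64)
        if len(self.levels) != len(self.n_samples):
            raise ValueError("levels and n_samples must have equal length")
        if np.any(self.levels < 0) or np.any(self.n_samples <= 0):
            raise ValueError("levels must be >= 0 and event lengths positive")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def durations(self) -> np.ndarray:
        return self.n_samples / self.sample_rate

    @property
    def starts(self) -> np.ndarray:
        return np.concatenate(
            ([0], np.cumsum(self.n_samples)[:-1])
        ) / self.sample_rate

    @property
    def record_length(self) -> float:
        return int(self.n_samples.sum()) / self.sample_rate


@dataclass
class ChannelStats:
    """Summary gating statistics of one idealized record."""

    npo: float
    mot: float  # s; NaN when not applicable
    mct: float  # s; NaN when undefined (e.g. no closures)
    n_open_events: int
    n_channels_est: int
    record_length: float
    mot_applicable: bool = True
    dwell_fit_open: Optional[dict] = None
    dwell_fit_closed: Optional[dict] = None


def idealize_trace(
    trace,
    unitary: float,
    baseline: Optional[float] = None,
    n_levels: int = 1,
) -> Idealization:
    """Half-amplitude threshold idealization of a current record.

    ``trace`` is a :class:`~ip3rkit.bilayersim.CurrentTrace` or a plain
    array (then ``sample_rate`` is taken as 1.0).  A sample is assigned
    level ``k`` (clipped to ``[0, n_levels]``) when the baseline-subtracted
    current, in units of the unitary amplitude, rounds to ``k`` — i.e. it
    crosses the ``(k - 1/2)`` half-amplitude thresholds.  A negative
    ``unitary`` selects downward openings.

    With ``baseline=None`` the baseline is estimated as the center of the
    highest-density mode of the amplitude histogram (robust when Po is
    low); pass it explicitly when known.
    """
    if unitary == 0:
        raise ValueError("unitary amplitude must be nonzero")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if isinstance(trace, CurrentTrace):
        x = np.asarray(trace.samples, dtype=float)
        fs = trace.sample_rate
    else:
        x = np.asarray(trace, dtype=float)
        fs = 1.0
    if x.size == 0:
        raise ValueError("empty trace")

    sign = 1.0 if unitary > 0 else -1.0
    amp = abs(unitary)
    if baseline is None:
        baseline = _estimate_baseline(x, amp)

    rel = sign * (x - baseline) / amp
    if np.mean(rel) < -0.25:
        warnings.warn(
            "trace polarity appears opposite to the unitary amplitude sign; "
            "consider flipping the sign of `unitary`",
            stacklevel=2,
        )
    level = np.clip(np.floor(rel + 0.5).astype(np.int64), 0, n_levels)

    # run-length encode
    change = np.flatnonzero(np.diff(level)) + 1
    bounds = np.concatenate(([0], change, [len(level)]))
    levels = level[bounds[:-1]]
    counts = np.diff(bounds)
    return Idealization(
        levels=levels,
        n_samples=counts,
        sample_rate=fs,
        unitary_amplitude=float(unitary),
        baseline=float(baseline),
    )


def _estimate_baseline(x: np.ndarray, amp: float) -> float:
    """Histogram-mode baseline: median of samples near the densest bin."""
    nbins = max(50, int(np.ptp(x) / (amp / 20)) if amp > 0 else 50)
    nbins = min(nbins, 2000)
    hist, edges = np.histogram(x, bins=nbins)
    k = int(np.argmax(hist))
    center = 0.5 * (edges[k] + edges[k + 1])
    near = x[np.abs(x - center) < 0.5 * amp]
    return float(np.median(near)) if near.size else center


def apply_dead_time(
    ideal: Idealization, dead_time: float = DEFAULT_DEAD_TIME
) -> Idealization:
    """Censor events briefer than ``dead_time``.

    Each too-brief event is removed and its duration merged into the
    surrounding events: flanking events of equal level concatenate with it
    into one; otherwise it is absorbed into the longer flank (ties go to
    the preceding event).  Idempotent, and total duration is conserved
    exactly.
    """
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    if dead_time == 0 or len(ideal) <= 1:
        return replace(
            ideal,
            levels=ideal.levels.copy(),
            n_samples=ideal.n_samples.copy(),
            dead_time=max(dead_time, ideal.dead_time),
        )
    min_samples = int(math.ceil(dead_time * ideal.sample_rate - _EPS))
    levels = list(ideal.levels)
    counts = list(ideal.n_samples)

    def merge_equal_neighbors(i: int) -> None:
        # merge event i with i+1 when levels match (after a deletion)
        while 0 <= i < len(levels) - 1 and levels[i] == levels[i + 1]:
            counts[i] += counts.pop(i + 1)
            levels.pop(i + 1)

    changed = True
    while changed and len(levels) > 1:
        changed = False
        i = 0
        while i < len(levels) and len(levels) > 1:
            if counts[i] >= min_samples:
                i += 1
                continue
            changed = True
            if i == 0:
                counts[1] += counts.pop(0)
                levels.pop(0)
                continue
            if i == len(levels) - 1:
                counts[i - 1] += counts.pop(i)
                levels.pop(i)
                continue
            if levels[i - 1] == levels[i + 1]:
                counts[i - 1] += counts.pop(i) + counts[i]  # note: shifted
                counts.pop(i)
                levels.pop(i)
                levels.pop(i)
                i -= 1
                continue
            # flanks differ in level: absorb into the longer flank
            if counts[i + 1] > counts[i - 1]:
                counts[i + 1] += counts.pop(i)
                levels.pop(i)
            else:
                counts[i - 1] += counts.pop(i)
                levels.pop(i)
                merge_equal_neighbors(i - 1)
    return Idealization(
        levels=np.asarray(levels),
        n_samples=np.asarray(counts),
        sample_rate=ideal.sample_rate,
        unitary_amplitude=ideal.unitary_amplitude,
        baseline=ideal.baseline,
        dead_time=dead_time,
    )


def estimate_n_channels(ideal: Idealization) -> int:
    """Channel count as the maximal observed stacking level.

    Returns 0 (with a warning) for records with no openings, where the
    count is indeterminate.  Corroborate against
    :func:`amplitude_histogram_modes` on the raw trace.
    """
    if len(ideal) == 0:
        raise ValueError("empty idealization")
    n = int(ideal.levels.max())
    if n == 0:
        warnings.warn(
            "record contains no openings: channel count indeterminate",
            stacklevel=2,
        )
    return n


def amplitude_histogram_modes(
    trace, unitary: float, baseline: float = 0.0, min_weight: float = 0.005
) -> int:
    """Diagnostic mode count of the smoothed all-points amplitude histogram.

    The number of modes minus one corroborates the stacking-based channel
    count.  ``min_weight`` suppresses spurious peaks carrying less than
    that fraction of the samples.
    """
    x = trace.samples if isinstance(trace, CurrentTrace) else np.asarray(trace)
    amp = abs(unitary)
    bin_width = amp / 20.0
    lo, hi = x.min() - bin_width, x.max() + bin_width
    nbins = int(np.ceil((hi - lo) / bin_width))
    hist, _ = np.histogram(x, bins=nbins, range=(lo, hi))
    smooth = gaussian_filter1d(hist.astype(float), sigma=2.0)
    peaks, _ = find_peaks(smooth, height=min_weight * len(x), distance=10)
    return int(len(peaks))


def channel_stats(
    ideal: Idealization,
    fit_dwells: bool = False,
    min_record_s: float = MIN_RECORD_S,
) -> ChannelStats:
    """nPo, mean open/closed time and event counts from an idealization.

    nPo is the time-average level: ``sum_k k * t_k / T``.  MOT/MCT are
    arithmetic means of open (level >= 1) and closed dwell durations; for
    records where stacked openings occur (max level > 1) the per-channel
    open time is not identifiable from level dwells alone, so MOT/MCT are
    reported as NaN with ``mot_applicable=False``.  With ``fit_dwells``,
    exponential-mixture maximum-likelihood fits (1 or 2 components by
    likelihood ratio at alpha=0.05) are attached.
    """
    if len(ideal) == 0:
        raise ValueError("no events: statistics undefined")
    T = ideal.record_length
    if T <= 0:
        raise ValueError("record_length must be > 0")
    if T < min_record_s:
        warnings.warn(
            f"record is {T:.1f} s (< {min_record_s:.0f} s); open-probability "
            "estimates from short records are unreliable",
            stacklevel=2,
        )
    durations = ideal.durations
    levels = ideal.levels
    npo = float((levels * durations).sum() / T)
    open_mask = levels >= 1
    closed_mask = levels == 0
    n_open = int(open_mask.sum())
    n_ch = int(levels.max())
    mot_applicable = n_ch <= 1
    if n_open and mot_applicable:
        mot = float(durations[open_mask].mean())
    else:
        mot = float("nan")
    if closed_mask.any() and mot_applicable:
        mct = float(durations[closed_mask].mean())
    else:
        mct = float("nan")
    stats = ChannelStats(
        npo=npo,
        mot=mot,
        mct=mct,
        n_open_events=n_open,
        n_channels_est=n_ch,
        record_length=T,
        mot_applicable=mot_applicable,
    )
    if fit_dwells and mot_applicable:
        if n_open:
            stats.dwell_fit_open = fit_dwell_mixture(durations[open_mask])
        if closed_mask.any():
            stats.dwell_fit_closed = fit_dwell_mixture(durations[closed_mask])
    return stats


def _exp_mixture_loglik(t: np.ndarray, w: np.ndarray, tau: np.ndarray) -> float:
    dens = (w / tau) * np.exp(-t[:, None] / tau)
    return float(np.log(dens.sum(axis=1)).sum())


def fit_dwell_mixture(
    dwells: np.ndarray,
    max_components: int = 2,
    alpha: float = 0.05,
    n_iter: int = 300,
) -> dict:
    """ML exponential-mixture fit to dwell times (raw values, not binned).

    Fits 1- and (if allowed) 2-component exponential mixtures by EM and
    keeps the extra component only when the likelihood-ratio test improves
    at level ``alpha`` (chi-square, 2 df).  The single-component rate is
    exactly ``1/mean``.
    """
    t = np.asarray(dwells, dtype=float)
    t = t[t > 0]
    if t.size == 0:
        raise ValueError("no positive dwells")
    mean = float(t.mean())
    ll1 = _exp_mixture_loglik(t, np.array([1.0]), np.array([mean]))
    result = {
        "n_components": 1,
        "weights": [1.0],
        "taus": [mean],
        "loglik": ll1,
    }
    if max_components < 2 or t.size < 10:
        return result
    # EM for 2 components, quantile-split init
    tau = np.array([np.quantile(t, 0.25), np.quantile(t, 0.9)])
    tau = np.maximum(tau, 1e-12)
    if tau[1] <= tau[0]:
        tau[1] = tau[0] * 3
    w = np.array([0.5, 0.5])
    for _ in range(n_iter):
        dens = (w / tau) * np.exp(-t[:, None] / tau)
        resp = dens / dens.sum(axis=1, keepdims=True)
        nk = resp.sum(axis=0)
        w = nk / t.size
        tau = (resp * t[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        tau = np.maximum(tau, 1e-12)
    ll2 = _exp_mixture_loglik(t, w, tau)
    lr = 2.0 * (ll2 - ll1)
    if lr > chi2.ppf(1.0 - alpha, df=2):
        order = np.argsort(tau)
        result = {
            "n_components": 2,
            "weights": list(w[order]),
            "taus": list(tau[order]),
            "loglik": ll2,
            "lr_stat": lr,
        }
    return result
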