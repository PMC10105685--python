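"""Half-amplitude idealization, dead-time censoring, gating statistics."""

import warnings

import numpy as np
import pytest

from ip3rkit.bilayersim import CurrentTrace, SimConfig, render_trace, simulate_train
from ip3rkit.idealize import (
    Idealization,
    amplitude_histogram_modes,
    apply_dead_time,
    channel_stats,
    estimate_n_channels,
    fit_dwell_mixture,
    idealize_trace,
)

FS = 20_000.0


def trace_from(samples, fs=FS):
    return CurrentTrace(samples=np.asarray(samples, float), sample_rate=fs)


def ideal_from(levels, counts, fs=FS, unitary=1.0):
    return Idealization(
        levels=np.asarray(levels), n_samples=np.asarray(counts),
        sample_rate=fs, unitary_amplitude=unitary, baseline=0.0,
    )


class TestIdealizeTrace:
    def test_square_pulse_one_event(self):
        n = int(0.02 * FS)
        x = np.zeros(n)
        pulse = slice(int(0.005 * FS), int(0.010 * FS))
        x[pulse] = 7.44
        ideal = idealize_trace(trace_from(x), unitary=7.44, baseline=0.0)
        opens = ideal.levels == 1
        assert opens.sum() == 1
        assert ideal.durations[opens][0] == pytest.approx(0.005, abs=1 / FS)

    def test_stacked_pulse_level_two(self):
        x = np.zeros(1000)
        x[200:400] = 2 * 7.44
        ideal = idealize_trace(
            trace_from(x), unitary=7.44, baseline=0.0, n_levels=2
        )
        assert ideal.levels.max() == 2

    def test_negative_unitary_detects_downward_openings(self):
        x = np.zeros(1000)
        x[100:300] = -5.0
        ideal = idealize_trace(trace_from(x), unitary=-5.0, baseline=0.0)
        assert ideal.levels.max() == 1

    def test_wrong_polarity_warns(self):
        x = np.zeros(1000)
        x[:] = -5.0
        with pytest.warns(UserWarning, match="polarity"):
            idealize_trace(trace_from(x), unitary=5.0, baseline=0.0)

    def test_oracle_equivalence_on_clean_trace(self):
        """With no noise and no filtering, recovered event boundaries match
        the generating train within one sample."""
        train = simulate_train(40.0, 125.0, 10.0, seed=21)
        config = SimConfig(
            duration=10.0, noise_sd=0.0, filter_corner=None, em=30.0
        )
        trace = render_trace([train], config)
        ideal = idealize_trace(trace, unitary=7.44, baseline=0.0)
        got = ideal.starts[ideal.levels == 1]
        want = train.starts[train.states == 1]
        want_dur = train.durations[train.states == 1]
        # dwells shorter than one sample cannot survive rendering; every
        # surviving boundary must sit within one sample of a true one
        for g in got:
            assert np.abs(want - g).min() <= 1.0 / FS
        for w in want[want_dur >= 2.0 / FS]:
            assert np.abs(got - w).min() <= 1.0 / FS
        got_open = ideal.durations[ideal.levels == 1].sum()
        true_open = want_dur.sum()
        assert got_open == pytest.approx(true_open, abs=len(want) * 2.0 / FS)
        assert ideal.record_length == pytest.approx(10.0, rel=1e-12)

    def test_noisy_filtered_po_recovery(self):
        train = simulate_train(31.25, 125.0, 30.0, seed=33)  # Po = 0.2
        config = SimConfig(duration=30.0, em=30.0, noise_sd=0.8, seed=4)
        trace = render_trace([train], config)
        ideal = apply_dead_time(
            idealize_trace(trace, unitary=7.44, baseline=0.0), 300e-6
        )
        open_time = ideal.durations[ideal.levels == 1].sum()
        assert open_time / 30.0 == pytest.approx(
            train.open_fraction, rel=0.05
        )

    def test_baseline_autodetect_at_low_po(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.5, 0.3, 20000)  # offset baseline, no openings
        x[5000:5400] += 7.44
        ideal = idealize_trace(trace_from(x), unitary=7.44)
        assert ideal.baseline == pytest.approx(1.5, abs=0.1)
        assert (ideal.levels == 1).sum() == 1


class TestApplyDeadTime:
    def test_brief_event_removed_and_flanks_merge(self):
        # 200 us open event between closed epochs -> removed, one closed run
        counts = [1000, 4, 1000]  # 4 samples = 200 us
        ideal = ideal_from([0, 1, 0], counts)
        out = apply_dead_time(ideal, 300e-6)
        assert len(out) == 1
        assert out.levels[0] == 0
        assert out.n_samples[0] == 2004

    def test_300us_event_is_kept(self):
        ideal = ideal_from([0, 1, 0], [1000, 6, 1000])  # exactly 300 us
        out = apply_dead_time(ideal, 300e-6)
        assert len(out) == 3

    def test_zero_dead_time_is_identity(self):
        ideal = ideal_from([0, 1, 0, 1], [100, 3, 50, 2])
        out = apply_dead_time(ideal, 0.0)
        assert np.array_equal(out.levels, ideal.levels)
        assert np.array_equal(out.n_samples, ideal.n_samples)

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        n = 200
        levels = np.arange(n) % 2
        counts = rng.integers(1, 30, size=n)
        ideal = ideal_from(levels, counts)
        once = apply_dead_time(ideal, 300e-6)
        twice = apply_dead_time(once, 300e-6)
        assert np.array_equal(once.levels, twice.levels)
        assert np.array_equal(once.n_samples, twice.n_samples)

    def test_conservation_and_event_count(self):
        rng = np.random.default_rng(5)
        n = 500
        levels = np.arange(n) % 2
        counts = rng.integers(1, 40, size=n)
        ideal = ideal_from(levels, counts)
        out = apply_dead_time(ideal, 300e-6)
        assert out.n_samples.sum() == ideal.n_samples.sum()  # exact
        assert len(out) <= len(ideal)
        assert np.all(out.n_samples >= 6)


class TestEstimateNChannels:
    def test_single_channel(self):
        ideal = ideal_from([0, 1, 0], [100, 50, 100])
        assert estimate_n_channels(ideal) == 1

    def test_three_channel_simulation_reaches_three(self):
        """Po = 0.4 per channel for 3 channels: triple stacking is near
        certain over 3 minutes."""
        config = SimConfig(
            duration=180.0, n_channels=3, em=30.0, noise_sd=0.0,
            filter_corner=None,
        )
        trains = [
            simulate_train(*((0.4 / 0.6 / 8e-3, 1 / 8e-3)), 180.0, seed=s)
            for s in (1, 2, 3)
        ]
        trace = render_trace(trains, config)
        ideal = idealize_trace(trace, unitary=7.44, baseline=0.0, n_levels=3)
        assert estimate_n_channels(ideal) == 3

    def test_all_closed_warns_and_returns_zero(self):
        ideal = ideal_from([0], [1000])
        with pytest.warns(UserWarning, match="indeterminate"):
            assert estimate_n_channels(ideal) == 0

    def test_amplitude_histogram_modes_corroborate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.3, 50000)
        x[10000:25000] += 7.44  # one open level
        assert amplitude_histogram_modes(trace_from(x), unitary=7.44) == 2


class TestChannelStats:
    def test_alternating_fixed_dwells(self):
        # 10 ms open / 30 ms closed repeated: npo = 0.25 exactly
        reps = 50
        levels = np.tile([1, 0], reps)
        counts = np.tile([200, 600], reps)  # samples at 20 kHz
        stats = channel_stats(ideal_from(levels, counts), min_record_s=0.0)
        assert stats.npo == pytest.approx(0.25, rel=1e-12)
        assert stats.mot == pytest.approx(0.010, rel=1e-12)
        assert stats.mct == pytest.approx(0.030, rel=1e-12)
        assert stats.n_open_events == reps

    def test_permanently_open_channel(self):
        stats = channel_stats(ideal_from([1], [100000]), min_record_s=0.0)
        assert stats.npo == pytest.approx(1.0)
        assert np.isnan(stats.mct)

    def test_exponential_dwell_mean_recovery(self):
        """5000 exponential open dwells of mean 10 ms: MOT within 3 SE."""
        rng = np.random.default_rng(8)
        n = 5000
        opens = rng.exponential(0.010, n)
        closed = rng.exponential(0.020, n)
        counts = np.empty(2 * n, dtype=int)
        counts[0::2] = np.maximum((opens * FS).round(), 1)
        counts[1::2] = np.maximum((closed * FS).round(), 1)
        levels = np.tile([1, 0], n)
        stats = channel_stats(ideal_from(levels, counts), min_record_s=0.0)
        se = 0.010 / np.sqrt(n)
        assert stats.mot == pytest.approx(0.010, abs=3 * se)

    def test_short_record_warns(self):
        with pytest.warns(UserWarning, match="unreliable"):
            channel_stats(ideal_from([0, 1, 0], [1000, 100, 1000]))

    def test_multichannel_mot_not_applicable(self):
        stats = channel_stats(
            ideal_from([0, 1, 2, 1, 0], [100, 50, 20, 50, 100]),
            min_record_s=0.0,
        )
        assert not stats.mot_applicable
        assert np.isnan(stats.mot)
        # npo still well defined: (1*50 + 2*20 + 1*50)/320
        assert stats.npo == pytest.approx(140.0 / 320.0, rel=1e-12)


class TestDwellMixture:
    def test_single_exponential_rate_is_inverse_mean(self):
        rng = np.random.default_rng(17)
        dwells = rng.exponential(0.01, 3000)
        fit = fit_dwell_mixture(dwells)
        assert fit["n_components"] == 1
        assert fit["taus"][0] == pytest.approx(dwells.mean(), rel=1e-9)

    def test_clear_two_component_mixture_detected(self):
        rng = np.random.default_rng(23)
        dwells = np.concatenate([
            rng.exponential(0.001, 3000), rng.exponential(0.05, 3000)
        ])
        fit = fit_dwell_mixture(dwells)
        assert fit["n_components"] == 2
        taus = fit["taus"]
        assert taus[0] == pytest.approx(0.001, rel=0.2)
        assert taus[1] == pytest.approx(0.05, rel=0.2)
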