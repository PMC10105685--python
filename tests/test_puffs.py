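"""Linescan synthesis, puff detection, kinetic measurement."""

import math

import numpy as np
import pytest

from ip3rkit.puffs import (
    LN2,
    LN4,
    LinescanImage,
    PuffGenSpec,
    _event_waveform,
    delta_f_over_f0,
    detect_puffs,
    measure_kinetics,
    puff_frequency,
    synthesize_linescan,
)

WT_SPEC = PuffGenSpec(
    rate=0.04, amplitude=2.0, rise_time=0.35 / 0.6,
    decay_tau=(0.68 - 0.5 * 0.35 / 0.6) / LN2,
    noise_sd=20.0, baseline_f0=100.0, duration=120.0,
)


def single_event_image(spec, t0=15.0, x_um=5.0, rng=None):
    quiet = PuffGenSpec(
        rate=1e-12, amplitude=spec.amplitude, rise_time=spec.rise_time,
        decay_tau=spec.decay_tau, noise_sd=spec.noise_sd,
        baseline_f0=spec.baseline_f0, duration=spec.duration,
    )
    image, _ = synthesize_linescan(quiet, n_cells=1, rng=rng)
    t = np.arange(image.pixels.shape[1]) * spec.dt
    w = _event_waveform(t - t0, spec.rise_time, spec.decay_tau)
    x = np.arange(image.pixels.shape[0]) * spec.dx
    g = np.exp(-((x - x_um) ** 2) / (2 * spec.spatial_sigma**2))
    image.pixels += spec.amplitude * spec.baseline_f0 * np.outer(g, w)
    return image


class TestSynthesize:
    def test_zero_rate_detects_nothing(self):
        spec = PuffGenSpec(rate=1e-12, noise_sd=20.0, duration=60.0)
        image, truth = synthesize_linescan(
            spec, n_cells=4, rng=np.random.default_rng(0)
        )
        assert truth == []
        assert detect_puffs(image, k_sd=5.5) == []

    def test_clean_single_event_peak_equals_amplitude(self):
        spec = PuffGenSpec(rate=0.04, amplitude=2.0, noise_sd=0.0)
        # align the event's peak time and center with the sampling grid so
        # the identity is exact rather than sampling-limited
        image = single_event_image(
            spec, t0=15.6 - spec.rise_time, x_um=8 * spec.dx,
            rng=np.random.default_rng(1),
        )
        dff = delta_f_over_f0(image)
        assert dff.max() == pytest.approx(2.0, rel=1e-9)

    def test_poisson_event_count_within_99pct_interval(self):
        # expectation 40 events: 99% interval approx mean +/- 2.58 sqrt(mean)
        spec = PuffGenSpec(rate=0.05, amplitude=2.0, noise_sd=0.0,
                           duration=100.0)
        _, truth = synthesize_linescan(
            spec, n_cells=8, rng=np.random.default_rng(2)
        )
        mean = 0.05 * 100.0 * 8
        assert abs(len(truth) - mean) <= 2.58 * math.sqrt(mean) + 1

    def test_ground_truth_kinetics_closed_form(self):
        spec = PuffGenSpec(rate=0.5, amplitude=2.0, noise_sd=0.0,
                           duration=30.0)
        _, truth = synthesize_linescan(
            spec, n_cells=1, rng=np.random.default_rng(3)
        )
        e = truth[0]
        assert e.rise_20_80 == pytest.approx(0.6 * spec.rise_time)
        assert e.decay_80_20 == pytest.approx(spec.decay_tau * LN4)
        assert e.fdhm == pytest.approx(
            0.5 * spec.rise_time + spec.decay_tau * LN2
        )


class TestDetect:
    def test_recall_and_precision_on_strong_events(self):
        """Amplitude >= 8 background SDs: recall >= 0.95, false-positive
        rate <= 0.02 events/cell/min over a 200-image Monte Carlo."""
        rng = np.random.default_rng(42)
        tp = fp = fn = 0
        cell_minutes = 0.0
        for _ in range(200):
            spec = PuffGenSpec(
                rate=0.03, amplitude=1.6, noise_sd=20.0, duration=60.0
            )
            image, truth = synthesize_linescan(spec, n_cells=2, rng=rng)
            events = detect_puffs(image, k_sd=5.5)
            cell_minutes += 2 * 1.0
            used = set()
            for e in events:
                match = None
                for i, t in enumerate(truth):
                    if i in used:
                        continue
                    if (
                        abs(t.t_peak - e.t_peak) < 1.5
                        and abs(t.position - e.position) < 3.0
                    ):
                        match = i
                        break
                if match is None:
                    fp += 1
                else:
                    used.add(match)
                    tp += 1
            fn += len(truth) - len(used)
        assert tp / (tp + fn) >= 0.95
        assert fp / cell_minutes <= 0.02

    def test_subthreshold_event_missed_by_construction(self):
        spec = PuffGenSpec(rate=0.04, amplitude=0.3, noise_sd=20.0)
        image = single_event_image(spec, rng=np.random.default_rng(4))
        # amplitude 0.3 = 1.5 background SDs: below the 5.5 SD criterion
        assert detect_puffs(image, k_sd=5.5) == []

    def test_well_separated_events_never_merge(self):
        spec = PuffGenSpec(rate=1e-12, amplitude=2.0, noise_sd=5.0,
                           duration=120.0)
        image, _ = synthesize_linescan(
            spec, n_cells=1, cell_width_um=30.0, rng=np.random.default_rng(5)
        )
        t = np.arange(image.pixels.shape[1]) * spec.dt
        x = np.arange(image.pixels.shape[0]) * spec.dx
        for t0, x0 in ((20.0, 6.0), (60.0, 24.0)):  # >5 fdhm, >3 sigma apart
            w = _event_waveform(t - t0, spec.rise_time, spec.decay_tau)
            g = np.exp(-((x - x0) ** 2) / 2.0)
            image.pixels += 200.0 * np.outer(g, w)
        events = detect_puffs(image, k_sd=5.5)
        assert len(events) == 2

    def test_out_of_range_k_warns(self):
        spec = PuffGenSpec(rate=0.04, amplitude=2.0, noise_sd=20.0)
        image = single_event_image(spec, rng=np.random.default_rng(6))
        with pytest.warns(UserWarning, match="5-6.5"):
            detect_puffs(image, k_sd=3.0)

    def test_detected_kinetics_match_generator(self):
        spec = PuffGenSpec(rate=0.04, amplitude=2.0, noise_sd=20.0)
        image = single_event_image(spec, rng=np.random.default_rng(7))
        (event,) = detect_puffs(image, k_sd=5.5)
        assert event.fdhm == pytest.approx(0.68, rel=0.2)
        assert event.amplitude == pytest.approx(2.0, rel=0.25)
        assert event.cell_id == 0


class TestMeasureKinetics:
    def test_symmetric_triangle_fdhm_is_half_base(self):
        dt = 0.01
        w = 1.0
        t = np.arange(0, 2 * w + 5 * dt, dt)
        y = np.concatenate([np.zeros(50), np.maximum(1 - np.abs(t - w) / w, 0)])
        kin = measure_kinetics(y, dt)
        assert kin.fdhm == pytest.approx(w, abs=2 * dt)

    @pytest.mark.parametrize("rise", [0.3, 0.6, 1.2])
    @pytest.mark.parametrize("tau", [0.4, 1.0, 2.5])
    def test_ramp_exponential_closed_forms(self, rise, tau):
        dt = 0.01
        t = np.arange(0, rise + 10 * tau, dt)
        y = np.concatenate([np.zeros(30), _event_waveform(t, rise, tau)])
        kin = measure_kinetics(y, dt)
        assert kin.rise_20_80 == pytest.approx(0.6 * rise, abs=dt)
        assert kin.decay_80_20 == pytest.approx(tau * LN4, abs=dt)
        assert kin.fdhm == pytest.approx(0.5 * rise + tau * LN2, abs=dt)
        assert kin.time_to_peak == pytest.approx(rise, abs=dt)
        assert not kin.censored

    def test_one_sample_spike_floors_at_dt(self):
        y = np.zeros(50)
        y[25] = 1.0
        kin = measure_kinetics(y, 0.1)
        assert kin.fdhm == pytest.approx(0.1)
        assert kin.rise_20_80 == pytest.approx(0.1)

    def test_never_returning_profile_is_censored(self):
        y = np.concatenate([np.zeros(10), np.linspace(0, 1, 40)])
        kin = measure_kinetics(y, 0.1)
        assert kin.censored

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            measure_kinetics(np.zeros(20), 0.1)


class TestFrequency:
    def test_zero_events(self):
        assert puff_frequency([], 4, 120.0) == 0.0

    def test_arithmetic(self):
        assert puff_frequency(list(range(12)), 1, 120.0) == pytest.approx(0.1)
        assert puff_frequency(list(range(24)), 2, 120.0) == pytest.approx(0.1)

    def test_estimator_unbiased_over_seeds(self):
        """Mean detected frequency over independent syntheses lies within
        2 SE of the generating rate (sparse regime)."""
        rate = 0.03
        freqs = []
        for seed in range(30):
            spec = PuffGenSpec(
                rate=rate, amplitude=2.0, noise_sd=20.0, duration=60.0
            )
            image, _ = synthesize_linescan(
                spec, n_cells=4, rng=np.random.default_rng(seed)
            )
            events = detect_puffs(image, k_sd=5.5)
            freqs.append(puff_frequency(events, 4, 60.0))
        mean = np.mean(freqs)
        se = np.std(freqs, ddof=1) / math.sqrt(len(freqs))
        assert abs(mean - rate) <= 2 * se + 0.002

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            puff_frequency([], 0, 120.0)
        with pytest.raises(ValueError):
            puff_frequency([], 1, 0.0)
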