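"""Curve fitting: self-consistency, noise tolerance, degenerate flags."""

import math

import numpy as np
import pandas as pd
import pytest

from ip3rkit.bilayersim import SimConfig, render_trace, simulate_train
from ip3rkit.fits import (
    dose_response_pipeline,
    fit_biphasic_hill,
    fit_hill,
    fit_linear_iv,
    fit_mot_edf,
    mct_overlay,
)
from ip3rkit.gating import (
    BiphasicHillParams,
    FeedthroughMotParams,
    HillParams,
    biphasic_po,
    hill_po,
    mot_edf_model,
    rates_from_po,
)

WT_HILL = HillParams(0.2, 660e-9, 1.8)
WT_BIPH = BiphasicHillParams(0.1, 78e-9, 2.0, 562e-9, 2.0)
MOT = FeedthroughMotParams(3.0, 111.5, 7.8, 170.7, 3.7)


class TestFitHill:
    x8 = np.logspace(-8, -5, 8)

    def test_noise_free_exact_recovery(self):
        fit = fit_hill((self.x8, hill_po(self.x8, WT_HILL)))
        assert fit.converged
        assert fit["pmax"] == pytest.approx(0.2, rel=1e-6)
        assert fit["ec50"] == pytest.approx(660e-9, rel=1e-6)
        assert fit["h"] == pytest.approx(1.8, rel=1e-6)

    def test_noisy_replicate_means_within_15pct(self):
        rng = np.random.default_rng(1)
        y = hill_po(self.x8, WT_HILL)
        reps = y[None, :] * (1 + rng.normal(0, 0.05, (6, 8)))
        fit = fit_hill((self.x8, reps.mean(axis=0)))
        assert fit["ec50"] == pytest.approx(660e-9, rel=0.15)

    def test_flat_data_flagged_not_raised(self):
        fit = fit_hill((self.x8, np.full(8, 0.07)))
        assert not fit.converged
        assert "unidentifiable" in fit.message or math.isnan(fit["ec50"])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_hill((self.x8[:3], np.ones(3)))

    def test_narrow_x_span_rejected(self):
        x = np.linspace(1e-6, 2e-6, 6)
        with pytest.raises(ValueError):
            fit_hill((x, hill_po(x, WT_HILL)))

    def test_estimator_calibration(self):
        """Across 200 noisy replicates: median relative EC50 error < 5%
        and 95% CI coverage within [90%, 99%]."""
        rng = np.random.default_rng(99)
        errors, covered = [], 0
        n_rep = 200
        for _ in range(n_rep):
            y0 = hill_po(self.x8, WT_HILL)
            y = y0 * (1 + rng.normal(0, 0.05, 8) / math.sqrt(6))
            fit = fit_hill((self.x8, y), y_err=0.05 * y0 / math.sqrt(6))
            err = fit["ec50"] / 660e-9 - 1
            errors.append(abs(err))
            if abs(fit["ec50"] - 660e-9) <= 1.96 * fit.se["ec50"]:
                covered += 1
        assert np.median(errors) < 0.05
        assert 0.90 <= covered / n_rep <= 0.99


class TestFitBiphasic:
    x12 = np.logspace(-8, -5, 12)

    def test_noise_free_exact_recovery(self):
        fit = fit_biphasic_hill((self.x12, biphasic_po(self.x12, WT_BIPH)))
        assert fit.converged
        assert fit["ec50_act"] == pytest.approx(78e-9, rel=1e-5)
        assert fit["ic50_inh"] == pytest.approx(562e-9, rel=1e-5)
        assert fit["pmax"] == pytest.approx(0.1, rel=1e-5)

    def test_3pct_noise_within_20pct(self):
        rng = np.random.default_rng(7)
        y = biphasic_po(self.x12, WT_BIPH)
        y = y * (1 + rng.normal(0, 0.03, 12))
        fit = fit_biphasic_hill((self.x12, y), y_err=0.03 * np.abs(y))
        assert fit["ec50_act"] == pytest.approx(78e-9, rel=0.20)
        assert fit["ic50_inh"] == pytest.approx(562e-9, rel=0.20)

    def test_ordering_constraint_holds(self):
        rng = np.random.default_rng(3)
        y = biphasic_po(self.x12, WT_BIPH) * (1 + rng.normal(0, 0.05, 12))
        fit = fit_biphasic_hill((self.x12, y))
        assert fit["ic50_inh"] > fit["ec50_act"]

    def test_monotone_data_flags_inhibition_unidentifiable(self):
        y = hill_po(self.x12, HillParams(0.1, 300e-9, 2.0))
        fit = fit_biphasic_hill((self.x12, y))
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_biphasic_hill((self.x12[:5], np.ones(5)))


class TestFitLinearIV:
    def test_exact_line(self):
        v = np.array([-40.0, -20.0, 20.0, 40.0])
        fit = fit_linear_iv((v, 0.248 * v))
        assert fit["conductance_pS"] == pytest.approx(248.0, rel=1e-12)
        assert fit["reversal_mV"] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_within_2se(self):
        rng = np.random.default_rng(3)
        v = np.array([-40.0, -30.0, -20.0, 20.0, 30.0, 40.0])
        i = 0.248 * v + rng.normal(0, 0.2, 6)
        fit = fit_linear_iv((v, i))
        assert abs(fit["conductance_pS"] - 248.0) <= 2 * fit.se["conductance_pS"]

    def test_two_points_exact_interpolation(self):
        fit = fit_linear_iv((np.array([-30.0, 30.0]), np.array([-7.44, 7.44])))
        assert fit["conductance_pS"] == pytest.approx(248.0, rel=1e-12)

    def test_order_invariance(self):
        v = np.array([-40.0, -20.0, 20.0, 40.0])
        i = 0.248 * v + np.array([0.1, -0.05, 0.02, -0.08])
        a = fit_linear_iv((v, i))
        b = fit_linear_iv((v[::-1], i[::-1]))
        assert a["conductance_pS"] == pytest.approx(
            b["conductance_pS"], rel=1e-12
        )

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_iv((np.array([10.0, 10.0]), np.array([1.0, 2.0])))


class TestFitMotEdf:
    edf12 = np.linspace(60.0, 260.0, 12)

    def test_noise_free_exact_recovery(self):
        fit = fit_mot_edf((self.edf12, mot_edf_model(self.edf12, MOT)))
        assert fit.converged
        assert fit["va50"] == pytest.approx(111.5, rel=1e-4)
        assert fit["vi50"] == pytest.approx(170.7, rel=1e-4)
        assert fit["ha"] == pytest.approx(7.8, rel=1e-3)

    def test_5pct_noise_va50_within_10pct(self):
        rng = np.random.default_rng(11)
        y = mot_edf_model(self.edf12, MOT)
        y = y * (1 + rng.normal(0, 0.05, 12))
        fit = fit_mot_edf((self.edf12, y))
        assert fit["va50"] == pytest.approx(111.5, rel=0.10)

    def test_activation_limb_only_flags_vi50(self):
        e = np.linspace(60.0, 130.0, 8)
        fit = fit_mot_edf((e, mot_edf_model(e, MOT)))
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_too_few_positive_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mot_edf((np.array([-40.0, -20.0, 60.0, 80.0]), np.ones(4)))


class TestMctOverlay:
    edf = np.linspace(60.0, 260.0, 10)

    def _mot_fit(self):
        return fit_mot_edf((self.edf, mot_edf_model(self.edf, MOT)))

    def test_exact_affine_recovery(self):
        mot_fit = self._mot_fit()
        m = mot_edf_model(self.edf, MOT)
        mct = 5.0 - 2.0 * m
        out = mct_overlay(mot_fit, (self.edf, mct))
        assert out["a"] == pytest.approx(5.0, rel=1e-6)
        assert out["b"] == pytest.approx(2.0, rel=1e-6)
        assert out["rss"] < 1e-10

    def test_constant_mct_gives_zero_scale(self):
        out = mct_overlay(self._mot_fit(), (self.edf, np.full(10, 3.0)))
        assert out["b"] == pytest.approx(0.0, abs=1e-9)

    def test_inverted_noisy_model_beats_constant(self):
        rng = np.random.default_rng(5)
        m = mot_edf_model(self.edf, MOT)
        mct = 4.0 - 1.5 * m + rng.normal(0, 0.1, 10)
        out = mct_overlay(self._mot_fit(), (self.edf, mct))
        assert out["rss"] < out["rss_const"]
        assert out["p_value"] < 0.05


class TestDoseResponsePipeline:
    @staticmethod
    def _traces(levels, n_rep=2, duration=10.0):
        out = {}
        config = SimConfig(duration=duration, em=30.0, noise_sd=0.8)
        seed = 0
        for conc in levels:
            po = hill_po(conc, HillParams(0.1, 660e-9, 1.8))
            traces = []
            for _ in range(n_rep):
                if po > 0:
                    train = simulate_train(
                        *rates_from_po(po, 8e-3), duration, seed=seed
                    )
                else:
                    train = simulate_train(1e-9, 125.0, duration, seed=seed)
                traces.append(
                    render_trace(
                        [train], config, rng=np.random.default_rng(1000 + seed)
                    )
                )
                seed += 1
            out[conc] = traces
        return out

    def test_table_and_fit_round_trip(self):
        levels = np.logspace(math.log10(30e-9), math.log10(10e-6), 7)
        table, fit = dose_response_pipeline(
            self._traces(levels, duration=20.0), unitary=7.44
        )
        assert list(table.columns) == ["x", "y", "y_err", "n"]
        assert len(table) == 7
        assert fit["ec50"] == pytest.approx(660e-9, rel=0.5)

    def test_single_condition_returns_table_refuses_fit(self):
        traces = self._traces([1e-6])
        with pytest.raises(ValueError, match="fit=None"):
            dose_response_pipeline(traces, unitary=7.44)
        table, fit = dose_response_pipeline(traces, unitary=7.44, fit=None)
        assert len(table) == 1 and fit is None

    def test_zero_activity_conditions_retained(self):
        levels = [1e-9, 3e-9, 1e-8, 1e-6, 3e-6, 1e-5]
        table, _ = dose_response_pipeline(
            self._traces(levels), unitary=7.44, fit=None
        )
        assert len(table) == 6
        assert (table["y"] >= 0).all()
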