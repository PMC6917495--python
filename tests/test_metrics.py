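"""Trace statistics: QC thresholds, robust peaks, DSI arithmetic, event
detection, rise/decay timing on closed-form ramps, superposition, MAD,
and cosine fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from t5model.metrics import (EventThresholds, StimulusTrials, TrialSet,
                             baseline_sd, detect_flash_response, dsi,
                             fit_cosine, mad_peak, response_max,
                             rise_decay_metrics, superpose, trial_qc)


def _trial_set(traces_by_label, dt_ms=1.0, onset_ms=100.0, group="flash"):
    ts = TrialSet()
    for label, traces in traces_by_label.items():
        ts.add(StimulusTrials(traces=np.asarray(traces, float), dt_ms=dt_ms,
                              onset_ms=onset_ms, label=label, group=group))
    return ts


class TestTrialQC:
    def test_identical_trials_all_included(self):
        ts = _trial_set({"a": np.full((3, 500), -58.0)})
        masks = trial_qc(ts, "flash")
        assert masks["a"].all()

    def test_group_baseline_shift_excluded_at_10mV(self):
        base = np.full((5, 500), -58.0)
        base[2] += 15.0  # pre-stim baseline 12 mV off the pooled group mean
        ts = _trial_set({"a": base})
        masks = trial_qc(ts, "flash")
        assert not masks["a"][2]
        assert masks["a"][[0, 1, 3, 4]].all()

    def test_trial_overall_mean_rule_15_vs_25(self):
        # baseline 0, large sustained response shifts the whole-trial mean
        trace = np.zeros(1000)
        trace[100:] = 22.0  # overall mean ~19.8, pre-stim mean 0
        trials = np.tile(trace, (3, 1))
        ts = _trial_set({"bar": trials}, group="movbar")
        assert not trial_qc(ts, "movbar", slow_moving_bar=False)["bar"].any()
        assert trial_qc(ts, "movbar", slow_moving_bar=True)["bar"].all()

    def test_empty_prestim_window_rejected(self):
        ts = _trial_set({"a": np.zeros((2, 100))}, onset_ms=0.0)
        with pytest.raises(ValueError, match="pre-stimulus"):
            trial_qc(ts, "flash")


class TestResponseMax:
    def test_constant_trace(self):
        assert response_max(np.full(100, 3.2)) == pytest.approx(3.2)

    def test_linear_interpolation_quantile(self):
        assert response_max(np.arange(1000.0)) == pytest.approx(994.005)

    def test_single_sample_window(self):
        assert response_max(np.array([1.0, 5.0, 2.0]), slice(1, 2)) == 5.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            response_max(np.arange(10.0), slice(5, 5))


class TestDSI:
    def test_arithmetic(self):
        pd_t = np.full(200, 10.0)
        nd_t = np.full(200, 4.0)
        assert dsi(pd_t, nd_t) == pytest.approx(0.6)

    def test_identical_traces_zero(self):
        t = np.random.default_rng(0).normal(5, 1, 300)
        assert dsi(t, t) == pytest.approx(0.0)

    def test_zero_nd_gives_one(self):
        assert dsi(np.full(100, 8.0), np.zeros(100)) == pytest.approx(1.0)

    def test_nonpositive_pd_undefined(self):
        assert math.isnan(dsi(np.full(100, -1.0), np.zeros(100)))

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_positive_rescaling(self, scale):
        rng = np.random.default_rng(4)
        pd_t = rng.uniform(1, 10, 200)
        nd_t = rng.uniform(0, 5, 200)
        assert dsi(scale * pd_t, scale * nd_t) == pytest.approx(dsi(pd_t, nd_t))


class TestFlashDetection:
    def _trace(self, peak_sd, sd=1.0, n=800, onset=200, dur=160):
        trace = np.zeros(n)
        trace[onset + 50:onset + 150] = peak_sd * sd
        return trace

    def test_flat_trace_no_events(self):
        base = np.random.default_rng(1).normal(0, 1.0, 5000)
        dep, hyp = detect_flash_response(np.zeros(800), 1.0, 200.0, 160.0, 2, base)
        assert dep == 0.0 and hyp == 0.0

    @pytest.mark.parametrize("width,peak_sd,detected", [
        (1, 3.0, True),   # threshold 2.5
        (1, 2.4, False),
        (2, 2.8, True),   # threshold 2.7
        (2, 2.6, False),
        (4, 2.8, False),  # threshold 2.9
        (4, 3.0, True),
    ])
    def test_depolarization_width_thresholds(self, width, peak_sd, detected):
        sd = 1.0
        base = np.random.default_rng(2).normal(0, sd, 200_000)
        sd_est = baseline_sd(base)
        trace = self._trace(peak_sd * sd_est / sd, sd=sd)
        dep, _ = detect_flash_response(trace, 1.0, 200.0, 160.0, width, base)
        assert (dep > 0) == detected

    @pytest.mark.parametrize("width,dip_sd,detected", [
        (1, 2.0, True),   # threshold 1.5
        (1, 1.2, False),
        (4, 1.8, False),  # threshold 1.9
        (4, 2.2, True),
    ])
    def test_hyperpolarization_thresholds(self, width, dip_sd, detected):
        base = np.random.default_rng(3).normal(0, 1.0, 200_000)
        sd_est = baseline_sd(base)
        trace = np.zeros(800)
        trace[500:700] = -dip_sd * sd_est
        _, hyp = detect_flash_response(trace, 1.0, 200.0, 160.0, width, base)
        assert (hyp < 0) == detected

    def test_depol_window_excludes_late_peak(self):
        # peak after flash offset + 75 ms must not count as depolarization
        base = np.random.default_rng(4).normal(0, 1.0, 100_000)
        trace = np.zeros(1000)
        trace[600:700] = 10.0  # onset 200 + dur 160 + 75 = 435 window end
        dep, _ = detect_flash_response(trace, 1.0, 200.0, 160.0, 2, base)
        assert dep == 0.0

    def test_degenerate_baseline_floored(self):
        trace = np.zeros(800)
        trace[300:400] = 1e-3
        dep, _ = detect_flash_response(trace, 1.0, 200.0, 160.0, 1,
                                       np.zeros(1000))
        assert dep > 0  # any response clears the floored SD

    def test_gaussian_fit_sd_close_to_sample_sd(self):
        samples = np.random.default_rng(5).normal(0, 1.3, 50_000)
        assert baseline_sd(samples, "gaussian_fit") == pytest.approx(
            baseline_sd(samples, "sample_sd"), rel=1e-9)


class TestRiseDecay:
    def test_linear_ramp_closed_form(self):
        T = 400.0
        trace = np.concatenate([np.zeros(100), np.linspace(0, 1, int(T) + 1)])
        rise_start, rise_time, decay_time = rise_decay_metrics(trace, 1.0, 100.0)
        assert rise_start == pytest.approx(0.1 * T, abs=0.5)
        assert rise_time == pytest.approx(0.4 * T, abs=0.5)
        assert math.isnan(decay_time)  # never decays

    def test_step_to_max_at_onset(self):
        trace = np.concatenate([np.zeros(100), np.ones(200)])
        rise_start, rise_time, _ = rise_decay_metrics(trace, 1.0, 100.0)
        assert rise_start == 0.0 and rise_time == 0.0

    def test_triangular_pulse_decay(self):
        up = np.linspace(0, 1, 101)
        down = np.linspace(1, 0, 201)
        trace = np.concatenate([np.zeros(50), up, down[1:]])
        _, _, decay_time = rise_decay_metrics(trace, 1.0, 50.0)
        assert decay_time == pytest.approx(0.6 * 200, abs=0.5)


class TestSuperpose:
    def test_single_component_identity(self):
        comp = np.sin(np.linspace(0, 3, 200))
        out = superpose({0: comp}, {0: 0.0}, 200, 1.0)
        assert np.allclose(out, comp)

    def test_disjoint_supports_concatenate(self):
        a = np.ones(50)
        out = superpose({0: a, 1: 2 * a}, {0: 0.0, 1: 100.0}, 200, 1.0)
        assert out[:50].sum() == 50 and out[100:150].sum() == 100
        assert not out[50:100].any() and not out[150:].any()

    def test_overlap_sums(self):
        a = np.ones(100)
        out = superpose({0: a, 1: a}, {0: 0.0, 1: 50.0}, 200, 1.0)
        assert out[60] == 2.0

    def test_missing_component_named(self):
        with pytest.raises(ValueError, match="position 3"):
            superpose({0: np.ones(10)}, {0: 0.0, 3: 5.0}, 50, 1.0)


class TestMadPeak:
    def test_identical_repeats_zero(self):
        mean = np.sin(np.linspace(0, 3, 500))
        trials = np.tile(mean, (4, 1))
        assert mad_peak(trials, mean, 1.0) == pytest.approx(0.0)

    def test_uniform_offsets(self):
        mean = np.zeros(500)
        mean[250] = 5.0
        trials = np.stack([mean + 1.0, mean - 1.0])
        assert mad_peak(trials, mean, 1.0) == pytest.approx(1.0)

    def test_window_clipped_at_edge(self):
        mean = np.zeros(120)
        mean[110] = 3.0  # peak within 50 ms of the end
        trials = np.tile(mean, (3, 1))
        assert mad_peak(trials, mean, 1.0) == pytest.approx(0.0)

    def test_requires_two_trials(self):
        mean = np.zeros(100)
        with pytest.raises(ValueError, match="2 trials"):
            mad_peak(mean[None, :], mean, 1.0)


class TestCosineFit:
    def _cosine(self, amp, phase, f_hz, n_ms=3000, dt=1.0, offset=0.0):
        t = np.arange(0, n_ms, dt) / 1000.0
        return offset + amp * np.cos(2 * np.pi * f_hz * t + phase)

    def test_recovers_amplitude_and_phase(self):
        trace = self._cosine(3.0, np.pi / 4, 3.125)
        fit = fit_cosine(trace, 1.0, 3.125)
        assert fit.amplitude_mV == pytest.approx(3.0, rel=1e-6)
        assert fit.phase_rad == pytest.approx(np.pi / 4, abs=1e-6)

    def test_dc_offset_does_not_change_amplitude(self):
        a = fit_cosine(self._cosine(2.0, 0.3, 0.78125, n_ms=6000), 1.0, 0.78125)
        b = fit_cosine(self._cosine(2.0, 0.3, 0.78125, n_ms=6000, offset=-57.0),
                       1.0, 0.78125)
        assert a.amplitude_mV == pytest.approx(b.amplitude_mV, rel=1e-9)
        assert b.offset_mV == pytest.approx(-57.0, rel=1e-6)

    def test_first_cycle_transient_removed(self):
        trace = self._cosine(2.0, 1.0, 3.125)
        corrupted = trace.copy()
        corrupted[:320] += 15.0  # onset transient confined to cycle 1
        fit_drop = fit_cosine(corrupted, 1.0, 3.125, drop_first_cycle=True)
        fit_keep = fit_cosine(corrupted, 1.0, 3.125, drop_first_cycle=False)
        assert fit_drop.amplitude_mV == pytest.approx(2.0, rel=1e-6)
        assert abs(fit_keep.amplitude_mV - 2.0) > 0.05

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="2 cycles"):
            fit_cosine(self._cosine(1.0, 0.0, 3.125, n_ms=700), 1.0, 3.125)


class TestEventThresholds:
    def test_defaults_match_analysis_conventions(self):
        thr = EventThresholds()
        assert thr.depolarization == {1: 2.5, 2: 2.7, 4: 2.9}
        assert thr.hyperpolarization == {1: 1.5, 2: 1.7, 4: 1.9}

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            EventThresholds(depolarization={1: 1.0}, hyperpolarization={1: 1.5})
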