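"""Trace statistics for whole-cell-style voltage recordings.

Implements the standard analysis battery for flashed-bar / moving-bar
experiments: baseline-stability trial QC, robust quantile peaks, the
directional selectivity index, single-position flash-response detection
against baseline-noise thresholds, rise/decay timing, linear superposition
predictions, trial-to-trial peak deviation (MAD), and cosine fits to
drifting-grating responses.

All operators are pure functions of their inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "StimulusTrials",
    "TrialSet",
    "EventThresholds",
    "trial_qc",
    "response_max",
    "dsi",
    "baseline_sd",
    "detect_flash_response",
    "rise_decay_metrics",
    "superpose",
    "mad_peak",
    "fit_cosine",
    "CosineFit",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class StimulusTrials:
    """Repeated trials for one stimulus: absolute voltage in mV.

    ``traces`` has shape (n_trials, n_samples); ``onset_ms`` marks stimulus
    appearance on the shared time grid; ``group`` identifies the stimulus
    block used for cross-trial baseline statistics.
    """

    traces: np.ndarray
    dt_ms: float
    onset_ms: float
    label: str
    group: str = "default"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.traces.shape[0] < 1:
            raise ValueError("at least one trial is required")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def onset_sample(self) -> int:
        return int(round(self.onset_ms / self.dt_ms))

    def pre_stimulus(self) -> np.ndarray:
        """Pre-stimulus samples, shape (n_trials, onset_sample)."""
        if self.onset_sample <= 0:
            raise ValueError(f"stimulus {self.label!r} has no pre-stimulus window")
        return self.traces[:, :self.onset_sample]

    def mean_trace(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Across-trial mean (optionally over QC-included trials only)."""
        traces = self.traces if mask is None else self.traces[np.asarray(mask, bool)]
        if traces.shape[0] == 0:
            raise ValueError(f"no included trials for stimulus {self.label!r}")
        return traces.mean(axis=0)


@dataclass
class TrialSet:
    """Collection of per-stimulus trial blocks sharing one recording."""

    stimuli: dict[str, StimulusTrials] = field(default_factory=dict)

    def add(self, st: StimulusTrials) -> None:
        self.stimuli[st.label] = st

    def __getitem__(self, label: str) -> StimulusTrials:
        return self.stimuli[label]

    def __iter__(self):
        return iter(self.stimuli.values())

    def __len__(self) -> int:
        return len(self.stimuli)

    def labels(self) -> list[str]:
        return list(self.stimuli)

    def group(self, group: str) -> list[StimulusTrials]:
        return [s for s in self.stimuli.values() if s.group == group]


# ---------------------------------------------------------------------------
# trial QC

def trial_qc(trials: TrialSet, group: str,
             slow_moving_bar: bool = False,
             group_limit_mV: float = 10.0,
             trial_limit_mV: float = 15.0,
             slow_bar_limit_mV: float = 25.0) -> dict[str, np.ndarray]:
    """Baseline-stability inclusion mask per stimulus in a group.

    A trial is included iff (a) its pre-stimulus mean lies within
    ``group_limit_mV`` of the pooled pre-stimulus mean over all trials of
    the group, and (b) its pre-stimulus mean lies within
    ``trial_limit_mV`` (or ``slow_bar_limit_mV`` for slow moving bars) of
    its own whole-trial mean.
    """
    members = trials.group(group)
    if not members:
        raise ValueError(f"no stimuli in group {group!r}")
    pre_means = {s.label: s.pre_stimulus().mean(axis=1) for s in members}
    group_mean = float(np.concatenate(list(pre_means.values())).mean())
    limit_b = slow_bar_limit_mV if slow_moving_bar else trial_limit_mV
    masks: dict[str, np.ndarray] = {}
    for s in members:
        overall = s.traces.mean(axis=1)
        pm = pre_means[s.label]
        masks[s.label] = (np.abs(pm - group_mean) <= group_limit_mV) \
            & (np.abs(pm - overall) <= limit_b)
    return masks


# ---------------------------------------------------------------------------
# peaks and DSI

def response_max(trace: np.ndarray, window: slice | None = None,
                 quantile: float = 0.995) -> float:
    """Robust response maximum: the ``quantile`` (default 0.995) of the
    samples in ``window``, using the linear-interpolation quantile
    estimator. More robust to single-sample noise than the raw peak."""
    trace = np.asarray(trace, dtype=float)
    seg = trace[window] if window is not None else trace
    if seg.size == 0:
        raise ValueError("response window is empty")
    return float(np.quantile(seg, quantile))


def dsi(pd_trace: np.ndarray, nd_trace: np.ndarray,
        window: slice | None = None) -> float:
    """Directional selectivity index (PDmax - NDmax) / PDmax, with each
    maximum the robust 0.995-quantile peak within the stimulus window.

    Returns nan when PDmax is not positive (undefined index).
    """
    pd_max = response_max(pd_trace, window)
    nd_max = response_max(nd_trace, window)
    if pd_max <= 0:
        return math.nan
    return (pd_max - nd_max) / pd_max


# ---------------------------------------------------------------------------
# flash-response detection

@dataclass(frozen=True)
class EventThresholds:
    """Detection thresholds in multiples of the baseline SD, keyed by bar
    width. Hyperpolarization uses lower multiples than depolarization
    because those responses are weaker."""

    depolarization: Mapping[int, float] = field(
        default_factory=lambda: {1: 2.5, 2: 2.7, 4: 2.9})
    hyperpolarization: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.5, 2: 1.7, 4: 1.9})
    sd_method: str = "gaussian_fit"

    def __post_init__(self) -> None:
        for w, thr in self.depolarization.items():
            if thr <= 0 or self.hyperpolarization[w] <= 0:
                raise ValueError("thresholds must be positive")
            if self.hyperpolarization[w] >= thr:
                raise ValueError("hyperpolarization thresholds must be below "
                                 "depolarization thresholds")


#: Floor applied when the pooled baseline is degenerate (zero variance).
SD_FLOOR_MV = 1e-6


def baseline_sd(baseline_samples: np.ndarray,
                method: str = "gaussian_fit") -> float:
    """Baseline noise SD from pooled pre-stimulus samples.

    ``gaussian_fit`` fits a normal distribution and takes its sigma (the
    default); ``sample_sd`` is the plain standard deviation fallback. A
    zero-variance baseline is floored at ``SD_FLOOR_MV``.
    """
    samples = np.asarray(baseline_samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("baseline_samples must be nonempty")
    if method == "gaussian_fit":
        _, sd = stats.norm.fit(samples)
    elif method == "sample_sd":
        sd = samples.std(ddof=0)
    else:
        raise ValueError(f"unknown baseline SD method {method!r}")
    return max(float(sd), SD_FLOOR_MV)


def detect_flash_response(mean_trace: np.ndarray, dt_ms: float,
                          onset_ms: float, flash_duration_ms: float,
                          width: int, baseline_samples: np.ndarray,
                          thresholds: EventThresholds | None = None,
                          extra_window_ms: float = 75.0) -> tuple[float, float]:
    """Detect the depolarizing and hyperpolarizing single-position flash
    response (SPFR) amplitudes of a baseline-subtracted mean trace.

    Depolarization: 0.995 quantile between stimulus onset and flash offset
    + 75 ms; zero unless it exceeds the width-specific SD multiple.
    Hyperpolarization: 0.005 quantile between onset and trace end (slower
    time course), zero unless below minus its (lower) SD multiple.

    Returns ``(depol, hyperpol)``; depol >= 0 and hyperpol <= 0, either
    being exactly 0 when undetected.
    """
    thresholds = thresholds or EventThresholds()
    mean_trace = np.asarray(mean_trace, dtype=float)
    sd = baseline_sd(baseline_samples, thresholds.sd_method)
    i_on = int(round(onset_ms / dt_ms))
    i_dep = int(round((onset_ms + flash_duration_ms + extra_window_ms) / dt_ms))
    i_dep = min(i_dep, mean_trace.size)
    dep = response_max(mean_trace, slice(i_on, i_dep), 0.995)
    hyp = float(np.quantile(mean_trace[i_on:], 0.005))
    dep_out = dep if dep > thresholds.depolarization[width] * sd else 0.0
    hyp_out = hyp if hyp < -thresholds.hyperpolarization[width] * sd else 0.0
    return dep_out, hyp_out


# ---------------------------------------------------------------------------
# rise / decay timing

def _cross_time(t: np.ndarray, y: np.ndarray, level: float,
                rising: bool) -> float:
    """First time y crosses ``level`` (linear interpolation); nan if never."""
    above = y >= level if rising else y <= level
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return math.nan
    i = idx[0]
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    frac = (level - y0) / (y1 - y0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def rise_decay_metrics(mean_trace: np.ndarray, dt_ms: float,
                       onset_ms: float) -> tuple[float, float, float]:
    """Timing of a depolarizing response relative to stimulus onset.

    Returns ``(rise_start_ms, rise_time_ms, decay_time_ms)``:
    time from onset to the first 10%-of-peak crossing, from the 10% to the
    50% crossing, and from the post-peak 80% crossing down to the 20%
    crossing. Crossings are linearly interpolated; a level never crossed
    yields nan for that metric.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    i_on = int(round(onset_ms / dt_ms))
    resp = mean_trace[i_on:]
    if resp.size == 0:
        raise ValueError("no samples after stimulus onset")
    t = np.arange(resp.size) * dt_ms
    i_peak = int(np.argmax(resp))
    peak = resp[i_peak]
    if peak <= 0:
        return math.nan, math.nan, math.nan
    t10 = _cross_time(t[:i_peak + 1], resp[:i_peak + 1], 0.1 * peak, rising=True)
    t50 = _cross_time(t[:i_peak + 1], resp[:i_peak + 1], 0.5 * peak, rising=True)
    fall_t, fall_y = t[i_peak:], resp[i_peak:]
    t80 = _cross_time(fall_t, fall_y, 0.8 * peak, rising=False)
    t20 = _cross_time(fall_t, fall_y, 0.2 * peak, rising=False)
    rise_start = t10
    rise_time = t50 - t10 if not (math.isnan(t50) or math.isnan(t10)) else math.nan
    decay_time = t20 - t80 if not (math.isnan(t20) or math.isnan(t80)) else math.nan
    return rise_start, rise_time, decay_time


# ---------------------------------------------------------------------------
# superposition

def superpose(flash_traces: Mapping[int, np.ndarray],
              schedule: Mapping[int, float], total_samples: int,
              dt_ms: float) -> np.ndarray:
    """Linear prediction for a composite stimulus: the sum of zero-padded
    component flash responses, each shifted to the onset time at which its
    position appears in the composite stimulus.

    ``flash_traces`` maps position -> baseline-subtracted mean trace
    aligned so that sample 0 is the component's stimulus onset;
    ``schedule`` maps position -> onset time (ms) in the composite movie.
    """
    out = np.zeros(total_samples)
    for pos, onset in schedule.items():
        if pos not in flash_traces:
            raise ValueError(f"no component flash trace for position {pos}")
        comp = np.asarray(flash_traces[pos], dtype=float)
        shift = int(round(onset / dt_ms))
        n = min(comp.size, total_samples - shift)
        if n > 0:
            out[shift:shift + n] += comp[:n]
    return out


# ---------------------------------------------------------------------------
# trial-to-trial variability

def mad_peak(trials: np.ndarray, mean_trace: np.ndarray, dt_ms: float,
             window_ms: float = 100.0) -> float:
    """Mean absolute deviation of per-trial peaks from the mean-trace peak.

    The mean-trace peak is located first; each trial's maximum is then
    taken within a ``window_ms`` window centred on that peak time (clipped
    at the trace edges), and the MAD is the mean absolute difference from
    the mean-trace peak value.
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    mean_trace = np.asarray(mean_trace, dtype=float)
    if trials.shape[0] < 2:
        raise ValueError("mad_peak requires at least 2 trials")
    if trials.shape[1] != mean_trace.size:
        raise ValueError("trials and mean trace lengths differ")
    i_peak = int(np.argmax(mean_trace))
    half = int(round(window_ms / (2 * dt_ms)))
    lo = max(i_peak - half, 0)
    hi = min(i_peak + half + 1, mean_trace.size)
    trial_peaks = trials[:, lo:hi].max(axis=1)
    return float(np.abs(trial_peaks - mean_trace[i_peak]).mean())


# ---------------------------------------------------------------------------
# grating phase / amplitude

@dataclass
class CosineFit:
    """Least-squares cosine fit a + A cos(2 pi f t + phi) at fixed f.

    ``phase_rad`` is the raw phase in (-pi, pi]; ``phase_display_rad``
    re-wraps it into (-2 pi, pi] (identity unless a caller shifted it),
    the convention that separates preferred- from null-direction grating
    responses starting at opposite phases.
    """

    amplitude_mV: float
    phase_rad: float
    offset_mV: float
    freq_hz: float

    @property
    def phase_display_rad(self) -> float:
        phi = self.phase_rad
        while phi > math.pi:
            phi -= 2 * math.pi
        while phi <= -2 * math.pi:
            phi += 2 * math.pi
        return phi


def fit_cosine(trace: np.ndarray, dt_ms: float, temporal_freq_hz: float,
               drop_first_cycle: bool = True) -> CosineFit:
    """Fit amplitude and phase of an oscillatory response at the stimulus
    temporal frequency.

    The first cycle is dropped by default to eliminate the onset transient
    of the grating appearance; at least two full cycles must remain. The
    frequency is fixed to the stimulus temporal frequency; only offset,
    amplitude and phase are estimated (a linear least-squares problem in
    cosine and sine regressors).
    """
    trace = np.asarray(trace, dtype=float)
    if temporal_freq_hz <= 0:
        raise ValueError("temporal_freq_hz must be positive")
    period_samples = 1000.0 / (temporal_freq_hz * dt_ms)
    start = int(round(period_samples)) if drop_first_cycle else 0
    seg = trace[start:]
    if seg.size < 2 * period_samples:
        raise ValueError("trace must span at least 2 cycles after the drop")
    t_s = (start + np.arange(seg.size)) * dt_ms / 1000.0
    w = 2 * math.pi * temporal_freq_hz
    design = np.column_stack([np.ones_like(t_s), np.cos(w * t_s), np.sin(w * t_s)])
    coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
    a0, b, c = coef
    amplitude = math.hypot(b, c)
    phase = math.atan2(-c, b)  # y = a0 + A cos(w t + phi)
    return CosineFit(amplitude_mV=float(amplitude), phase_rad=float(phase),
                     offset_mV=float(a0), freq_hz=temporal_freq_hz)
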