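"""Synthetic whole-cell-like data: ground-truth cells, noisy trials, and
the full stimulus battery.

The generator produces data with the statistical structure the analysis
pipeline assumes: per-stimulus repeated trials (5 for single-bar flashes,
3 otherwise), a resting baseline near -58 mV, per-sample additive Gaussian
recording noise (default SD 1 mV), and an optional fraction of trials with
a constant baseline-drift offset large enough for the QC rules to reject.
All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import StimulusTrials, TrialSet
from .model import (ChannelParams, EIParams, EpEmParams, MembraneFrame,
                    ModelParams, simulate)
from .stimuli import (DisplayGeometry, StimulusMovie, make_bar_flash,
                      make_bar_pair, make_drifting_grating, make_grating_flash,
                      make_moving_bar, fixed_speed_gap)

__all__ = [
    "NoiseModel",
    "ground_truth_cell",
    "generate_trials",
    "make_protocol_suite",
    "ARCHETYPES",
]


@dataclass
class NoiseModel:
    """Trial-generation parameters emulating a stable whole-cell recording.

    ``additive_sd_mV`` is the per-sample Gaussian recording noise;
    ``baseline_mV`` the resting potential (recordings are stabilized in the
    -60 to -55 mV range); ``drift_fraction`` of trials receive an extra
    constant baseline offset drawn uniformly from ``drift_range_mV`` in
    magnitude with random sign, exercising the baseline-stability QC.
    """

    additive_sd_mV: float = 1.0
    baseline_mV: float = -58.0
    drift_fraction: float = 0.0
    drift_range_mV: tuple[float, float] = (12.0, 30.0)
    n_repeats_flash: int = 5
    n_repeats_other: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd_mV < 0:
            raise ValueError("additive_sd_mV must be non-negative")
        if not 0 <= self.drift_fraction <= 1:
            raise ValueError("drift_fraction must be in [0, 1]")
        if self.n_repeats_flash < 1 or self.n_repeats_other < 1:
            raise ValueError("repeat counts must be >= 1")

    def n_repeats(self, label: str) -> int:
        """Single-bar flashes get 5 repeats, everything else 3."""
        return self.n_repeats_flash if label.startswith("flash") else self.n_repeats_other


# ---------------------------------------------------------------------------
# ground-truth parameter archetypes
#
# Draw ranges sit comfortably inside the default fitting bounds and keep
# every parameter bounded away from zero so that relative recovery errors
# are well defined. The trailing-inhibition archetype encodes the measured
# receptive-field structure: fast, broad, roughly centered excitation and
# slow, narrower inhibition offset to the trailing (positive) side.

def _draw_ei_trailing(rng: np.random.Generator) -> EIParams:
    exc = ChannelParams(
        tau_rise_ms=rng.uniform(8.0, 15.0),
        tau_decay_ms=rng.uniform(25.0, 45.0),
        amplitude=rng.uniform(3.0, 6.0),
        center=rng.uniform(-0.5, -0.2),
        width=rng.uniform(1.5, 2.5),
    )
    inh = ChannelParams(
        tau_rise_ms=rng.uniform(30.0, 60.0),
        tau_decay_ms=rng.uniform(90.0, 150.0),
        amplitude=rng.uniform(4.0, 8.0),
        center=rng.uniform(1.0, 2.0),
        width=rng.uniform(0.8, 1.4),
    )
    frame = MembraneFrame.from_alpha(rng.uniform(0.2, 0.35))
    return EIParams(exc=exc, inh=inh, frame=frame)


def _draw_epem(rng: np.random.Generator) -> EpEmParams:
    e_plus = ChannelParams(
        tau_rise_ms=rng.uniform(8.0, 15.0),
        tau_decay_ms=rng.uniform(25.0, 45.0),
        amplitude=rng.uniform(3.0, 6.0),
        center=rng.uniform(-0.5, -0.2),
        width=rng.uniform(1.5, 2.5),
    )
    e_minus = ChannelParams(
        tau_rise_ms=rng.uniform(30.0, 60.0),
        tau_decay_ms=rng.uniform(90.0, 150.0),
        amplitude=rng.uniform(4.0, 8.0),
        center=rng.uniform(1.0, 2.0),
        width=rng.uniform(0.8, 1.4),
    )
    frame = MembraneFrame.from_alpha(rng.uniform(0.2, 0.35))
    return EpEmParams(e_plus=e_plus, e_minus=e_minus,
                      g_e_star=rng.uniform(0.8, 2.0), frame=frame)


def _draw_symmetric_null(rng: np.random.Generator) -> EIParams:
    """Spatially symmetric E and I fields: mirror-symmetric construction,
    hence zero directional selectivity for symmetric motion spans."""
    width = rng.uniform(1.5, 2.5)
    exc = ChannelParams(
        tau_rise_ms=rng.uniform(8.0, 15.0),
        tau_decay_ms=rng.uniform(25.0, 45.0),
        amplitude=rng.uniform(3.0, 6.0),
        center=0.0, width=width,
    )
    inh = ChannelParams(
        tau_rise_ms=rng.uniform(30.0, 60.0),
        tau_decay_ms=rng.uniform(90.0, 150.0),
        amplitude=rng.uniform(1.0, 3.0),
        center=0.0, width=width,
    )
    frame = MembraneFrame.from_alpha(rng.uniform(0.2, 0.35))
    return EIParams(exc=exc, inh=inh, frame=frame)


ARCHETYPES = {
    "ei_trailing_inhibition": _draw_ei_trailing,
    "epem": _draw_epem,
    "symmetric_null": _draw_symmetric_null,
}


def ground_truth_cell(archetype: str, rng_seed: int = 0) -> ModelParams:
    """Draw a ground-truth parameter set of the given archetype.

    Deterministic per seed; every draw respects the archetype's ordering
    constraints (e.g. trailing inhibition: slower inhibitory decay and a
    positive inhibitory offset relative to excitation).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; "
                         f"choose from {sorted(ARCHETYPES)}")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0]))
    return ARCHETYPES[archetype](rng)


# ---------------------------------------------------------------------------
# trial generation

def generate_trials(params: ModelParams, protocol_suite: list[StimulusMovie],
                    noise: NoiseModel) -> TrialSet:
    """Simulate noisy repeated trials for every stimulus in the suite.

    Each trial is baseline + simulated (V - Vb) + iid Gaussian noise;
    drift trials additionally receive a constant offset. Stimuli are
    processed in label-sorted order from a single seeded stream, so equal
    configurations give identical trial sets.
    """
    ts = TrialSet()
    rng = np.random.default_rng(np.random.SeedSequence([noise.rng_seed, 1]))
    for movie in sorted(protocol_suite, key=lambda m: m.label):
        v, _ = simulate(params, movie)
        n_rep = noise.n_repeats(movie.label)
        clean = noise.baseline_mV + v.v_mV
        traces = np.tile(clean, (n_rep, 1))
        if noise.additive_sd_mV > 0:
            traces = traces + rng.normal(0.0, noise.additive_sd_mV, traces.shape)
        drifted = rng.random(n_rep) < noise.drift_fraction
        if drifted.any():
            lo, hi = noise.drift_range_mV
            offs = rng.uniform(lo, hi, int(drifted.sum()))
            offs *= rng.choice([-1.0, 1.0], offs.size)
            traces[drifted] += offs[:, None]
        onset = movie.stim_onset_ms
        ts.add(StimulusTrials(
            traces=traces, dt_ms=movie.dt_ms,
            onset_ms=0.0 if np.isnan(onset) else onset,
            label=movie.label, group=_group_of(movie.label),
            meta={"drifted": drifted.tolist()}))
    return ts


def _group_of(label: str) -> str:
    """Stimulus block identifier (flashes / pairs / moving bars / gratings)."""
    return label.split("_", 1)[0]


# ---------------------------------------------------------------------------
# protocol battery

def make_protocol_suite(geometry: DisplayGeometry | None = None,
                        dt_ms: float = 1.0,
                        flash_positions: tuple[int, int] = (-6, 6),
                        motion_span: tuple[int, int] = (-4, 4),
                        include: tuple[str, ...] = ("flash", "pair", "movbar",
                                                    "gratflash", "gratdrift"),
                        ) -> list[StimulusMovie]:
    """The complete stimulus battery used throughout the analysis.

    * single-bar flashes: widths 1/2/4 x durations 40/160 ms x >= 13
      positions along the PD-ND axis,
    * apparent-motion bar pairs: width-2 fixed-speed pairs (both orders)
      and the width-4 immediate-succession configuration,
    * moving bars: widths 1/2/4 x 40/80/160 ms steps x both directions
      over a 9-position span,
    * grating flashes: 8 phases x 40/160 ms,
    * drifting gratings: 40/160 ms steps x start phases 0/0.5 x both
      directions (3 full cycles).
    """
    geometry = geometry or DisplayGeometry()
    p_lo, p_hi = flash_positions
    m_lo, m_hi = motion_span
    suite: list[StimulusMovie] = []

    if "flash" in include:
        for width in (1, 2, 4):
            for dur in (40.0, 160.0):
                for pos in range(p_lo, p_hi + 1):
                    suite.append(make_bar_flash(pos, width, dur, geometry, dt_ms))

    if "pair" in include:
        for dur in (40.0, 160.0):
            for p1 in range(m_lo, m_hi - 1, 2):
                p2 = p1 + 2
                gap = fixed_speed_gap(p1, p2, 2, dur)
                suite.append(make_bar_pair(p1, p2, 2, dur, gap, geometry, dt_ms))
                suite.append(make_bar_pair(p2, p1, 2, dur, gap, geometry, dt_ms))
        for p1, p2 in ((m_lo, m_lo + 4), (m_lo + 4, m_lo)):
            suite.append(make_bar_pair(p1, p2, 4, 160.0, 160.0, geometry, dt_ms))

    if "movbar" in include:
        for width in (1, 2, 4):
            for step in (40.0, 80.0, 160.0):
                suite.append(make_moving_bar(m_lo, m_hi, width, step, geometry, dt_ms))
                suite.append(make_moving_bar(m_hi, m_lo, width, step, geometry, dt_ms))

    if "gratflash" in include:
        for phase in range(8):
            for dur in (40.0, 160.0):
                suite.append(make_grating_flash(phase, dur, 9, geometry, dt_ms))

    if "gratdrift" in include:
        for step in (40.0, 160.0):
            for start_phase in (0.0, 0.5):
                for direction in (1, -1):
                    suite.append(make_drifting_grating(
                        start_phase, step, direction, 24, 9, geometry, dt_ms))

    return suite
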