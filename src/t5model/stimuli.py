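"""Spatiotemporal OFF-stimulus construction for a 1-D LED-arena model.

Stimuli are binary movies ``S(x, t)`` over integer positions along the
preferred/null-direction (PD-ND) axis of a directionally selective cell.
Position 0 is the empirically strongest depolarizing flash location;
positive positions lie on the trailing side of the receptive field.
``S = 1`` means a dark (OFF) bar of width one covers that position.

Time is a uniform grid of ``dt_ms`` samples; ON intervals are half-open
``[onset, onset + duration)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DisplayGeometry",
    "StimulusMovie",
    "make_bar_flash",
    "make_bar_pair",
    "fixed_speed_gap",
    "make_moving_bar",
    "make_grating_flash",
    "make_drifting_grating",
    "speed_deg_per_s",
    "diagonal_step_count",
    "DEFAULT_POSITIONS",
]

#: Default PD-ND axis, wide enough for the full flashing-bar battery
#: (width-4 bars anchored at their leftmost pixel up to position +6).
DEFAULT_POSITIONS = np.arange(-10, 11)

#: Default padding around the stimulus: the pre window provides a baseline
#: estimate, the post window lets slow conductances decay back to rest.
DEFAULT_PRE_MS = 200.0
DEFAULT_POST_MS = 500.0


@dataclass(frozen=True)
class DisplayGeometry:
    """Angular geometry of the hemi-cylindrical LED display.

    Parameters
    ----------
    pixel_deg
        Angular size of one display pixel, degrees (2.25 by default).
    azimuth_extent_deg, elevation_extent_deg
        Total display coverage, degrees.
    """

    pixel_deg: float = 2.25
    azimuth_extent_deg: float = 216.0
    elevation_extent_deg: float = 72.0

    def __post_init__(self) -> None:
        if self.pixel_deg <= 0:
            raise ValueError(f"pixel_deg must be positive, got {self.pixel_deg}")
        if self.azimuth_extent_deg <= 0 or self.elevation_extent_deg <= 0:
            raise ValueError("display extents must be positive")

    def bar_width_deg(self, width_px: int) -> float:
        """Angular width of a bar of ``width_px`` pixels."""
        return width_px * self.pixel_deg


@dataclass
class StimulusMovie:
    """Binary 1-D space x time stimulus pattern.

    Attributes
    ----------
    values
        uint8 array of shape ``(n_positions, n_samples)``; 1 = OFF bar
        present at that position and time.
    dt_ms
        Sample interval in ms (uniform).
    positions
        Strictly increasing consecutive integer offsets along the PD-ND
        axis; 0 marks the receptive-field center.
    label
        Protocol descriptor, e.g. ``"flash_w2_d160_p+1"``.
    geometry
        Display geometry the movie was built for.
    """

    values: np.ndarray
    dt_ms: float
    positions: np.ndarray
    label: str = ""
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=int)
        if self.dt_ms <= 0:
            raise ValueError(f"dt_ms must be positive, got {self.dt_ms}")
        if self.values.ndim != 2:
            raise ValueError("values must be a (positions, time) matrix")
        if self.values.shape[0] != self.positions.size:
            raise ValueError("positions length does not match values rows")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) == 1):
            raise ValueError("positions must be strictly increasing consecutive integers")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("stimulus values must be binary")

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    @property
    def t_ms(self) -> np.ndarray:
        """Time axis (sample start times)."""
        return np.arange(self.n_samples) * self.dt_ms

    @property
    def stim_onset_ms(self) -> float:
        """Time of the first ON sample (nan for an all-zero movie)."""
        on = np.flatnonzero(self.values.any(axis=0))
        return float(on[0]) * self.dt_ms if on.size else math.nan

    @property
    def stim_offset_ms(self) -> float:
        """Time just after the last ON sample (nan for an all-zero movie)."""
        on = np.flatnonzero(self.values.any(axis=0))
        return float(on[-1] + 1) * self.dt_ms if on.size else math.nan

    def reversed_positions(self) -> "StimulusMovie":
        """Mirror the movie across position 0 (PD movie -> ND movie)."""
        return StimulusMovie(
            values=self.values[::-1].copy(),
            dt_ms=self.dt_ms,
            positions=-self.positions[::-1],
            label=self.label + "_mirrored",
            geometry=self.geometry,
        )

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the movie as CSV (rows = time samples, columns = positions)
        with a JSON metadata sidecar next to it."""
        path = Path(path)
        header = ",".join(str(p) for p in self.positions)
        np.savetxt(path, self.values.T, fmt="%d", delimiter=",",
                   header=header, comments="")
        meta = {
            "dt_ms": self.dt_ms,
            "label": self.label,
            "geometry": {
                "pixel_deg": self.geometry.pixel_deg,
                "azimuth_extent_deg": self.geometry.azimuth_extent_deg,
                "elevation_extent_deg": self.geometry.elevation_extent_deg,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimulusMovie":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().strip()
        positions = np.array([int(tok) for tok in header.split(",")])
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2, dtype=int)
        meta = json.loads(path.with_suffix(".json").read_text())
        geom = DisplayGeometry(**meta.get("geometry", {}))
        return cls(values=values.T, dt_ms=meta["dt_ms"],
                   positions=positions, label=meta.get("label", ""), geometry=geom)


# ---------------------------------------------------------------------------
# helpers

def _n_samples(duration_ms: float, dt_ms: float, what: str) -> int:
    n = duration_ms / dt_ms
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"{what} ({duration_ms} ms) must be a multiple of dt_ms ({dt_ms} ms)")
    return int(round(n))


def _empty_movie(total_ms: float, dt_ms: float, positions: np.ndarray) -> np.ndarray:
    n = _n_samples(total_ms, dt_ms, "total duration")
    return np.zeros((len(positions), n), dtype=np.uint8)


def _position_rows(positions: np.ndarray, start: int, width: int) -> np.ndarray:
    rows = np.searchsorted(positions, np.arange(start, start + width))
    if rows.max(initial=-1) >= len(positions) or not np.array_equal(
            positions[rows], np.arange(start, start + width)):
        raise ValueError(
            f"bar at positions [{start}, {start + width}) lies outside the "
            f"movie axis [{positions[0]}, {positions[-1]}]")
    return rows


# ---------------------------------------------------------------------------
# protocols

def make_bar_flash(position: int, width: int, duration_ms: float,
                   geometry: DisplayGeometry | None = None,
                   dt_ms: float = 1.0,
                   pre_ms: float = DEFAULT_PRE_MS,
                   post_ms: float = DEFAULT_POST_MS,
                   positions: np.ndarray | None = None,
                   label: str | None = None) -> StimulusMovie:
    """Single dark-bar flash: ``width`` consecutive positions starting at
    ``position`` turn ON for ``duration_ms`` after a ``pre_ms`` baseline.

    A zero duration yields an all-zero movie of the full padded length.
    """
    if width <= 0:
        raise ValueError(f"width must be a positive integer, got {width}")
    if duration_ms < 0:
        raise ValueError(f"duration_ms must be non-negative, got {duration_ms}")
    geometry = geometry or DisplayGeometry()
    positions = DEFAULT_POSITIONS if positions is None else np.asarray(positions)
    values = _empty_movie(pre_ms + duration_ms + post_ms, dt_ms, positions)
    if duration_ms > 0:
        rows = _position_rows(positions, position, width)
        i0 = _n_samples(pre_ms, dt_ms, "pre_ms")
        i1 = i0 + _n_samples(duration_ms, dt_ms, "duration_ms")
        values[rows, i0:i1] = 1
    if label is None:
        label = f"flash_w{width}_d{duration_ms:g}_p{position:+d}"
    return StimulusMovie(values, dt_ms, positions, label, geometry)


def fixed_speed_gap(pos_first: int, pos_second: int, width: int,
                    duration_ms: float) -> float:
    """Onset delay for the fixed-speed bar-pair configuration.

    The delay between the two bar onsets is scaled with the positional
    difference so the implied sweep speed matches a bar of ``width``
    stepping every ``duration_ms / width`` ms per pixel.
    """
    return duration_ms * abs(pos_second - pos_first) / width


def make_bar_pair(pos_first: int, pos_second: int, width: int,
                  duration_ms: float, onset_gap_ms: float,
                  geometry: DisplayGeometry | None = None,
                  dt_ms: float = 1.0,
                  pre_ms: float = DEFAULT_PRE_MS,
                  post_ms: float = DEFAULT_POST_MS,
                  positions: np.ndarray | None = None) -> StimulusMovie:
    """Two-step apparent-motion stimulus: a bar at ``pos_first`` followed,
    ``onset_gap_ms`` later, by a bar at ``pos_second``.

    Overlapping positions are allowed; values combine by logical OR so the
    movie stays binary. A degenerate pair (same position, zero gap) is
    permitted and flagged in the label.
    """
    if onset_gap_ms < 0:
        raise ValueError(f"onset_gap_ms must be non-negative, got {onset_gap_ms}")
    geometry = geometry or DisplayGeometry()
    positions = DEFAULT_POSITIONS if positions is None else np.asarray(positions)
    total = pre_ms + onset_gap_ms + duration_ms + post_ms
    values = _empty_movie(total, dt_ms, positions)
    ndur = _n_samples(duration_ms, dt_ms, "duration_ms")
    i0 = _n_samples(pre_ms, dt_ms, "pre_ms")
    values[_position_rows(positions, pos_first, width), i0:i0 + ndur] = 1
    j0 = i0 + _n_samples(onset_gap_ms, dt_ms, "onset_gap_ms")
    values[_position_rows(positions, pos_second, width), j0:j0 + ndur] = 1
    label = f"pair_w{width}_{pos_first:+d}to{pos_second:+d}_d{duration_ms:g}_g{onset_gap_ms:g}"
    if pos_first == pos_second and onset_gap_ms == 0:
        label += "_degenerate-single-flash"
    return StimulusMovie(values, dt_ms, positions, label, geometry)


def make_moving_bar(start: int, end: int, width: int, step_ms: float,
                    geometry: DisplayGeometry | None = None,
                    dt_ms: float = 1.0,
                    pre_ms: float = DEFAULT_PRE_MS,
                    post_ms: float = DEFAULT_POST_MS,
                    positions: np.ndarray | None = None) -> StimulusMovie:
    """Bar of ``width`` pixels sweeping from ``start`` to ``end``, its
    leading edge advancing one position every ``step_ms``.

    Each swept position stays ON for ``width * step_ms`` (the time the bar
    body covers it), so the movie is exactly the logical OR of the delayed
    single-position flashes that compose it.
    """
    if start == end:
        raise ValueError("start and end must differ for a moving bar")
    span = abs(end - start) + 1
    if width > span:
        raise ValueError(f"width {width} exceeds the traversed span of {span} positions")
    geometry = geometry or DisplayGeometry()
    positions = DEFAULT_POSITIONS if positions is None else np.asarray(positions)
    direction = 1 if end > start else -1
    n_steps = span  # leading-edge positions visited
    on_ms = width * step_ms
    total = pre_ms + (n_steps - 1) * step_ms + on_ms + post_ms
    values = _empty_movie(total, dt_ms, positions)
    nstep = _n_samples(step_ms, dt_ms, "step_ms")
    non = width * nstep
    i0 = _n_samples(pre_ms, dt_ms, "pre_ms")
    for i in range(n_steps):
        row = _position_rows(positions, start + i * direction, 1)[0]
        values[row, i0 + i * nstep:i0 + i * nstep + non] = 1
    tag = "pd" if direction > 0 else "nd"
    label = f"movbar_w{width}_s{step_ms:g}_{tag}_{start:+d}to{end:+d}"
    return StimulusMovie(values, dt_ms, positions, label, geometry)


#: Spatial period of the square-wave grating, pixels (4 OFF / 4 background).
GRATING_PERIOD_PX = 8


def _grating_pattern(positions: np.ndarray, phase_index: float) -> np.ndarray:
    """Boolean mask of dark pixels for a square grating at a given phase.

    Phase advances with the pattern: increasing ``phase_index`` shifts the
    dark bars toward larger positions.
    """
    return np.mod(positions - phase_index, GRATING_PERIOD_PX) < GRATING_PERIOD_PX // 2


def make_grating_flash(phase_index: int, duration_ms: float,
                       span_positions: int = 9,
                       geometry: DisplayGeometry | None = None,
                       dt_ms: float = 1.0,
                       pre_ms: float = DEFAULT_PRE_MS,
                       post_ms: float = DEFAULT_POST_MS,
                       positions: np.ndarray | None = None) -> StimulusMovie:
    """Static square-wave grating (period 8 px, 4 dark / 4 background)
    flashed for ``duration_ms`` at one of 8 spatial phases."""
    if not 0 <= phase_index <= 7:
        raise ValueError(f"phase_index must be in 0..7, got {phase_index}")
    if span_positions < GRATING_PERIOD_PX:
        raise ValueError(f"span_positions must cover at least one period "
                         f"({GRATING_PERIOD_PX}), got {span_positions}")
    geometry = geometry or DisplayGeometry()
    if positions is None:
        positions = np.arange(-(span_positions // 2),
                              span_positions - span_positions // 2)
    else:
        positions = np.asarray(positions)
    values = _empty_movie(pre_ms + duration_ms + post_ms, dt_ms, positions)
    i0 = _n_samples(pre_ms, dt_ms, "pre_ms")
    i1 = i0 + _n_samples(duration_ms, dt_ms, "duration_ms")
    values[_grating_pattern(positions, phase_index), i0:i1] = 1
    label = f"gratflash_ph{phase_index}_d{duration_ms:g}"
    return StimulusMovie(values, dt_ms, positions, label, geometry)


def make_drifting_grating(start_phase: float, step_ms: float, direction: int,
                          n_steps: int, span_positions: int = 9,
                          geometry: DisplayGeometry | None = None,
                          dt_ms: float = 1.0,
                          pre_ms: float = DEFAULT_PRE_MS,
                          post_ms: float = DEFAULT_POST_MS,
                          positions: np.ndarray | None = None) -> StimulusMovie:
    """Square-wave grating drifting one pixel per ``step_ms``.

    ``start_phase`` is in cycles (0 or 0.5 in the standard battery);
    ``direction`` +1 moves the pattern toward larger positions (PD by the
    sign convention of this package). Temporal frequency is
    ``1 / (8 * step_ms)``.
    """
    if direction not in (-1, 1):
        raise ValueError(f"direction must be +1 or -1, got {direction}")
    if n_steps < GRATING_PERIOD_PX:
        raise ValueError(f"n_steps must be >= {GRATING_PERIOD_PX} for at least one full cycle")
    geometry = geometry or DisplayGeometry()
    if positions is None:
        positions = np.arange(-(span_positions // 2),
                              span_positions - span_positions // 2)
    else:
        positions = np.asarray(positions)
    total = pre_ms + n_steps * step_ms + post_ms
    values = _empty_movie(total, dt_ms, positions)
    nstep = _n_samples(step_ms, dt_ms, "step_ms")
    i0 = _n_samples(pre_ms, dt_ms, "pre_ms")
    phase0 = start_phase * GRATING_PERIOD_PX
    for j in range(n_steps):
        mask = _grating_pattern(positions, phase0 + direction * j)
        values[mask, i0 + j * nstep:i0 + (j + 1) * nstep] = 1
    tag = "fwd" if direction > 0 else "rev"
    label = f"gratdrift_s{step_ms:g}_ph{start_phase:g}_{tag}"
    return StimulusMovie(values, dt_ms, positions, label, geometry)


# ---------------------------------------------------------------------------
# display arithmetic

def speed_deg_per_s(step_ms: float, geometry: DisplayGeometry | None = None) -> int:
    """Bar sweep speed in degrees/second for a one-pixel step every
    ``step_ms``, rounded to the nearest integer (80 ms -> 28 deg/s)."""
    if step_ms <= 0:
        raise ValueError(f"step_ms must be positive, got {step_ms}")
    geometry = geometry or DisplayGeometry()
    return round(geometry.pixel_deg / (step_ms / 1000.0))


def grating_temporal_freq_hz(step_ms: float) -> float:
    """Temporal frequency of a drifting grating stepping one pixel per
    ``step_ms`` with an 8-pixel spatial period."""
    if step_ms <= 0:
        raise ValueError(f"step_ms must be positive, got {step_ms}")
    return 1000.0 / (GRATING_PERIOD_PX * step_ms)


def diagonal_step_count(cardinal_steps: int) -> int:
    """Number of lattice steps needed along a 45-degree axis to cover the
    same angular span as ``cardinal_steps`` cardinal steps.

    One diagonal step projects pixel/sqrt(2) onto the motion axis, so
    ceil(cardinal_steps * sqrt(2)) steps are required (9 -> 13).
    """
    if cardinal_steps < 0:
        raise ValueError(f"cardinal_steps must be non-negative, got {cardinal_steps}")
    return math.ceil(cardinal_steps * math.sqrt(2) - 1e-12) if cardinal_steps else 0
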