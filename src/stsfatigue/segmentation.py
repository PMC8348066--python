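"""Stand-to-stand cycle detection from the mid-hip vertical trajectory.

The repeated sit-to-stand movement makes the mid-hip height quasi-harmonic:
maxima are standing instants, minima sitting instants. Detection works on the
mean-subtracted signal; a (maximum, minimum, maximum) triple is one
stand-to-stand cycle, split into a stand-to-sit phase ``[start, sit]`` and a
sit-to-stand phase ``[sit, end]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .io_core import MarkerId, TestSession

__all__ = [
    "ExtremumEvent",
    "StandToStandCycle",
    "CycleSegmentation",
    "detect_extrema",
    "build_cycles",
    "segment_session",
]

logger = logging.getLogger(__name__)

#: A person cannot complete a sit-to-stand phase faster than this (seconds),
#: so same-kind extrema closer together are detection artefacts.
DEFAULT_MIN_SEPARATION = 0.5
#: Required peak prominence, as a fraction of the mean-subtracted signal's SD.
DEFAULT_MIN_PROMINENCE_FRACTION = 0.2
#: Frame gaps longer than this (seconds) split the signal for detection.
MAX_GAP_S = 0.2


@dataclass(frozen=True)
class ExtremumEvent:
    """A detected extremum of the mean-subtracted hip-height signal."""

    time: float
    kind: str  # "maximum" | "minimum"
    value: float  # mean-subtracted signal value at the event


@dataclass(frozen=True)
class StandToStandCycle:
    """One cycle: stand -> sit -> stand, sharing stands with its neighbours."""

    index: int
    start_stand: float
    sit: float
    end_stand: float

    def __post_init__(self) -> None:
        if not self.start_stand < self.sit < self.end_stand:
            raise ValueError(
                f"cycle {self.index}: events out of order "
                f"({self.start_stand}, {self.sit}, {self.end_stand})"
            )

    @property
    def duration(self) -> float:
        # composed from the phases so their sum is exact by construction
        return self.stand_to_sit_duration + self.sit_to_stand_duration

    @property
    def stand_to_sit_duration(self) -> float:
        return self.sit - self.start_stand

    @property
    def sit_to_stand_duration(self) -> float:
        return self.end_stand - self.sit

    @property
    def mid_time(self) -> float:
        return 0.5 * (self.start_stand + self.end_stand)


@dataclass
class CycleSegmentation:
    cycles: Sequence[StandToStandCycle] = field(default_factory=tuple)
    signal_mean: float = 0.0

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def mid_times(self) -> np.ndarray:
        return np.array([c.mid_time for c in self.cycles])


def _plateau_time(times: np.ndarray, peak: int, left: int, right: int) -> float:
    # tie-break for flat peaks: centre of the plateau
    if right > left:
        return 0.5 * (times[left] + times[right])
    return float(times[peak])


def _enforce_separation(
    events: list[ExtremumEvent], min_separation: float, sign: float
) -> list[ExtremumEvent]:
    """Keep the more extreme of same-kind events closer than min_separation.

    Greedy by extremity (ties toward the earlier event), mirroring how a
    human would merge double-detections of the same stand or sit.
    """
    order = sorted(events, key=lambda e: (-sign * e.value, e.time))
    kept: list[ExtremumEvent] = []
    for event in order:
        if all(abs(event.time - k.time) >= min_separation for k in kept):
            kept.append(event)
    return sorted(kept, key=lambda e: e.time)


def _alternate(events: list[ExtremumEvent]) -> list[ExtremumEvent]:
    """Collapse runs of same-kind events, keeping the most extreme of a run."""
    out: list[ExtremumEvent] = []
    for event in events:
        if out and out[-1].kind == event.kind:
            prev = out[-1]
            sign = 1.0 if event.kind == "maximum" else -1.0
            if sign * event.value > sign * prev.value:
                out[-1] = event
        else:
            out.append(event)
    return out


def detect_extrema(
    signal: np.ndarray,
    times: np.ndarray,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    min_prominence_fraction: float = DEFAULT_MIN_PROMINENCE_FRACTION,
) -> list[ExtremumEvent]:
    """Detect alternating maxima/minima of the mean-subtracted signal.

    The signal mean is subtracted internally; maxima must lie above zero and
    minima below zero on the centred signal. Same-kind events closer than
    ``min_separation`` seconds are merged keeping the more extreme one, and
    the returned sequence strictly alternates in kind. A flat (or too-flat)
    signal yields an empty list with a warning rather than an exception.
    """
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(signal) < 3:
        raise ValueError("detect_extrema requires at least 3 samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    x = signal - signal.mean()
    sd = x.std()
    if sd == 0:
        logger.warning("flat signal: no extrema detected")
        return []
    # required excursion from the mean: the fraction is in SD units, so a
    # flat-plus-ripple signal yields nothing while true sit/stand extrema
    # (roughly one SD from the mean) always pass
    min_excursion = min_prominence_fraction * sd

    events: list[ExtremumEvent] = []
    for sign, kind in ((1.0, "maximum"), (-1.0, "minimum")):
        peaks, props = find_peaks(sign * x, height=min_excursion,
                                  plateau_size=(1, None))
        cands = [
            ExtremumEvent(
                time=_plateau_time(times, p, le, re), kind=kind,
                value=float(x[p]),
            )
            for p, le, re in zip(
                peaks, props["left_edges"], props["right_edges"]
            )
        ]
        cands = [
            e for e in cands
            if (e.value > 0 if kind == "maximum" else e.value < 0)
        ]
        events.extend(_enforce_separation(cands, min_separation, sign))

    events.sort(key=lambda e: e.time)
    events = _alternate(events)
    if not events:
        logger.warning("no extremum passed the prominence threshold")
    return events


def build_cycles(
    extrema: Sequence[ExtremumEvent], signal_mean: float = 0.0
) -> CycleSegmentation:
    """Assemble stand-to-stand cycles from alternating extrema.

    Each consecutive (maximum, minimum, maximum) triple becomes one cycle;
    leading/trailing extrema that cannot complete a triple are dropped, so a
    sequence starting and ending with a maximum yields (#maxima - 1) cycles.
    """
    events = list(extrema)
    for prev, cur in zip(events, events[1:]):
        if prev.kind == cur.kind:
            raise ValueError("extrema must alternate in kind")
    # trim to start and end on a maximum (a standing event)
    while events and events[0].kind != "maximum":
        events.pop(0)
    while events and events[-1].kind != "maximum":
        events.pop()
    n_maxima = sum(1 for e in events if e.kind == "maximum")
    if n_maxima < 2:
        logger.warning("fewer than 2 standing events: empty segmentation")
        return CycleSegmentation(cycles=(), signal_mean=signal_mean)

    cycles = tuple(
        StandToStandCycle(
            index=i,
            start_stand=events[2 * i].time,
            sit=events[2 * i + 1].time,
            end_stand=events[2 * i + 2].time,
        )
        for i in range(n_maxima - 1)
    )
    return CycleSegmentation(cycles=cycles, signal_mean=signal_mean)


def segment_session(
    session: TestSession,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    min_prominence_fraction: float = DEFAULT_MIN_PROMINENCE_FRACTION,
    max_gap: float = MAX_GAP_S,
) -> CycleSegmentation:
    """Segment a session's mid-hip vertical trajectory into cycles.

    Recording gaps longer than ``max_gap`` seconds split the signal; extrema
    are detected per contiguous block and re-joined (alternation is enforced
    across block boundaries by :func:`build_cycles`' precondition, so a
    duplicate kind at a seam keeps the more extreme event).
    """
    times = session.skeleton.times
    hip_y = session.skeleton.positions[MarkerId.M_HIP][:, 1]
    mean = float(hip_y.mean())

    gaps = np.flatnonzero(np.diff(times) > max_gap)
    if len(gaps):
        logger.warning(
            "%d gap(s) longer than %.2f s in the skeleton series; "
            "detecting extrema per contiguous block", len(gaps), max_gap,
        )
    blocks = np.split(np.arange(len(times)), gaps + 1)

    events: list[ExtremumEvent] = []
    for block in blocks:
        if len(block) < 3:
            continue
        block_events = detect_extrema(
            hip_y[block],
            times[block],
            min_separation=min_separation,
            min_prominence_fraction=min_prominence_fraction,
        )
        # detect_extrema centres on the block mean; re-express event values
        # relative to the whole-signal mean so blocks stay comparable
        shift = float(hip_y[block].mean()) - mean
        events.extend(
            ExtremumEvent(time=e.time, kind=e.kind, value=e.value + shift)
            for e in block_events
        )

    events.sort(key=lambda e: e.time)
    events = _alternate(events)
    return build_cycles(events, signal_mean=mean)
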