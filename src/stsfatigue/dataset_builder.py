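"""Assemble the labeled fatigue dataset from segmented, featurized sessions.

Borg CR10 reports (every 30 s, with an assumed 0 at t = 0) are linearly
interpolated onto a 10 s grid. At each grid timepoint the 32 kinematic
features are averaged over the five stand-to-stand cycles nearest in time
(chronological greedy assignment without cycle reuse, except at the last
labeled timepoint where the slowing cycle rate forces reuse), and the heart
rate (feature F33) over the five nearest 1 Hz samples. Every aggregate is
divided by its own value at the t = 0 baseline -- the zero-fatigue reference
-- turning features into dimensionless ratios comparable across subjects.
The baseline itself and the final grid value yield no observation, so a
complete 120 s session contributes 11 *registers*, each labeled low (Borg
0-3), moderate (4-6) or high (7-10) fatigue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_IDS, extract_cycle_features
from .io_core import BorgReport, HeartRateSeries, Participant, TestSession
from .segmentation import segment_session

__all__ = [
    "BorgGrid",
    "Register",
    "FatigueDataset",
    "BuildConfig",
    "InsufficientCyclesError",
    "DegenerateBaselineError",
    "ALL_FEATURE_IDS",
    "LABELS",
    "interpolate_borg",
    "label_fatigue",
    "select_nearest_cycles",
    "assign_cycles",
    "aggregate_hr",
    "normalize",
    "build_dataset",
    "class_summary",
]

logger = logging.getLogger(__name__)

ALL_FEATURE_IDS: tuple[str, ...] = FEATURE_IDS + ("F33",)
LABELS = ("LF", "MF", "HF")
GRID_STEP_S = 10.0


class InsufficientCyclesError(ValueError):
    """Too few unused cycles (or samples) to aggregate at a timepoint."""


class DegenerateBaselineError(ValueError):
    """A baseline value is zero or non-finite and cannot normalize."""


@dataclass
class BorgGrid:
    """Borg values interpolated on a 10 s grid starting at (0, 0)."""

    times: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def interpolate_borg(
    reports: Sequence[BorgReport], duration: float
) -> BorgGrid:
    """Piecewise-linear Borg curve through (0, 0) and the reports, on a 10 s grid.

    The participant starts at zero fatigue, so (0, 0) anchors the first
    segment. A complete 120 s test yields 13 grid values.
    """
    times = [0.0]
    values = [0.0]
    last = 0.0
    for report in reports:
        if report.time <= last:
            raise ValueError("borg reports must be sorted with distinct times")
        if report.time > duration + 1e-9:
            raise ValueError(
                f"borg report at {report.time} s is beyond the session "
                f"duration {duration} s"
            )
        times.append(report.time)
        values.append(report.value)
        last = report.time
    grid_times = np.arange(0.0, duration + 1e-9, GRID_STEP_S)
    if last < grid_times[-1] - 1e-9:
        logger.warning(
            "last Borg report (%.0f s) precedes the session end (%.0f s); "
            "holding the last value", last, duration,
        )
    grid_values = np.interp(grid_times, times, values)
    return BorgGrid(times=grid_times, values=grid_values)


def label_fatigue(borg_value: float) -> str:
    """Map a (possibly interpolated) Borg value to LF / MF / HF.

    Fractional values are rounded half-up to the nearest integer before the
    banding 0-3 -> LF, 4-6 -> MF, 7-10 -> HF.
    """
    if not 0.0 <= borg_value <= 10.0:
        raise ValueError(f"borg value {borg_value} outside [0, 10]")
    rounded = math.floor(borg_value + 0.5)
    if rounded <= 3:
        return "LF"
    if rounded <= 6:
        return "MF"
    return "HF"


def select_nearest_cycles(
    cycle_mid_times: np.ndarray,
    target: float,
    k: int = 5,
    already_used: Iterable[int] = (),
    allow_reuse: bool = False,
) -> list[int]:
    """Indices of the ``k`` cycles nearest to ``target`` by mid-time.

    Ties break toward the earlier cycle. Used indices are excluded unless
    ``allow_reuse``; running out of unused cycles raises
    :class:`InsufficientCyclesError`.
    """
    mid_times = np.asarray(cycle_mid_times, dtype=float)
    used = set() if allow_reuse else set(already_used)
    available = [i for i in range(len(mid_times)) if i not in used]
    if len(available) < k:
        raise InsufficientCyclesError(
            f"{len(available)} unused cycles available, {k} required "
            f"at t = {target:g} s"
        )
    available.sort(key=lambda i: (abs(mid_times[i] - target), mid_times[i], i))
    return sorted(available[:k])


def assign_cycles(
    cycle_mid_times: np.ndarray, grid_times: np.ndarray, k: int = 5
) -> list[list[int]]:
    """Greedy chronological nearest-k cycle assignment for a Borg grid.

    Timepoints 0 .. n-2 each get the ``k`` nearest cycles; no cycle is
    reused, except at the last labeled timepoint (index n-2) where the
    slowing cycle rate makes reuse unavoidable. The final grid value (index
    n-1) is never related to any cycle and gets no assignment.
    """
    used: set[int] = set()
    assignments: list[list[int]] = []
    n = len(grid_times)
    for j in range(n - 1):
        final_labeled = j == n - 2
        chosen = select_nearest_cycles(
            cycle_mid_times, float(grid_times[j]), k=k,
            already_used=used, allow_reuse=final_labeled,
        )
        if not final_labeled:
            used.update(chosen)
        assignments.append(chosen)
    return assignments


def aggregate_hr(hr: HeartRateSeries, target: float, k: int = 5) -> float:
    """Mean of the ``k`` heart-rate samples nearest to ``target`` (ties earlier)."""
    if len(hr.times) < k:
        raise InsufficientCyclesError(
            f"{len(hr.times)} heart-rate samples available, {k} required"
        )
    order = sorted(
        range(len(hr.times)), key=lambda i: (abs(hr.times[i] - target), i)
    )
    return float(np.mean(hr.bpm[order[:k]]))


def normalize(value: float, baseline: float, name: str = "") -> float:
    """Baseline ratio value / baseline; the zero-fatigue aggregate is 1 by construction."""
    if baseline == 0 or not np.isfinite(baseline):
        raise DegenerateBaselineError(
            f"baseline for {name or 'feature'} is degenerate ({baseline})"
        )
    return value / baseline


@dataclass(frozen=True)
class Register:
    """One labeled observation: 33 normalized features at one Borg timepoint."""

    participant_id: str
    borg_time: float
    borg_value: float
    features: Mapping[str, float]
    label: str

    def __post_init__(self) -> None:
        missing = set(ALL_FEATURE_IDS) - set(self.features)
        if missing:
            raise ValueError(f"register missing features {sorted(missing)}")
        bad = [k for k in ALL_FEATURE_IDS if not np.isfinite(self.features[k])]
        if bad:
            raise ValueError(f"register has non-finite features {bad}")


@dataclass
class FatigueDataset:
    registers: list[Register] = field(default_factory=list)
    feature_names: tuple[str, ...] = ALL_FEATURE_IDS
    participants: dict[str, Participant] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.registers)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": r.participant_id,
                "borg_time_s": r.borg_time,
                "borg_value": r.borg_value,
                **{fid: r.features[fid] for fid in self.feature_names},
                "label": r.label,
            }
            for r in self.registers
        ]
        frame = pd.DataFrame(
            rows,
            columns=["participant_id", "borg_time_s", "borg_value",
                     *self.feature_names, "label"],
        )
        return frame.sort_values(
            ["participant_id", "borg_time_s"], kind="stable"
        ).reset_index(drop=True)

    def design_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) arrays in register order for model fitting."""
        X = np.array(
            [[r.features[fid] for fid in self.feature_names]
             for r in self.registers]
        )
        y = np.array([r.label for r in self.registers])
        return X, y


@dataclass
class BuildConfig:
    """Aggregation and normalization settings for dataset construction."""

    k_cycles: int = 5
    k_hr: int = 5
    hr_baseline: str = "t0"  # "t0": the t=0 HR aggregate; "resting": pre-test
    smooth_window: int | None = None

    def __post_init__(self) -> None:
        if self.hr_baseline not in ("t0", "resting"):
            raise ValueError("hr_baseline must be 't0' or 'resting'")


def _session_registers(
    session: TestSession, config: BuildConfig
) -> list[Register]:
    segmentation = segment_session(session)
    features = extract_cycle_features(
        session, segmentation, smooth_window=config.smooth_window
    )
    if not features:
        raise InsufficientCyclesError(
            f"session {session.participant.id}: no usable cycles"
        )
    mid_times = np.array([f.mid_time for f in features])
    matrix = np.array(
        [[f.values[fid] for fid in FEATURE_IDS] for f in features]
    )

    grid = interpolate_borg(session.borg, session.duration)
    n = len(grid)
    if n < 3:
        raise ValueError(
            f"session {session.participant.id}: grid too short ({n} points)"
        )

    try:
        assignments = assign_cycles(mid_times, grid.times, k=config.k_cycles)
        hr_aggregates = [
            aggregate_hr(session.heart_rate, float(t), k=config.k_hr)
            for t in grid.times[:-1]
        ]
    except InsufficientCyclesError as exc:
        raise InsufficientCyclesError(
            f"session {session.participant.id}: {exc}"
        ) from exc
    aggregates = [matrix[chosen].mean(axis=0) for chosen in assignments]

    baseline = aggregates[0]
    hr_base = (
        hr_aggregates[0] if config.hr_baseline == "t0"
        else session.heart_rate.resting_bpm
    )
    registers = []
    for j in range(1, n - 1):
        try:
            values = {
                fid: normalize(aggregates[j][i], baseline[i], fid)
                for i, fid in enumerate(FEATURE_IDS)
            }
            values["F33"] = normalize(hr_aggregates[j], hr_base, "F33")
        except DegenerateBaselineError as exc:
            raise DegenerateBaselineError(
                f"session {session.participant.id}, t = {grid.times[j]:g} s: "
                f"{exc}"
            ) from exc
        registers.append(
            Register(
                participant_id=session.participant.id,
                borg_time=float(grid.times[j]),
                borg_value=float(grid.values[j]),
                features=values,
                label=label_fatigue(float(grid.values[j])),
            )
        )
    return registers


def build_dataset(
    sessions: Iterable[TestSession], config: BuildConfig | None = None
) -> FatigueDataset:
    """Build the labeled dataset; a complete 120 s session yields 11 registers."""
    config = config or BuildConfig()
    dataset = FatigueDataset()
    for session in sessions:
        dataset.registers.extend(_session_registers(session, config))
        dataset.participants[session.participant.id] = session.participant
    return dataset


def class_summary(dataset: FatigueDataset) -> pd.DataFrame:
    """Per-feature mean and SD of the normalized values within each class.

    Returns a frame indexed by feature with a (label, statistic) column
    MultiIndex; classes absent from the dataset yield NaN with a warning.
    """
    if not dataset.registers:
        raise ValueError("class_summary requires a non-empty dataset")
    frame = dataset.to_frame()
    columns = pd.MultiIndex.from_product([LABELS, ("mean", "sd")])
    out = pd.DataFrame(index=list(dataset.feature_names), columns=columns,
                       dtype=float)
    for label in LABELS:
        sub = frame[frame["label"] == label]
        if sub.empty:
            logger.warning("class %s has no registers; summary left missing",
                           label)
            continue
        for fid in dataset.feature_names:
            out.loc[fid, (label, "mean")] = sub[fid].mean()
            out.loc[fid, (label, "sd")] = sub[fid].std(ddof=0)
    return out
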