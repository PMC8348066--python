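"""Per-cycle kinematic and temporal features of the sit-to-stand movement.

For every stand-to-stand cycle, 32 features (F1-F32) are computed from the
skeleton series: phase durations, marker displacement ranges, peak linear
velocities, and joint-angle ranges/velocities. Joint angles come from two
sources:

* vertex angles between three markers (knee: hip-knee-ankle; ankle:
  knee-ankle-foot), and
* Tait-Bryan angles of the relative rotation between two tracked
  orientations (hip and spine flexo-extension from the X angle,
  abduction-adduction from the Z angle), using the intrinsic X-Y-Z sequence.

Features marked ``side_averaged`` (F10-F21) are the mean of the left and
right side values. Time-windowing follows the cycle phases: ranges of angle
signals and minimum angular velocities are taken over the sit-to-stand
phase, maximum angular velocities over the stand-to-sit phase; marker ranges
span the whole stand-to-stand cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io_core import MarkerId, TestSession
from .segmentation import CycleSegmentation

__all__ = [
    "FeatureDefinition",
    "CycleFeatures",
    "FEATURE_DEFINITIONS",
    "FEATURE_IDS",
    "joint_angle",
    "relative_axis_angle",
    "finite_difference",
    "extract_cycle_features",
    "features_to_frame",
]

logger = logging.getLogger(__name__)

STAND_TO_STAND = "stand_to_stand"
SIT_TO_STAND = "sit_to_stand"
STAND_TO_SIT = "stand_to_sit"


@dataclass(frozen=True)
class FeatureDefinition:
    id: str
    name: str
    units: str
    source_signal: str
    window: str
    statistic: str  # duration | range | max_derivative | min_derivative
    side_averaged: bool = False


def _angle_feature_block(
    start: int, prefix: str, signal: str, side_averaged: bool
) -> list[FeatureDefinition]:
    """Range / max velocity / min velocity triple for one angle signal."""
    return [
        FeatureDefinition(
            f"F{start}", f"{prefix} range", "degrees", signal,
            SIT_TO_STAND, "range", side_averaged,
        ),
        FeatureDefinition(
            f"F{start + 1}", f"{prefix} max velocity", "degrees/s", signal,
            STAND_TO_SIT, "max_derivative", side_averaged,
        ),
        FeatureDefinition(
            f"F{start + 2}", f"{prefix} min velocity", "degrees/s", signal,
            SIT_TO_STAND, "min_derivative", side_averaged,
        ),
    ]


FEATURE_DEFINITIONS: tuple[FeatureDefinition, ...] = tuple(
    [
        FeatureDefinition("F1", "Stand-to-stand time", "s", "phase",
                          STAND_TO_STAND, "duration"),
        FeatureDefinition("F2", "Sit-to-stand time", "s", "phase",
                          SIT_TO_STAND, "duration"),
        FeatureDefinition("F3", "Stand-to-sit time", "s", "phase",
                          STAND_TO_SIT, "duration"),
        FeatureDefinition("F4", "M_hip vertical range", "m", "hip_y",
                          STAND_TO_STAND, "range"),
        FeatureDefinition("F5", "M_hip depth range", "m", "hip_z",
                          STAND_TO_STAND, "range"),
        FeatureDefinition("F6", "M_hip max vertical velocity", "m/s", "hip_y",
                          SIT_TO_STAND, "max_derivative"),
        FeatureDefinition("F7", "M_hip min vertical velocity", "m/s", "hip_y",
                          STAND_TO_SIT, "min_derivative"),
        FeatureDefinition("F8", "M_hip max depth velocity", "m/s", "hip_z",
                          STAND_TO_SIT, "max_derivative"),
        FeatureDefinition("F9", "M_hip min depth velocity", "m/s", "hip_z",
                          SIT_TO_STAND, "min_derivative"),
    ]
    + _angle_feature_block(10, "Knee flexo-extension", "knee_angle", True)
    + _angle_feature_block(13, "Hip flexo-extension", "hip_flex", True)
    + _angle_feature_block(16, "Hip abduction-adduction", "hip_abd", True)
    + _angle_feature_block(19, "Ankle flexo-extension", "ankle_angle", True)
    + [
        FeatureDefinition("F22", "M_shoulder vertical range", "m",
                          "shoulder_y", STAND_TO_STAND, "range"),
        FeatureDefinition("F23", "M_shoulder depth range", "m",
                          "shoulder_z", STAND_TO_STAND, "range"),
        FeatureDefinition("F24", "M_shoulder max vertical velocity", "m/s",
                          "shoulder_y", SIT_TO_STAND, "max_derivative"),
        FeatureDefinition("F25", "M_shoulder min vertical velocity", "m/s",
                          "shoulder_y", STAND_TO_SIT, "min_derivative"),
        FeatureDefinition("F26", "M_shoulder max depth velocity", "m/s",
                          "shoulder_z", SIT_TO_STAND, "max_derivative"),
    ]
    + _angle_feature_block(27, "Spine flexo-extension", "spine_flex", False)
    + _angle_feature_block(30, "Spine abduction-adduction", "spine_abd", False)
)

FEATURE_IDS: tuple[str, ...] = tuple(d.id for d in FEATURE_DEFINITIONS)
assert len(FEATURE_DEFINITIONS) == 32


@dataclass
class CycleFeatures:
    """Feature values of one stand-to-stand cycle.

    ``mid_time`` (the cycle midpoint) is the cycle's representative time for
    nearest-cycle selection downstream.
    """

    cycle_index: int
    mid_time: float
    values: Mapping[str, float]


def joint_angle(a, b, c) -> float:
    """Angle in degrees at vertex ``b`` between vectors (a-b) and (c-b)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("joint_angle: zero-length limb vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _joint_angle_series(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    u, v = a - b, c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("joint angle series: zero-length limb vector")
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _as_rotation(quat_wxyz: np.ndarray) -> Rotation:
    q = np.atleast_2d(np.asarray(quat_wxyz, dtype=float))
    # stored (w, x, y, z); scipy expects (x, y, z, w)
    return Rotation.from_quat(q[:, [1, 2, 3, 0]])


_AXIS_INDEX = {"X": 0, "Z": 2}


def relative_axis_angle(q_ref, q_child, axis: str) -> float:
    """Tait-Bryan angle (degrees) of the rotation from ``q_ref`` to ``q_child``.

    The relative rotation ``R = R(q_ref)^T R(q_child)`` is decomposed with the
    intrinsic X-Y-Z sequence; ``axis`` selects the first (X) or third (Z)
    angle, in (-180, 180]. Near gimbal lock (|Y angle| = 90 deg) the
    decomposition is not unique; the convention-resolved value (Y absorbed,
    third angle zeroed) is returned with a warning.
    """
    return float(
        _relative_axis_angle_series(
            np.atleast_2d(q_ref), np.atleast_2d(q_child), axis
        )[0]
    )


def _relative_axis_angle_series(
    q_ref: np.ndarray, q_child: np.ndarray, axis: str
) -> np.ndarray:
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be 'X' or 'Z', got {axis!r}")
    rel = _as_rotation(q_ref).inv() * _as_rotation(q_child)
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        euler = rel.as_euler("XYZ", degrees=True)
    if any("Gimbal lock" in str(w.message) for w in caught):
        logger.warning(
            "gimbal lock in relative rotation: returning the "
            "convention-resolved %s angle", axis,
        )
    return euler[:, _AXIS_INDEX[axis]]


def finite_difference(signal: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Time derivative: central differences inside, one-sided at the ends."""
    signal = np.asarray(signal, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(signal) < 2:
        raise ValueError("finite_difference requires at least 2 samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return np.gradient(signal, times)


def _moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(signal, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    return out[pad: pad + len(signal)] if pad else out


def _session_signals(session: TestSession) -> dict[str, list[np.ndarray]]:
    """Compute every source signal once over the whole series.

    Values are lists of per-side arrays (one element for unsided signals).
    """
    pos = session.skeleton.positions
    ori = session.skeleton.orientations

    signals: dict[str, list[np.ndarray]] = {
        "hip_y": [pos[MarkerId.M_HIP][:, 1]],
        "hip_z": [pos[MarkerId.M_HIP][:, 2]],
        "shoulder_y": [pos[MarkerId.M_SHOULDER][:, 1]],
        "shoulder_z": [pos[MarkerId.M_SHOULDER][:, 2]],
        "knee_angle": [
            _joint_angle_series(
                pos[hip], pos[knee], pos[ankle]
            )
            for hip, knee, ankle in (
                (MarkerId.L_HIP, MarkerId.L_KNEE, MarkerId.L_ANKLE),
                (MarkerId.R_HIP, MarkerId.R_KNEE, MarkerId.R_ANKLE),
            )
        ],
        "ankle_angle": [
            _joint_angle_series(pos[knee], pos[ankle], pos[foot])
            for knee, ankle, foot in (
                (MarkerId.L_KNEE, MarkerId.L_ANKLE, MarkerId.L_FOOT),
                (MarkerId.R_KNEE, MarkerId.R_ANKLE, MarkerId.R_FOOT),
            )
        ],
    }
    q_hip = ori[MarkerId.M_HIP]
    q_sh = ori[MarkerId.M_SHOULDER]
    for axis, key in (("X", "hip_flex"), ("Z", "hip_abd")):
        signals[key] = [
            _relative_axis_angle_series(q_hip, ori[knee], axis)
            for knee in (MarkerId.L_KNEE, MarkerId.R_KNEE)
        ]
    for axis, key in (("X", "spine_flex"), ("Z", "spine_abd")):
        signals[key] = [_relative_axis_angle_series(q_sh, q_hip, axis)]
    return signals


def extract_cycle_features(
    session: TestSession,
    segmentation: CycleSegmentation,
    smooth_window: int | None = None,
) -> list[CycleFeatures]:
    """Compute F1-F32 for every cycle of a segmented session.

    ``smooth_window`` optionally applies a moving average (in samples) to the
    source signals before differentiation, for noisy recordings. Cycles whose
    window falls outside the skeleton series are skipped with a warning.
    """
    times = session.skeleton.times
    signals = _session_signals(session)
    if smooth_window and smooth_window > 1:
        signals = {
            k: [_moving_average(s, smooth_window) for s in sides]
            for k, sides in signals.items()
        }
    derivatives = {
        k: [finite_difference(s, times) for s in sides]
        for k, sides in signals.items()
    }

    eps = 1e-9
    results: list[CycleFeatures] = []
    for cycle in segmentation.cycles:
        if cycle.start_stand < times[0] - eps or cycle.end_stand > times[-1] + eps:
            logger.warning(
                "cycle %d window [%.2f, %.2f] outside the skeleton series; "
                "skipped", cycle.index, cycle.start_stand, cycle.end_stand,
            )
            continue
        windows = {
            STAND_TO_STAND: (cycle.start_stand, cycle.end_stand),
            STAND_TO_SIT: (cycle.start_stand, cycle.sit),
            SIT_TO_STAND: (cycle.sit, cycle.end_stand),
        }
        slices = {}
        empty = False
        for name, (lo, hi) in windows.items():
            i0 = np.searchsorted(times, lo - eps, side="left")
            i1 = np.searchsorted(times, hi + eps, side="right")
            if i1 <= i0:
                empty = True
                break
            slices[name] = slice(i0, i1)
        if empty:
            logger.warning("cycle %d has an empty sample window; skipped",
                           cycle.index)
            continue

        values: dict[str, float] = {}
        for spec in FEATURE_DEFINITIONS:
            if spec.statistic == "duration":
                if spec.window == STAND_TO_STAND:
                    values[spec.id] = cycle.duration
                elif spec.window == SIT_TO_STAND:
                    values[spec.id] = cycle.sit_to_stand_duration
                else:
                    values[spec.id] = cycle.stand_to_sit_duration
                continue
            window = slices[spec.window]
            source = (
                derivatives[spec.source_signal]
                if spec.statistic.endswith("derivative")
                else signals[spec.source_signal]
            )
            per_side = []
            for series in source:  # one entry for unsided, two for L/R
                segment = series[window]
                if spec.statistic == "range":
                    per_side.append(float(segment.max() - segment.min()))
                elif spec.statistic == "max_derivative":
                    per_side.append(float(segment.max()))
                else:  # min_derivative
                    per_side.append(float(segment.min()))
            values[spec.id] = float(np.mean(per_side))

        # F1 must equal F2 + F3 exactly; recompute to kill rounding drift
        values["F1"] = values["F2"] + values["F3"]
        results.append(
            CycleFeatures(
                cycle_index=cycle.index, mid_time=cycle.mid_time, values=values
            )
        )
    return results


def features_to_frame(features: Sequence[CycleFeatures]) -> pd.DataFrame:
    """Tabulate per-cycle features (cycle_index, mid_time_s, F1..F32)."""
    rows = [
        {"cycle_index": f.cycle_index, "mid_time_s": f.mid_time,
         **{fid: f.values[fid] for fid in FEATURE_IDS}}
        for f in features
    ]
    return pd.DataFrame(rows, columns=["cycle_index", "mid_time_s", *FEATURE_IDS])
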