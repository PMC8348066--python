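"""Domain types and session-bundle I/O for sit-to-stand (STS) fatigue tests.

A *test session* is one participant's recording of a timed sit-to-stand
exercise: a skeleton time series from a depth camera (11 body markers, 3-D
positions in metres, plus unit-quaternion orientations for four of them),
a 1 Hz heart-rate series with a resting value, and Borg CR10 perceived
exertion reports collected every 30 s during the test.

Coordinate convention (depth-camera frame): X lateral, Y vertical up,
Z depth along the camera axis; units are metres. Time origin t = 0 is the
start command; all series are re-based on load.

On disk a session is a *bundle* directory::

    manifest.json   participant fields, duration, resting_bpm, file names
    skeleton.csv    time_s, marker, px_m, py_m, pz_m, qw, qx, qy, qz
    heart_rate.csv  time_s, bpm
    borg.csv        time_s, value

Orientation columns are left empty for markers that carry no orientation.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerId",
    "ORIENTED_MARKERS",
    "SkeletonSeries",
    "HeartRateSeries",
    "BorgReport",
    "Participant",
    "TestSession",
    "SchemaError",
    "tanaka_mhr",
    "should_terminate",
    "read_session",
    "write_session",
]

_QUAT_NORM_TOL = 1e-6


class SchemaError(ValueError):
    """A session bundle violates the documented schema."""


class MarkerId(str, enum.Enum):
    """The 11 skeleton markers used by the pipeline.

    Three sit on the midline of the upper body (shoulder centre, spine,
    mid-hip) and four on each leg.
    """

    M_SHOULDER = "M_shoulder"
    M_SPINE = "M_spine"
    M_HIP = "M_hip"
    R_HIP = "R_hip"
    R_KNEE = "R_knee"
    R_ANKLE = "R_ankle"
    R_FOOT = "R_foot"
    L_HIP = "L_hip"
    L_KNEE = "L_knee"
    L_ANKLE = "L_ankle"
    L_FOOT = "L_foot"


#: Markers whose orientation quaternions are required.
ORIENTED_MARKERS = (
    MarkerId.M_SHOULDER,
    MarkerId.M_HIP,
    MarkerId.R_KNEE,
    MarkerId.L_KNEE,
)


def _check_times(times: np.ndarray, what: str) -> None:
    if times.ndim != 1 or len(times) == 0:
        raise SchemaError(f"{what}: times must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise SchemaError(f"{what}: times must be strictly increasing")


@dataclass
class SkeletonSeries:
    """Marker positions (and some orientations) sampled at a nominal rate.

    positions maps every :class:`MarkerId` to an ``(n, 3)`` array of metres;
    orientations maps each marker in :data:`ORIENTED_MARKERS` to an
    ``(n, 4)`` array of unit quaternions in ``(w, x, y, z)`` order.
    """

    times: np.ndarray
    positions: Mapping[MarkerId, np.ndarray]
    orientations: Mapping[MarkerId, np.ndarray]
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        _check_times(self.times, "skeleton")
        n = len(self.times)
        for marker in MarkerId:
            if marker not in self.positions:
                raise SchemaError(f"skeleton: missing marker {marker.value}")
        self.positions = {
            m: np.asarray(p, dtype=float) for m, p in self.positions.items()
        }
        for m, p in self.positions.items():
            if p.shape != (n, 3):
                raise SchemaError(
                    f"skeleton: positions[{m.value}] has shape {p.shape}, "
                    f"expected ({n}, 3)"
                )
        for marker in ORIENTED_MARKERS:
            if marker not in self.orientations:
                raise SchemaError(
                    f"skeleton: missing orientation for {marker.value}"
                )
        self.orientations = {
            m: np.asarray(q, dtype=float) for m, q in self.orientations.items()
        }
        for m, q in self.orientations.items():
            if q.shape != (n, 4):
                raise SchemaError(
                    f"skeleton: orientations[{m.value}] has shape {q.shape}, "
                    f"expected ({n}, 4)"
                )
            norms = np.linalg.norm(q, axis=1)
            if np.any(np.abs(norms - 1.0) > _QUAT_NORM_TOL):
                raise SchemaError(
                    f"skeleton: orientations[{m.value}] contain non-unit "
                    f"quaternions (max |norm-1| = {np.abs(norms - 1).max():.2e})"
                )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class HeartRateSeries:
    """Heart-rate samples in bpm (nominally 1 Hz) plus the resting value."""

    times: np.ndarray
    bpm: np.ndarray
    resting_bpm: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        _check_times(self.times, "heart_rate")
        if self.bpm.shape != self.times.shape:
            raise SchemaError("heart_rate: times and bpm lengths differ")
        if np.any(self.bpm <= 0):
            raise SchemaError("heart_rate: bpm values must be positive")
        if self.resting_bpm <= 0:
            raise SchemaError("heart_rate: resting_bpm must be positive")


@dataclass(frozen=True)
class BorgReport:
    """One Borg CR10 perceived-exertion report (0-10) at a given time."""

    time: float
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 10.0:
            raise SchemaError(
                f"borg: value {self.value} outside the CR10 range [0, 10]"
            )


@dataclass(frozen=True)
class Participant:
    """Participant metadata; age (years) feeds the Tanaka MHR estimate."""

    id: str
    age: float
    sex: str  # "female" | "male"
    weight: float  # kg
    height: float  # cm

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise SchemaError("participant: age must be positive")
        if self.sex not in ("female", "male"):
            raise SchemaError(f"participant: unknown sex {self.sex!r}")


@dataclass
class TestSession:
    """One participant's full sit-to-stand test recording."""

    participant: Participant
    skeleton: SkeletonSeries
    heart_rate: HeartRateSeries
    borg: Sequence[BorgReport] = field(default_factory=tuple)
    duration: float = 120.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SchemaError("session: duration must be positive")
        self.borg = tuple(sorted(self.borg, key=lambda r: r.time))
        eps = 1e-9
        for name, times in (
            ("skeleton", self.skeleton.times),
            ("heart_rate", self.heart_rate.times),
        ):
            if times[0] < -eps or times[-1] > self.duration + eps:
                raise SchemaError(
                    f"session: {name} times outside [0, {self.duration}]"
                )
        for report in self.borg:
            if report.time < -eps or report.time > self.duration + eps:
                raise SchemaError(
                    f"session: borg report at {report.time} s outside "
                    f"[0, {self.duration}]"
                )


def tanaka_mhr(age: float) -> float:
    """Age-predicted maximal heart rate (Tanaka): 206.9 - 0.67 * age.

    Recommended for healthy adults; ``age`` is in years. Age 0 is allowed
    (useful as a neutral reference), negative ages are rejected.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return 206.9 - 0.67 * age


def should_terminate(current_bpm: float, mhr: float, borg_value: float) -> bool:
    """Protocol stop rule: heart rate above 90% of MHR, or Borg at 10."""
    if mhr <= 0:
        raise ValueError("mhr must be positive")
    return current_bpm > 0.9 * mhr or borg_value >= 10.0


# ---------------------------------------------------------------------------
# Bundle I/O

_SKELETON_COLUMNS = [
    "time_s", "marker", "px_m", "py_m", "pz_m", "qw", "qx", "qy", "qz",
]
_FLOAT_FORMAT = "%.17g"  # lossless for float64


def write_session(session: TestSession, bundle_path: str | Path) -> Path:
    """Write a session bundle (manifest + three CSV files) to a directory."""
    path = Path(bundle_path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "participant": {
            "id": session.participant.id,
            "age": session.participant.age,
            "sex": session.participant.sex,
            "weight": session.participant.weight,
            "height": session.participant.height,
        },
        "duration": session.duration,
        "resting_bpm": session.heart_rate.resting_bpm,
        "nominal_rate": session.skeleton.nominal_rate,
        "files": {
            "skeleton": "skeleton.csv",
            "heart_rate": "heart_rate.csv",
            "borg": "borg.csv",
        },
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    frames = []
    for marker in MarkerId:
        pos = session.skeleton.positions[marker]
        frame = pd.DataFrame(
            {
                "time_s": session.skeleton.times,
                "marker": marker.value,
                "px_m": pos[:, 0],
                "py_m": pos[:, 1],
                "pz_m": pos[:, 2],
            }
        )
        if marker in session.skeleton.orientations:
            quat = session.skeleton.orientations[marker]
            frame["qw"], frame["qx"] = quat[:, 0], quat[:, 1]
            frame["qy"], frame["qz"] = quat[:, 2], quat[:, 3]
        else:
            for col in ("qw", "qx", "qy", "qz"):
                frame[col] = np.nan
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        path / "skeleton.csv", index=False, float_format=_FLOAT_FORMAT
    )

    pd.DataFrame(
        {"time_s": session.heart_rate.times, "bpm": session.heart_rate.bpm}
    ).to_csv(path / "heart_rate.csv", index=False, float_format=_FLOAT_FORMAT)

    pd.DataFrame(
        {
            "time_s": [r.time for r in session.borg],
            "value": [r.value for r in session.borg],
        }
    ).to_csv(path / "borg.csv", index=False, float_format=_FLOAT_FORMAT)
    return path


def read_session(bundle_path: str | Path) -> TestSession:
    """Read a session bundle; raises :class:`SchemaError` naming any bad field."""
    path = Path(bundle_path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise SchemaError(f"bundle {path}: manifest.json not found")
    manifest = json.loads(manifest_file.read_text())
    try:
        part = Participant(**manifest["participant"])
        duration = float(manifest["duration"])
        resting = float(manifest["resting_bpm"])
        nominal_rate = float(manifest.get("nominal_rate", 30.0))
        files = manifest["files"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"bundle {path}: malformed manifest ({exc})") from exc

    skel = pd.read_csv(path / files["skeleton"], float_precision="round_trip")
    missing_cols = set(_SKELETON_COLUMNS) - set(skel.columns)
    if missing_cols:
        raise SchemaError(
            f"skeleton.csv: missing columns {sorted(missing_cols)}"
        )
    positions: dict[MarkerId, np.ndarray] = {}
    orientations: dict[MarkerId, np.ndarray] = {}
    times: np.ndarray | None = None
    for marker in MarkerId:
        rows = skel[skel["marker"] == marker.value]
        if rows.empty:
            raise SchemaError(f"skeleton.csv: missing marker {marker.value}")
        t = rows["time_s"].to_numpy()
        if times is None:
            times = t
        elif len(t) != len(times) or not np.array_equal(t, times):
            raise SchemaError(
                f"skeleton.csv: time grid for {marker.value} differs from "
                "the other markers"
            )
        positions[marker] = rows[["px_m", "py_m", "pz_m"]].to_numpy()
        quat = rows[["qw", "qx", "qy", "qz"]].to_numpy()
        if marker in ORIENTED_MARKERS:
            if np.any(~np.isfinite(quat)):
                raise SchemaError(
                    f"skeleton.csv: malformed quaternion for {marker.value}"
                )
            orientations[marker] = quat

    skeleton = SkeletonSeries(
        times=times, positions=positions, orientations=orientations,
        nominal_rate=nominal_rate,
    )

    hr = pd.read_csv(path / files["heart_rate"], float_precision="round_trip")
    heart_rate = HeartRateSeries(
        times=hr["time_s"].to_numpy(), bpm=hr["bpm"].to_numpy(),
        resting_bpm=resting,
    )

    borg_frame = pd.read_csv(path / files["borg"], float_precision="round_trip")
    borg = tuple(
        BorgReport(time=float(row.time_s), value=float(row.value))
        for row in borg_frame.itertuples()
    )
    return TestSession(
        participant=part, skeleton=skeleton, heart_rate=heart_rate,
        borg=borg, duration=duration,
    )
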