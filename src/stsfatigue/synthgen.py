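"""Synthetic sit-to-stand test sessions with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* a quasi-harmonic mid-hip vertical trajectory built from raised-cosine
  transitions between standing and sitting levels (so the stand-to-sit and
  sit-to-stand phase durations are independently controllable), whose cycle
  period grows as the participant tires;
* upper-body lean whose depth excursion shrinks with fatigue;
* leg markers placed by forward kinematics from shank-tilt and knee-angle
  waveforms, and orientation quaternions composed as X (flexion) then Z
  (abduction) rotations so the relative-rotation features recover the
  injected angle waveforms exactly;
* a saturating heart-rate ramp whose amplitude is solved in closed form so
  the final/initial aggregate ratio equals the configured target while
  respecting the 0.9 x MHR termination ceiling;
* a monotone Borg schedule reported every 30 s.

Fatigue accrues along a square-root envelope, zero before ``effect_onset_s``
and saturating at the last labeled timepoint (duration - 10 s): perceived
effort and performance loss build fastest early in a high-intensity bout.
Noise is independent Gaussian jitter on marker positions, orientations and
heart rate; real recordings' occlusion artefacts and autocorrelated tracking
error are *not* modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io_core import (
    BorgReport,
    HeartRateSeries,
    MarkerId,
    Participant,
    SkeletonSeries,
    TestSession,
    tanaka_mhr,
)

__all__ = ["SynthConfig", "GroundTruth", "generate_session", "generate_cohort"]

#: Final/initial ratios injected per feature family (values near the study's
#: reported normalized class trends).
DEFAULT_EFFECTS: dict[str, float] = {
    "stand_to_stand_time": 1.45,
    "hip_vertical_range": 0.95,
    "hip_depth_range": 0.85,
    "shoulder_vertical_range": 0.85,
    "shoulder_depth_range": 0.80,
    "knee_angle_range": 0.93,
    "hip_flex_range": 1.10,
    "hip_abd_range": 1.00,
    "ankle_angle_range": 0.95,
    "spine_flex_range": 1.15,
    "spine_abd_range": 1.00,
    "heart_rate": 1.60,
}

# baseline posture / amplitude constants (metres, degrees)
_HIP_STAND_Y = 0.96
_HIP_AMP_Y = 0.38
_HIP_Z0 = 4.00
_HIP_AMP_Z = 0.10
_SH_STAND_Y = 1.46
_SH_AMP_Y = 0.30
_SH_Z0 = 3.95
_SH_AMP_Z = 0.16
_TORSO_PITCH_AMP = 10.0
_KNEE_STAND_DEG = 172.0
_KNEE_AMP_DEG = 75.0
_SHANK_TILT_STAND = 4.0
_SHANK_TILT_AMP = 18.0
_HIP_FLEX_AMP = 80.0
_HIP_ABD_AMP = 6.0
_SPINE_FLEX_AMP = 25.0
_SPINE_ABD_AMP = 4.0
_SHANK_LEN = 0.42
_THIGH_LEN = 0.44
_HIP_X = 0.11
_START_OFFSET = 0.5
_END_DIP = 0.15  # fractional dip before/after the first/last stand


@dataclass
class SynthConfig:
    """Study conditions for synthetic cohorts (defaults mirror the protocol)."""

    n_participants: int = 60
    duration: float = 120.0
    sample_rate: float = 30.0
    base_cycle_period: float = 1.25
    stand_to_sit_fraction: float = 0.45
    fatigue_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    borg_schedule: tuple[tuple[float, float], ...] = (
        (30.0, 3.0), (60.0, 5.0), (90.0, 8.0), (120.0, 10.0),
    )
    marker_noise_sd: float = 0.004  # m
    hr_noise_sd: float = 1.0  # bpm
    orientation_noise_deg: float = 0.3
    effect_onset_s: float = 7.0
    hr_tau_s: float = 45.0
    period_jitter: float = 0.12  # per-participant spread of the base period
    effect_jitter: float = 0.2  # per-participant spread of effect sizes
    borg_jitter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration % 10 != 0:
            raise ValueError("duration must be a multiple of 10 s")
        effects = dict(DEFAULT_EFFECTS)
        effects.update(self.fatigue_effects)
        unknown = set(effects) - set(DEFAULT_EFFECTS)
        if unknown:
            raise ValueError(f"unknown fatigue effects {sorted(unknown)}")
        if any(r <= 0 for r in effects.values()):
            raise ValueError("fatigue effect ratios must be positive")
        self.fatigue_effects = effects

    def noiseless(self) -> "SynthConfig":
        """A copy with all noise and between-participant jitter removed."""
        return replace(
            self, marker_noise_sd=0.0, hr_noise_sd=0.0,
            orientation_noise_deg=0.0, period_jitter=0.0,
            effect_jitter=0.0, borg_jitter=False,
        )


@dataclass
class GroundTruth:
    """What the generator actually injected, cycle by cycle and per timepoint."""

    participant_id: str
    cycles: pd.DataFrame  # start/sit/end times, phase durations, true ranges
    grid_times: np.ndarray
    borg_grid: np.ndarray
    register_expectations: pd.DataFrame  # per register: expected norm F1/F23/F33
    effect_ratios: dict[str, float]  # realized final/initial ratios
    resting_bpm: float


def _envelope(t: np.ndarray | float, onset: float, end: float):
    """Fatigue accrual in [0, 1]: square-root ramp from onset to end."""
    frac = np.clip((np.asarray(t, dtype=float) - onset) / (end - onset), 0, 1)
    return np.sqrt(frac)


def _cycle_schedule(
    config: SynthConfig, base_period: float, time_ratio: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stand/sit/stand event times with the period drifting by the envelope."""
    onset, end = config.effect_onset_s, config.duration - 10.0

    def snap(x: float) -> float:
        # events sit on the sampling grid so injected phase durations are
        # exactly representable at the nominal rate
        return round(x * config.sample_rate) / config.sample_rate

    starts, sits, ends = [], [], []
    t = snap(_START_OFFSET)
    while True:
        d = base_period
        for _ in range(2):  # fixed point on the mid-cycle envelope
            d = base_period * (
                1.0 + (time_ratio - 1.0)
                * float(_envelope(t + d / 2.0, onset, end))
            )
        if d <= 0:
            raise ValueError("fatigue effects produced a non-positive period")
        sit = snap(t + config.stand_to_sit_fraction * d)
        cycle_end = snap(t + d)
        if cycle_end > config.duration - 0.35 or not t < sit < cycle_end:
            break
        starts.append(t)
        sits.append(sit)
        ends.append(cycle_end)
        t = cycle_end
    if not starts:
        raise ValueError("duration too short for a single cycle")
    return np.array(starts), np.array(sits), np.array(ends)


def _sit_wave(
    times: np.ndarray, starts: np.ndarray, sits: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """u(t): 1 standing, 0 sitting, raised-cosine transitions at each phase."""
    u = np.ones_like(times)
    # small dip before the first and after the last stand so boundary stands
    # are genuine local maxima for the detector
    first, last = starts[0], ends[-1]
    pre = times < first
    u[pre] = 1.0 - _END_DIP * 0.5 * (
        1 + np.cos(np.pi * times[pre] / max(first, 1e-6))
    )
    post = times > last
    if post.any():
        tail = (times[post] - last) / max(times[-1] - last, 1e-6)
        u[post] = 1.0 - _END_DIP * 0.5 * (1 - np.cos(np.pi * tail))
    for s, m, e in zip(starts, sits, ends):
        seg = (times >= s) & (times < m)
        u[seg] = 0.5 * (1 + np.cos(np.pi * (times[seg] - s) / (m - s)))
        seg = (times >= m) & (times < e)
        u[seg] = 0.5 * (1 - np.cos(np.pi * (times[seg] - m) / (e - m)))
    return u


def _greedy_nearest(
    mid_times: np.ndarray, grid_times: np.ndarray, k: int = 5
) -> list[np.ndarray]:
    """Chronological nearest-k assignment, reuse allowed only at the last
    labeled timepoint (mirrors the dataset-construction rule)."""
    used: set[int] = set()
    chosen: list[np.ndarray] = []
    for j, target in enumerate(grid_times[:-1]):
        final_labeled = j == len(grid_times) - 2
        pool = [
            i for i in range(len(mid_times)) if final_labeled or i not in used
        ]
        pool.sort(key=lambda i: (abs(mid_times[i] - target), mid_times[i]))
        picked = np.array(sorted(pool[:k]))
        if not final_labeled:
            used.update(picked.tolist())
        chosen.append(picked)
    return chosen


def _rot_xz(flex_deg: np.ndarray, abd_deg: np.ndarray) -> Rotation:
    # intrinsic X (flexion) then Z (abduction): relative decomposition in the
    # X-Y-Z sequence recovers these angles exactly (Y stays 0)
    return Rotation.from_euler(
        "XZ", np.column_stack([flex_deg, abd_deg]), degrees=True
    )


def _quat_wxyz(rot: Rotation) -> np.ndarray:
    q = rot.as_quat()  # (x, y, z, w)
    return q[:, [3, 0, 1, 2]]


def generate_session(
    config: SynthConfig,
    participant: Participant,
    seed: int | None = None,
) -> tuple[TestSession, GroundTruth]:
    """Generate one synthetic test session and its ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    effects = config.fatigue_effects
    onset, ramp_end = config.effect_onset_s, config.duration - 10.0

    # per-participant variation of the study conditions
    base_period = config.base_cycle_period * (
        1.0 + config.period_jitter * rng.uniform(-1, 1)
    )
    eff = {
        key: 1.0 + (ratio - 1.0)
        * (1.0 + config.effect_jitter * rng.uniform(-1, 1))
        for key, ratio in effects.items()
    }

    starts, sits, ends = _cycle_schedule(
        config, base_period, eff["stand_to_stand_time"]
    )
    times = np.arange(0.0, config.duration, 1.0 / config.sample_rate)
    u = _sit_wave(times, starts, sits, ends)
    w = 1.0 - u  # 0 standing, 1 sitting
    env = _envelope(times, onset, ramp_end)

    def amp(base: float, key: str) -> np.ndarray:
        return base * (1.0 + (eff[key] - 1.0) * env)

    hip_y = _HIP_STAND_Y - amp(_HIP_AMP_Y, "hip_vertical_range") * w
    hip_z = _HIP_Z0 + amp(_HIP_AMP_Z, "hip_depth_range") * w
    sh_y = _SH_STAND_Y - amp(_SH_AMP_Y, "shoulder_vertical_range") * w
    sh_z = _SH_Z0 - amp(_SH_AMP_Z, "shoulder_depth_range") * w

    # angle waveforms (degrees)
    knee_angle = _KNEE_STAND_DEG - amp(_KNEE_AMP_DEG, "knee_angle_range") * w
    shank_tilt = _SHANK_TILT_STAND + amp(
        _SHANK_TILT_AMP, "ankle_angle_range") * w
    hip_flex = amp(_HIP_FLEX_AMP, "hip_flex_range") * w
    hip_abd = amp(_HIP_ABD_AMP, "hip_abd_range") * w
    spine_flex = amp(_SPINE_FLEX_AMP, "spine_flex_range") * w
    spine_abd = amp(_SPINE_ABD_AMP, "spine_abd_range") * w
    torso_pitch = _TORSO_PITCH_AMP * w

    n = len(times)
    positions: dict[MarkerId, np.ndarray] = {
        MarkerId.M_HIP: np.column_stack([np.zeros(n), hip_y, hip_z]),
        MarkerId.M_SHOULDER: np.column_stack([np.zeros(n), sh_y, sh_z]),
        MarkerId.M_SPINE: np.column_stack(
            [np.zeros(n), 0.5 * (hip_y + sh_y), 0.5 * (hip_z + sh_z)]
        ),
    }
    phi = np.radians(shank_tilt)
    theta = np.radians(knee_angle)
    for side, (hip_m, knee_m, ankle_m, foot_m) in (
        (+1, (MarkerId.R_HIP, MarkerId.R_KNEE, MarkerId.R_ANKLE,
              MarkerId.R_FOOT)),
        (-1, (MarkerId.L_HIP, MarkerId.L_KNEE, MarkerId.L_ANKLE,
              MarkerId.L_FOOT)),
    ):
        ankle = np.tile([side * _HIP_X, 0.09, _HIP_Z0 + 0.05], (n, 1))
        foot = ankle + np.array([side * 0.02, -0.05, -0.18])
        knee = ankle + _SHANK_LEN * np.column_stack(
            [np.zeros(n), np.cos(phi), -np.sin(phi)]
        )
        # thigh direction: rotate the knee->ankle unit vector by -theta about X
        v = (ankle - knee) / _SHANK_LEN
        ct, st = np.cos(-theta), np.sin(-theta)
        wy = v[:, 1] * ct - v[:, 2] * st
        wz = v[:, 1] * st + v[:, 2] * ct
        hip_side = knee + _THIGH_LEN * np.column_stack([np.zeros(n), wy, wz])
        positions[hip_m] = hip_side
        positions[knee_m] = knee
        positions[ankle_m] = ankle
        positions[foot_m] = foot

    if config.marker_noise_sd > 0:
        for marker in positions:
            positions[marker] = positions[marker] + rng.normal(
                0.0, config.marker_noise_sd, (n, 3)
            )

    q_shoulder = Rotation.from_euler(
        "X", torso_pitch[:, None], degrees=True
    )
    q_hip = q_shoulder * _rot_xz(spine_flex, spine_abd)
    q_knee_r = q_hip * _rot_xz(hip_flex, hip_abd)
    q_knee_l = q_hip * _rot_xz(hip_flex, -hip_abd)
    rotations = {
        MarkerId.M_SHOULDER: q_shoulder,
        MarkerId.M_HIP: q_hip,
        MarkerId.R_KNEE: q_knee_r,
        MarkerId.L_KNEE: q_knee_l,
    }
    if config.orientation_noise_deg > 0:
        sd = np.radians(config.orientation_noise_deg)
        rotations = {
            m: r * Rotation.from_rotvec(rng.normal(0.0, sd, (n, 3)))
            for m, r in rotations.items()
        }
    orientations = {m: _quat_wxyz(r) for m, r in rotations.items()}

    skeleton = SkeletonSeries(
        times=times, positions=positions, orientations=orientations,
        nominal_rate=config.sample_rate,
    )

    # ---- heart rate: saturating ramp solved for the target ratio ----------
    mhr = tanaka_mhr(participant.age)
    resting = float(rng.uniform(62.0, 75.0))
    hr_times = np.arange(0.0, config.duration, 1.0)
    ramp = 1.0 - np.exp(-hr_times / config.hr_tau_s)
    base_idx = np.argsort(np.abs(hr_times - 0.0), kind="stable")[:5]
    last_idx = np.argsort(np.abs(hr_times - ramp_end), kind="stable")[:5]
    c1 = float(ramp[base_idx].mean())
    c2 = float(ramp[last_idx].mean())
    rho = eff["heart_rate"]
    delta = resting * (rho - 1.0) / (c2 - rho * c1)
    max_delta = (0.88 * mhr - resting) / float(ramp.max())
    delta = min(delta, max_delta)
    hr_clean = resting + delta * ramp
    realized_hr_ratio = float(
        (resting + delta * c2) / (resting + delta * c1)
    )
    bpm = hr_clean + rng.normal(0.0, config.hr_noise_sd, len(hr_times))
    bpm = np.clip(bpm, 40.0, 0.9 * mhr - 0.1)
    heart_rate = HeartRateSeries(
        times=hr_times, bpm=bpm, resting_bpm=resting
    )

    # ---- Borg reports ------------------------------------------------------
    report_times = np.array([t for t, _ in config.borg_schedule])
    report_vals = np.array([v for _, v in config.borg_schedule], dtype=float)
    if config.borg_jitter and len(report_vals) > 1:
        jitter = rng.integers(-1, 2, size=len(report_vals) - 1)
        report_vals[:-1] = report_vals[:-1] + jitter
    report_vals = np.clip(np.maximum.accumulate(report_vals), 0.0, 10.0)
    borg = tuple(
        BorgReport(time=float(t), value=float(v))
        for t, v in zip(report_times, report_vals)
    )

    session = TestSession(
        participant=participant, skeleton=skeleton, heart_rate=heart_rate,
        borg=borg, duration=config.duration,
    )

    # ---- ground truth ------------------------------------------------------
    env_sit = _envelope(sits, onset, ramp_end)

    def amp_at_sit(base: float, key: str) -> np.ndarray:
        return base * (1.0 + (eff[key] - 1.0) * env_sit)

    cycles = pd.DataFrame(
        {
            "start_stand": starts,
            "sit": sits,
            "end_stand": ends,
            "stand_to_stand": ends - starts,
            "sit_to_stand": ends - sits,
            "stand_to_sit": sits - starts,
            "hip_vertical_range": amp_at_sit(
                _HIP_AMP_Y, "hip_vertical_range"),
            "shoulder_depth_range": amp_at_sit(
                _SH_AMP_Z, "shoulder_depth_range"),
            "knee_angle_range": amp_at_sit(_KNEE_AMP_DEG, "knee_angle_range"),
            "hip_flex_range": amp_at_sit(_HIP_FLEX_AMP, "hip_flex_range"),
            "spine_flex_range": amp_at_sit(
                _SPINE_FLEX_AMP, "spine_flex_range"),
        }
    )

    grid_times = np.arange(0.0, config.duration + 1e-9, 10.0)
    borg_grid = np.interp(
        grid_times,
        np.concatenate([[0.0], report_times]),
        np.concatenate([[0.0], report_vals]),
    )
    mids = 0.5 * (starts + ends)
    chosen = _greedy_nearest(mids, grid_times, k=5)
    f1_agg = np.array(
        [cycles["stand_to_stand"].to_numpy()[c].mean() for c in chosen]
    )
    f23_agg = np.array(
        [cycles["shoulder_depth_range"].to_numpy()[c].mean() for c in chosen]
    )
    f33_agg = np.array(
        [
            hr_clean[np.argsort(np.abs(hr_times - t), kind="stable")[:5]].mean()
            for t in grid_times[:-1]
        ]
    )
    register_expectations = pd.DataFrame(
        {
            "borg_time_s": grid_times[1:-1],
            "f1_norm": f1_agg[1:] / f1_agg[0],
            "f23_norm": f23_agg[1:] / f23_agg[0],
            "f33_norm": f33_agg[1:] / f33_agg[0],
        }
    )
    effect_ratios = {
        "stand_to_stand_time": float(f1_agg[-1] / f1_agg[0]),
        "shoulder_depth_range": float(f23_agg[-1] / f23_agg[0]),
        "heart_rate": realized_hr_ratio,
    }
    truth = GroundTruth(
        participant_id=participant.id,
        cycles=cycles,
        grid_times=grid_times,
        borg_grid=borg_grid,
        register_expectations=register_expectations,
        effect_ratios=effect_ratios,
        resting_bpm=resting,
    )
    return session, truth


#: Demographic (mean, SD) per sex: age (years), weight (kg), height (cm).
_DEMOGRAPHICS = {
    "female": ((20.8, 1.7), (59.3, 5.5), (164.1, 7.7)),
    "male": ((21.9, 1.9), (65.9, 6.4), (172.8, 8.3)),
}


def _sample_participant(rng: np.random.Generator, index: int,
                        sex: str) -> Participant:
    (age_m, age_sd), (w_m, w_sd), (h_m, h_sd) = _DEMOGRAPHICS[sex]
    age = float(np.clip(rng.uniform(age_m - 2 * age_sd, age_m + 2 * age_sd),
                        18.0, 30.0))
    weight = float(rng.uniform(w_m - 2 * w_sd, w_m + 2 * w_sd))
    height = float(rng.uniform(h_m - 2 * h_sd, h_m + 2 * h_sd))
    return Participant(
        id=f"P{index:03d}", age=age, sex=sex, weight=weight, height=height
    )


def generate_cohort(
    config: SynthConfig, seed: int | None = None
) -> list[tuple[TestSession, GroundTruth]]:
    """Generate a sex-balanced cohort of synthetic sessions (deterministic)."""
    if config.n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    master = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for i in range(config.n_participants):
        sex = "female" if i % 2 == 0 else "male"
        participant = _sample_participant(master, i, sex)
        child_seed = int(master.integers(0, 2**31 - 1))
        out.append(generate_session(config, participant, seed=child_seed))
    return out
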