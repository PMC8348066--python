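"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the extremum oracle is a
direct neighbourhood scan, and the Euler oracle uses textbook
quaternion-to-matrix and closed-form Tait-Bryan decomposition formulas.
"""

import numpy as np


def brute_force_extrema(signal, times, min_separation):
    """An interior sample is a maximum (minimum) iff it beats every other
    sample within min_separation, on the mean-subtracted signal, and lies
    above (below) zero."""
    x = np.asarray(signal, float) - np.mean(signal)
    events = []
    idx = np.arange(len(x))
    for i in range(1, len(x) - 1):
        win = (np.abs(times - times[i]) <= min_separation) & (idx != i)
        if x[i] > 0 and np.all(x[i] > x[win]):
            events.append(("maximum", times[i], x[i]))
        elif x[i] < 0 and np.all(x[i] < x[win]):
            events.append(("minimum", times[i], x[i]))
    return events


def smooth_signal(rng, n, rate=30.0):
    """An amplitude-modulated sinusoid whose extrema are well separated."""
    period = rng.uniform(1.5, 4.0)
    amp = rng.uniform(0.5, 2.0)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / rate
    carrier = np.sin(2 * np.pi * t / period + phase)
    modulation = 1.0 + 0.3 * np.sin(2 * np.pi * t / (5 * period))
    return amp * modulation * carrier, t


def quat_to_matrix(q):
    """Quaternion (w, x, y, z) -> rotation matrix, textbook formula."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def euler_xyz_oracle(rotation_matrix):
    """Closed-form intrinsic X-Y-Z Tait-Bryan angles (degrees), derived from
    R = Rx(a) @ Ry(b) @ Rz(c)."""
    r = rotation_matrix
    b = np.arcsin(np.clip(r[0, 2], -1, 1))
    a = np.arctan2(-r[1, 2], r[2, 2])
    c = np.arctan2(-r[0, 1], r[0, 0])
    return np.degrees([a, b, c])


def random_unit_quat(rng):
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def quat_multiply(p, q):
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def random_relative_quats(rng):
    """(q_ref, q_child, relative rotation matrix) with a small relative
    rotation, safely away from gimbal lock."""
    q_ref = random_unit_quat(rng)
    rotvec = rng.uniform(-0.6, 0.6, 3)
    angle = np.linalg.norm(rotvec)
    axis = rotvec / angle
    small = np.concatenate([[np.cos(angle / 2)], np.sin(angle / 2) * axis])
    q_child = quat_multiply(q_ref, small)
    rel = quat_to_matrix(q_ref).T @ quat_to_matrix(q_child)
    return q_ref, q_child, rel
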