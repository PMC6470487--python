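"""Anatomical-frame kinematics from NED navigation output.

For walking and running on level ground the anatomical frame (x anterior,
z up) is well approximated by horizontal speed and the direction of travel
(ground track):

    V(t)   = sqrt(V_N(t)^2 + V_E(t)^2)
    Psi(t) = atan2(V_E(t), V_N(t))

Vertical quantities flip sign from the NED "down" axis to up-positive, and
pitch/yaw come from the orientation quaternion via the aerospace Z-Y-X
Euler convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io_streams import DataError, SensorStream

#: m/s below which the ground track is held at its last valid value —
#: heading from horizontal velocity is undefined near standstill.
STALL_SPEED = 0.3


@dataclass
class AnatomicalSeries:
    """Per-sample anatomical-frame kinematics of one trial."""

    t: np.ndarray
    speed: np.ndarray           # m/s, >= 0
    ground_track: np.ndarray    # rad in (-pi, pi]
    a_forward: np.ndarray       # m/s^2, horizontal magnitude, >= 0
    v_vertical: np.ndarray      # m/s, up-positive
    a_vertical: np.ndarray      # m/s^2, up-positive
    pitch: np.ndarray           # rad, forward-positive lean
    yaw: np.ndarray             # rad
    rate: float = 400.0


def compute_speed(v_north: np.ndarray, v_east: np.ndarray) -> np.ndarray:
    """Horizontal speed: elementwise Euclidean norm of (V_N, V_E)."""
    v_north = np.asarray(v_north, float)
    v_east = np.asarray(v_east, float)
    if v_north.shape != v_east.shape:
        raise ValueError(f"shape mismatch: {v_north.shape} vs {v_east.shape}")
    return np.hypot(v_north, v_east)


def compute_ground_track(v_north: np.ndarray, v_east: np.ndarray,
                         stall_speed: float = STALL_SPEED) -> np.ndarray:
    """Direction of travel in radians, (-pi, pi], 0 = north, pi/2 = east.

    Uses the four-quadrant arctangent (a plain atan of V_E/V_N cannot tell
    north from south).  Where speed is below ``stall_speed`` the heading is
    ill-conditioned and the last valid value is held; leading stalled
    samples take the first valid value (0 if the whole series is stalled).
    """
    v_north = np.asarray(v_north, float)
    v_east = np.asarray(v_east, float)
    if v_north.shape != v_east.shape:
        raise ValueError(f"shape mismatch: {v_north.shape} vs {v_east.shape}")
    psi = np.arctan2(v_east, v_north)
    speed = np.hypot(v_north, v_east)
    stalled = speed < stall_speed
    if stalled.any() and not stalled.all():
        idx = np.arange(len(psi))
        valid = ~stalled
        # hold-last-valid: index of most recent valid sample at or before i
        last = np.maximum.accumulate(np.where(valid, idx, -1))
        first_valid = idx[valid][0]
        last = np.where(last < 0, first_valid, last)
        psi = psi[last]
    elif stalled.all():
        psi = np.zeros_like(psi)
    return wrap_angle(psi)


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    out = np.mod(np.asarray(a, float) + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def compute_forward_acceleration(a_north: np.ndarray, a_east: np.ndarray) -> np.ndarray:
    """Magnitude of the horizontal acceleration components, m/s^2."""
    a_north = np.asarray(a_north, float)
    a_east = np.asarray(a_east, float)
    if a_north.shape != a_east.shape:
        raise ValueError(f"shape mismatch: {a_north.shape} vs {a_east.shape}")
    return np.hypot(a_north, a_east)


def vertical_from_ned(v_down: np.ndarray) -> np.ndarray:
    """Convert the NED down-positive axis to the anatomical up-positive axis."""
    return -np.asarray(v_down, float)


def euler_from_quaternion(q: np.ndarray, tol: float = 1e-6
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Extract (pitch, yaw) from scalar-first unit quaternions.

    Z-Y-X (yaw-pitch-roll) aerospace convention; pitch in [-pi/2, pi/2],
    yaw in (-pi, pi].  Raises DataError if any quaternion norm departs from
    1 by more than ``tol``.
    """
    q = np.asarray(q, float).reshape(-1, 4)
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > tol):
        i = int(np.argmax(np.abs(norms - 1.0)))
        raise DataError(f"non-unit quaternion at index {i}: norm {norms[i]:.9f}")
    rot = Rotation.from_quat(q[:, [1, 2, 3, 0]])  # scipy wants (x, y, z, w)
    yaw, pitch, _roll = rot.as_euler("ZYX").T
    return pitch, yaw


def anatomical_from_stream(stream: SensorStream,
                           stall_speed: float = STALL_SPEED) -> AnatomicalSeries:
    """Full anatomical-frame transformation of a fused sensor stream."""
    pitch, yaw = euler_from_quaternion(stream.q)
    return AnatomicalSeries(
        t=stream.t,
        speed=compute_speed(stream.v_north, stream.v_east),
        ground_track=compute_ground_track(stream.v_north, stream.v_east, stall_speed),
        a_forward=compute_forward_acceleration(stream.a_north, stream.a_east),
        v_vertical=vertical_from_ned(stream.v_down),
        a_vertical=stream.a_vertical,
        pitch=pitch,
        yaw=yaw,
        rate=stream.rate,
    )
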