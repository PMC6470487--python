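"""Per-step walking/running metrics.

Each regular step (apex-to-apex segment) yields a metric vector: cadence,
step duration, step length (time integral of speed), mean and peak-to-peak
speed, peak-to-peak vertical displacement (cumulative trapezoidal integral
of drift-free vertical velocity about the window mean), forward lean (mean
pitch), body rotation (yaw swing about the ground track), and — when a
contact series is available — contact time, duty factor, flight time and
flight distance.  Total mechanical energy needs the subject's mass.

Integrals are trapezoidal; segment boundaries are sub-sample, so boundary
values are obtained by linear interpolation of the cumulative integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .io_streams import ContactSeries, RangeError
from .kinematics import AnatomicalSeries
from .segmentation import StepSegment, regular

G = 9.81  # m/s^2

_ABSENT = float("nan")


@dataclass
class StepMetrics:
    """Metric vector of one step; optional metrics are NaN when absent."""

    t_start: float
    t_end: float
    step_duration: float
    cadence: float              # steps/min = 60 / duration
    step_length: float          # m
    speed_mean: float           # m/s = step_length / duration
    speed_p2p: float            # m/s
    vertical_disp_p2p: float    # m
    vertical_closure: float     # m, displacement change start->end (error proxy)
    forward_lean: float         # deg
    body_rotation: float        # deg
    contact_time: float = _ABSENT       # s
    duty_factor: float = _ABSENT        # % of step duration
    flight_time: float = _ABSENT        # s
    flight_distance: float = _ABSENT    # m
    mech_energy: float = _ABSENT        # J


def _cumint(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    return cumulative_trapezoid(y, t, initial=0.0)


def _at(t_query: float, t: np.ndarray, cum: np.ndarray) -> float:
    return float(np.interp(t_query, t, cum))


def _segment_values(y: np.ndarray, t: np.ndarray, seg: StepSegment) -> np.ndarray:
    """Samples inside the segment plus interpolated boundary values."""
    inner = y[seg.i_start:seg.i_end]
    ends = np.interp([seg.t_start, seg.t_end], t, y)
    return np.concatenate([[ends[0]], inner, [ends[1]]])


def step_length(speed: np.ndarray, t: np.ndarray, seg: StepSegment,
                _cum: np.ndarray | None = None) -> float:
    """Distance travelled during one step: trapezoidal integral of speed."""
    if seg.t_start < t[0] - 1e-9 or seg.t_end > t[-1] + 1e-9:
        raise RangeError("segment lies outside the stream time span")
    cum = _cumint(speed, t) if _cum is None else _cum
    return _at(seg.t_end, t, cum) - _at(seg.t_start, t, cum)


def vertical_displacement(v_vertical: np.ndarray, t: np.ndarray,
                          segments: list[StepSegment]
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Vertical displacement series and per-step oscillation.

    The displacement is the cumulative trapezoidal integral of the
    (drift-free) vertical velocity, referenced to the window mean height —
    the window being the integer number of steps spanned by ``segments``.
    Returns the displacement series and a table with, per step, the
    peak-to-peak displacement and the closure residual (displacement change
    from step start to step end, zero for ideal level-ground gait).
    """
    disp = _cumint(v_vertical, t)
    if segments:
        i0 = segments[0].i_start
        i1 = segments[-1].i_end
        disp = disp - np.mean(disp[i0:i1])
    rows = []
    for seg in segments:
        vals = _segment_values(disp, t, seg)
        rows.append({
            "t_start": seg.t_start,
            "p2p": float(np.max(vals) - np.min(vals)),
            "closure": float(vals[-1] - vals[0]),
        })
    return disp, pd.DataFrame(rows)


def speed_p2p(speed: np.ndarray, t: np.ndarray, seg: StepSegment) -> float:
    """Peak-to-peak speed difference within one step, m/s."""
    vals = _segment_values(speed, t, seg)
    return float(np.max(vals) - np.min(vals))


def forward_lean(pitch: np.ndarray, t: np.ndarray, seg: StepSegment) -> float:
    """Mean sagittal lean over the step, degrees, forward-positive."""
    vals = _segment_values(pitch, t, seg)
    return float(np.degrees(np.mean(vals)))


def body_rotation(yaw: np.ndarray, ground_track: np.ndarray, t: np.ndarray,
                  seg: StepSegment) -> float:
    """Peak-to-peak rotation about the vertical axis relative to the ground
    track, degrees.  Both angle series are unwrapped before differencing so
    heading wrap-around does not inflate the swing."""
    rel = np.unwrap(yaw) - np.unwrap(ground_track)
    vals = _segment_values(rel, t, seg)
    return float(np.degrees(np.max(vals) - np.min(vals)))


def _stance_runs(contact: np.ndarray, t: np.ndarray) -> list[tuple[float, float]]:
    c = np.asarray(contact).astype(int)
    d = np.diff(np.concatenate([[0], c, [0]]))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    return [(t[s], t[min(e, len(t) - 1)] + (dt if e == len(t) else 0.0))
            for s, e in zip(starts, ends)]


def duty_and_flight(contact: ContactSeries, seg: StepSegment,
                    speed: np.ndarray, t: np.ndarray,
                    _cum_dist: np.ndarray | None = None) -> dict[str, float]:
    """Contact time, duty factor, flight time and flight distance of a step.

    The contact time is the stance duration of the foot whose stance
    midpoint falls inside the step.  With double support (walking) one foot
    is grounded for longer than a step, so the duty factor — defined as
    100 * contact_time / step_duration — can exceed 100%.  Flight is the
    part of the step where neither foot is grounded (running only).
    """
    stances = (_stance_runs(contact.contact_left, contact.t)
               + _stance_runs(contact.contact_right, contact.t))
    ct = _ABSENT
    for s0, s1 in stances:
        mid = 0.5 * (s0 + s1)
        if seg.t_start <= mid < seg.t_end:
            ct = s1 - s0
            break
    out = {"contact_time": ct,
           "duty_factor": 100.0 * ct / seg.duration if np.isfinite(ct) else _ABSENT}
    both = (contact.contact_left == 0) & (contact.contact_right == 0)
    i0 = int(np.searchsorted(contact.t, seg.t_start, side="left"))
    i1 = int(np.searchsorted(contact.t, seg.t_end, side="left"))
    airborne = both[i0:i1]
    dt = contact.t[1] - contact.t[0] if len(contact.t) > 1 else 0.0
    out["flight_time"] = float(np.sum(airborne) * dt)
    cum = _cumint(speed, t) if _cum_dist is None else _cum_dist
    dist = 0.0
    for s0, s1 in _stance_runs(airborne.astype(int), contact.t[i0:i1]):
        dist += _at(s1, t, cum) - _at(s0, t, cum)
    out["flight_distance"] = float(dist)
    return out


def mech_energy(speed: np.ndarray, v_vertical: np.ndarray, disp: np.ndarray,
                t: np.ndarray, seg: StepSegment, mass: float) -> float:
    """Mean total mechanical energy over the step, joules.

    Kinetic (horizontal + vertical) plus potential about the window-mean
    height: E = 1/2 m (V^2 + v_z^2) + m g h.
    """
    if not mass > 0:
        raise ValueError("mass must be > 0")
    V = _segment_values(speed, t, seg)
    vz = _segment_values(v_vertical, t, seg)
    h = _segment_values(disp, t, seg)
    return float(np.mean(0.5 * mass * (V ** 2 + vz ** 2) + mass * G * h))


def windowed_speed(speed: np.ndarray, t: np.ndarray,
                   boundaries: np.ndarray,
                   distances: tuple[float, ...] = (10.0, 20.0, 50.0)
                   ) -> pd.DataFrame:
    """Mean speed over rolling distance windows, evaluated at step starts.

    For each target distance D and boundary time tb, the speed is
    D / (time to travel D metres starting at tb); NaN where the remaining
    trial is shorter than D.
    """
    cum = _cumint(speed, t)
    rows = {}
    for D in distances:
        vals = []
        for tb in boundaries:
            d0 = _at(tb, t, cum)
            if cum[-1] - d0 < D:
                vals.append(_ABSENT)
                continue
            t_reach = float(np.interp(d0 + D, cum, t))
            vals.append(D / (t_reach - tb))
        rows[f"speed_{D:g}m"] = vals
    rows["t_start"] = list(boundaries)
    return pd.DataFrame(rows)


def compute_step_metrics(anat: AnatomicalSeries,
                         segments: list[StepSegment],
                         contact: ContactSeries | None = None,
                         mass: float | None = None) -> pd.DataFrame:
    """Metric table for the regular steps of a trial (one row per step)."""
    segs = regular(segments)
    t = anat.t
    cum_dist = _cumint(anat.speed, t)
    disp, vtab = vertical_displacement(anat.v_vertical, t, segs)
    rows = []
    for k, seg in enumerate(segs):
        L = step_length(anat.speed, t, seg, _cum=cum_dist)
        m = StepMetrics(
            t_start=seg.t_start,
            t_end=seg.t_end,
            step_duration=seg.duration,
            cadence=60.0 / seg.duration,
            step_length=L,
            speed_mean=L / seg.duration,
            speed_p2p=speed_p2p(anat.speed, t, seg),
            vertical_disp_p2p=float(vtab["p2p"].iloc[k]),
            vertical_closure=float(vtab["closure"].iloc[k]),
            forward_lean=forward_lean(anat.pitch, t, seg),
            body_rotation=body_rotation(anat.yaw, anat.ground_track, t, seg),
        )
        if contact is not None:
            for key, val in duty_and_flight(contact, seg, anat.speed, t,
                                            _cum_dist=cum_dist).items():
                setattr(m, key, val)
        if mass is not None:
            m.mech_energy = mech_energy(anat.speed, anat.v_vertical, disp,
                                        t, seg, mass)
        rows.append(asdict(m))
    return pd.DataFrame(rows)
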