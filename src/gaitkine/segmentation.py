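"""Step segmentation from filtered vertical velocity.

A step starts at the instant the (drift-free) vertical velocity of the
centre of mass crosses zero going negative — the CoM apex.  Between two
consecutive apexes the velocity crosses zero once going positive, at the
CoM's lowest point (mid-step).  Crossing times are refined to sub-sample
resolution by linear interpolation between the bracketing samples, which
at 400 Hz (2.5 ms/sample) is what makes millisecond-level step timing
possible.

Windows containing irregular motion (neither walking nor running) are not
segmentable; :func:`reject_irregular` flags segments that fail simple
regularity rules so they can be excluded from metric computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: m/s — |v| must exceed this between crossings for a crossing to count
ZERO_THRESHOLD = 0.02
#: s — crossings of equal sign closer than this are merged (steepest kept)
REFRACTORY = 0.150

# irregular-motion rules
DURATION_BOUNDS = (0.2, 1.5)        # s, plausible step durations
MIN_P2P_VELOCITY = 0.1              # m/s, minimum vertical-velocity swing
MAX_MEDIAN_DEVIATION = 0.40         # fraction vs trailing 5-step median


@dataclass
class StepSegment:
    """One gait cycle: the half-open interval [t_start, t_end).

    ``t_midzero`` is the downward-to-upward velocity crossing inside the
    step (CoM lowest).  ``i_start``/``i_end`` are the sample indices whose
    times bracket the segment from inside.
    """

    t_start: float
    t_end: float
    i_start: int
    i_end: int
    t_midzero: float | None = None
    quality_flag: str = "regular"

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def find_zero_crossings(v: np.ndarray, t: np.ndarray,
                        threshold: float = ZERO_THRESHOLD,
                        refractory: float = REFRACTORY
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Locate sub-sample zero crossings of a filtered velocity series.

    Returns (times, signs): sign -1 for positive-to-negative (apex),
    +1 for negative-to-positive (mid-step).  Noise handling: a crossing is
    kept only if the signal reaches at least ``threshold`` in magnitude on
    both sides before the neighbouring opposite crossings, and same-sign
    crossings closer than ``refractory`` seconds are merged keeping the one
    with the steepest slope.
    """
    v = np.asarray(v, float)
    t = np.asarray(t, float)
    # hysteresis: the signal must leave the +/- threshold dead band on the
    # other side before a new crossing is recognized (Schmitt trigger), so
    # noise wiggles inside the band cannot create or destroy crossings
    armed = np.where(v >= threshold, 1, np.where(v <= -threshold, -1, 0))
    nz = np.nonzero(armed)[0]
    if nz.size == 0:
        return np.empty(0), np.empty(0)
    flips = np.nonzero(np.diff(armed[nz]) != 0)[0]

    raw = np.nonzero(np.sign(v[:-1]) * np.sign(v[1:]) < 0)[0]
    raw_slope = np.abs(v[raw + 1] - v[raw]) / (t[raw + 1] - t[raw])

    times, signs, slopes = [], [], []
    for f in flips:
        i0, i1 = nz[f], nz[f + 1]          # last sample at old state, first at new
        sign = -1.0 if armed[i0] > 0 else 1.0
        cand = raw[(raw >= i0) & (raw < i1)]
        if cand.size == 0:                 # exact-zero samples inside the band
            j = i0 + int(np.argmin(np.abs(v[i0:i1 + 1])))
            times.append(t[j])
            signs.append(sign)
            slopes.append(0.0)
            continue
        k = cand[int(np.argmax(raw_slope[np.isin(raw, cand)]))]
        frac = v[k] / (v[k] - v[k + 1])
        times.append(t[k] + frac * (t[k + 1] - t[k]))
        signs.append(sign)
        slopes.append(abs(v[k + 1] - v[k]) / (t[k + 1] - t[k]))
    times = np.asarray(times)
    signs = np.asarray(signs)
    slopes = np.asarray(slopes)

    # refractory merge per sign: keep steepest of each close-spaced cluster
    out_t, out_s = [], []
    for sign in (-1.0, 1.0):
        mask = signs == sign
        tt, sl = times[mask], slopes[mask]
        i = 0
        while i < len(tt):
            j = i
            while j + 1 < len(tt) and tt[j + 1] - tt[i] < refractory:
                j += 1
            k = i + int(np.argmax(sl[i:j + 1]))
            out_t.append(tt[k])
            out_s.append(sign)
            i = j + 1
    order = np.argsort(out_t)
    return np.asarray(out_t)[order], np.asarray(out_s)[order]


def segment_steps(v: np.ndarray, t: np.ndarray,
                  threshold: float = ZERO_THRESHOLD,
                  refractory: float = REFRACTORY) -> list[StepSegment]:
    """Partition a filtered vertical-velocity window into steps.

    One StepSegment per pair of consecutive negative-going crossings; the
    positive-going crossing between them becomes ``t_midzero`` (the
    steepest if noise produced several).  Partial steps at the window edges
    are dropped.  With fewer than two apexes an empty list is returned.
    """
    times, signs = find_zero_crossings(v, t, threshold, refractory)
    apexes = times[signs < 0]
    if len(apexes) < 2:
        logger.warning("fewer than 2 negative-going crossings: no complete steps")
        return []
    mids = times[signs > 0]
    segments = []
    for a, b in zip(apexes[:-1], apexes[1:]):
        inside = mids[(mids > a) & (mids < b)]
        mid = float(inside[0]) if inside.size else None
        i0 = int(np.searchsorted(t, a, side="left"))
        i1 = int(np.searchsorted(t, b, side="left"))
        segments.append(StepSegment(t_start=float(a), t_end=float(b),
                                    i_start=i0, i_end=i1, t_midzero=mid))
    return segments


def reject_irregular(v: np.ndarray, t: np.ndarray,
                     segments: list[StepSegment],
                     duration_bounds: tuple[float, float] = DURATION_BOUNDS,
                     min_p2p: float = MIN_P2P_VELOCITY,
                     max_median_dev: float = MAX_MEDIAN_DEVIATION,
                     edge_guard: float = 0.0) -> list[StepSegment]:
    """Flag segments that do not look like steady walking or running.

    A segment is flagged ``irregular`` when any of:

    * duration outside ``duration_bounds`` (default 0.2-1.5 s);
    * vertical-velocity peak-to-peak inside the segment below ``min_p2p``;
    * duration departing from the trailing 5-step median by more than
      ``max_median_dev`` (default 40%);
    * overlap with the first/last ``edge_guard`` seconds of the window,
      where a zero-phase filter's output carries its edge transient.

    Flags are set in place (and the list returned for convenience);
    flagged segments are excluded from metric computation downstream.
    """
    v = np.asarray(v, float)
    durations = [s.duration for s in segments]
    for k, seg in enumerate(segments):
        flag = "regular"
        if seg.t_start < t[0] + edge_guard or seg.t_end > t[-1] - edge_guard:
            flag = "irregular"
        elif not duration_bounds[0] <= seg.duration <= duration_bounds[1]:
            flag = "irregular"
        elif np.ptp(v[seg.i_start:seg.i_end]) < min_p2p:
            flag = "irregular"
        else:
            trailing = durations[max(0, k - 5):k]
            if trailing:
                med = float(np.median(trailing))
                if abs(seg.duration - med) > max_median_dev * med:
                    flag = "irregular"
        seg.quality_flag = flag
    return segments


def regular(segments: list[StepSegment]) -> list[StepSegment]:
    """The sub-list of segments flagged regular."""
    return [s for s in segments if s.quality_flag == "regular"]


def segment_trial(stream, filter_spec=None, threshold: float = ZERO_THRESHOLD,
                  refractory: float = REFRACTORY):
    """Full segmentation of a fused sensor stream.

    Convenience chain: anatomical transform -> high-pass drift removal ->
    zero-crossing segmentation -> regularity flagging (with the filter's
    edge-transient region guarded).  Returns (AnatomicalSeries with
    ``v_vertical`` replaced by its filtered version, segments).
    """
    from dataclasses import replace as _replace

    from .kinematics import anatomical_from_stream
    from .preprocess import edge_guard, highpass_vertical_velocity

    anat = anatomical_from_stream(stream)
    vf = highpass_vertical_velocity(anat.v_vertical, filter_spec, fs=stream.rate)
    segs = segment_steps(vf, anat.t, threshold, refractory)
    guard = edge_guard(filter_spec, stream.rate)
    reject_irregular(vf, anat.t, segs, edge_guard=guard)
    return _replace(anat, v_vertical=vf), segs


def segments_to_table(segments: list[StepSegment]):
    """Segments as a pandas DataFrame (t_start, t_end, t_midzero, flag)."""
    import pandas as pd

    return pd.DataFrame({
        "t_start": [s.t_start for s in segments],
        "t_end": [s.t_end for s in segments],
        "t_midzero": [s.t_midzero for s in segments],
        "i_start": [s.i_start for s in segments],
        "i_end": [s.i_end for s in segments],
        "quality_flag": [s.quality_flag for s in segments],
    })
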