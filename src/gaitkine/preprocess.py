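"""High-pass drift removal for vertical velocity.

Integrated navigation velocity carries low-frequency drift (accelerometer
bias, inclined terrain); gait information lives at the step frequency and
its harmonics (roughly 1.5-3.5 Hz and up).  Before zero-crossing
segmentation and displacement integration the vertical velocity is
high-pass filtered with a minimum-order linear-phase FIR designed from a
(passband edge, stopband attenuation, steepness) triple:

* passband edge: fraction of Nyquist, default 0.005 (1 Hz at 400 Hz);
* stopband attenuation: 30 dB;
* steepness 0.7: the transition band occupies (1 - steepness) of the band
  below the passband edge, i.e. the stopband edge sits at
  steepness * f_pass.

The kernel is an odd-length Kaiser-window design applied with exact
group-delay compensation (centred convolution over odd-reflection padding),
so the filter is zero-phase: zero-crossing times of in-band components are
preserved, which is what the segmentation relies on.  The tap sum is nulled
so the DC gain is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin, kaiserord

from .io_streams import DataError


@dataclass(frozen=True)
class FilterSpec:
    """Design triple for the drift-removal high-pass filter."""

    passband_edge: float = 0.005     # fraction of Nyquist
    stopband_attenuation: float = 30.0  # dB
    steepness: float = 0.7
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.passband_edge < 1.0:
            raise ValueError("passband_edge must be in (0, 1) (fraction of Nyquist)")
        if self.stopband_attenuation <= 0:
            raise ValueError("stopband_attenuation must be > 0 dB")
        if not 0.5 <= self.steepness < 1.0:
            raise ValueError("steepness must be in [0.5, 1)")

    def passband_hz(self, fs: float) -> float:
        return self.passband_edge * fs / 2.0

    def transition_width_hz(self, fs: float) -> float:
        return (1.0 - self.steepness) * self.passband_hz(fs)


def design_highpass(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the minimum-order Kaiser FIR high-pass kernel (odd length)."""
    nyq = fs / 2.0
    width = spec.transition_width_hz(fs)
    numtaps, beta = kaiserord(spec.stopband_attenuation, width / nyq)
    numtaps |= 1  # odd length -> exactly compensable (integer) group delay
    cutoff = spec.passband_hz(fs) - width / 2.0  # transition band centre
    h = firwin(numtaps, cutoff, window=("kaiser", beta), pass_zero=False, fs=fs)
    h = h - h.sum() / numtaps  # null the DC gain exactly
    return h


def edge_guard(spec: FilterSpec | None = None, fs: float = 400.0) -> float:
    """Seconds at each end of a filtered window inside which the output is
    contaminated by the filter's edge transient (half the kernel span).
    Steps overlapping this region should not be scored."""
    spec = spec or FilterSpec()
    return (len(design_highpass(spec, fs)) // 2) / fs


def highpass_vertical_velocity(v: np.ndarray, spec: FilterSpec | None = None,
                               fs: float = 400.0) -> np.ndarray:
    """Remove sub-passband drift from a velocity series, zero-phase.

    Raises DataError if the series is shorter than 3x the filter length
    (the minimum-order design at the default spec spans ~5 s at 400 Hz, so
    trials should be >= ~16 s).
    """
    spec = spec or FilterSpec()
    v = np.asarray(v, float)
    h = design_highpass(spec, fs)
    n = len(h)
    if len(v) <= 3 * n:
        raise DataError(
            f"series of {len(v)} samples too short for the minimum-order filter: "
            f"need more than {3 * n} samples ({3 * n / fs:.1f} s at {fs:g} Hz)"
        )
    if not spec.zero_phase:
        return np.convolve(v, h)[: len(v)]
    half = n // 2
    # odd reflection about the end points suppresses edge transients
    pad_l = 2 * v[0] - v[half:0:-1]
    pad_r = 2 * v[-1] - v[-2:-half - 2:-1]
    ext = np.concatenate([pad_l, v, pad_r])
    out = fftconvolve(ext, h, mode="same")
    return out[half:half + len(v)]
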