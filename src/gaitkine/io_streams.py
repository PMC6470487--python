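"""Time-series data model and I/O for fused INS/GPS and insole logs.

The pipeline consumes the fused output of a GPS-aided inertial navigation
sensor sampled at 400 Hz: NED velocity, body acceleration, angular velocity
and an orientation quaternion, optionally position.  Instrumented-insole
force logs (50 or 100 Hz native) provide per-foot vertical force and serve
as ground truth for contact and GRF.  This module defines the validated
in-memory containers, delimited-text readers/writers, and the multi-rate
resampling/alignment used to bring insole data onto the 400 Hz grid.

Timestamps are float seconds from an arbitrary origin (GPS-time-like); all
internal computation uses seconds from stream start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

NOMINAL_RATE = 400.0  #: Hz, the fused-navigation output rate
INSOLE_NATIVE_RATES = (50.0, 100.0)  #: Hz, supported insole output rates
DEFAULT_CONTACT_THRESHOLD_N = 20.0  #: N, force level defining ground contact
_FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """A log file does not match the declared column dialect."""


class DataError(ValueError):
    """Stream contents violate an invariant (monotonicity, unit norm, ...)."""


class RangeError(ValueError):
    """A requested interval lies (partly) outside the available data."""


def _check_monotone(t: np.ndarray) -> None:
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise DataError(
            f"timestamps not strictly increasing: first violation at index {bad[0] + 1}"
        )


@dataclass
class SensorStream:
    """Fused INS/GPS record set on a (nominally) 400 Hz grid.

    Attributes
    ----------
    t : ndarray
        Seconds, strictly increasing.
    v_north, v_east, v_down : ndarray
        NED velocity components, m/s.
    a_north, a_east : ndarray
        Horizontal acceleration components, m/s^2.
    a_vertical : ndarray
        Vertical acceleration, m/s^2, up-positive.
    omega : ndarray, shape (n, 3)
        Body angular velocity, rad/s.
    q : ndarray, shape (n, 4)
        Orientation quaternion, scalar-first (w, x, y, z), unit norm.
    pos : ndarray, shape (n, 3), optional
        Local-level position (north, east, down metres) if logged.
    rate : float
        Nominal sample rate, Hz.
    """

    t: np.ndarray
    v_north: np.ndarray
    v_east: np.ndarray
    v_down: np.ndarray
    a_north: np.ndarray
    a_east: np.ndarray
    a_vertical: np.ndarray
    omega: np.ndarray
    q: np.ndarray
    pos: np.ndarray | None = None
    rate: float = NOMINAL_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("v_north", "v_east", "v_down", "a_north", "a_east", "a_vertical"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.omega = np.asarray(self.omega, dtype=float).reshape(len(self.t), 3)
        self.q = np.asarray(self.q, dtype=float).reshape(len(self.t), 4)
        self.validate()

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        n = len(self.t)
        for name in ("v_north", "v_east", "v_down", "a_north", "a_east", "a_vertical"):
            if len(getattr(self, name)) != n:
                raise DataError(f"field {name!r} length != len(t)")
        _check_monotone(self.t)
        if n > 2:
            med = np.median(np.diff(self.t))
            if abs(med - 1.0 / self.rate) > 0.01 / self.rate:
                raise DataError(
                    f"median sample interval {med:.6g} s departs >1% from 1/{self.rate:g} s"
                )
        norms = np.linalg.norm(self.q, axis=1)
        worst = np.argmax(np.abs(norms - 1.0))
        if abs(norms[worst] - 1.0) > 1e-6:
            raise DataError(
                f"quaternion norm {norms[worst]:.9f} at index {worst} departs from 1 by >1e-6"
            )

    def slice(self, i0: int, i1: int) -> "SensorStream":
        """Return the half-open sample range [i0, i1) as a new stream."""
        kw = dict(
            t=self.t[i0:i1],
            v_north=self.v_north[i0:i1],
            v_east=self.v_east[i0:i1],
            v_down=self.v_down[i0:i1],
            a_north=self.a_north[i0:i1],
            a_east=self.a_east[i0:i1],
            a_vertical=self.a_vertical[i0:i1],
            omega=self.omega[i0:i1],
            q=self.q[i0:i1],
            rate=self.rate,
        )
        if self.pos is not None:
            kw["pos"] = self.pos[i0:i1]
        return SensorStream(**kw)


@dataclass
class InsoleStream:
    """Per-foot total vertical force from instrumented insoles.

    ``native_rate`` is the rate the insoles logged at (50 or 100 Hz with 13
    or 6 pressure sensors per insole respectively); after
    :func:`resample_insole` the stream carries ``rate`` = target rate.
    """

    t: np.ndarray
    force_left: np.ndarray
    force_right: np.ndarray
    native_rate: float = 50.0
    rate: float | None = None  # current rate; None means == native_rate

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.force_left = np.asarray(self.force_left, dtype=float)
        self.force_right = np.asarray(self.force_right, dtype=float)
        if self.rate is None:
            self.rate = float(self.native_rate)
        self.validate()

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        if len(self.force_left) != len(self.t) or len(self.force_right) != len(self.t):
            raise DataError("force series length != len(t)")
        _check_monotone(self.t)
        if np.any(self.force_left < 0) or np.any(self.force_right < 0):
            raise DataError("insole forces must be non-negative")
        if self.rate == self.native_rate and self.native_rate not in INSOLE_NATIVE_RATES:
            raise DataError(
                f"native insole rate must be one of {INSOLE_NATIVE_RATES}, got {self.native_rate}"
            )


@dataclass
class ContactSeries:
    """Binary per-foot ground contact on the 400 Hz grid (1 = foot on ground)."""

    t: np.ndarray
    contact_left: np.ndarray
    contact_right: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.contact_left = np.asarray(self.contact_left)
        self.contact_right = np.asarray(self.contact_right)
        for c in (self.contact_left, self.contact_right):
            if not np.isin(c, (0, 1)).all():
                raise DataError("contact values must be exactly 0 or 1")
        self.contact_left = self.contact_left.astype(np.int8)
        self.contact_right = self.contact_right.astype(np.int8)

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

#: canonical column order for sensor logs; dialects map field -> column name
SENSOR_FIELDS = (
    "t", "v_north", "v_east", "v_down",
    "a_north", "a_east", "a_vertical",
    "omega_x", "omega_y", "omega_z",
    "q_w", "q_x", "q_y", "q_z",
)
SENSOR_POS_FIELDS = ("pos_n", "pos_e", "pos_d")
INSOLE_FIELDS = ("t", "force_left", "force_right")

DEFAULT_SENSOR_DIALECT: dict[str, str] = {f: f for f in SENSOR_FIELDS + SENSOR_POS_FIELDS}
DEFAULT_INSOLE_DIALECT: dict[str, str] = {f: f for f in INSOLE_FIELDS}


def _resolve(df: pd.DataFrame, dialect: Mapping[str, str], fld: str, path) -> np.ndarray:
    col = dialect.get(fld, fld)
    if col not in df.columns:
        raise FormatError(f"{path}: missing mandatory column {col!r} (field {fld!r})")
    return df[col].to_numpy(dtype=float)


def read_sensor_log(path, dialect: Mapping[str, str] | None = None,
                    rate: float = NOMINAL_RATE) -> SensorStream:
    """Read a delimited fused-navigation log into a validated SensorStream.

    ``dialect`` maps canonical field names (see :data:`SENSOR_FIELDS`) to the
    file's column names; omitted entries default to the canonical name.
    Quaternion order is scalar-first (w, x, y, z) unless remapped by the
    dialect.  Position columns are optional.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path)
    cols = {f: _resolve(df, dialect, f, path) for f in SENSOR_FIELDS}
    pos = None
    if all(dialect.get(f, f) in df.columns for f in SENSOR_POS_FIELDS):
        pos = np.column_stack([df[dialect.get(f, f)].to_numpy(float) for f in SENSOR_POS_FIELDS])
    return SensorStream(
        t=cols["t"],
        v_north=cols["v_north"], v_east=cols["v_east"], v_down=cols["v_down"],
        a_north=cols["a_north"], a_east=cols["a_east"], a_vertical=cols["a_vertical"],
        omega=np.column_stack([cols["omega_x"], cols["omega_y"], cols["omega_z"]]),
        q=np.column_stack([cols["q_w"], cols["q_x"], cols["q_y"], cols["q_z"]]),
        pos=pos, rate=rate,
    )


def write_sensor_log(stream: SensorStream, path,
                     dialect: Mapping[str, str] | None = None) -> None:
    """Write a SensorStream as CSV with fixed column order, 12 sig. digits."""
    dialect = dict(dialect or {})
    data = {
        "t": stream.t,
        "v_north": stream.v_north, "v_east": stream.v_east, "v_down": stream.v_down,
        "a_north": stream.a_north, "a_east": stream.a_east, "a_vertical": stream.a_vertical,
        "omega_x": stream.omega[:, 0], "omega_y": stream.omega[:, 1], "omega_z": stream.omega[:, 2],
        "q_w": stream.q[:, 0], "q_x": stream.q[:, 1], "q_y": stream.q[:, 2], "q_z": stream.q[:, 3],
    }
    if stream.pos is not None:
        for i, f in enumerate(SENSOR_POS_FIELDS):
            data[f] = stream.pos[:, i]
    df = pd.DataFrame({dialect.get(k, k): v for k, v in data.items()})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_insole_log(path, dialect: Mapping[str, str] | None = None,
                    native_rate: float = 50.0) -> InsoleStream:
    """Read a delimited insole force log (per-foot total vertical force, N)."""
    dialect = dict(dialect or {})
    df = pd.read_csv(path)
    cols = {f: _resolve(df, dialect, f, path) for f in INSOLE_FIELDS}
    return InsoleStream(t=cols["t"], force_left=cols["force_left"],
                        force_right=cols["force_right"], native_rate=native_rate)


def write_insole_log(stream: InsoleStream, path,
                     dialect: Mapping[str, str] | None = None) -> None:
    dialect = dict(dialect or {})
    df = pd.DataFrame({
        dialect.get("t", "t"): stream.t,
        dialect.get("force_left", "force_left"): stream.force_left,
        dialect.get("force_right", "force_right"): stream.force_right,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Resampling, binarization, alignment
# ---------------------------------------------------------------------------

def resample_insole(s: InsoleStream, target_rate: float = NOMINAL_RATE) -> InsoleStream:
    """Linearly interpolate an insole stream onto a uniform target grid.

    The insole logs at 50 or 100 Hz; the fused navigation output at 400 Hz.
    Interpolation is linear with clamped endpoints; forces stay >= 0 because
    linear interpolation preserves non-negativity.
    """
    if target_rate < s.rate:
        raise ValueError(f"target rate {target_rate} < current rate {s.rate}")
    n = int(np.floor((s.t[-1] - s.t[0]) * target_rate)) + 1
    t_new = s.t[0] + np.arange(n) / target_rate
    if t_new[-1] > s.t[-1] + 1e-12:
        raise RangeError("target grid extends beyond source time span")
    fl = np.interp(t_new, s.t, s.force_left)
    fr = np.interp(t_new, s.t, s.force_right)
    return InsoleStream(t=t_new, force_left=fl, force_right=fr,
                        native_rate=s.native_rate, rate=float(target_rate))


def binarize_contact(s: InsoleStream,
                     force_threshold: float = DEFAULT_CONTACT_THRESHOLD_N) -> ContactSeries:
    """Threshold per-foot force into a 0/1 ground-contact series."""
    if force_threshold <= 0:
        raise ValueError("force_threshold must be > 0")
    return ContactSeries(
        t=s.t,
        contact_left=(s.force_left > force_threshold).astype(np.int8),
        contact_right=(s.force_right > force_threshold).astype(np.int8),
    )


def align_streams(a: SensorStream, b: InsoleStream, offset: float = 0.0
                  ) -> tuple[SensorStream, InsoleStream]:
    """Put a sensor and an insole stream on a common 400 Hz grid.

    ``offset`` (seconds) is added to the insole timestamps before computing
    the overlap; both returned streams cover exactly the overlap interval on
    the sensor stream's sample grid.
    """
    tb = b.t + offset
    t0 = max(a.t[0], tb[0])
    t1 = min(a.t[-1], tb[-1])
    if t1 <= t0:
        raise RangeError("streams do not overlap after applying offset")
    i0 = int(np.searchsorted(a.t, t0 - 1e-12, side="left"))
    i1 = int(np.searchsorted(a.t, t1 + 1e-12, side="right"))
    a_sub = a.slice(i0, i1)
    fl = np.interp(a_sub.t, tb, b.force_left)
    fr = np.interp(a_sub.t, tb, b.force_right)
    b_sub = InsoleStream(t=a_sub.t.copy(), force_left=fl, force_right=fr,
                         native_rate=b.native_rate, rate=a.rate)
    return a_sub, b_sub


def estimate_offset(sig_a: np.ndarray, t_a: np.ndarray,
                    sig_b: np.ndarray, t_b: np.ndarray,
                    max_lag: float = 5.0) -> float:
    """Recover the time offset between two streams from a shared transient.

    Field recordings are synchronized by having the subject jump so that a
    sharp spike appears in both the navigation and insole streams; the lag
    maximizing the cross-correlation of the two (mean-removed, linearly
    resampled onto a common grid) estimates the offset to add to stream b's
    timestamps.  Returns seconds, positive if b lags a.
    """
    rate = NOMINAL_RATE
    t0 = min(t_a[0], t_b[0])
    t1 = max(t_a[-1], t_b[-1])
    grid = np.arange(t0, t1, 1.0 / rate)
    xa = np.interp(grid, t_a, sig_a, left=0.0, right=0.0)
    xb = np.interp(grid, t_b, sig_b, left=0.0, right=0.0)
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    from scipy.signal import correlate

    corr = correlate(xa, xb, mode="full")
    lags = np.arange(-len(grid) + 1, len(grid)) / rate
    keep = np.abs(lags) <= max_lag
    best = np.argmax(corr[keep])
    return float(lags[keep][best])
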