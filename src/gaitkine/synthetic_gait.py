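"""Synthetic gait generator with full ground truth.

Emulates the two stream types the pipeline consumes — fused INS/GPS output
at 400 Hz and instrumented-insole vertical force at 50/100 Hz — for
walking, running, or mixed trials, together with the ground truth every
stage can be scored against: apex (step-start) times, per-step length /
speed / vertical oscillation, per-stance touchdown and toe-off, and
per-sample GRF per foot.

The kinematic model is a step-parameterized quasi-sinusoid: within step k
of duration d_k the gait phase is phi = 2*pi*(t - a_k)/d_k and

* vertical velocity  v_z = -(2*pi*h_k/d_k) * sin(phi)  (apex at phi = 0,
  CoM lowest at phi = pi), giving a per-step peak-to-peak vertical
  displacement of exactly 2*h_k;
* horizontal speed   V = S(t) + B(t) * sin(phi), S and B piecewise-linear
  across steps (braking/propulsion oscillation of half-amplitude B);
* step durations carry lognormal-ish cycle-to-cycle jitter (default 3% SD).

Vertical GRF uses the standard stance waveform families — a two-peak curve
for walking, a single half-sine for running — scaled so each stance's
impulse equals body weight times the step duration (two stances per
stride), which keeps steady-gait force balance.  Walking duty factors
(stance as % of the stride) above 50% give double support and no flight;
running duty below 50% gives flight phases.

The sensor error model mirrors a navigation-grade MEMS accelerometer
(in-run bias 0.04 mg, noise density 0.14 mg/rtHz, nonlinearity 0.5% of a
16 g full scale) and a GPS-corrected velocity error that is bounded
(±0.05 m/s) and zero-mean: a leaky integral of the accelerometer noise
plus slow GPS-like wander plus a small broadband component, rather than an
unbounded inertial drift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io_streams import ContactSeries, InsoleStream, SensorStream

G = 9.81


@dataclass(frozen=True)
class SensorErrorModel:
    """Accelerometer + fused-velocity error injection parameters."""

    accel_bias_mg: float = 0.04          # in-run bias stability, milli-g
    noise_density_mg: float = 0.14       # mg per root-Hz
    nonlinearity_frac: float = 0.005     # 0.5% of full scale
    full_scale_g: float = 16.0
    vel_bound: float = 0.05              # m/s, fused velocity error bound
    vel_wander_amps: tuple[float, ...] = (0.006, 0.004, 0.002)  # m/s, <0.2 Hz
    vel_broadband_sd: float = 0.002      # m/s, band-limited to ~15 Hz
    angle_noise_deg: tuple[float, float] = (0.1, 0.3)  # pitch/roll, yaw RMS
    gyro_noise_sd: float = 0.002         # rad/s
    force_noise_sd: float = 3.0          # N, insole measurement noise


@dataclass(frozen=True)
class GaitScenario:
    """Study conditions for one synthetic trial.

    ``duty_factor`` is the stance duration as a percentage of the stride
    (two steps), the biomechanics convention: walking ~62% implies double
    support, running ~35% implies flight phases.  ``vert_amp`` is the
    half-amplitude of the CoM vertical oscillation (peak-to-peak = 2x).
    """

    mode: str = "walk"                   # walk | run | mixed
    duration: float = 60.0               # s
    cadence: float = 120.0               # steps/min (walk 120, run 172)
    speed: float = 1.4                   # m/s base (walk 1-2, run 3-8)
    speed_osc: float = 0.15              # m/s within-step half-amplitude
    vert_amp: float = 0.015              # m half-amplitude
    duty_factor: float = 62.0            # % of stride
    lean_deg: float = 2.0                # mean forward lean
    lean_osc_deg: float = 1.0
    yaw_osc_deg: float = 3.0             # body-rotation half-amplitude
    roll_amp_deg: float = 3.0
    heading: float = 0.3                 # rad, base ground track
    heading_drift_amp: float = 0.1       # rad at 0.01 Hz
    speed_drift_amp: float = 0.05        # m/s at 0.02 Hz
    incline_drift: float = 0.0           # m/s^2-equivalent vertical bias
    cycle_jitter: float = 0.03           # SD fraction of step duration
    mass: float = 70.0                   # kg
    insole_rate: float = 100.0           # Hz (50 or 100)
    block_duration: float = 40.0         # s, mixed-mode block length
    error_model: SensorErrorModel | None = None
    seed: int = 0
    rate: float = 400.0

    def __post_init__(self) -> None:
        if not 0 < self.duty_factor < 100:
            raise ValueError("duty_factor must be in (0, 100)")
        if self.mode not in ("walk", "run", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "run" and self.duty_factor >= 50:
            raise ValueError("run mode requires duty_factor < 50 (flight phases)")

    @classmethod
    def walk(cls, **kw) -> "GaitScenario":
        return cls(**{**dict(mode="walk"), **kw})

    @classmethod
    def run(cls, **kw) -> "GaitScenario":
        base = dict(mode="run", cadence=172.0, speed=5.0, speed_osc=0.35,
                    vert_amp=0.05, duty_factor=35.0, lean_deg=6.0,
                    yaw_osc_deg=4.0)
        return cls(**{**base, **kw})

    @classmethod
    def mixed(cls, **kw) -> "GaitScenario":
        return cls(**{**dict(mode="mixed", duration=120.0), **kw})

    @classmethod
    def for_steps(cls, n_steps: int, **kw) -> "GaitScenario":
        """Scenario sized to contain ~n_steps complete steps."""
        tmp = cls(**kw) if kw.get("mode", "walk") != "run" else cls.run(**kw)
        duration = (n_steps + 4) * 60.0 / tmp.cadence
        return replace(tmp, duration=duration)


#: per-mode parameter presets used by mixed-mode blocks
_MODE_PARAMS = {
    "walk": dict(cadence=120.0, speed=1.4, speed_osc=0.15, vert_amp=0.015,
                 duty_factor=62.0, lean_deg=2.0, yaw_osc_deg=3.0),
    "run": dict(cadence=172.0, speed=5.0, speed_osc=0.35, vert_amp=0.05,
                duty_factor=35.0, lean_deg=6.0, yaw_osc_deg=4.0),
}
_SMOOTH_STEPS = 5  # moving-average width for mixed-mode transitions


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    apex_times: np.ndarray          # step boundaries (CoM apexes), s
    steps: pd.DataFrame             # per-step truth table
    stances: pd.DataFrame           # foot, touchdown, toeoff, gct, mode
    grf_left: np.ndarray            # N at 400 Hz
    grf_right: np.ndarray
    t: np.ndarray                   # the 400 Hz grid


class _StepPlan:
    """Per-step parameter arrays and the analytic signal closures."""

    def __init__(self, scenario: GaitScenario, rng: np.random.Generator):
        sc = scenario
        # draw steps until the cumulative time covers the trial (+margin)
        params = {k: [] for k in _MODE_PARAMS["walk"]}
        modes, durations = [], []
        t_cum = 0.0
        while t_cum < sc.duration + 2.0:
            if sc.mode == "mixed":
                block = int(t_cum // sc.block_duration)
                mode = "walk" if block % 2 == 0 else "run"
                p = _MODE_PARAMS[mode]
            else:
                mode = sc.mode
                p = dict(cadence=sc.cadence, speed=sc.speed,
                         speed_osc=sc.speed_osc, vert_amp=sc.vert_amp,
                         duty_factor=sc.duty_factor, lean_deg=sc.lean_deg,
                         yaw_osc_deg=sc.yaw_osc_deg)
            d = 60.0 / p["cadence"]
            d *= 1.0 + np.clip(sc.cycle_jitter * rng.standard_normal(), -3 * sc.cycle_jitter, 3 * sc.cycle_jitter)
            modes.append(mode)
            durations.append(d)
            for k in params:
                params[k].append(p[k])
            t_cum += d
        self.mode = np.asarray(modes)
        self.d = np.asarray(durations)
        if sc.mode == "mixed":  # soften block transitions over a few steps
            for k in params:
                params[k] = (pd.Series(params[k])
                             .rolling(_SMOOTH_STEPS, center=True, min_periods=1)
                             .mean().to_numpy())
            self.d = (pd.Series(self.d).rolling(_SMOOTH_STEPS, center=True,
                                                min_periods=1).mean().to_numpy())
        else:
            params = {k: np.asarray(v) for k, v in params.items()}
        self.p = params
        self.apex = np.concatenate([[0.0], np.cumsum(self.d)])
        self.mid = 0.5 * (self.apex[:-1] + self.apex[1:])
        self.K = len(self.d)
        self.scenario = sc

    # -- phase bookkeeping ------------------------------------------------
    def index(self, t: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(self.apex, t, side="right") - 1, 0, self.K - 1)

    def phase(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = self.index(t)
        phi = 2 * np.pi * (t - self.apex[k]) / self.d[k]
        return k, phi

    def _interp(self, key: str, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.mid, self.p[key])

    # -- analytic signals -------------------------------------------------
    def speed(self, t: np.ndarray) -> np.ndarray:
        sc = self.scenario
        _, phi = self.phase(t)
        drift = sc.speed_drift_amp * np.sin(2 * np.pi * 0.02 * t)
        return self._interp("speed", t) + self._interp("speed_osc", t) * np.sin(phi) + drift

    def v_vertical(self, t: np.ndarray) -> np.ndarray:
        k, phi = self.phase(t)
        amp = 2 * np.pi * self.p["vert_amp"][k] / self.d[k]
        out = -amp * np.sin(phi)
        if self.scenario.incline_drift:
            out = out + self.scenario.incline_drift * t / max(t[-1], 1e-9)
        return out

    def heading(self, t: np.ndarray) -> np.ndarray:
        sc = self.scenario
        return sc.heading + sc.heading_drift_amp * np.sin(2 * np.pi * 0.01 * t)

    def euler(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        sc = self.scenario
        k, phi = self.phase(t)
        yaw = self.heading(t) + np.radians(self._interp("yaw_osc_deg", t)) \
            * np.sin(phi) * np.where(k % 2 == 0, 1.0, -1.0)
        pitch = np.radians(self._interp("lean_deg", t)) \
            + np.radians(sc.lean_osc_deg) * np.sin(phi)
        roll = np.radians(sc.roll_amp_deg) * np.sin(phi / 2 + k * np.pi)
        return yaw, pitch, roll

    # -- ground reaction forces -------------------------------------------
    def stance_table(self) -> pd.DataFrame:
        """One row per stance: foot, touchdown, toe-off, peak force scale."""
        sc = self.scenario
        rows = []
        bw = sc.mass * G
        for k in range(self.K):
            tau = self.p["duty_factor"][k] / 100.0 * 2.0 * self.d[k]
            centre = self.apex[k] + 0.5 * self.d[k]
            walkish = self.p["duty_factor"][k] >= 50.0
            i_w = 2 / np.pi + 0.25 * 2 / (3 * np.pi) if walkish else 2 / np.pi
            rows.append({
                "foot": "left" if k % 2 == 0 else "right",
                "touchdown": centre - tau / 2,
                "toeoff": centre + tau / 2,
                "gct": tau,
                "scale": bw * self.d[k] / (i_w * tau),
                "two_peak": walkish,
                "mode": self.mode[k],
                "step": k,
            })
        return pd.DataFrame(rows)

    def grf(self, t: np.ndarray, foot: str,
            stances: pd.DataFrame | None = None) -> np.ndarray:
        st = (stances if stances is not None else self.stance_table())
        st = st[st.foot == foot]
        td = st.touchdown.to_numpy()
        toe = st.toeoff.to_numpy()
        scale = st.scale.to_numpy()
        two = st.two_peak.to_numpy()
        out = np.zeros_like(t, dtype=float)
        j = np.searchsorted(td, t, side="right") - 1
        ok = (j >= 0) & (t < toe[np.clip(j, 0, len(td) - 1)])
        jj = j[ok]
        s = (t[ok] - td[jj]) / (toe[jj] - td[jj])
        w = np.sin(np.pi * s)
        w = np.where(two[jj], w + 0.25 * np.sin(3 * np.pi * s), w)
        out[ok] = scale[jj] * w
        return out


def _angular_rates(rot: Rotation, dt: float) -> np.ndarray:
    """Body angular velocity from a rotation sequence (central logic:
    relative rotation between consecutive samples as a rotation vector)."""
    rel = rot[:-1].inv() * rot[1:]
    omega = rel.as_rotvec() / dt
    return np.vstack([omega, omega[-1:]])


def generate(scenario: GaitScenario
             ) -> tuple[SensorStream, InsoleStream, ContactSeries, GroundTruth]:
    """Synthesize one trial: sensor stream, insole stream, contact, truth.

    Deterministic: the same scenario (including seed) yields bit-identical
    outputs.  If ``scenario.error_model`` is set, the sensor and insole
    streams are corrupted accordingly; the ground truth always refers to
    the clean underlying motion.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    plan = _StepPlan(sc, rng)
    n = int(round(sc.duration * sc.rate))
    t = np.arange(n) / sc.rate
    dt = 1.0 / sc.rate

    V = plan.speed(t)
    psi = plan.heading(t)
    v_north = V * np.cos(psi)
    v_east = V * np.sin(psi)
    v_z = plan.v_vertical(t)
    a_north = np.gradient(v_north, dt)
    a_east = np.gradient(v_east, dt)
    a_vert = np.gradient(v_z, dt)

    yaw, pitch, roll = plan.euler(t)
    rot = Rotation.from_euler("ZYX", np.column_stack([yaw, pitch, roll]))
    q_xyzw = rot.as_quat()
    q = q_xyzw[:, [3, 0, 1, 2]]
    omega = _angular_rates(rot, dt)

    pos = np.column_stack([
        np.concatenate([[0.0], np.cumsum(0.5 * (v_north[1:] + v_north[:-1]) * dt)]),
        np.concatenate([[0.0], np.cumsum(0.5 * (v_east[1:] + v_east[:-1]) * dt)]),
        np.concatenate([[0.0], np.cumsum(0.5 * (-v_z[1:] + -v_z[:-1]) * dt)]),
    ])

    stances = plan.stance_table()
    grf_left = plan.grf(t, "left", stances)
    grf_right = plan.grf(t, "right", stances)

    # insole stream at native rate, evaluated from the analytic waveform
    n_ins = int(np.floor(sc.duration * sc.insole_rate))
    t_ins = np.arange(n_ins) / sc.insole_rate
    ins_left = plan.grf(t_ins, "left", stances)
    ins_right = plan.grf(t_ins, "right", stances)

    contact = ContactSeries(
        t=t.copy(),
        contact_left=(grf_left > 0).astype(np.int8),
        contact_right=(grf_right > 0).astype(np.int8),
    )

    # --- ground truth (before any corruption) ----------------------------
    fine = np.arange(int(round(sc.duration * 4 * sc.rate))) / (4 * sc.rate)
    cum_fine = np.concatenate([[0.0], np.cumsum(
        0.5 * (plan.speed(fine)[1:] + plan.speed(fine)[:-1]) / (4 * sc.rate))])
    apex = plan.apex
    keep = (apex[:-1] >= t[0]) & (plan.apex[1:] <= t[-1])
    idx = np.nonzero(keep)[0]
    lengths = np.interp(apex[idx + 1], fine, cum_fine) - np.interp(apex[idx], fine, cum_fine)
    steps = pd.DataFrame({
        "step": idx,
        "t_start": apex[idx],
        "t_end": apex[idx + 1],
        "t_midzero": apex[idx] + 0.5 * plan.d[idx],
        "duration": plan.d[idx],
        "length": lengths,
        "speed_mean": lengths / plan.d[idx],
        "vert_p2p": 2.0 * plan.p["vert_amp"][idx],
        "mode": plan.mode[idx],
        "foot": np.where(idx % 2 == 0, "left", "right"),
    })
    st = stances[(stances.touchdown >= t[0]) & (stances.toeoff <= t[-1])]
    truth = GroundTruth(
        apex_times=apex[(apex >= t[0]) & (apex <= t[-1])],
        steps=steps,
        stances=st[["foot", "touchdown", "toeoff", "gct", "mode", "step"]].reset_index(drop=True),
        grf_left=grf_left.copy(),
        grf_right=grf_right.copy(),
        t=t.copy(),
    )

    stream = SensorStream(
        t=t, v_north=v_north, v_east=v_east, v_down=-v_z,
        a_north=a_north, a_east=a_east, a_vertical=a_vert,
        omega=omega, q=q, pos=pos, rate=sc.rate,
    )
    insole = InsoleStream(t=t_ins, force_left=ins_left, force_right=ins_right,
                          native_rate=sc.insole_rate)

    if sc.error_model is not None:
        stream, insole = inject_sensor_errors(stream, insole, sc.error_model, rng)
    return stream, insole, contact, truth


# ---------------------------------------------------------------------------
# Sensor error injection
# ---------------------------------------------------------------------------

def _velocity_error(n: int, dt: float, em: SensorErrorModel,
                    rng: np.random.Generator) -> np.ndarray:
    """Bounded zero-mean fused-velocity error for one axis.

    Leaky integral (reversion 2 rad/s) of the accelerometer white noise,
    plus slow GPS-like wander (random-phase sinusoids below 0.2 Hz), plus
    a broadband component low-passed at ~15 Hz; clipped to the bound.
    """
    sigma_a = em.noise_density_mg * 1e-3 * G * np.sqrt(0.5 / dt)
    theta = 2.0
    w = rng.standard_normal(n) * sigma_a * dt
    ou = np.empty(n)
    acc = 0.0
    decay = 1.0 - theta * dt
    # leaky integration; scipy.signal.lfilter would do, but the loop is cheap
    from scipy.signal import lfilter
    ou = lfilter([1.0], [1.0, -decay], w)

    t = np.arange(n) * dt
    wander = np.zeros(n)
    freqs = (0.05, 0.11, 0.19)
    for a, f in zip(em.vel_wander_amps, freqs):
        wander += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    from scipy.signal import butter, filtfilt
    b, a_ = butter(2, 15.0, fs=1.0 / dt)
    bb = filtfilt(b, a_, rng.standard_normal(n))
    bb *= em.vel_broadband_sd / max(np.std(bb), 1e-12)
    return np.clip(ou + wander + bb, -em.vel_bound, em.vel_bound)


def inject_sensor_errors(stream: SensorStream, insole: InsoleStream | None,
                         em: SensorErrorModel,
                         rng: np.random.Generator | int = 0
                         ) -> tuple[SensorStream, InsoleStream | None]:
    """Corrupt clean streams with the accelerometer/velocity error model.

    Acceleration axes get output = a*(1 + alpha*a/FS) + bias + white noise;
    velocity axes get the bounded fused error of :func:`_velocity_error`;
    orientation gets slow small-angle noise (0.1 deg pitch/roll, 0.3 deg
    yaw RMS); angular rate gets white noise; insole forces get white noise
    clamped at zero.  The ground truth of the originating scenario is
    unaffected.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(stream)
    dt = 1.0 / stream.rate
    fs = em.full_scale_g * G
    sigma_a = em.noise_density_mg * 1e-3 * G * np.sqrt(0.5 / dt)
    bias = em.accel_bias_mg * 1e-3 * G

    def corrupt_accel(a: np.ndarray) -> np.ndarray:
        b = bias * rng.choice((-1.0, 1.0))
        return a * (1.0 + em.nonlinearity_frac * a / fs) + b \
            + sigma_a * rng.standard_normal(n)

    a_north = corrupt_accel(stream.a_north)
    a_east = corrupt_accel(stream.a_east)
    a_vert = corrupt_accel(stream.a_vertical)

    v_north = stream.v_north + _velocity_error(n, dt, em, rng)
    v_east = stream.v_east + _velocity_error(n, dt, em, rng)
    v_down = stream.v_down + _velocity_error(n, dt, em, rng)

    from scipy.signal import butter, filtfilt
    b_, a_ = butter(2, 0.5, fs=stream.rate)

    def slow_angle(rms_deg: float) -> np.ndarray:
        x = filtfilt(b_, a_, rng.standard_normal(n))
        return np.radians(rms_deg) * x / max(np.std(x), 1e-12)

    rot = Rotation.from_quat(stream.q[:, [1, 2, 3, 0]])
    yaw, pitch, roll = rot.as_euler("ZYX").T
    yaw = yaw + slow_angle(em.angle_noise_deg[1])
    pitch = pitch + slow_angle(em.angle_noise_deg[0])
    roll = roll + slow_angle(em.angle_noise_deg[0])
    q_noisy = Rotation.from_euler(
        "ZYX", np.column_stack([yaw, pitch, roll])).as_quat()[:, [3, 0, 1, 2]]

    omega = stream.omega + em.gyro_noise_sd * rng.standard_normal((n, 3))

    out_stream = SensorStream(
        t=stream.t.copy(), v_north=v_north, v_east=v_east, v_down=v_down,
        a_north=a_north, a_east=a_east, a_vertical=a_vert,
        omega=omega, q=q_noisy,
        pos=None if stream.pos is None else stream.pos.copy(),
        rate=stream.rate,
    )
    out_insole = insole
    if insole is not None:
        m = len(insole)
        out_insole = InsoleStream(
            t=insole.t.copy(),
            force_left=np.maximum(insole.force_left + em.force_noise_sd * rng.standard_normal(m), 0.0),
            force_right=np.maximum(insole.force_right + em.force_noise_sd * rng.standard_normal(m), 0.0),
            native_rate=insole.native_rate, rate=insole.rate,
        )
    return out_stream, out_insole
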