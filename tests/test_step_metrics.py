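"""Per-step metric computations against closed-form and brute-force oracles."""

import numpy as np
import pytest

from gaitkine.io_streams import ContactSeries, RangeError
from gaitkine.segmentation import StepSegment, regular
from gaitkine.step_metrics import (body_rotation, compute_step_metrics,
                                   duty_and_flight, forward_lean, mech_energy,
                                   speed_p2p, step_length,
                                   vertical_displacement, windowed_speed)

FS = 400.0


def _grid(seconds):
    return np.arange(0, seconds, 1 / FS)


def _seg(t0, t1):
    return StepSegment(t0, t1, int(round(t0 * FS)), int(round(t1 * FS)))


def test_step_length_constant_speed():
    t = _grid(2)
    assert step_length(np.full_like(t, 2.0), t, _seg(0.5, 1.0)) == pytest.approx(1.0)
    assert step_length(np.zeros_like(t), t, _seg(0.5, 1.0)) == 0.0


def test_step_length_outside_span_raises():
    t = _grid(1)
    with pytest.raises(RangeError):
        step_length(np.ones_like(t), t, _seg(0.5, 1.5))


def test_step_lengths_conserve_total_distance(walk_segmented):
    """Sum of per-step lengths equals the trapezoidal distance over the
    regular portion within 0.1%."""
    anat, segs = walk_segmented
    regs = regular(segs)
    tab = compute_step_metrics(anat, segs)
    total = tab.step_length.sum()
    t0, t1 = regs[0].t_start, regs[-1].t_end
    m = (anat.t >= t0) & (anat.t <= t1)
    direct = np.trapezoid(anat.speed[m], anat.t[m])
    assert abs(total - direct) / direct < 1e-3


def test_cadence_speed_length_identities(walk_segmented):
    anat, segs = walk_segmented
    tab = compute_step_metrics(anat, segs)
    np.testing.assert_allclose(tab.cadence, 60.0 / tab.step_duration, rtol=1e-9)
    np.testing.assert_allclose(tab.speed_mean,
                               tab.step_length / tab.step_duration, rtol=1e-9)
    # cadence (steps/min) * step_length (m) = 60 * mean speed (m/min)
    np.testing.assert_allclose(tab.cadence * tab.step_length,
                               60.0 * tab.speed_mean, rtol=1e-6)


def test_vertical_displacement_closed_form():
    """v = A sin(2 pi f t): per-step displacement p2p = 2A/(2 pi f)."""
    A, f = 0.5, 1.5
    t = _grid(4)
    v = A * np.sin(2 * np.pi * f * t)
    segs = [_seg(k / f, (k + 1) / f) for k in range(1, 5)]
    _, tab = vertical_displacement(v, t, segs)
    np.testing.assert_allclose(tab.p2p, 2 * A / (2 * np.pi * f), rtol=1e-3)
    np.testing.assert_allclose(tab.closure, 0.0, atol=1e-5)


def test_vertical_displacement_zero_velocity():
    t = _grid(2)
    _, tab = vertical_displacement(np.zeros_like(t), t, [_seg(0.0, 1.0)])
    assert tab.p2p.iloc[0] == 0.0


def test_speed_p2p_examples(rng):
    t = _grid(2)
    seg = _seg(0.5, 1.5)  # one full period of a 1 Hz oscillation
    assert speed_p2p(np.full_like(t, 3.0), t, seg) == 0.0
    v = 3 + 0.2 * np.sin(2 * np.pi * 1.0 * t)
    assert speed_p2p(v, t, seg) == pytest.approx(0.4, abs=1e-4)
    x = rng.normal(size=len(t))
    vals = x[seg.i_start:seg.i_end]
    assert speed_p2p(x, t, seg) >= vals.max() - vals.min() - 1e-12


def test_forward_lean_mean_pitch():
    t = _grid(2)
    seg = _seg(0.5, 1.5)
    assert forward_lean(np.zeros_like(t), t, seg) == 0.0
    assert forward_lean(np.full_like(t, np.radians(5)), t, seg) == pytest.approx(5.0)
    pitch = np.radians(4) + np.radians(2) * np.sin(2 * np.pi * 1.0 * t)
    assert forward_lean(pitch, t, seg) == pytest.approx(4.0, abs=1e-3)


def test_body_rotation_swing_and_offset_invariance():
    t = _grid(2)
    seg = _seg(0.5, 1.5)
    psi = np.full_like(t, 0.3)
    assert body_rotation(psi, psi, t, seg) == 0.0
    yaw = psi + np.radians(6) * np.sin(2 * np.pi * 1.0 * t)
    assert body_rotation(yaw, psi, t, seg) == pytest.approx(12.0, abs=1e-3)
    # constant heading offset added to both leaves the metric unchanged
    off = 1.234
    assert body_rotation(yaw + off, psi + off, t, seg) == pytest.approx(
        body_rotation(yaw, psi, t, seg), abs=1e-9)


def test_duty_factor_example():
    """Contact 0.25 s inside a 0.35 s step -> duty factor 71.43%."""
    t = _grid(1)
    seg = _seg(0.30, 0.65)
    contact = np.zeros(len(t), np.int8)
    contact[(t >= 0.35) & (t < 0.60)] = 1
    c = ContactSeries(t=t, contact_left=contact, contact_right=np.zeros_like(contact))
    out = duty_and_flight(c, seg, np.full_like(t, 5.0), t)
    assert out["contact_time"] == pytest.approx(0.25, abs=2 / FS)
    assert out["duty_factor"] == pytest.approx(71.43, abs=1.0)


def test_walking_has_no_flight(walk_trial, walk_segmented):
    stream, insole, contact, truth = walk_trial
    anat, segs = walk_segmented
    tab = compute_step_metrics(anat, segs, contact=contact)
    assert np.allclose(tab.flight_time, 0.0)
    assert np.allclose(tab.flight_distance, 0.0)
    # double support: contact time exceeds the step duration
    assert (tab.contact_time > tab.step_duration).all()


def test_running_flight_matches_generator(run_trial):
    """Running at duty 35% of the stride: flight fraction 30% of the step;
    flight distance matches the airborne speed integral within 1%."""
    from gaitkine.segmentation import segment_trial

    stream, insole, contact, truth = run_trial
    anat, segs = segment_trial(stream)
    tab = compute_step_metrics(anat, segs, contact=contact)
    frac = (tab.flight_time / tab.step_duration).to_numpy()
    assert np.allclose(frac, 0.30, atol=0.03)
    expected = tab.speed_mean * tab.flight_time
    np.testing.assert_allclose(tab.flight_distance, expected, rtol=0.01)


def test_mech_energy_examples():
    t = _grid(2)
    seg = _seg(0.5, 1.5)
    V = np.full_like(t, 3.0)
    zero = np.zeros_like(t)
    assert mech_energy(V, zero, zero, t, seg, mass=70.0) == pytest.approx(315.0)
    assert mech_energy(zero, zero, zero, t, seg, mass=70.0) == 0.0
    with pytest.raises(ValueError):
        mech_energy(V, zero, zero, t, seg, mass=0.0)


def test_energy_exchange_reduces_variance():
    """With KE and PE oscillating in antiphase the total-energy variance is
    below the KE-only variance (pendulum-like exchange)."""
    t = _grid(10)
    m, g = 70.0, 9.81
    h = 0.02 * np.sin(2 * np.pi * 2 * t)
    V = np.sqrt(np.maximum(2.0 ** 2 - 2 * g * h, 0.0))  # energy-conserving speed
    seg = _seg(1.0, 9.0)
    total = 0.5 * m * V ** 2 + m * g * h
    ke = 0.5 * m * V ** 2
    assert np.var(total) < np.var(ke)


def test_windowed_speed_constant_and_two_phase():
    t = _grid(30)
    out = windowed_speed(np.full_like(t, 4.0), t, np.array([0.0, 5.0]),
                         distances=(20.0,))
    np.testing.assert_allclose(out["speed_20m"], 4.0, rtol=1e-6)
    # 10 s at 2 m/s then 10 s at 4 m/s: over the full 60 m, 60/20 = 3 m/s
    v = np.where(t < 10, 2.0, 4.0)
    out = windowed_speed(v, t[:len(v)], np.array([0.0]), distances=(59.9,))
    assert out["speed_59.9m"].iloc[0] == pytest.approx(3.0, abs=0.02)
    # trial shorter than the target distance -> absent
    out = windowed_speed(v, t, np.array([0.0]), distances=(1000.0,))
    assert np.isnan(out["speed_1000m"].iloc[0])


def test_metrics_invariant_under_time_shift(walk_trial):
    """Translating the whole trial in time changes no metric."""
    from dataclasses import replace

    from gaitkine.segmentation import segment_trial

    stream, _, _, _ = walk_trial
    anat, segs = segment_trial(stream)
    tab = compute_step_metrics(anat, segs)

    shifted_stream = replace(stream, t=stream.t + 1000.0)
    anat2, segs2 = segment_trial(shifted_stream)
    tab2 = compute_step_metrics(anat2, segs2)
    assert len(tab) == len(tab2)
    for col in ("step_duration", "step_length", "speed_mean", "speed_p2p",
                "vertical_disp_p2p"):
        np.testing.assert_allclose(tab2[col], tab[col], atol=1e-6)
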