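"""The generator's own contracts: determinism, cadence, impulse balance,
error-model behaviour, and consistency between streams and ground truth."""

import numpy as np
import pytest

from gaitkine.synthetic_gait import (GaitScenario, SensorErrorModel,
                                     generate, inject_sensor_errors)


def test_same_seed_bit_identical():
    a = generate(GaitScenario.walk(duration=10.0, seed=3,
                                   error_model=SensorErrorModel()))
    b = generate(GaitScenario.walk(duration=10.0, seed=3,
                                   error_model=SensorErrorModel()))
    np.testing.assert_array_equal(a[0].v_down, b[0].v_down)
    np.testing.assert_array_equal(a[0].a_vertical, b[0].a_vertical)
    np.testing.assert_array_equal(a[1].force_left, b[1].force_left)
    c = generate(GaitScenario.walk(duration=10.0, seed=4,
                                   error_model=SensorErrorModel()))
    assert not np.array_equal(a[0].v_down, c[0].v_down)


def test_walk_apex_count_matches_cadence(walk_trial):
    """60 steps/30 s at cadence 120 (+/- 1 edge step)."""
    _, _, _, truth = walk_trial
    assert abs(len(truth.steps) - 60) <= 2


def test_scenario_validation():
    with pytest.raises(ValueError):
        GaitScenario.run(duty_factor=60.0)
    with pytest.raises(ValueError):
        GaitScenario(mode="crawl")
    with pytest.raises(ValueError):
        GaitScenario(duty_factor=0.0)


@pytest.mark.parametrize("trial", ["walk_trial", "run_trial"])
def test_per_stance_impulse_equals_bodyweight_times_step(trial, request):
    """Steady-gait force balance: the time integral of each stance's GRF
    equals body weight x step duration within 5% (independent quadrature
    on the emitted 400 Hz force series)."""
    stream, _, _, truth = request.getfixturevalue(trial)
    bw = 70.0 * 9.81
    checked = 0
    for _, row in truth.stances.iterrows():
        if row.touchdown < 1 or row.toeoff > truth.t[-1] - 1:
            continue
        grf = truth.grf_left if row.foot == "left" else truth.grf_right
        m = (truth.t >= row.touchdown) & (truth.t <= row.toeoff)
        impulse = np.trapezoid(grf[m], truth.t[m])
        step = truth.steps[truth.steps.step == row.step]
        if step.empty:
            continue
        expected = bw * step.duration.iloc[0]
        assert abs(impulse - expected) / expected < 0.05
        checked += 1
    assert checked > 20


def test_walk_grf_two_peaks_run_single_peak(walk_trial, run_trial):
    def peaks_in_stance(truth, i):
        row = truth.stances[truth.stances.foot == "left"].iloc[i]
        grf = truth.grf_left
        m = (truth.t > row.touchdown) & (truth.t < row.toeoff)
        f = grf[m]
        local_max = (f[1:-1] > f[:-2]) & (f[1:-1] > f[2:])
        return local_max.sum(), f.max()

    _, _, _, wt = walk_trial
    n_peaks, peak = peaks_in_stance(wt, 3)
    assert n_peaks == 2
    assert 0.9 * 70 * 9.81 < peak < 1.3 * 70 * 9.81   # ~1.1 BW walking
    _, _, _, rt = run_trial
    n_peaks, peak = peaks_in_stance(rt, 3)
    assert n_peaks == 1
    assert 1.8 * 70 * 9.81 < peak < 2.9 * 70 * 9.81   # ~2.2-2.8 BW running


def test_zero_error_model_changes_nothing(walk_trial):
    stream, insole, _, _ = walk_trial
    em = SensorErrorModel(accel_bias_mg=0.0, noise_density_mg=0.0,
                          nonlinearity_frac=0.0, vel_wander_amps=(0.0,),
                          vel_broadband_sd=0.0, angle_noise_deg=(0.0, 0.0),
                          gyro_noise_sd=0.0, force_noise_sd=0.0)
    out, out_ins = inject_sensor_errors(stream, insole, em, rng=0)
    np.testing.assert_allclose(out.v_down, stream.v_down, atol=1e-12)
    np.testing.assert_allclose(out.a_vertical, stream.a_vertical, atol=1e-12)
    np.testing.assert_allclose(out_ins.force_left, insole.force_left, atol=1e-12)


def test_bias_only_model_offsets_acceleration(walk_trial):
    """A bias-only error model shifts each acceleration axis by exactly the
    bias magnitude and leaves the (GPS-corrected) velocity untouched."""
    stream, insole, _, _ = walk_trial
    em = SensorErrorModel(accel_bias_mg=0.04, noise_density_mg=0.0,
                          nonlinearity_frac=0.0, vel_wander_amps=(0.0,),
                          vel_broadband_sd=0.0, angle_noise_deg=(0.0, 0.0),
                          gyro_noise_sd=0.0, force_noise_sd=0.0)
    out, _ = inject_sensor_errors(stream, insole, em, rng=0)
    shift = out.a_vertical - stream.a_vertical
    assert np.allclose(np.abs(shift), 0.04e-3 * 9.81, atol=1e-12)
    np.testing.assert_allclose(out.v_down, stream.v_down, atol=1e-12)


def test_velocity_error_is_bounded(noisy_walk_trial):
    clean = generate(GaitScenario.walk(duration=60.0, seed=7))[0]
    noisy = noisy_walk_trial[0]
    for f in ("v_north", "v_east", "v_down"):
        err = getattr(noisy, f) - getattr(clean, f)
        assert np.max(np.abs(err)) <= 0.05 + 1e-9
        assert abs(np.mean(err)) < 0.02


def test_contact_alternates_between_feet(run_trial):
    _, _, _, truth = run_trial
    feet = truth.stances.sort_values("touchdown").foot.to_numpy()
    assert all(a != b for a, b in zip(feet[:-1], feet[1:]))


def test_insole_native_rate_and_resampled_grid(walk_trial):
    _, insole, _, _ = walk_trial
    assert insole.native_rate in (50.0, 100.0)
    dt = np.diff(insole.t)
    np.testing.assert_allclose(dt, 1.0 / insole.native_rate, rtol=1e-9)


def test_mixed_mode_contains_both_gaits():
    sc = GaitScenario.mixed(duration=100.0, seed=5, block_duration=40.0)
    _, _, _, truth = generate(sc)
    assert {"walk", "run"} <= set(truth.steps["mode"])
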