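"""End-to-end study procedures on synthetic gait.

Each function generates data with the synthetic generator, runs the
relevant pipeline stages, and scores the result against the generator's
ground truth:

* :func:`segmentation_timing` — step-start and step-duration errors of the
  zero-crossing segmentation under the sensor error model;
* :func:`shift_robustness_walk` — the boundary-shift sensitivity study on
  a long walking trial;
* :func:`displacement_error` — per-step step-length and vertical-closure
  errors under the accelerometer/velocity error model;
* :func:`contact_grf_experiment` — train the recurrent contact and GRF
  models on one portion of a mixed trial and score GCT/GRF on a disjoint
  held-out portion.

Seeds are taken explicitly so every experiment is reproducible.
"""

from __future__ import annotations

import numpy as np

from . import contact_model as cm
from .io_streams import align_streams, binarize_contact
from .segmentation import regular, segment_trial
from .shift_robustness import ShiftReport, run_shift_experiment
from .step_metrics import compute_step_metrics
from .synthetic_gait import GaitScenario, SensorErrorModel, generate

G = 9.81


def _match_steps(detected, truth_steps) -> list[tuple[object, object]]:
    """Pair detected segments with truth steps by start-time proximity."""
    pairs = []
    ts = truth_steps.t_start.to_numpy()
    for seg in detected:
        i = int(np.argmin(np.abs(ts - seg.t_start)))
        if abs(ts[i] - seg.t_start) < 0.5 * truth_steps.duration.iloc[i]:
            pairs.append((seg, truth_steps.iloc[i]))
    return pairs


def segmentation_timing(seed: int, n_steps: int = 500) -> dict:
    """Max absolute step-start and step-duration error (ms) vs ground truth.

    Walk (cadence 120) and run (cadence 172) scenarios with the spec-level
    sensor error model; the reported numbers are maxima over both modes
    and all regular steps.
    """
    start_errs, dur_errs, counted = [], [], 0
    for mode_seed, factory in ((0, GaitScenario.walk), (1, GaitScenario.run)):
        base = factory(seed=seed + mode_seed, error_model=SensorErrorModel())
        sc = factory(seed=seed + mode_seed, error_model=SensorErrorModel(),
                     duration=(n_steps + 6) * 60.0 / base.cadence)
        stream, _, _, truth = generate(sc)
        _, segs = segment_trial(stream)
        regs = regular(segs)
        counted += len(regs)
        apex = truth.apex_times
        for seg, row in _match_steps(regs, truth.steps):
            start_errs.append(abs(seg.t_start - row.t_start))
            dur_errs.append(abs(seg.duration - row.duration))
    return {
        "max_start_error_ms": 1e3 * float(np.max(start_errs)),
        "max_duration_error_ms": 1e3 * float(np.max(dur_errs)),
        "max_timing_error_ms": 1e3 * float(max(np.max(start_errs), np.max(dur_errs))),
        "n_steps": counted,
    }


def shift_robustness_walk(seed: int, n_steps: int = 500,
                          mode: str = "walk") -> tuple[ShiftReport, dict]:
    """Boundary-shift study on a long trial; returns the report and the
    headline summary numbers:

    * speed/length mean relative change (%), max over ±5..±30% levels;
    * step-length mean absolute change (mm), max over levels;
    * vertical-oscillation mean relative change (%), max over levels;
    * peak-to-peak-speed mean absolute change (m/s), max over levels
      beyond ±10%.
    """
    factory = {"walk": GaitScenario.walk, "run": GaitScenario.run,
               "mixed": GaitScenario.mixed}[mode]
    base = factory(seed=seed)
    sc = factory(seed=seed, duration=(n_steps + 6) * 60.0 / base.cadence)
    stream, _, _, _ = generate(sc)
    anat, segs = segment_trial(stream)
    report = run_shift_experiment(anat, segs)
    nonzero = tuple(l for l in report.levels if l != 0)
    big = tuple(l for l in report.levels if abs(l) > 10)
    summary = {
        "speed_length_rel_pct": max(
            report.max_over_levels("speed_mean", "mean_rel_diff", nonzero),
            report.max_over_levels("step_length", "mean_rel_diff", nonzero)),
        "step_length_abs_mm": 1e3 * report.max_over_levels(
            "step_length", "mean_abs_diff", nonzero),
        "vertical_osc_rel_pct": report.max_over_levels(
            "vertical_disp_p2p", "mean_rel_diff", nonzero),
        "speed_p2p_abs_ms": report.max_over_levels(
            "speed_p2p", "mean_abs_diff", big),
        "n_steps": len(regular(segs)),
    }
    return report, summary


def displacement_error(seed: int, n_steps: int = 300) -> dict:
    """Per-step step-length and vertical-closure error bound (cm) on
    level-ground walk and run trials under the sensor error model."""
    len_errs, closure_errs = [], []
    for mode_seed, factory in ((0, GaitScenario.walk), (1, GaitScenario.run)):
        base = factory(seed=seed + mode_seed)
        sc = factory(seed=seed + mode_seed, error_model=SensorErrorModel(),
                     duration=(n_steps + 6) * 60.0 / base.cadence)
        stream, _, _, truth = generate(sc)
        anat, segs = segment_trial(stream)
        regs = regular(segs)
        tab = compute_step_metrics(anat, segs)
        for (seg, row), (_, mrow) in zip(_match_steps(regs, truth.steps),
                                         tab.iterrows()):
            len_errs.append(abs(mrow.step_length - row.length))
            closure_errs.append(abs(mrow.vertical_closure))
    return {
        "max_step_length_error_cm": 1e2 * float(np.max(len_errs)),
        "max_closure_cm": 1e2 * float(np.max(closure_errs)),
        "max_error_cm": 1e2 * float(max(np.max(len_errs), np.max(closure_errs))),
        "n_steps": len(len_errs),
    }


def contact_grf_experiment(seed: int, duration: float = 600.0,
                           holdout_fraction: float = 0.25,
                           contact_spec: cm.ModelSpec | None = None,
                           grf_spec: cm.ModelSpec | None = None,
                           verbose: bool = False) -> dict:
    """Train contact + GRF models on mixed gait and score a held-out tail.

    The trial is mixed walking/running with the sensor error model active.
    Targets come from the insole stream via the standard pipeline
    (resampling to 400 Hz, 20 N contact threshold); GRF is trained in
    body-weight units.  The last ``holdout_fraction`` of the trial is
    never windowed for training; GCT nRMSE (per-stance, normalized by the
    reference GCT range) and per-sample GRF nRMSE (normalized by the
    reference force range) are computed there, per foot, worse foot
    reported.
    """
    sc = GaitScenario.mixed(duration=duration, seed=seed,
                            error_model=SensorErrorModel())
    stream, insole, _, truth = generate(sc)
    stream, insole_400 = align_streams(stream, insole)
    contact_ref = binarize_contact(insole_400)
    features = np.column_stack([stream.a_north, stream.a_east,
                                stream.a_vertical, stream.omega])
    bw = sc.mass * G
    y_contact = np.column_stack([contact_ref.contact_left,
                                 contact_ref.contact_right]).astype(np.float32)
    y_grf = np.column_stack([insole_400.force_left,
                             insole_400.force_right]).astype(np.float32) / bw

    n = len(features)
    n_train = int(n * (1 - holdout_fraction))
    contact_spec = contact_spec or cm.ModelSpec(head="sigmoid", seed=seed)
    grf_spec = grf_spec or cm.ModelSpec(head="relu", seed=seed)

    results = {"n_samples": n, "n_train": n_train}
    scale = None
    for name, spec_, y in (("gct", contact_spec, y_contact),
                           ("grf", grf_spec, y_grf)):
        batch = cm.make_sequences(features[:n_train], y[:n_train], scale=scale)
        scale = batch.scale  # share input scaling between the two models
        model = cm.train(batch, spec_, verbose=verbose)
        pred = model.predict_series(features[n_train:])
        valid = ~np.isnan(pred[:, 0])
        per_foot = []
        for foot in (0, 1):
            ref = y[n_train:, foot]
            if name == "gct":
                binary = np.where(valid, pred[:, foot] > 0.5, 0.0)
                p_gct, r_gct = cm.match_stances(
                    cm.contact_runs(binary[valid]),
                    cm.contact_runs(ref[valid]))
                rng_ref = float(np.ptp(r_gct))
                score = 100.0 * float(np.sqrt(np.mean((p_gct - r_gct) ** 2))) / rng_ref
                per_foot.append(score)
            else:
                per_foot.append(cm.nrmse(pred[valid, foot], ref[valid]))
        results[f"{name}_nrmse_pct"] = float(np.max(per_foot))
        results[f"{name}_nrmse_per_foot"] = [float(v) for v in per_foot]
        results[f"{name}_epochs"] = len(model.history)
        results[f"{name}_model"] = model
    return results
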