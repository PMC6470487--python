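"""Sequence windowing, the numpy recurrent network, and the scoring helpers."""

import numpy as np
import pytest

from gaitkine.contact_model import (WARMUP, WINDOW, ModelSpec,
                                    RecurrentModel, contact_runs,
                                    gct_from_contact, make_sequences,
                                    match_stances, nrmse, predict_contact_grf,
                                    stitch, train)
from gaitkine.io_streams import DataError


# ---------------------------------------------------------------------------
# Windowing and stitching
# ---------------------------------------------------------------------------

def test_window_arithmetic(rng):
    x = rng.normal(size=(2401, 6))
    batch = make_sequences(x)
    assert batch.x.shape == (3, WINDOW, 6)
    np.testing.assert_array_equal(batch.starts, [0, 600, 1200])

    one = make_sequences(x[:WINDOW])
    assert len(one) == 1
    out = stitch(np.ones((1, WINDOW, 2)), one.starts, WINDOW)
    assert np.isnan(out[:WARMUP]).all()
    assert np.isfinite(out[WARMUP:]).all()


def test_trial_shorter_than_window_rejected(rng):
    with pytest.raises(DataError):
        make_sequences(rng.normal(size=(1200, 6)))


def test_second_half_tiling_is_exact(rng):
    """Every post-warm-up sample is covered by exactly one window's second
    half: stitching a per-sample function of the input reproduces it."""
    n = 5000
    x = rng.normal(size=(n, 3))
    batch = make_sequences(x)
    fn = lambda w: w[..., :2] * 2.0  # memoryless per-sample map
    preds = np.stack([fn(xi) for xi in batch.x])
    out = stitch(preds, batch.starts, n)
    covered = ~np.isnan(out[:, 0])
    last = batch.starts[-1] + WINDOW
    assert covered[WARMUP:last].all() and not covered[:WARMUP].any()
    np.testing.assert_allclose(out[covered], (x / batch.scale[:3])[covered, :2] * 2.0,
                               rtol=1e-5)


def test_stitching_independent_of_window_offset(rng):
    """A forgetting network gives the same stitched predictions whichever
    valid window offset is used (beyond the warm-up region)."""
    spec = ModelSpec(layers=(("gru", 8),), dropout=0.0, seed=5)
    model = RecurrentModel(spec, 4, scale=np.ones(4, np.float32))
    # bias the update and reset gates hard off: h_t = tanh(Wx_n x_t + b_n),
    # a memoryless map, so warm-up history cannot matter
    for cell in model.cells:
        cell.b[:16] = -30.0
    x = rng.normal(size=(6000, 4)).astype(np.float32)

    outs = []
    for off in (0, 600):
        batch = make_sequences(x, scale=model.scale, offset=off)
        u = model.forward(batch.x)
        outs.append(stitch(model._activate(u), batch.starts, len(x)))
    a, b = outs
    both = ~np.isnan(a[:, 0]) & ~np.isnan(b[:, 0])
    assert both.sum() > 4000
    np.testing.assert_allclose(a[both], b[both], atol=1e-4)


# ---------------------------------------------------------------------------
# Training mechanics
# ---------------------------------------------------------------------------

def test_masked_loss_gradient_is_zero_on_first_half(rng):
    spec = ModelSpec(layers=(("gru", 4),), dropout=0.0)
    model = RecurrentModel(spec, 3, np.ones(3, np.float32))
    x = rng.normal(size=(2, WINDOW, 3)).astype(np.float32)
    y = (rng.random((2, WINDOW, 2)) > 0.5).astype(np.float32)
    mask = np.zeros(WINDOW, np.float32)
    mask[WARMUP:] = 1.0
    u = model.forward(x)
    _, dU = model.loss_and_dU(u, y, mask)
    assert np.all(dU[:, :WARMUP] == 0.0)
    assert np.any(dU[:, WARMUP:] != 0.0)


def test_relu_head_output_nonnegative(rng):
    spec = ModelSpec(layers=(("lstm", 6),), head="relu", dropout=0.0, seed=2)
    model = RecurrentModel(spec, 4, np.ones(4, np.float32))
    out = model.predict_series(rng.normal(size=(2000, 4)).astype(np.float32))
    valid = ~np.isnan(out)
    assert (out[valid] >= 0.0).all()


def test_toy_training_converges_and_is_deterministic(rng):
    """A constant-target problem is learned to small loss within a few
    epochs, and a seed-fixed re-run reproduces the loss curve exactly."""
    x = rng.normal(size=(WINDOW * 4, 3)).astype(np.float32)
    y = np.ones((WINDOW * 4, 2), np.float32)
    spec = ModelSpec(layers=(("gru", 6),), dropout=0.0, epochs=15,
                     lr=2e-2, batch_size=2, val_fraction=0.34, seed=9)
    batch = make_sequences(x, y)
    m1 = train(batch, spec)
    m2 = train(batch, spec)
    assert m1.history[-1]["train_loss"] < 1e-2
    assert [h["train_loss"] for h in m1.history] == \
           [h["train_loss"] for h in m2.history]


def test_training_requires_targets(rng):
    batch = make_sequences(rng.normal(size=(WINDOW * 4, 3)))
    with pytest.raises(ValueError):
        train(batch, ModelSpec())


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(layers=())
    with pytest.raises(ValueError):
        ModelSpec(layers=(("elman", 8),))
    with pytest.raises(ValueError):
        ModelSpec(head="tanh")


def test_save_load_round_trip(tmp_path, rng):
    spec = ModelSpec(layers=(("gru", 5), ("lstm", 4)), head="relu", seed=1)
    model = RecurrentModel(spec, 6, scale=np.arange(1, 7, dtype=np.float32))
    x = rng.normal(size=(WINDOW + 100, 6)).astype(np.float32)
    ref = model.predict_series(x)
    path = tmp_path / "model.npz"
    model.save(path)
    back = RecurrentModel.load(path)
    out = back.predict_series(x)
    both = ~np.isnan(ref)
    np.testing.assert_array_equal(out[both], ref[both])
    assert back.spec == spec


# ---------------------------------------------------------------------------
# Post-processing and scoring
# ---------------------------------------------------------------------------

def test_probability_thresholding():
    prob = np.tile([0.4, 0.6], 500)[:, None].repeat(2, axis=1)
    binary = (prob > 0.5).astype(float)
    assert binary[::2].sum() == 0 and binary[1::2].all()


def test_gct_examples():
    c = np.zeros(1000)
    c[100:200] = 1  # 100 samples at 400 Hz
    assert gct_from_contact(c) == pytest.approx([0.25])
    assert len(gct_from_contact(np.zeros(500))) == 0
    # runs shorter than 40 ms are discarded as spurious
    c2 = np.zeros(1000)
    c2[10:20] = 1
    assert len(gct_from_contact(c2)) == 0


def test_gct_recovered_exactly_on_noise_free_contact(walk_trial):
    _, _, contact, truth = walk_trial
    runs = contact_runs(contact.contact_left)
    st = truth.stances[truth.stances.foot == "left"]
    ref_runs = [(row.touchdown * 400, row.toeoff * 400) for _, row in st.iterrows()]
    p, r = match_stances(runs, ref_runs)
    assert len(r) == len(ref_runs)
    np.testing.assert_allclose(p, r, atol=1.5 / 400)


def test_match_stances_pairs_by_midpoint():
    ref = [(0, 100), (400, 520)]
    pred = [(5, 95), (395, 530), (900, 1000)]
    p, r = match_stances(pred, ref)
    np.testing.assert_allclose(r, [0.25, 0.30])
    np.testing.assert_allclose(p, [90 / 400, 135 / 400])


def test_nrmse_examples(rng):
    ref = rng.normal(size=500)
    assert nrmse(ref, ref) == 0.0
    ref_scaled = 1000.0 * (ref - ref.min()) / np.ptp(ref)  # range 1000 N
    assert nrmse(ref_scaled + 50.0, ref_scaled) == pytest.approx(5.0)
    pred = rng.normal(size=500)
    brute = 100 * np.sqrt(np.mean((pred - ref) ** 2)) / (ref.max() - ref.min())
    assert nrmse(pred, ref) == pytest.approx(brute)
    with pytest.raises(ValueError):
        nrmse(np.ones(5), np.ones(5))


def test_predict_contact_grf_head_checks(rng):
    spec = ModelSpec(layers=(("gru", 4),), head="relu", seed=0)
    grf_model = RecurrentModel(spec, 2, np.ones(2, np.float32))
    with pytest.raises(ValueError):
        predict_contact_grf(grf_model, None, rng.normal(size=(WINDOW, 2)),
                            np.arange(WINDOW) / 400.0)
    pred = predict_contact_grf(None, grf_model,
                               rng.normal(size=(WINDOW, 2)).astype(np.float32),
                               np.arange(WINDOW) / 400.0)
    assert pred.grf is not None and pred.probability is None
    assert pred.valid.sum() == WINDOW - WARMUP
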