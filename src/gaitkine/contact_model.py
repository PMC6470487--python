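"""Indirect ground-contact and vertical-GRF estimation from inertial data.

Ground contact time and ground reaction force normally require in-shoe
pressure hardware; here they are regressed from the six inertial channels
(3-axis acceleration, 3-axis angular velocity) of a single body-mounted
sensor with a small recurrent network.  Insole recordings supply the
training targets only — at prediction time no foot pressure is used.

Sequence protocol
-----------------
Trials are cut into windows of 1201 samples (3 s at 400 Hz) overlapping by
50% (hop 600).  Inputs are scaled per channel to roughly [-1, 1].  The
loss ignores the first half of every window so the network sees context
before its predictions are scored, and only the second half of each
window's predictions is used when stitching windows back into a
full-length series — every post-warm-up sample is covered exactly once.

The network is a compact recurrent model implemented directly in numpy
(stacked GRU and/or LSTM cells with inter-layer dropout, a dense head,
masked binary cross-entropy or masked squared error, Adam, backprop
through time).  Two heads are used: sigmoid for per-foot contact
probability, ReLU for per-foot vertical GRF (which keeps the force
estimate non-negative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_streams import DataError

WINDOW = 1201   #: samples per sequence (3 s + 1 sample at 400 Hz)
HOP = 600       #: 50% overlap
WARMUP = WINDOW - HOP  #: leading samples per window ignored by the loss
RATE = 400.0
MIN_STANCE_S = 0.040  #: predicted 1-runs shorter than this are spurious


# ---------------------------------------------------------------------------
# Sequence windowing
# ---------------------------------------------------------------------------

@dataclass
class SequenceBatch:
    """Overlapping windows of scaled features (+ optional targets)."""

    x: np.ndarray                 # (n_win, WINDOW, n_features) float32
    starts: np.ndarray            # (n_win,) window start sample indices
    scale: np.ndarray             # (n_features,) per-channel max-abs
    n_samples: int                # length of the source trial
    y: np.ndarray | None = None   # (n_win, WINDOW, n_out) float32
    mask: np.ndarray = field(default_factory=lambda: np.zeros(WINDOW, np.float32))

    def __post_init__(self) -> None:
        if self.mask.sum() == 0:
            m = np.zeros(WINDOW, np.float32)
            m[WARMUP:] = 1.0
            self.mask = m

    def __len__(self) -> int:
        return len(self.starts)


def make_sequences(features: np.ndarray, targets: np.ndarray | None = None,
                   scale: np.ndarray | None = None,
                   offset: int = 0) -> SequenceBatch:
    """Cut a trial into 1201-sample windows with 50% overlap.

    ``scale`` (per-channel max-abs) is computed from the data when not
    given; pass a trained model's scale at prediction time.  ``offset``
    shifts the first window start (used by the stitching-equivalence
    tests).  Raises DataError for trials shorter than one window.
    """
    features = np.asarray(features, np.float32)
    n = len(features)
    if n - offset < WINDOW:
        raise DataError(f"trial of {n} samples is shorter than one window ({WINDOW})")
    starts = np.arange(offset, n - WINDOW + 1, HOP)
    if scale is None:
        # robust max-abs: spiky channels (impact transients) would otherwise
        # shrink the bulk of the signal far inside [-1, 1]
        scale = np.maximum(np.percentile(np.abs(features), 99.5, axis=0),
                           1e-9).astype(np.float32)
    x = np.stack([features[s:s + WINDOW] for s in starts]) / scale
    y = None
    if targets is not None:
        targets = np.asarray(targets, np.float32)
        if len(targets) != n:
            raise DataError("features and targets must share the sample grid")
        y = np.stack([targets[s:s + WINDOW] for s in starts])
    return SequenceBatch(x=x.astype(np.float32), starts=starts,
                         scale=np.asarray(scale, np.float32), n_samples=n, y=y)


def stitch(preds: np.ndarray, starts: np.ndarray, n_samples: int) -> np.ndarray:
    """Reassemble windowed predictions into a full-length series.

    Each output sample after the warm-up region is taken from the second
    half of exactly one window; samples never covered (the first WARMUP
    samples and any tail beyond the last window) are NaN.
    """
    n_out = preds.shape[2]
    out = np.full((n_samples, n_out), np.nan, np.float32)
    for w, s in enumerate(starts):
        out[s + WARMUP:s + WINDOW] = preds[w, WARMUP:]
    return out


# ---------------------------------------------------------------------------
# Recurrent cells (numpy, forward + backward)
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, (n_in, n_out)).astype(np.float32)


class _GRUCell:
    """Gated recurrent unit; update/reset gates, reset applied inside tanh."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        H = n_hidden
        self.H = H
        self.Wx = _glorot(rng, n_in, 3 * H)       # [z | r | n] blocks
        self.Wh = _glorot(rng, H, 3 * H)
        self.b = np.zeros(3 * H, np.float32)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, h, cache=None):
        H = self.H
        gx = x @ self.Wx + self.b
        gh = h @ self.Wh
        z = _sigmoid(gx[:, :H] + gh[:, :H])
        r = _sigmoid(gx[:, H:2 * H] + gh[:, H:2 * H])
        hn = gh[:, 2 * H:]
        c = np.tanh(gx[:, 2 * H:] + r * hn)
        h_new = (1 - z) * c + z * h
        if cache is not None:
            cache.append((x, h, z, r, c, hn))
        return h_new

    def init_grads(self):
        return [np.zeros_like(p) for p in self.params()]

    def backward(self, d_hnew, cache_t, grads):
        """One BPTT step: returns (dx, dh_prev); accumulates into grads."""
        x, h, z, r, c, hn = cache_t
        H = self.H
        dz = d_hnew * (h - c)
        dc = d_hnew * (1 - z)
        dh = d_hnew * z
        dc_pre = dc * (1 - c * c)
        dr = dc_pre * hn
        dhn = dc_pre * r
        dz_pre = dz * z * (1 - z)
        dr_pre = dr * r * (1 - r)
        dgx = np.concatenate([dz_pre, dr_pre, dc_pre], axis=1)
        dgh = np.concatenate([dz_pre, dr_pre, dhn], axis=1)
        dWx, dWh, db = grads
        dWx += x.T @ dgx
        dWh += h.T @ dgh
        db += dgx.sum(axis=0)
        dx = dgx @ self.Wx.T
        dh += dgh @ self.Wh.T
        return dx, dh


class _LSTMCell:
    """Long short-term memory cell with forget-gate bias 1."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        H = n_hidden
        self.H = H
        self.Wx = _glorot(rng, n_in, 4 * H)       # [i | f | g | o]
        self.Wh = _glorot(rng, H, 4 * H)
        self.b = np.zeros(4 * H, np.float32)
        self.b[H:2 * H] = 1.0

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, state, cache=None):
        h, cs = state
        H = self.H
        g = x @ self.Wx + h @ self.Wh + self.b
        i = _sigmoid(g[:, :H])
        f = _sigmoid(g[:, H:2 * H])
        gg = np.tanh(g[:, 2 * H:3 * H])
        o = _sigmoid(g[:, 3 * H:])
        cs_new = f * cs + i * gg
        tc = np.tanh(cs_new)
        h_new = o * tc
        if cache is not None:
            cache.append((x, h, cs, i, f, gg, o, tc))
        return h_new, cs_new

    def init_grads(self):
        return [np.zeros_like(p) for p in self.params()]

    def backward(self, d_h, d_cs, cache_t, grads):
        x, h, cs, i, f, gg, o, tc = cache_t
        do = d_h * tc
        dcs = d_cs + d_h * o * (1 - tc * tc)
        di = dcs * gg
        df = dcs * cs
        dgg = dcs * i
        dcs_prev = dcs * f
        dg = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                             dgg * (1 - gg * gg), do * o * (1 - o)], axis=1)
        dWx, dWh, db = grads
        dWx += x.T @ dg
        dWh += h.T @ dg
        db += dg.sum(axis=0)
        dx = dg @ self.Wx.T
        dh_prev = dg @ self.Wh.T
        return dx, dh_prev, dcs_prev


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Architecture and optimizer settings for the sequence model.

    ``layers`` is a tuple of (cell type, width) pairs, cell type "gru" or
    "lstm"; at least one recurrent layer is required.  ``head`` selects the
    output nonlinearity: "sigmoid" (contact probability, trained with
    masked binary cross-entropy) or "relu" (non-negative GRF, masked MSE).
    """

    layers: tuple = (("gru", 32),)
    dropout: float = 0.15
    head: str = "sigmoid"
    n_outputs: int = 2
    lr: float = 5e-3
    epochs: int = 40
    batch_size: int = 16
    grad_clip: float = 5.0
    val_fraction: float = 0.15
    patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("at least one recurrent layer is required")
        for kind, width in self.layers:
            if kind not in ("gru", "lstm") or width < 1:
                raise ValueError(f"bad layer ({kind}, {width})")
        if self.head not in ("sigmoid", "relu"):
            raise ValueError("head must be 'sigmoid' or 'relu'")


@dataclass
class ContactPrediction:
    """Stitched per-sample model output for one trial."""

    t: np.ndarray
    probability: np.ndarray | None   # (n, 2) in [0, 1]; None for GRF models
    contact: np.ndarray | None       # (n, 2) binary after thresholding
    grf: np.ndarray | None           # (n, 2) >= 0, same units as training targets
    valid: np.ndarray = None         # bool mask of covered samples

    def __post_init__(self):
        ref = self.probability if self.probability is not None else self.grf
        if self.valid is None:
            self.valid = ~np.isnan(ref[:, 0])


class RecurrentModel:
    """A trained stack of recurrent cells with a dense head."""

    def __init__(self, spec: ModelSpec, n_features: int, scale: np.ndarray):
        self.spec = spec
        self.n_features = n_features
        self.scale = np.asarray(scale, np.float32)
        rng = np.random.default_rng(spec.seed)
        self.cells = []
        n_in = n_features
        for kind, width in spec.layers:
            cell = _GRUCell(n_in, width, rng) if kind == "gru" else _LSTMCell(n_in, width, rng)
            cell.kind = kind
            self.cells.append(cell)
            n_in = width
        self.Wo = _glorot(rng, n_in, spec.n_outputs)
        self.bo = np.zeros(spec.n_outputs, np.float32)
        self.history: list[dict] = []

    # -- parameter plumbing ----------------------------------------------
    def parameters(self):
        ps = []
        for c in self.cells:
            ps.extend(c.params())
        ps.extend([self.Wo, self.bo])
        return ps

    # -- forward ----------------------------------------------------------
    def forward(self, x, train_rng=None, caches=None):
        """Run the stack over a batch of windows.

        x: (B, T, F) scaled inputs.  Returns pre-activation outputs
        (B, T, n_out).  With ``train_rng`` inter-layer inverted dropout is
        active and, if ``caches`` is a list, per-layer BPTT caches and
        dropout masks are appended to it.
        """
        B, T, _ = x.shape
        inp = x
        drop_masks = []
        for li, cell in enumerate(self.cells):
            H = cell.H
            h = np.zeros((B, H), np.float32)
            cs = np.zeros((B, H), np.float32)
            cache = [] if caches is not None else None
            outs = np.empty((B, T, H), np.float32)
            for t in range(T):
                if cell.kind == "gru":
                    h = cell.forward(inp[:, t], h, cache)
                else:
                    h, cs = cell.forward(inp[:, t], (h, cs), cache)
                outs[:, t] = h
            if train_rng is not None and self.spec.dropout > 0 and li < len(self.cells):
                keep = 1.0 - self.spec.dropout
                m = (train_rng.random(outs.shape) < keep).astype(np.float32) / keep
                outs = outs * m
                drop_masks.append(m)
            else:
                drop_masks.append(None)
            if caches is not None:
                caches.append(cache)
            inp = outs
        if caches is not None:
            caches.append(drop_masks)
            caches.append(inp)
        return inp @ self.Wo + self.bo

    def _activate(self, u):
        return _sigmoid(u) if self.spec.head == "sigmoid" else np.maximum(u, 0.0)

    # -- loss and gradients -----------------------------------------------
    def loss_and_dU(self, u, y, mask):
        """Masked loss and its gradient w.r.t. the head pre-activations.

        Sigmoid head: mean binary cross-entropy over unmasked samples.
        ReLU head: mean squared error over unmasked samples.  The mask
        zeroes the first half of every window, so gradients w.r.t. those
        predictions are exactly zero.
        """
        m = mask[None, :, None]
        denom = float(np.sum(np.broadcast_to(m, u.shape)))
        if self.spec.head == "sigmoid":
            p = _sigmoid(u)
            eps = 1e-7
            loss = -np.sum(m * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))) / denom
            dU = m * (p - y) / denom
        else:
            yh = np.maximum(u, 0.0)
            loss = np.sum(m * (yh - y) ** 2) / denom
            dU = m * 2.0 * (yh - y) * (u > 0) / denom
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss ({loss})")
        return float(loss), dU.astype(np.float32)

    def backward(self, x, dU, caches):
        """Backprop through the head and the recurrent stack."""
        drop_masks = caches[len(self.cells)]
        top = caches[len(self.cells) + 1]
        B, T, _ = x.shape
        grads = [c.init_grads() for c in self.cells]
        gWo = np.einsum("bth,bto->ho", top, dU).astype(np.float32)
        gbo = dU.sum(axis=(0, 1)).astype(np.float32)
        d_inp = dU @ self.Wo.T
        for li in range(len(self.cells) - 1, -1, -1):
            cell = self.cells[li]
            if drop_masks[li] is not None:
                d_inp = d_inp * drop_masks[li]
            cache = caches[li]
            d_below = np.zeros((B, T, cell.Wx.shape[0]), np.float32)
            dh = np.zeros((B, cell.H), np.float32)
            dcs = np.zeros((B, cell.H), np.float32)
            for t in range(T - 1, -1, -1):
                d_h_total = d_inp[:, t] + dh
                if cell.kind == "gru":
                    dx, dh = cell.backward(d_h_total, cache[t], grads[li])
                else:
                    dx, dh, dcs = cell.backward(d_h_total, dcs, cache[t], grads[li])
                d_below[:, t] = dx
            d_inp = d_below
        flat = []
        for g in grads:
            flat.extend(g)
        flat.extend([gWo, gbo])
        return flat

    # -- prediction ---------------------------------------------------------
    def predict_series(self, features: np.ndarray) -> np.ndarray:
        """Stitched activated output for a full trial (NaN outside coverage)."""
        batch = make_sequences(features, scale=self.scale)
        u = self.forward(batch.x)
        return stitch(self._activate(u), batch.starts, batch.n_samples)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        arrays["scale"] = self.scale
        meta = dict(spec=asdict(self.spec), n_features=self.n_features)
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "RecurrentModel":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        spec_d = meta["spec"]
        spec_d["layers"] = tuple(tuple(l) for l in spec_d["layers"])
        spec = ModelSpec(**spec_d)
        model = cls(spec, meta["n_features"], z["scale"])
        for i, p in enumerate(model.parameters()):
            p[...] = z[f"p{i}"]
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(batch: SequenceBatch, spec: ModelSpec,
          verbose: bool = False) -> RecurrentModel:
    """Train a recurrent model on a windowed batch with Adam.

    A contiguous tail of the windows (``spec.val_fraction``) is held out
    for early stopping, with one boundary window dropped so training and
    validation windows do not overlap in time.  Deterministic under a
    fixed ``spec.seed``.
    """
    if batch.y is None:
        raise ValueError("training requires targets in the batch")
    n_win = len(batch)
    n_val = max(1, int(round(spec.val_fraction * n_win)))
    n_train = n_win - n_val - 1  # drop one boundary window (50% overlap)
    if n_train < 1:
        raise ValueError("not enough windows to split off a validation set")
    x_tr, y_tr = batch.x[:n_train], batch.y[:n_train]
    x_va, y_va = batch.x[n_train + 1:], batch.y[n_train + 1:]

    model = RecurrentModel(spec, batch.x.shape[2], batch.scale)
    rng = np.random.default_rng(spec.seed + 1)
    params = model.parameters()
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best = (np.inf, None)
    bad_epochs = 0
    for epoch in range(spec.epochs):
        order = rng.permutation(n_train)
        tr_loss = 0.0
        for i0 in range(0, n_train, spec.batch_size):
            idx = order[i0:i0 + spec.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            caches = []
            u = model.forward(xb, train_rng=rng, caches=caches)
            loss, dU = model.loss_and_dU(u, yb, batch.mask)
            grads = model.backward(xb, dU, caches)
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            clip = min(1.0, spec.grad_clip / (gnorm + 1e-12))
            step += 1
            for p, g, m_, v_ in zip(params, grads, m_adam, v_adam):
                g = g * clip
                m_ *= beta1
                m_ += (1 - beta1) * g
                v_ *= beta2
                v_ += (1 - beta2) * g * g
                mhat = m_ / (1 - beta1 ** step)
                vhat = v_ / (1 - beta2 ** step)
                p -= spec.lr * mhat / (np.sqrt(vhat) + eps)
            tr_loss += loss * len(idx)
        tr_loss /= n_train
        u_va = model.forward(x_va)
        va_loss, _ = model.loss_and_dU(u_va, y_va, batch.mask)
        model.history.append(dict(epoch=epoch, train_loss=tr_loss, val_loss=va_loss))
        if verbose:
            print(f"epoch {epoch:3d}  train {tr_loss:.5f}  val {va_loss:.5f}")
        if va_loss < best[0] - 1e-6:
            best = (va_loss, [p.copy() for p in params])
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= spec.patience:
                break
    if best[1] is not None:
        for p, bp in zip(params, best[1]):
            p[...] = bp
    return model


# ---------------------------------------------------------------------------
# Post-processing and scoring
# ---------------------------------------------------------------------------

def predict_contact_grf(contact_model: RecurrentModel | None,
                        grf_model: RecurrentModel | None,
                        features: np.ndarray, t: np.ndarray,
                        threshold: float = 0.5) -> ContactPrediction:
    """Stitched per-sample contact probability/binary contact and GRF."""
    prob = contact = grf = None
    if contact_model is not None:
        if contact_model.spec.head != "sigmoid":
            raise ValueError("contact model must have a sigmoid head")
        prob = contact_model.predict_series(features)
        contact = np.where(np.isnan(prob), np.nan, (prob > threshold).astype(float))
    if grf_model is not None:
        if grf_model.spec.head != "relu":
            raise ValueError("GRF model must have a relu head")
        grf = grf_model.predict_series(features)
    return ContactPrediction(t=np.asarray(t), probability=prob,
                             contact=contact, grf=grf)


def contact_runs(binary: np.ndarray, rate: float = RATE,
                 min_stance: float = MIN_STANCE_S) -> list[tuple[int, int]]:
    """Half-open index runs of 1s, discarding runs shorter than min_stance."""
    c = np.nan_to_num(np.asarray(binary, float), nan=0.0).astype(int)
    d = np.diff(np.concatenate([[0], c, [0]]))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    min_len = int(round(min_stance * rate))
    return [(s, e) for s, e in zip(starts, ends) if e - s >= min_len]


def gct_from_contact(binary: np.ndarray, rate: float = RATE,
                     min_stance: float = MIN_STANCE_S) -> np.ndarray:
    """Per-stance ground contact times (s) from a binary contact series."""
    return np.array([(e - s) / rate for s, e in contact_runs(binary, rate, min_stance)])


def match_stances(pred_runs, ref_runs, rate: float = RATE
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Pair predicted with reference stances by midpoint proximity.

    Each reference stance is matched to the predicted stance whose midpoint
    is nearest, provided the midpoint falls within the reference interval
    extended by half its length; unmatched references are skipped.
    Returns paired (pred_gct, ref_gct) arrays in seconds.
    """
    if not pred_runs or not ref_runs:
        return np.empty(0), np.empty(0)
    pmids = np.array([(s + e) / 2 for s, e in pred_runs])
    out_p, out_r = [], []
    for s, e in ref_runs:
        mid = (s + e) / 2
        half = (e - s) / 2
        i = int(np.argmin(np.abs(pmids - mid)))
        if abs(pmids[i] - mid) <= 1.5 * half:
            ps, pe = pred_runs[i]
            out_p.append((pe - ps) / rate)
            out_r.append((e - s) / rate)
    return np.asarray(out_p), np.asarray(out_r)


def nrmse(pred: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square error as a percentage of the reference range."""
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise ValueError("series must be equal length and aligned")
    rng = float(np.max(ref) - np.min(ref))
    if rng == 0:
        raise ValueError("nRMSE is undefined for a constant reference")
    return 100.0 * float(np.sqrt(np.mean((pred - ref) ** 2))) / rng
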