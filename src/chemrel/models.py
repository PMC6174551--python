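"""Sentence encoders and the relation classifier.

Three encoders turn a relation instance (word ids + two position-id tracks)
into a fixed-width vector:

* ``cnn`` — 1-D convolution (100 filters of length 3 over the 400-dim token
  features) with tanh nonlinearity, followed by global max-pooling;
* ``gru`` — a gated recurrent unit run left-to-right, taking the hidden
  state at the last real token;
* ``att_gru`` — the same GRU with word-level attention pooling: a learned
  softmax over token scores weights the hidden states into the relation
  representation.

The GRU follows the convention in which the update gate z scales the
PREVIOUS hidden state:

    z_t = sigma(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigma(W_r x_t + U_r h_{t-1} + b_r)
    h~_t = tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)
    h_t = z_t * h_{t-1} + (1 - z_t) * h~_t

(some libraries implement the complement, z scaling the candidate; a
conformance test pins this form).  Attention pooling:

    u_t = tanh(W_w h_t + b_w)
    alpha_t = exp(u_t' u_w) / sum_t exp(u_t' u_w)
    s = sum_t alpha_t h_t

A dropout layer (rate 0.5) sits before the final softmax over the K = 6
labels (five evaluated CPR groups plus NA).  All gradients are derived by
hand and checked numerically in the test suite; training uses Adam on
sparse categorical cross-entropy.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import EncodedInstance, FEATURE_DIM, PAD_ID, POS_DIM, WORD_DIM
from .nn import Adam, glorot_uniform, orthogonal, sigmoid, softmax

logger = logging.getLogger(__name__)

N_LABELS = 6


# ---------------------------------------------------------------------------
# parameter containers + pure functional ops (the equation homes)
# ---------------------------------------------------------------------------


@dataclass
class GRUParams:
    """Weights of one GRU cell: input transforms W_*, hidden transforms U_*,
    biases b_* for the update gate (z), reset gate (r) and state candidate."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    U_z: np.ndarray
    U_r: np.ndarray
    U_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray

    @classmethod
    def init(cls, input_dim: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        return cls(
            W_z=glorot_uniform(rng, (input_dim, hidden), dtype),
            W_r=glorot_uniform(rng, (input_dim, hidden), dtype),
            W_h=glorot_uniform(rng, (input_dim, hidden), dtype),
            U_z=orthogonal(rng, hidden, dtype),
            U_r=orthogonal(rng, hidden, dtype),
            U_h=orthogonal(rng, hidden, dtype),
            b_z=np.zeros(hidden, dtype=dtype),
            b_r=np.zeros(hidden, dtype=dtype),
            b_h=np.zeros(hidden, dtype=dtype),
        )


@dataclass
class AttentionParams:
    """Word-level attention: hidden transform W_w, bias b_w and the trained
    word-importance vector u_w scored against each u_t."""

    W_w: np.ndarray
    b_w: np.ndarray
    u_w: np.ndarray

    @classmethod
    def init(cls, hidden: int, rng: np.random.Generator, dtype=np.float32):
        return cls(
            W_w=glorot_uniform(rng, (hidden, hidden), dtype),
            b_w=np.zeros(hidden, dtype=dtype),
            u_w=glorot_uniform(rng, (hidden, 1), dtype)[:, 0],
        )


@dataclass
class CNNParams:
    """Convolution filters, stored as (filter_length * input_dim, n_filters)."""

    W: np.ndarray
    b: np.ndarray
    filter_length: int

    @classmethod
    def init(cls, input_dim: int, n_filters: int, filter_length: int,
             rng: np.random.Generator, dtype=np.float32):
        return cls(
            W=glorot_uniform(rng, (filter_length * input_dim, n_filters), dtype),
            b=np.zeros(n_filters, dtype=dtype),
            filter_length=filter_length,
        )

    @property
    def n_filters(self) -> int:
        return self.W.shape[1]


@dataclass
class ClassifierParams:
    """Final fully connected softmax layer over the K = 6 labels."""

    W: np.ndarray  # (encoder width, K)
    b: np.ndarray  # (K,)

    @classmethod
    def init(cls, width: int, rng: np.random.Generator, dtype=np.float32):
        return cls(
            W=glorot_uniform(rng, (width, N_LABELS), dtype),
            b=np.zeros(N_LABELS, dtype=dtype),
        )


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, p: GRUParams) -> np.ndarray:
    """One GRU update.  Accepts a single vector or a batch (leading axis)."""
    if x_t.shape[-1] != p.W_z.shape[0] or h_prev.shape[-1] != p.U_z.shape[0]:
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, "
            f"W {p.W_z.shape}, U {p.U_z.shape}"
        )
    z = sigmoid(x_t @ p.W_z + h_prev @ p.U_z + p.b_z)
    r = sigmoid(x_t @ p.W_r + h_prev @ p.U_r + p.b_r)
    h_cand = np.tanh(x_t @ p.W_h + (r * h_prev) @ p.U_h + p.b_h)
    return z * h_prev + (1.0 - z) * h_cand


def gru_forward(xs: np.ndarray, p: GRUParams, true_length: int | None = None) -> np.ndarray:
    """Run the GRU over a (T, D) sequence from h_0 = 0; returns (T, H).

    Positions at or beyond ``true_length`` keep the last real hidden state,
    so padding content never influences the outputs.
    """
    T = xs.shape[0]
    H = p.U_z.shape[0]
    L = T if true_length is None else min(true_length, T)
    hs = np.zeros((T, H), dtype=np.result_type(xs, np.float32))
    h = np.zeros(H, dtype=hs.dtype)
    for t in range(L):
        h = gru_step(xs[t], h, p)
        hs[t] = h
    hs[L:] = h
    return hs


def attention_pool(
    hs: np.ndarray, a: AttentionParams, true_length: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Attention-weighted sum of hidden states.

    Returns (alphas, s) where alphas is a probability simplex over the
    first ``true_length`` positions (padded positions get weight 0) and
    s = sum_t alpha_t h_t.
    """
    hs = np.asarray(hs)
    T = hs.shape[0]
    L = T if true_length is None else min(true_length, T)
    if L < 1:
        raise ValueError("attention pooling needs at least one real token")
    u = np.tanh(hs[:L] @ a.W_w + a.b_w)
    scores = u @ a.u_w
    alphas = np.zeros(T, dtype=u.dtype)
    alphas[:L] = softmax(scores)
    s = alphas[:L] @ hs[:L]
    return alphas, s


def cnn_encode(xs: np.ndarray, c: CNNParams) -> np.ndarray:
    """Valid 1-D convolution + tanh + global max-pooling over positions.

    ``xs`` is (T, D); returns a vector of width ``n_filters``.
    """
    T, D = xs.shape
    fl = c.filter_length
    if T < fl:
        raise ValueError(f"sequence length {T} shorter than filter length {fl}")
    windows = np.stack([xs[p : p + fl].ravel() for p in range(T - fl + 1)])
    act = np.tanh(windows @ c.W + c.b)
    return act.max(axis=0)


def classify(h_star: np.ndarray, cp: ClassifierParams) -> np.ndarray:
    """Softmax label probabilities for an encoder output (vector or batch)."""
    return softmax(h_star @ cp.W + cp.b, axis=-1)


def predict_label(probs: np.ndarray) -> int:
    """Argmax label id; ties break toward the lowest index."""
    return int(np.argmax(probs))


# ---------------------------------------------------------------------------
# trainable models (batched forward/backward, hand-derived gradients)
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Training hyperparameters.  Defaults are the grid-search optima:
    batch 64, 100 filters of length 3, RNN dimension 128, learning rate
    0.001, dropout 0.5."""

    model: str = "att_gru"  # cnn | gru | att_gru
    batch_size: int = 64
    n_filters: int = 100
    filter_length: int = 3
    rnn_dim: int = 128
    learning_rate: float = 0.001
    dropout: float = 0.5
    epochs: int = 30
    seed: int = 0
    max_len: int = 150
    pos_offset: int = 150
    class_weights: dict[int, float] | None = None  # off by default
    dtype: str = "float32"


def _pack(batch: Sequence[EncodedInstance], min_len: int = 1):
    """Stack instances into batch arrays, cropped to the longest real
    length in the batch (dynamic padding)."""
    tmax = max(min_len, max(e.true_length for e in batch))
    w = np.stack([e.word_ids[:tmax] for e in batch])
    pc = np.stack([e.pos_chem_ids[:tmax] for e in batch])
    pg = np.stack([e.pos_gene_ids[:tmax] for e in batch])
    y = np.array([e.label_id for e in batch], dtype=np.int64)
    lens = np.array([e.true_length for e in batch], dtype=np.int64)
    mask = (np.arange(tmax)[None, :] < lens[:, None])
    return w, pc, pg, y, lens, mask


class RelationModel:
    """A trainable relation classifier: embeddings -> encoder -> dropout ->
    softmax, with manual backpropagation."""

    def __init__(self, cfg: ModelConfig, vocab_size: int, pos_table_size: int,
                 word_init: np.ndarray | None = None):
        if cfg.model not in ("cnn", "gru", "att_gru"):
            raise ValueError(f"unknown model kind {cfg.model!r}")
        self.cfg = cfg
        self.dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self.rng = rng
        dt = self.dtype

        if word_init is not None:
            E_w = np.array(word_init, dtype=dt)
            if E_w.shape != (vocab_size, WORD_DIM):
                raise ValueError(
                    f"word embedding shape {E_w.shape} != {(vocab_size, WORD_DIM)}"
                )
        else:
            E_w = rng.uniform(-0.25, 0.25, (vocab_size, WORD_DIM)).astype(dt)
            E_w[PAD_ID] = 0.0
        # position tables are trained jointly; small uniform init
        E_pc = rng.uniform(-0.05, 0.05, (pos_table_size, POS_DIM)).astype(dt)
        E_pg = rng.uniform(-0.05, 0.05, (pos_table_size, POS_DIM)).astype(dt)

        self.params: dict[str, np.ndarray] = {"E_w": E_w, "E_pc": E_pc, "E_pg": E_pg}

        if cfg.model == "cnn":
            self.cnn = CNNParams.init(FEATURE_DIM, cfg.n_filters, cfg.filter_length, rng, dt)
            self.params.update(W_f=self.cnn.W, b_f=self.cnn.b)
            enc_width = cfg.n_filters
        else:
            self.gru = GRUParams.init(FEATURE_DIM, cfg.rnn_dim, rng, dt)
            for name in ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h", "b_z", "b_r", "b_h"):
                self.params[name] = getattr(self.gru, name)
            enc_width = cfg.rnn_dim
            if cfg.model == "att_gru":
                self.att = AttentionParams.init(cfg.rnn_dim, rng, dt)
                self.params.update(W_w=self.att.W_w, b_w=self.att.b_w, u_w=self.att.u_w)

        self.clf = ClassifierParams.init(enc_width, rng, dt)
        self.params.update(W_c=self.clf.W, b_c=self.clf.b)

    # -- forward ------------------------------------------------------------

    def _embed(self, w, pc, pg):
        X = np.concatenate(
            [self.params["E_w"][w], self.params["E_pc"][pc], self.params["E_pg"][pg]],
            axis=-1,
        )
        return X

    def _gru_batch(self, X, mask):
        """Masked batched GRU; returns (H_all, cache)."""
        p = self.params
        B, T, D = X.shape
        H = p["U_z"].shape[0]
        Wcat = np.concatenate([p["W_z"], p["W_r"], p["W_h"]], axis=1)  # (D, 3H)
        XW = X.reshape(B * T, D) @ Wcat
        XW = XW.reshape(B, T, 3 * H)
        h = np.zeros((B, H), dtype=X.dtype)
        H_all = np.empty((B, T, H), dtype=X.dtype)
        cache = []
        m = mask.astype(X.dtype)
        for t in range(T):
            h_prev = h
            a_z = XW[:, t, :H] + h_prev @ p["U_z"] + p["b_z"]
            a_r = XW[:, t, H : 2 * H] + h_prev @ p["U_r"] + p["b_r"]
            z = sigmoid(a_z)
            r = sigmoid(a_r)
            rh = r * h_prev
            h_cand = np.tanh(XW[:, t, 2 * H :] + rh @ p["U_h"] + p["b_h"])
            h_new = z * h_prev + (1.0 - z) * h_cand
            mt = m[:, t : t + 1]
            h = mt * h_new + (1.0 - mt) * h_prev
            H_all[:, t] = h
            cache.append((h_prev, z, r, rh, h_cand))
        return H_all, (X, XW, cache)

    def _gru_batch_backward(self, dH_all, mask, gru_cache, grads):
        p = self.params
        X, XW, cache = gru_cache
        B, T, D = X.shape
        H = p["U_z"].shape[0]
        m = mask.astype(X.dtype)
        dXW = np.zeros_like(XW)
        dh = np.zeros((B, H), dtype=X.dtype)
        for name in ("U_z", "U_r", "U_h", "b_z", "b_r", "b_h"):
            grads.setdefault(name, np.zeros_like(p[name]))
        for t in range(T - 1, -1, -1):
            h_prev, z, r, rh, h_cand = cache[t]
            dh_total = dH_all[:, t] + dh
            mt = m[:, t : t + 1]
            dh_new = mt * dh_total
            dh_prev = (1.0 - mt) * dh_total
            da_z = dh_new * (h_prev - h_cand) * z * (1.0 - z)
            dh_cand = dh_new * (1.0 - z)
            da_h = dh_cand * (1.0 - h_cand * h_cand)
            dh_prev = dh_prev + dh_new * z
            drh = da_h @ p["U_h"].T
            grads["U_h"] += rh.T @ da_h
            da_r = drh * h_prev * r * (1.0 - r)
            dh_prev = dh_prev + drh * r
            dh_prev = dh_prev + da_z @ p["U_z"].T + da_r @ p["U_r"].T
            grads["U_z"] += h_prev.T @ da_z
            grads["U_r"] += h_prev.T @ da_r
            grads["b_z"] += da_z.sum(0)
            grads["b_r"] += da_r.sum(0)
            grads["b_h"] += da_h.sum(0)
            dXW[:, t, :H] = da_z
            dXW[:, t, H : 2 * H] = da_r
            dXW[:, t, 2 * H :] = da_h
            dh = dh_prev
        Wcat = np.concatenate([p["W_z"], p["W_r"], p["W_h"]], axis=1)
        dX = (dXW.reshape(B * T, 3 * H) @ Wcat.T).reshape(B, T, D)
        dWcat = X.reshape(B * T, D).T @ dXW.reshape(B * T, 3 * H)
        grads["W_z"] = grads.get("W_z", 0) + dWcat[:, :H]
        grads["W_r"] = grads.get("W_r", 0) + dWcat[:, H : 2 * H]
        grads["W_h"] = grads.get("W_h", 0) + dWcat[:, 2 * H :]
        return dX

    def forward(self, w, pc, pg, lens, mask, train: bool):
        """Batched forward pass; returns (probs, alphas-or-None, cache)."""
        p = self.params
        X = self._embed(w, pc, pg)
        B, T, _ = X.shape
        alphas = None
        cache: dict = {"X": X, "w": w, "pc": pc, "pg": pg, "mask": mask, "lens": lens}

        if self.cfg.model == "cnn":
            fl = self.cfg.filter_length
            if T < fl:
                raise ValueError(f"batch length {T} < filter length {fl}")
            P = T - fl + 1
            windows = np.concatenate([X[:, k : k + P, :] for k in range(fl)], axis=2)
            Z = windows.reshape(B * P, -1) @ p["W_f"] + p["b_f"]
            A = np.tanh(Z).reshape(B, P, -1)
            # sequences shorter than the filter fall back to the first
            # (zero-padded) window so the batch stays well defined
            lens_eff = np.maximum(lens, fl)
            valid = (np.arange(P)[None, :] < (lens_eff - fl + 1)[:, None])
            A_masked = np.where(valid[:, :, None], A, -np.inf)
            arg = A_masked.argmax(axis=1)  # (B, F)
            s = np.take_along_axis(A_masked, arg[:, None, :], axis=1)[:, 0, :]
            cache.update(windows=windows, A=A, arg=arg, P=P, valid=valid)
        else:
            H_all, gru_cache = self._gru_batch(X, mask)
            cache["gru"] = gru_cache
            cache["H_all"] = H_all
            if self.cfg.model == "att_gru":
                u = np.tanh(
                    H_all.reshape(B * T, -1) @ p["W_w"] + p["b_w"]
                ).reshape(B, T, -1)
                scores = u @ p["u_w"]
                scores = np.where(mask, scores, -np.inf)
                alphas = softmax(scores, axis=1)
                s = np.einsum("bt,bth->bh", alphas, H_all)
                cache.update(u=u, alphas=alphas)
            else:
                idx = lens - 1
                s = H_all[np.arange(B), idx]
                cache["last_idx"] = idx

        if train and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            drop_mask = (self.rng.random(s.shape) < keep).astype(s.dtype) / keep
            s_d = s * drop_mask
            cache["drop_mask"] = drop_mask
        else:
            s_d = s
        cache["s_d"] = s_d
        probs = softmax(s_d @ p["W_c"] + p["b_c"], axis=-1)
        cache["probs"] = probs
        return probs, alphas, cache

    # -- backward -----------------------------------------------------------

    def backward(self, cache, y, sample_weights=None) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy w.r.t. every parameter."""
        p = self.params
        probs = cache["probs"]
        B = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        if sample_weights is not None:
            dlogits *= sample_weights[:, None] / sample_weights.sum()
        else:
            dlogits /= B
        grads: dict[str, np.ndarray] = {}
        s_d = cache["s_d"]
        grads["W_c"] = s_d.T @ dlogits
        grads["b_c"] = dlogits.sum(0)
        ds = dlogits @ p["W_c"].T
        if "drop_mask" in cache:
            ds = ds * cache["drop_mask"]

        X = cache["X"]
        Bx, T, D = X.shape

        if self.cfg.model == "cnn":
            A, arg, P = cache["A"], cache["arg"], cache["P"]
            fl = self.cfg.filter_length
            dA = np.zeros_like(A)
            np.put_along_axis(dA, arg[:, None, :], ds[:, None, :], axis=1)
            dZ = dA * (1.0 - A * A)
            windows = cache["windows"]
            Wd = windows.shape[2]
            grads["W_f"] = windows.reshape(Bx * P, Wd).T @ dZ.reshape(Bx * P, -1)
            grads["b_f"] = dZ.sum((0, 1))
            dwindows = (dZ.reshape(Bx * P, -1) @ p["W_f"].T).reshape(Bx, P, Wd)
            dX = np.zeros_like(X)
            for k in range(fl):
                dX[:, k : k + P, :] += dwindows[:, :, k * D : (k + 1) * D]
        else:
            H_all = cache["H_all"]
            Hdim = H_all.shape[2]
            if self.cfg.model == "att_gru":
                u, alphas = cache["u"], cache["alphas"]
                mask = cache["mask"]
                dalpha = np.einsum("bth,bh->bt", H_all, ds)
                dH_all = alphas[:, :, None] * ds[:, None, :]
                inner = (alphas * dalpha).sum(axis=1, keepdims=True)
                dscores = alphas * (dalpha - inner)
                du = dscores[:, :, None] * p["u_w"][None, None, :]
                da = du * (1.0 - u * u)
                grads["u_w"] = np.einsum("bth,bt->h", u, dscores)
                grads["W_w"] = H_all.reshape(-1, Hdim).T @ da.reshape(-1, Hdim)
                grads["b_w"] = da.sum((0, 1))
                dH_all = dH_all + da @ p["W_w"].T
                dH_all *= mask[:, :, None]
            else:
                dH_all = np.zeros_like(H_all)
                dH_all[np.arange(Bx), cache["last_idx"]] = ds
            dX = self._gru_batch_backward(dH_all, cache["mask"], cache["gru"], grads)

        # split dX back into the three embedding tracks and scatter-add
        dXw = dX[:, :, :WORD_DIM].reshape(-1, WORD_DIM)
        dXc = dX[:, :, WORD_DIM : WORD_DIM + POS_DIM].reshape(-1, POS_DIM)
        dXg = dX[:, :, WORD_DIM + POS_DIM :].reshape(-1, POS_DIM)
        dEw = np.zeros_like(p["E_w"])
        dEpc = np.zeros_like(p["E_pc"])
        dEpg = np.zeros_like(p["E_pg"])
        np.add.at(dEw, cache["w"].ravel(), dXw)
        np.add.at(dEpc, cache["pc"].ravel(), dXc)
        np.add.at(dEpg, cache["pg"].ravel(), dXg)
        dEw[PAD_ID] = 0.0  # padding row stays zero
        grads["E_w"] = dEw
        grads["E_pc"] = dEpc
        grads["E_pg"] = dEpg
        return grads

    def loss(self, probs, y, sample_weights=None) -> float:
        logp = -np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))
        if sample_weights is not None:
            return float((logp * sample_weights).sum() / sample_weights.sum())
        return float(logp.mean())


@dataclass
class TrainedModel:
    model: RelationModel
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_dev_f1: float = 0.0


def _micro_f1_ids(gold: np.ndarray, pred: np.ndarray) -> float:
    """Micro F1 over positive label ids 1..5 (NA = 0 excluded)."""
    tp = int(np.sum((gold == pred) & (gold > 0)))
    fp = int(np.sum((pred > 0) & (pred != gold)))
    fn = int(np.sum((gold > 0) & (gold != pred)))
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def train_model(
    train: Sequence[EncodedInstance],
    dev: Sequence[EncodedInstance],
    cfg: ModelConfig,
    word_init: np.ndarray | None = None,
    vocab_size: int | None = None,
) -> TrainedModel:
    """Mini-batch Adam training with best-dev-F1 model selection.

    The parameter snapshot with the highest development micro-F1 across
    epochs is retained; the per-epoch training curve (loss, dev F1) is
    logged and returned in the history.
    """
    if not train:
        raise ValueError("empty training set")
    if vocab_size is None:
        if word_init is None:
            raise ValueError("need vocab_size or word_init")
        vocab_size = word_init.shape[0]
    pos_table = 2 * cfg.pos_offset
    model = RelationModel(cfg, vocab_size, pos_table, word_init=word_init)
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    min_len = cfg.filter_length if cfg.model == "cnn" else 1

    weights_lut = None
    if cfg.class_weights:
        weights_lut = np.ones(N_LABELS)
        for k, v in cfg.class_weights.items():
            weights_lut[k] = v

    best_params = None
    best_f1 = -1.0
    best_epoch = -1
    history = []
    order = np.arange(len(train))
    for epoch in range(cfg.epochs):
        t0 = time.time()
        rng.shuffle(order)
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch = [train[j] for j in order[i : i + cfg.batch_size]]
            w, pc, pg, y, lens, mask = _pack(batch, min_len=min_len)
            probs, _, cache = model.forward(w, pc, pg, lens, mask, train=True)
            sw = weights_lut[y] if weights_lut is not None else None
            losses.append(model.loss(probs, y, sw))
            grads = model.backward(cache, y, sw)
            opt.step(model.params, grads)
        dev_f1 = 0.0
        if dev:
            pred_ids, _ = predict(model, dev)
            gold_ids = np.array([e.label_id for e in dev])
            dev_f1 = _micro_f1_ids(gold_ids, pred_ids)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "dev_micro_f1": dev_f1,
            "seconds": time.time() - t0,
        }
        history.append(entry)
        logger.info(
            "epoch %d: loss %.4f dev micro-F1 %.4f (%.1fs)",
            epoch, entry["train_loss"], dev_f1, entry["seconds"],
        )
        if dev_f1 >= best_f1 + 1e-12 or best_params is None:
            best_f1 = dev_f1
            best_epoch = epoch
            best_params = copy.deepcopy(model.params)
    if best_params is not None:
        for k in model.params:
            model.params[k][...] = best_params[k]
    return TrainedModel(model=model, history=history,
                        best_epoch=best_epoch, best_dev_f1=max(best_f1, 0.0))


def predict(
    model: RelationModel,
    instances: Sequence[EncodedInstance],
    batch_size: int = 256,
) -> tuple[np.ndarray, list[np.ndarray] | None]:
    """Deterministic inference (dropout off).

    Returns predicted label ids and, for attention models, one alpha vector
    per instance aligned to its unpadded tokens (None otherwise).
    """
    min_len = model.cfg.filter_length if model.cfg.model == "cnn" else 1
    preds = []
    all_alphas: list[np.ndarray] | None = (
        [] if model.cfg.model == "att_gru" else None
    )
    for i in range(0, len(instances), batch_size):
        batch = list(instances[i : i + batch_size])
        w, pc, pg, y, lens, mask = _pack(batch, min_len=min_len)
        probs, alphas, _ = model.forward(w, pc, pg, lens, mask, train=False)
        preds.append(probs.argmax(axis=1))
        if all_alphas is not None:
            for j, e in enumerate(batch):
                all_alphas.append(np.asarray(alphas[j, : e.true_length]))
    return np.concatenate(preds), all_alphas
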