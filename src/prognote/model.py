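"""Many-to-many recurrent survival classifier.

Architecture, per timestep (one timestep = one visit-note vector):

    input(D) -> LSTM(50) -> frame-wise batch norm -> LSTM(25)
             -> dropout(0.10) -> dense -> softmax over 3 classes

The three classes are Survival-positive, Survival-negative and Padded.
Both LSTM layers are unidirectional, so the class probabilities at
timestep t depend only on visits 1..t — the model never sees the
future. Training minimises a time-distributed weighted cross-entropy:
each timestep's CE term is scaled by the weight of its *true* class
(POS 2.0, NEG 1.0, PAD 0.1; censored-UNDEFINED timesteps get 0 and
contribute nothing), averaged over all timesteps. Optimisation is Adam
at learning rate 0.001 with inverse-time decay 0.0001/epoch and global
gradient-norm clipping at 5.

Everything is plain numpy in float64: forward, backpropagation through
time, batch-norm statistics, Adam state. Single-threaded and seeded, so
training is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dataset import NEG, PAD, POS, UNDEFINED, PatientSequence, stack

__all__ = [
    "ModelConfig",
    "SurvivalLSTM",
    "PredictionSequence",
    "weighted_loss",
    "train",
    "predict",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class ModelConfig:
    input_dim: int
    hidden1: int = 50
    hidden2: int = 25
    dropout: float = 0.10
    n_classes: int = 3
    lr: float = 0.001
    lr_decay_per_epoch: float = 0.0001
    epochs: int = 100
    batch_size: int = 32
    class_weights: tuple[float, float, float] = (2.0, 1.0, 0.1)
    clip_norm: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.hidden1 < 1 or self.hidden2 < 1 or self.input_dim < 1:
            raise ValueError("layer sizes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be > 0")


@dataclass
class PredictionSequence:
    """Per-timestep class probabilities for one patient, plus the scalar
    survival-probability curve (P of Survival-positive at each real visit)."""

    patient_id: str
    probs: np.ndarray          # (T, n_classes)
    labels: np.ndarray         # (T,)
    visit_dates: list
    note_ids: list[str]

    @property
    def p_surv(self) -> np.ndarray:
        return self.probs[: len(self.note_ids), POS]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_loss(
    labels: np.ndarray,
    probs: np.ndarray,
    class_weights=(2.0, 1.0, 0.1),
    mask: np.ndarray | None = None,
) -> float:
    """Time-distributed weighted cross-entropy.

    ``labels`` is (B, T) with values in {POS, NEG, PAD, UNDEFINED};
    ``probs`` is (B, T, C) of per-timestep class probabilities. Each
    timestep contributes -w * ln p[true class], with w the true class's
    weight, 0 for UNDEFINED (or wherever ``mask`` is 0); the result is
    the mean over all B*T timesteps.
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape[:2] != labels.shape:
        raise ValueError("labels/probs shape mismatch")
    sums = probs.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    w = np.zeros(labels.shape, dtype=np.float64)
    for cls, cw in zip((POS, NEG, PAD), class_weights):
        w[labels == cls] = cw
    if mask is not None:
        w = w * np.asarray(mask, dtype=np.float64)
    safe = np.where(labels == UNDEFINED, POS, labels)
    p_true = np.take_along_axis(probs, safe[..., None].astype(np.int64), axis=-1)[..., 0]
    ce = -np.log(np.clip(p_true, 1e-300, None))
    return float((w * ce).sum() / labels.size)


class SurvivalLSTM:
    """Stacked-LSTM sequence classifier (numpy implementation)."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, H1, H2, C = config.input_dim, config.hidden1, config.hidden2, config.n_classes

        def glorot(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        self.params: dict[str, np.ndarray] = {
            "Wx1": glorot((D, 4 * H1), D, 4 * H1),
            "Wh1": glorot((H1, 4 * H1), H1, 4 * H1),
            "b1": np.zeros(4 * H1),
            "gamma": np.ones(H1),
            "beta": np.zeros(H1),
            "Wx2": glorot((H1, 4 * H2), H1, 4 * H2),
            "Wh2": glorot((H2, 4 * H2), H2, 4 * H2),
            "b2": np.zeros(4 * H2),
            "Wo": glorot((H2, C), H2, C),
            "bo": np.zeros(C),
        }
        # forget-gate bias 1: standard trick for gradient flow early on
        self.params["b1"][H1 : 2 * H1] = 1.0
        self.params["b2"][H2 : 2 * H2] = 1.0
        self.bn_mean = np.zeros(H1)
        self.bn_var = np.ones(H1)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # ---- introspection -------------------------------------------------

    def parameter_count(self) -> dict[str, int]:
        """Trainable parameters per layer; LSTM layers follow the closed
        form 4*H*(D_in + H + 1)."""
        cfg = self.config
        return {
            "lstm_1": 4 * cfg.hidden1 * (cfg.input_dim + cfg.hidden1 + 1),
            "batch_normalization_1": 2 * cfg.hidden1,
            "lstm_2": 4 * cfg.hidden2 * (cfg.hidden1 + cfg.hidden2 + 1),
            "time_distributed_output": cfg.hidden2 * cfg.n_classes + cfg.n_classes,
        }

    @property
    def layer_order(self) -> list[str]:
        return ["lstm", "batchnorm", "lstm", "dropout", "time_distributed_softmax"]

    # ---- forward -------------------------------------------------------

    def _lstm_forward(self, x: np.ndarray, Wx, Wh, b, H: int):
        B, T, _ = x.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            a = x[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs, cache

    def forward(self, x: np.ndarray, training: bool = False):
        """Return (probs (B,T,C), cache). Training mode uses batch-norm
        batch statistics and samples a dropout mask; inference mode uses
        running statistics and no dropout (fully deterministic)."""
        p = self.params
        cfg = self.config
        h1, cache1 = self._lstm_forward(x, p["Wx1"], p["Wh1"], p["b1"], cfg.hidden1)

        B, T, H1 = h1.shape
        flat = h1.reshape(-1, H1)
        if training:
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.bn_mean = _BN_MOMENTUM * self.bn_mean + (1 - _BN_MOMENTUM) * mu
            self.bn_var = _BN_MOMENTUM * self.bn_var + (1 - _BN_MOMENTUM) * var
        else:
            mu, var = self.bn_mean, self.bn_var
        std = np.sqrt(var + _BN_EPS)
        xhat = (flat - mu) / std
        bn_out = (p["gamma"] * xhat + p["beta"]).reshape(B, T, H1)

        h2, cache2 = self._lstm_forward(bn_out, p["Wx2"], p["Wh2"], p["b2"], cfg.hidden2)

        if training and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            drop_mask = (self._dropout_rng.random(h2.shape) < keep) / keep
        else:
            drop_mask = np.ones_like(h2)
        h2d = h2 * drop_mask

        logits = h2d @ p["Wo"] + p["bo"]
        probs = _softmax(logits)
        cache = (x, cache1, xhat, std, bn_out, cache2, h2, drop_mask, h2d, probs)
        return probs, cache

    # ---- backward ------------------------------------------------------

    def _lstm_backward(self, dh_out: np.ndarray, cache, Wx, Wh, H: int):
        B, T, _ = dh_out.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.empty((B, T, Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dh_out[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x_t.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ Wx.T
            dh_next = da @ Wh.T
        return dx, dWx, dWh, db

    def backward(self, cache, labels: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the weighted time-distributed CE w.r.t. every
        parameter, for the batch whose forward pass produced ``cache``."""
        p = self.params
        cfg = self.config
        x, cache1, xhat, std, bn_out, cache2, h2, drop_mask, h2d, probs = cache
        B, T, C = probs.shape

        w = np.zeros((B, T), dtype=np.float64)
        for cls, cw in zip((POS, NEG, PAD), cfg.class_weights):
            w[labels == cls] = cw
        safe = np.where(labels == UNDEFINED, POS, labels).astype(np.int64)
        onehot = np.eye(C)[safe]
        dlogits = w[..., None] * (probs - onehot) / (B * T)

        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = h2d.reshape(-1, cfg.hidden2).T @ dlogits.reshape(-1, C)
        grads["bo"] = dlogits.sum(axis=(0, 1))
        dh2d = dlogits @ p["Wo"].T
        dh2 = dh2d * drop_mask

        dbn_out, grads["Wx2"], grads["Wh2"], grads["b2"] = self._lstm_backward(
            dh2, cache2, p["Wx2"], p["Wh2"], cfg.hidden2
        )

        dy = dbn_out.reshape(-1, cfg.hidden1)
        grads["gamma"] = (dy * xhat).sum(axis=0)
        grads["beta"] = dy.sum(axis=0)
        # batch-norm input gradient (batch statistics participate)
        m = dy.shape[0]
        dxhat = dy * p["gamma"]
        dflat = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
        dh1 = dflat.reshape(B, T, cfg.hidden1)

        _, grads["Wx1"], grads["Wh1"], grads["b1"] = self._lstm_backward(
            dh1, cache1, p["Wx1"], p["Wh1"], cfg.hidden1
        )
        return grads

    # ---- persistence ---------------------------------------------------

    def save(self, run_dir) -> None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        np.savez(
            run_dir / "checkpoint.npz",
            bn_mean=self.bn_mean,
            bn_var=self.bn_var,
            **self.params,
        )
        with open(run_dir / "model_config.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, run_dir) -> "SurvivalLSTM":
        run_dir = Path(run_dir)
        with open(run_dir / "model_config.json", encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["class_weights"] = tuple(raw["class_weights"])
        model = cls(ModelConfig(**raw))
        arrays = np.load(run_dir / "checkpoint.npz")
        for k in model.params:
            model.params[k] = arrays[k]
        model.bn_mean = arrays["bn_mean"]
        model.bn_var = arrays["bn_var"]
        return model


def _accuracy(probs: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(accuracy over all timesteps incl. padding, accuracy over real
    POS/NEG timesteps). The padded-in version is the over-optimistic
    bookkeeping; the real-timestep version is the honest one."""
    pred = probs.argmax(axis=-1)
    overall = float((pred == labels).mean())
    real = (labels == POS) | (labels == NEG)
    real_acc = float((pred[real] == labels[real]).mean()) if real.any() else float("nan")
    return overall, real_acc


def train(
    train_seqs: list[PatientSequence],
    config: ModelConfig,
    val_seqs: list[PatientSequence] | None = None,
) -> tuple[SurvivalLSTM, list[dict]]:
    """Fit the model with Adam; returns (best-validation model, history).

    Patient order is reshuffled every epoch (seeded); the learning rate
    follows lr_e = lr / (1 + decay * e). The checkpoint kept is the one
    with the best validation accuracy on real timesteps (training-set
    accuracy when no validation split is given).
    """
    if not train_seqs:
        raise ValueError("empty training split")
    model = SurvivalLSTM(config)
    x_train, y_train = stack(train_seqs)
    x_val, y_val = stack(val_seqs) if val_seqs else (None, None)
    rng = np.random.default_rng(config.seed + 2)

    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[dict] = []
    best_metric = -np.inf
    best_params = None
    best_bn = None

    n = len(train_seqs)
    for epoch in range(config.epochs):
        lr = config.lr / (1.0 + config.lr_decay_per_epoch * epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs, cache = model.forward(xb, training=True)
            epoch_loss += weighted_loss(yb, probs, config.class_weights)
            n_batches += 1
            grads = model.backward(cache, yb)

            norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if config.clip_norm and norm > config.clip_norm:
                scale = config.clip_norm / norm
                grads = {k: g * scale for k, g in grads.items()}
            step += 1
            for k, g in grads.items():
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g**2
                m_hat = m_state[k] / (1 - beta1**step)
                v_hat = v_state[k] / (1 - beta2**step)
                model.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

        train_probs, _ = model.forward(x_train, training=False)
        train_acc, train_acc_real = _accuracy(train_probs, y_train)
        row = {
            "epoch": epoch,
            "lr": lr,
            "loss": epoch_loss / n_batches,
            "train_acc": train_acc,
            "train_acc_real": train_acc_real,
        }
        if x_val is not None and len(x_val):
            val_probs, _ = model.forward(x_val, training=False)
            row["val_acc"], row["val_acc_real"] = _accuracy(val_probs, y_val)
            row["val_loss"] = weighted_loss(y_val, val_probs, config.class_weights)
            metric = -row["val_loss"]
        else:
            metric = -row["loss"]
        history.append(row)
        # checkpoint on best (lowest) validation loss; ties keep the earliest
        if metric > best_metric:
            best_metric = metric
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_bn = (model.bn_mean.copy(), model.bn_var.copy())

    if best_params is not None:
        model.params = best_params
        model.bn_mean, model.bn_var = best_bn
    return model, history


def predict(
    sequences: list[PatientSequence], model: SurvivalLSTM
) -> list[PredictionSequence]:
    """Deterministic inference (dropout off, batch norm on running
    statistics); causal by construction — ŷ(t) depends on x(1..t) only."""
    if not sequences:
        return []
    x, y = stack(sequences)
    if x.shape[2] != model.config.input_dim:
        raise ValueError(
            f"input dim {x.shape[2]} != model dim {model.config.input_dim}"
        )
    probs, _ = model.forward(x, training=False)
    return [
        PredictionSequence(
            patient_id=s.patient_id,
            probs=probs[i],
            labels=y[i],
            visit_dates=s.visit_dates,
            note_ids=s.note_ids,
        )
        for i, s in enumerate(sequences)
    ]


def predictions_frame(predictions: list[PredictionSequence]):
    """Flatten predictions to one row per real (non-padded) visit:
    patient_id, visit_index, visit_date, note_id, p_survival, true_label."""
    import pandas as pd

    from .dataset import LABELS

    rows = []
    for p in predictions:
        for t, nid in enumerate(p.note_ids):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "visit_index": t,
                    "visit_date": p.visit_dates[t].isoformat(),
                    "note_id": nid,
                    "p_survival": float(p.probs[t, POS]),
                    "true_label": LABELS[int(p.labels[t])],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "visit_index", "visit_date", "note_id",
                 "p_survival", "true_label"],
    )
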