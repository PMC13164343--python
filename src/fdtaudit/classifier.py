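"""Reference convolutional classifier and its training protocol.

A deliberately small, transparent CNN gives the audit loop a genuine
learned predictor without any pretrained weights: two convolutional
blocks of paired 3x3 convolutions with batch normalization and ReLU, the
second block wrapped in an identity skip connection added after its
final batch normalization (post-activation residual), then 2x2 max
pooling, global average pooling, dropout (p = 0.5), a 512-unit ReLU
fully-connected layer, and a linear 4-way softmax head.

Training uses AdamW (beta1 = 0.9, beta2 = 0.999, lr = 3e-4, weight
decay = 1e-4, batch size 32), weighted cross-entropy with normalized
inverse-frequency class weights, early stopping on validation macro-F1
(patience 5, best checkpoint retained), and plateau learning-rate
halving (factor 0.5, patience 2).  Width, input size, and hidden size
are configurable so phantom cohorts train in minutes on a CPU; the
audit layer is agnostic to these sizes.

Any external model can stand in for this one: the audit loop only needs
a callable ``PreprocessedSlice -> Prediction`` with a ``model_id``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .constraints import CLASSES
from .nn import (
    AdamW,
    BatchNorm2d,
    Conv2d,
    Dropout,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ReLU,
    softmax,
)
from .verifier import Prediction
from .weighting import ClassWeights

__all__ = [
    "TrainConfig",
    "PureCNN",
    "build_pure_cnn",
    "train",
    "EarlyStopper",
    "PlateauScheduler",
]


@dataclass
class TrainConfig:
    lr: float = 3e-4
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 20
    early_stop_patience: int = 5
    plateau_factor: float = 0.5
    plateau_patience: int = 2
    seed: int = 0
    mixed_precision: bool = False  # float16 activations when on; off by default

    def snapshot(self) -> dict:
        return asdict(self)


class EarlyStopper:
    """Halt after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best: Optional[float] = None
        self.bad = 0

    def update(self, value: float) -> bool:
        """Feed one epoch's metric; returns True when training should halt."""
        if self.best is None or value > self.best:
            self.best, self.bad = value, 0
            return False
        self.bad += 1
        return self.bad >= self.patience


class PlateauScheduler:
    """Halve the learning rate after ``patience`` non-improving epochs."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 2):
        self.lr, self.factor, self.patience = lr, factor, patience
        self.best: Optional[float] = None
        self.bad = 0

    def update(self, value: float) -> float:
        if self.best is None or value > self.best:
            self.best, self.bad = value, 0
        else:
            self.bad += 1
            if self.bad >= self.patience:
                self.lr *= self.factor
                self.bad = 0
        return self.lr


class PureCNN:
    """The two-block residual CNN with a softmax head."""

    def __init__(self, width: int = 64, n_classes: int = 4, in_channels: int = 3,
                 hidden: int = 512, input_size: int = 224, seed: int = 0):
        if width < 8:
            raise ValueError("width must be >= 8")
        rng = np.random.default_rng(seed)
        w = width
        self.b1c1, self.b1n1 = Conv2d(in_channels, w, rng=rng), BatchNorm2d(w)
        self.b1c2, self.b1n2 = Conv2d(w, w, rng=rng), BatchNorm2d(w)
        self.b2c1, self.b2n1 = Conv2d(w, w, rng=rng), BatchNorm2d(w)
        self.b2c2, self.b2n2 = Conv2d(w, w, rng=rng), BatchNorm2d(w)
        self.relus = [ReLU() for _ in range(5)]
        self.pool = MaxPool2d()
        self.gap = GlobalAvgPool()
        self.dropout = Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31)))
        self.fc1 = Linear(w, hidden, rng=rng)
        self.fc_relu = ReLU()
        self.fc2 = Linear(hidden, n_classes, rng=rng)
        self.width, self.hidden, self.n_classes = w, hidden, n_classes
        self.input_size = input_size
        self.model_id = f"pure-cnn-w{w}"

    # -- plumbing ------------------------------------------------------------
    def _layers(self):
        return [
            self.b1c1, self.b1n1, self.b1c2, self.b1n2,
            self.b2c1, self.b2n1, self.b2c2, self.b2n2,
            self.fc1, self.fc2,
        ]

    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def param_count(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def state_dict(self):
        return [np.copy(p) for p, _ in self.params()]

    def load_state_dict(self, state):
        for (p, _), saved in zip(self.params(), state):
            p[...] = saved

    # -- forward / backward ----------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 3, S, S) -> (N, n_classes) logits."""
        x = np.asarray(x, dtype=np.float32)
        r = self.relus
        h = r[0].forward(self.b1n1.forward(self.b1c1.forward(x, train), train))
        x1 = r[1].forward(self.b1n2.forward(self.b1c2.forward(h, train), train))
        h = r[2].forward(self.b2n1.forward(self.b2c1.forward(x1, train), train))
        y = self.b2n2.forward(self.b2c2.forward(h, train), train)
        z = r[3].forward(y + x1)  # post-activation residual
        h = self.pool.forward(z)
        h = self.gap.forward(h)
        h = self.dropout.forward(h, train)
        h = self.fc_relu.forward(self.fc1.forward(h))
        return self.fc2.forward(h)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = self.fc2.backward(grad_logits)
        g = self.fc1.backward(self.fc_relu.backward(g))
        g = self.dropout.backward(g)
        g = self.gap.backward(g)
        g = self.pool.backward(g)
        g = self.relus[3].backward(g)
        g_res = g  # gradient flows both into block 2 and the skip path
        g2 = self.b2c2.backward(self.b2n2.backward(g))
        g2 = self.b2c1.backward(self.b2n1.backward(self.relus[2].backward(g2)))
        g1 = self.relus[1].backward(g2 + g_res)
        g1 = self.b1c2.backward(self.b1n2.backward(g1))
        self.b1c1.backward(self.b1n1.backward(self.relus[0].backward(g1)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    # -- predictor interface ---------------------------------------------------
    def __call__(self, pre) -> Prediction:
        """PreprocessedSlice -> Prediction (the audit loop's contract)."""
        probs = self.predict_proba(pre.tensor[None, ...])[0]
        arg = int(max(range(len(probs)), key=lambda i: (probs[i], -i)))
        # exact renormalization guards against float32 drift
        probs = probs / probs.sum()
        return Prediction(CLASSES[arg], tuple(float(p) for p in probs))


def build_pure_cnn(width: int = 64, n_classes: int = 4, **kwargs) -> PureCNN:
    return PureCNN(width=width, n_classes=n_classes, **kwargs)


def _batch_loss_grad(model, xb, yb, weight_vec):
    logits = model.forward(xb, train=True)
    probs = softmax(logits)
    n = len(yb)
    py = np.maximum(probs[np.arange(n), yb], 1e-12)
    w = weight_vec[yb]
    loss = float(np.mean(-w * np.log(py)))
    grad = probs.copy()
    grad[np.arange(n), yb] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad.astype(np.float32)


def train(
    model: PureCNN,
    x_train: np.ndarray,
    y_train: Sequence[int],
    x_val: np.ndarray,
    y_val: Sequence[int],
    weights: Optional[ClassWeights] = None,
    cfg: Optional[TrainConfig] = None,
):
    """Optimize with weighted cross-entropy; returns (model, epoch log).

    ``weights=None`` trains unweighted (all class weights 1).  The model
    with the best validation macro-F1 is retained.  Fully seeded via
    ``cfg.seed``.
    """
    from sklearn.metrics import f1_score

    cfg = cfg or TrainConfig()
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if len(y_train) == 0 or len(y_val) == 0:
        raise ValueError("empty train or validation split")
    weight_vec = (
        np.asarray(weights.normalized_weights, dtype=np.float32)
        if weights is not None
        else np.ones(model.n_classes, dtype=np.float32)
    )
    opt = AdamW(model.params(), lr=cfg.lr, betas=cfg.betas, weight_decay=cfg.weight_decay)
    sched = PlateauScheduler(cfg.lr, cfg.plateau_factor, cfg.plateau_patience)
    stopper = EarlyStopper(cfg.early_stop_patience)
    rng = np.random.default_rng(cfg.seed)
    log = []
    best_state, best_f1 = model.state_dict(), -1.0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(y_train))
        total_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x_train[idx]
            if cfg.mixed_precision:
                xb = xb.astype(np.float16).astype(np.float32)
            loss, grad = _batch_loss_grad(model, xb, y_train[idx], weight_vec)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            total_loss += loss * len(idx)
        probs_tr = _predict_in_batches(model, x_train, cfg.batch_size)
        probs_val = _predict_in_batches(model, x_val, cfg.batch_size)
        pred_tr = probs_tr.argmax(axis=1)
        pred_val = probs_val.argmax(axis=1)
        val_f1 = float(f1_score(y_val, pred_val, average="macro", zero_division=0))
        py = np.maximum(probs_val[np.arange(len(y_val)), y_val], 1e-12)
        val_loss = float(np.mean(-weight_vec[y_val] * np.log(py)))
        entry = {
            "epoch": epoch,
            "train_loss": total_loss / len(y_train),
            "train_acc": float((pred_tr == y_train).mean()),
            "val_loss": val_loss,
            "val_acc": float((pred_val == y_val).mean()),
            "val_macro_f1": val_f1,
            "lr": opt.lr,
        }
        log.append(entry)
        if val_f1 > best_f1:
            best_f1, best_state = val_f1, model.state_dict()
        opt.lr = sched.update(val_f1)
        if stopper.update(val_f1):
            break
    model.load_state_dict(best_state)
    return model, log


def _predict_in_batches(model, x, batch_size):
    out = []
    for start in range(0, len(x), batch_size):
        out.append(model.predict_proba(x[start : start + batch_size]))
    return np.concatenate(out, axis=0)
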