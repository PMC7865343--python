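"""The 6-conv + 2-LSTM + 3-dense gait-phase classifier.

Per window, six stride-1 'same' convolutions extract features, with max
pooling after every second convolution; the flattened feature vector of each
window feeds a two-layer LSTM that runs along the sequence of windows, and a
per-step dense head (1024 -> 256 -> 5 at full scale) emits one softmax row
per window.  LSTM state is reset between sequences, which are shuffled as
whole units during training.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from gaitphase.errors import ConfigError, DataError, ShapeError
from gaitphase.nn.layers import (
    Adam,
    Conv2D,
    Dense,
    Dropout,
    LSTM,
    MaxPool2D,
    softmax,
    softmax_cross_entropy,
)

DEFAULT_CONV_KERNELS = ((6, 6), (3, 3), (3, 3), (3, 3), (3, 3), (3, 3))
DEFAULT_CONV_FILTERS = (16, 16, 32, 32, 64, 64)
DEFAULT_POOL_KERNELS = ((2, 2), (3, 3), (2, 2))


@dataclass
class ModelConfig:
    conv_kernels: tuple = DEFAULT_CONV_KERNELS
    conv_filters: tuple = DEFAULT_CONV_FILTERS
    pool_kernels: tuple = DEFAULT_POOL_KERNELS
    # None means "one unit per window in a sequence" (the best sweep value),
    # resolved when the sequence length is known; 480 at baseline scale.
    lstm_units: int | None = None
    dense_units: tuple = (1024, 256)
    n_classes: int = 5
    dropout: float = 0.2
    l2_coeff: float = 1e-4
    learning_rate: float = 1e-3
    seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if len(self.conv_kernels) != 6:
            raise ConfigError("conv_kernels must list exactly 6 kernel sizes")
        if len(self.conv_filters) != 6:
            raise ConfigError("conv_filters must list exactly 6 filter counts")
        if any(b < a for a, b in zip(self.conv_filters, self.conv_filters[1:])):
            raise ConfigError("conv_filters must be non-decreasing")
        if len(self.pool_kernels) != 3:
            raise ConfigError("pool_kernels must list exactly 3 pool sizes")
        if len(self.dense_units) != 2:
            raise ConfigError("dense_units must list exactly 2 hidden sizes")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")
        if self.lstm_units is not None and self.lstm_units < 1:
            raise ConfigError("lstm_units must be >= 1")

    def resolved(self, seq_len: int) -> "ModelConfig":
        """Concrete copy with lstm_units defaulted to the sequence length."""
        import dataclasses

        units = self.lstm_units if self.lstm_units is not None else seq_len
        return dataclasses.replace(self, lstm_units=units)


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 2  # sequences per optimizer step
    seed: int = 0
    early_stop: bool = False
    patience: int = 3

    def validate(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


@dataclass
class PredictionSet:
    """Per-window softmax rows, argmax classes and ground truth."""

    probs: np.ndarray  # [W, K]
    pred: np.ndarray  # [W]
    true: np.ndarray | None = None  # [W]
    subject_ids: np.ndarray | None = None

    @property
    def certainty(self) -> np.ndarray:
        """Maximum softmax output per window (the rejection score)."""
        return self.probs.max(axis=1)


class ConvLSTMNetwork:
    """Assembled network; see module docstring for the data flow."""

    def __init__(self, cfg: ModelConfig, input_shape: tuple[int, int]):
        cfg.validate()
        if cfg.lstm_units is None:
            raise ConfigError(
                "lstm_units is unresolved; call cfg.resolved(seq_len) first"
            )
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)

        h, w = input_shape
        self.conv_stack: list = []
        in_ch = 1
        pool_iter = iter(cfg.pool_kernels)
        for i, (kernel, filters) in enumerate(zip(cfg.conv_kernels, cfg.conv_filters)):
            self.conv_stack.append(
                Conv2D(in_ch, filters, tuple(kernel), rng, activation="relu",
                       l2=cfg.l2_coeff, dtype=dtype, input_grad=(i > 0))
            )
            in_ch = filters
            if i % 2 == 1:  # pool after conv layers 2, 4, 6
                ph, pw = next(pool_iter)
                h, w = h // ph, w // pw
                if h < 1 or w < 1:
                    raise ConfigError(
                        f"pooled spatial size collapsed to {h}x{w} after "
                        f"pool stage {i // 2 + 1}; shrink the pools or grow the window"
                    )
                self.conv_stack.append(MaxPool2D((ph, pw)))
        self.feature_shape = (h, w, in_ch)
        feat = h * w * in_ch

        self.lstm1 = LSTM(feat, cfg.lstm_units, rng, dtype=dtype)
        self.drop1 = Dropout(cfg.dropout, self._dropout_rng)
        self.lstm2 = LSTM(cfg.lstm_units, cfg.lstm_units, rng, dtype=dtype)
        self.drop2 = Dropout(cfg.dropout, self._dropout_rng)
        self.dense1 = Dense(cfg.lstm_units, cfg.dense_units[0], rng, activation="relu", dtype=dtype)
        self.drop3 = Dropout(cfg.dropout, self._dropout_rng)
        self.dense2 = Dense(cfg.dense_units[0], cfg.dense_units[1], rng, activation="relu", dtype=dtype)
        self.drop4 = Dropout(cfg.dropout, self._dropout_rng)
        self.head = Dense(cfg.dense_units[1], cfg.n_classes, rng, activation=None, dtype=dtype)

        self.seq_layers = [
            self.lstm1, self.drop1, self.lstm2, self.drop2,
            self.dense1, self.drop3, self.dense2, self.drop4, self.head,
        ]

    # --- parameter plumbing -------------------------------------------------
    def _trainable(self):
        return [l for l in self.conv_stack + self.seq_layers if l.trainable]

    def params(self) -> list[np.ndarray]:
        return [p for l in self._trainable() for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self._trainable() for g in l.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    def l2_loss(self) -> float:
        return sum(l.l2_loss() for l in self.conv_stack if isinstance(l, Conv2D))

    # --- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[2:] != self.input_shape:
            raise ShapeError(
                f"expected input [n_seq, seq_len, {self.input_shape[0]}, "
                f"{self.input_shape[1]}], received {x.shape}"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """[B, S, T_w, D] windows -> [B, S, K] logits."""
        self._check_input(x)
        B, S = x.shape[:2]
        h = x.reshape(B * S, *self.input_shape, 1).astype(self.cfg.dtype)
        for layer in self.conv_stack:
            h = layer.forward(h, training)
        h = h.reshape(B, S, -1)
        for layer in self.seq_layers:
            h = layer.forward(h, training)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        B, S = dlogits.shape[:2]
        d = dlogits
        for layer in reversed(self.seq_layers):
            d = layer.backward(d)
        d = d.reshape(B * S, *self.feature_shape)
        for layer in reversed(self.conv_stack):
            d = layer.backward(d)

    def predict_logits(self, x: np.ndarray, batch_seqs: int = 8) -> np.ndarray:
        self._check_input(x)
        outs = [
            self.forward(x[i : i + batch_seqs], training=False)
            for i in range(0, x.shape[0], batch_seqs)
        ]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, batch_seqs: int = 8) -> np.ndarray:
        return softmax(self.predict_logits(x, batch_seqs))

    def conv_features(self, x: np.ndarray) -> np.ndarray:
        """Activations of the last convolutional layer, [B*S, h, w, filters]."""
        self._check_input(x)
        B, S = x.shape[:2]
        h = x.reshape(B * S, *self.input_shape, 1).astype(self.cfg.dtype)
        last_conv_out = None
        for layer in self.conv_stack:
            h = layer.forward(h, training=False)
            if isinstance(layer, Conv2D):
                last_conv_out = h
        return last_conv_out


def build_model(cfg: ModelConfig, input_shape: tuple[int, int]) -> ConvLSTMNetwork:
    """Construct the network for windows of ``input_shape`` = (T_w, N*C)."""
    return ConvLSTMNetwork(cfg, input_shape)


def _accuracy(logits: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.argmax(logits, axis=-1) == y))


def train_model(
    net: ConvLSTMNetwork,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    tcfg: TrainConfig,
) -> tuple[ConvLSTMNetwork, list[dict]]:
    """Train with Adam on shuffled whole sequences; keep best-validation weights.

    ``train_data``/``val_data`` are ``(X [n_seq, S, T_w, D], y [n_seq, S])``.
    Returns the network (mutated in place) and a per-epoch history of
    ``{epoch, train_loss, train_acc, val_loss, val_acc}``.
    """
    tcfg.validate()
    X, y = train_data
    if X.shape[0] == 0:
        raise DataError("empty training set")
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(net.params(), lr=net.cfg.learning_rate)
    K = net.cfg.n_classes

    history: list[dict] = []
    best_val = -np.inf
    best_weights = None
    since_best = 0
    for epoch in range(1, tcfg.epochs + 1):
        order = rng.permutation(X.shape[0])
        losses, accs = [], []
        for i in range(0, len(order), tcfg.batch_size):
            idx = order[i : i + tcfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = net.forward(xb, training=True)
            flat_logits = logits.reshape(-1, K)
            flat_y = yb.reshape(-1)
            loss, dflat = softmax_cross_entropy(flat_logits, flat_y)
            loss += net.l2_loss()
            net.backward(dflat.reshape(logits.shape))
            opt.step(net.grads())
            losses.append(loss)
            accs.append(_accuracy(flat_logits, flat_y))
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": float(np.mean(accs)),
            "val_loss": float("nan"),
            "val_acc": float("nan"),
        }
        if val_data is not None and val_data[0].shape[0] > 0:
            vlogits = net.predict_logits(val_data[0])
            vloss, _ = softmax_cross_entropy(
                vlogits.reshape(-1, K), val_data[1].reshape(-1)
            )
            row["val_loss"] = vloss
            row["val_acc"] = _accuracy(
                vlogits.reshape(-1, K), val_data[1].reshape(-1)
            )
            if row["val_acc"] > best_val:
                best_val = row["val_acc"]
                best_weights = net.get_weights()
                since_best = 0
            else:
                since_best += 1
        history.append(row)
        if tcfg.early_stop and since_best >= tcfg.patience:
            break
    if best_weights is not None:
        net.set_weights(best_weights)
    return net, history


def predict(
    net: ConvLSTMNetwork,
    x: np.ndarray,
    y: np.ndarray | None = None,
    subject_ids: np.ndarray | None = None,
) -> PredictionSet:
    """Flatten per-sequence outputs into one row per window.

    Argmax ties break toward the lowest class index (np.argmax semantics).
    """
    probs = net.predict_proba(x).reshape(-1, net.cfg.n_classes)
    pred = np.argmax(probs, axis=1)
    true = None if y is None else np.asarray(y).reshape(-1)
    sids = None
    if subject_ids is not None:
        S = x.shape[1]
        sids = np.repeat(np.asarray(subject_ids, dtype=object), S)
    return PredictionSet(probs=probs, pred=pred, true=true, subject_ids=sids)


def clone_untrained(net: ConvLSTMNetwork) -> ConvLSTMNetwork:
    """Fresh network with the same config and initialization."""
    return ConvLSTMNetwork(copy.deepcopy(net.cfg), net.input_shape)
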