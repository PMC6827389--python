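"""The hybrid window classifier and a linear baseline.

The network consumes the 19x19 neighbourhood window through a stack of
(strided) convolutions and, after flattening, concatenates the two
auxiliary covariates — standardized mean annual temperature and the
one-hot regional outbreak stage — before a stack of fully connected
layers and a final two-unit softmax. Training minimises categorical
cross-entropy with weight decay, dropout and batch normalization;
per-epoch evaluation accuracy is recorded and the weights of the
best-evaluation epoch are the ones kept. The probability threshold is
left to the calibration step (max-F1 on training data).

The default configuration is the full five-convolution / five-dense
architecture; ``ModelConfig.small()`` is a compact variant for
desk-scale experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .dataset import ExampleSet, WINDOW_SIZE

__all__ = [
    "ModelConfig",
    "TrainedClassifier",
    "build_classifier",
    "train",
    "predict_proba",
    "fit_linear_baseline",
]

N_STAGES = 3
N_AUX = 1 + N_STAGES  # temperature + one-hot stage


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation settings.

    ``input_mode`` selects how window codes enter the convolution:
    'channels' expands each cell into three binary planes (host,
    attacked year-1, attacked year-2); 'ordinal' feeds the raw 0..3 code
    as a single plane. Both preserve the 363-variable information
    content of an example.
    """

    conv_channels: tuple[int, ...] = (8, 16, 16, 32, 32)
    conv_strides: tuple[int, ...] = (1, 2, 1, 2, 1)
    kernel_size: int = 3
    dense_widths: tuple[int, ...] = (256, 128, 64, 32, 16)
    dropout_rate: float = 0.2
    weight_decay: float = 1e-4
    batch_norm: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 256
    epochs: int = 60
    input_mode: str = "channels"
    class_weight: bool = False
    seed: int = 0

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_channels)

    @property
    def n_dense_layers(self) -> int:
        return len(self.dense_widths)

    def __post_init__(self) -> None:
        if len(self.conv_strides) != len(self.conv_channels):
            raise ValueError("conv_strides and conv_channels lengths differ")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_mode not in ("channels", "ordinal"):
            raise ValueError("input_mode must be 'channels' or 'ordinal'")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Compact network for CPU-scale experiments and tests."""
        base = dict(
            conv_channels=(8, 16),
            conv_strides=(1, 2),
            dense_widths=(64, 32),
            epochs=8,
            batch_size=512,
            learning_rate=2e-3,
            dropout_rate=0.1,
        )
        base.update(overrides)
        return cls(**base)


class BeetleNet:
    """Two-branch network: conv stack on the window, dense stack on
    [flattened conv features, auxiliary covariates]."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        c_in = 3 if config.input_mode == "channels" else 1
        h = w = WINDOW_SIZE
        self.conv_stack: list[nn.Layer] = []
        for c_out, stride in zip(config.conv_channels, config.conv_strides):
            conv = nn.Conv2D(c_in, c_out, config.kernel_size, stride, rng)
            self.conv_stack.append(conv)
            if config.batch_norm:
                self.conv_stack.append(nn.BatchNorm(c_out))
            self.conv_stack.append(nn.ReLU())
            h, w = conv.out_shape(h, w)
            c_in = c_out
        self.n_img_features = c_in * h * w
        self.flatten = nn.Flatten()
        self.dense_stack: list[nn.Layer] = []
        f_in = self.n_img_features + N_AUX
        for width in config.dense_widths:
            self.dense_stack.append(nn.Dense(f_in, width, rng))
            if config.batch_norm:
                self.dense_stack.append(nn.BatchNorm(width))
            self.dense_stack.append(nn.ReLU())
            if config.dropout_rate > 0:
                self.dense_stack.append(nn.Dropout(config.dropout_rate, rng))
            f_in = width
        self.head = nn.Dense(f_in, 2, rng)

    @property
    def all_layers(self) -> list[nn.Layer]:
        return [*self.conv_stack, self.flatten, *self.dense_stack, self.head]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for lay in self.all_layers for p in lay.params.values()))

    def forward(self, img: np.ndarray, aux: np.ndarray, train: bool) -> np.ndarray:
        x = img
        for lay in self.conv_stack:
            x = lay.forward(x, train)
        x = self.flatten.forward(x, train)
        x = np.concatenate([x, aux.astype(nn.DTYPE)], axis=1)
        for lay in self.dense_stack:
            x = lay.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        for lay in reversed(self.dense_stack):
            d = lay.backward(d)
        d = d[:, : self.n_img_features]
        d = self.flatten.backward(d)
        for lay in reversed(self.conv_stack):
            d = lay.backward(d)

    def state(self) -> list[dict]:
        return [lay.state() for lay in self.all_layers]

    def load_state(self, state: list[dict]) -> None:
        for lay, s in zip(self.all_layers, state):
            lay.load_state(s)


def build_classifier(config: ModelConfig) -> BeetleNet:
    """Instantiate an untrained network; identical seeds give identical weights."""
    return BeetleNet(config)


@dataclass
class FeatureEncoder:
    """Turns stored examples into network inputs.

    Temperature is z-scored with statistics fitted on the training set;
    the outbreak stage enters one-hot.
    """

    input_mode: str = "channels"
    temp_mean: float = 0.0
    temp_sd: float = 1.0

    def fit(self, example_set: ExampleSet) -> "FeatureEncoder":
        t = example_set.temperature.astype(np.float64)
        self.temp_mean = float(t.mean())
        self.temp_sd = float(t.std()) or 1.0
        return self

    def encode(self, windows: np.ndarray, temperature: np.ndarray, stage: np.ndarray):
        if self.input_mode == "channels":
            img = np.stack(
                [windows >= 1, windows == 3, windows == 2], axis=1
            ).astype(nn.DTYPE)
        else:
            img = windows[:, None, :, :].astype(nn.DTYPE)
        tz = (temperature.astype(np.float64) - self.temp_mean) / self.temp_sd
        onehot = np.eye(N_STAGES, dtype=nn.DTYPE)[stage.astype(int)]
        aux = np.column_stack([tz.astype(nn.DTYPE), onehot])
        return img, aux

    def encode_set(self, example_set: ExampleSet, idx=None):
        if idx is None:
            return self.encode(
                example_set.windows, example_set.temperature, example_set.stage
            )
        return self.encode(
            example_set.windows[idx], example_set.temperature[idx], example_set.stage[idx]
        )


@dataclass
class TrainedClassifier:
    config: ModelConfig
    network: BeetleNet
    encoder: FeatureEncoder
    history: list[dict]
    selected_epoch: int  # 1-based index of the best evaluation accuracy
    threshold: float = float("nan")  # set by calibration

    def predict_proba(self, example_set: ExampleSet) -> np.ndarray:
        return predict_proba(self, example_set)

    def predict(self, example_set: ExampleSet) -> np.ndarray:
        if not np.isfinite(self.threshold):
            raise ValueError("classifier has no calibrated threshold yet")
        return (self.predict_proba(example_set) >= self.threshold).astype(np.int8)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for i, s in enumerate(self.network.state()):
            for k, v in s.items():
                arrays[f"layer{i}/{k}"] = v
        arrays["history_json"] = np.frombuffer(
            json.dumps(self.history).encode(), dtype=np.uint8
        )
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        arrays["scalars"] = np.array(
            [self.selected_epoch, self.threshold, self.encoder.temp_mean, self.encoder.temp_sd]
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with np.load(path) as z:
            cfg_d = json.loads(bytes(z["config_json"]).decode())
            for key in ("conv_channels", "conv_strides", "dense_widths"):
                cfg_d[key] = tuple(cfg_d[key])
            config = ModelConfig(**cfg_d)
            history = json.loads(bytes(z["history_json"]).decode())
            sel, thr, tmean, tsd = z["scalars"]
            net = BeetleNet(config)
            state = [dict() for _ in net.all_layers]
            for name in z.files:
                if name.startswith("layer"):
                    i, k = name.split("/", 1)
                    state[int(i[5:])][k] = z[name]
            net.load_state(state)
        enc = FeatureEncoder(config.input_mode, float(tmean), float(tsd))
        return cls(config, net, enc, history, int(sel), float(thr))


def _check_two_classes(example_set: ExampleSet, what: str) -> None:
    n_pos, n_neg = example_set.class_counts
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"{what} contains a single class (positives={n_pos})")


def train(
    classifier: BeetleNet,
    train_set: ExampleSet,
    eval_set: ExampleSet,
    config: ModelConfig | None = None,
) -> TrainedClassifier:
    """Train with AdamW on cross-entropy; keep the best-evaluation-epoch weights.

    History records per-epoch mean training loss and evaluation accuracy
    (argmax rule). Fully reproducible for a fixed config seed.
    """
    config = config or classifier.config
    _check_two_classes(train_set, "training set")
    encoder = FeatureEncoder(config.input_mode).fit(train_set)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    opt = nn.AdamW(
        classifier.all_layers, lr=config.learning_rate, weight_decay=config.weight_decay
    )
    labels = train_set.labels.astype(np.int64)
    if config.class_weight:
        n_pos, n_neg = train_set.class_counts
        w_by_class = np.array([0.5 / n_neg, 0.5 / n_pos]) * len(train_set)
    n = len(train_set)
    history: list[dict] = []
    best_acc, best_state, best_epoch = -1.0, None, 0
    trained = TrainedClassifier(config, classifier, encoder, history, 0)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            img, aux = encoder.encode_set(train_set, idx)
            logits = classifier.forward(img, aux, train=True)
            sw = w_by_class[labels[idx]] if config.class_weight else None
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx], sw)
            classifier.backward(dlogits)
            opt.step()
            losses.append(loss)
        probs = predict_proba(trained, eval_set)
        acc = float(np.mean((probs >= 0.5).astype(np.int8) == eval_set.labels))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "eval_accuracy": acc}
        )
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_state = classifier.state()
    classifier.load_state(best_state)
    trained.selected_epoch = best_epoch
    return trained


def predict_proba(trained: TrainedClassifier, example_set: ExampleSet,
                  batch_size: int = 4096) -> np.ndarray:
    """Attack probability per example (softmax positive-class output).

    Deterministic: dropout off, batch norm in inference mode.
    """
    out = np.empty(len(example_set), dtype=np.float64)
    for start in range(0, len(example_set), batch_size):
        idx = np.arange(start, min(start + batch_size, len(example_set)))
        img, aux = trained.encoder.encode_set(example_set, idx)
        logits = trained.network.forward(img, aux, train=False)
        out[idx] = nn.softmax(logits.astype(np.float64))[:, 1]
    return out


# -- linear baseline --------------------------------------------------------


class LinearBaseline:
    """Logistic regression on the 363 flattened inputs (stage one-hot expanded).

    The comparison model: a single linear decision function over the raw
    window codes plus the auxiliary covariates.
    """

    def __init__(self, sk_model, encoder: FeatureEncoder):
        self._model = sk_model
        self.encoder = encoder
        self.threshold = float("nan")

    def _features(self, example_set: ExampleSet) -> np.ndarray:
        n = len(example_set)
        tz = (
            example_set.temperature.astype(np.float64) - self.encoder.temp_mean
        ) / self.encoder.temp_sd
        onehot = np.eye(N_STAGES)[example_set.stage.astype(int)]
        return np.column_stack(
            [example_set.windows.reshape(n, -1).astype(np.float64), tz, onehot]
        )

    def predict_proba(self, example_set: ExampleSet) -> np.ndarray:
        return self._model.predict_proba(self._features(example_set))[:, 1]

    def predict(self, example_set: ExampleSet) -> np.ndarray:
        if not np.isfinite(self.threshold):
            raise ValueError("baseline has no calibrated threshold yet")
        return (self.predict_proba(example_set) >= self.threshold).astype(np.int8)


def fit_linear_baseline(train_set: ExampleSet, config: ModelConfig | None = None) -> LinearBaseline:
    from sklearn.linear_model import LogisticRegression

    _check_two_classes(train_set, "training set")
    seed = config.seed if config is not None else 0
    encoder = FeatureEncoder("ordinal").fit(train_set)
    baseline = LinearBaseline(
        LogisticRegression(max_iter=1000, random_state=seed), encoder
    )
    X = baseline._features(train_set)
    baseline._model.fit(X, train_set.labels.astype(int))
    return baseline
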