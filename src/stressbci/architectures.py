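"""The seven multiclass deep architectures and their trainer.

All models consume 16-channel EEG windows (condition classes: baseline,
stressor, unguided, guided breathing) and emit 4 softmax scores:

* ``lstm1`` / ``lstm2`` / ``lstm3`` — recurrent stacks of 50 / 50+40 /
  50+40+40 LSTM units over the window read as a sequence of 16-dim channel
  vectors, then dropout 0.5, dense 20 (sigmoid), dropout 0.5, dense 10
  (ReLU), dense 4 (softmax).
* ``deep_convnet`` — four convolution-max-pool blocks (temporal (1,5)
  kernels; the first block adds a spatial convolution spanning all 16
  channels) with 25, 50, 100, 200 filters, then a dense softmax head.
* ``shallow_convnet`` — the first block only, with a larger temporal kernel
  of 13, followed by a squaring nonlinearity, average pooling and a log
  activation: a learnable analogue of band-power + CSP features.
* ``eegnet`` — 8 temporal filters of length 64, a depthwise spatial
  convolution spanning the 16 channels (depth multiplier 2), a separable
  convolution of length 16, batch-norm/ELU/average-pool/dropout throughout.
* ``lstm_fcn`` — a parallel 8-unit LSTM branch (dropout 0.8) and a
  temporal-convolution branch of 128/256/128 filters with kernels 8/5/3
  (batch-norm + ReLU each, global average pool), concatenated into the
  softmax head.

Training uses Adam (learning rate 0.001), batch size 200, categorical
cross-entropy. The study-scale schedule is 1000 epochs; the package default
is a desk-scale 100 (see :class:`TrainingConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AsConvInput,
    AvgPool2D,
    BatchNorm,
    Conv2D,
    Dense,
    DepthwiseConv2D,
    Dropout,
    ELU,
    Flatten,
    GlobalAvgPool2D,
    LSTM,
    MaxPool2D,
    Network,
    Parallel,
    ReLU,
    SafeLog,
    Sequential,
    Sigmoid,
    Square,
    Transpose,
    fit,
)
from .preprocess import WindowSet

DEEP_FAMILIES = (
    "lstm1", "lstm2", "lstm3",
    "deep_convnet", "shallow_convnet", "eegnet", "lstm_fcn",
)

N_CLASSES = 4


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one model family."""

    family: str
    input_shape: tuple[int, int] = (16, 125)  # (channels, samples)
    n_classes: int = N_CLASSES
    hyper: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in DEEP_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_classes != N_CLASSES:
            raise ValueError("these architectures are fixed at 4 classes")


@dataclass(frozen=True)
class TrainingConfig:
    """Adam / cross-entropy training hyperparameters.

    ``epochs`` defaults to a desk-scale 100; ``full_fidelity()`` restores
    the study-scale 1000.
    """

    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 200
    seed: int = 0
    standardize: bool = True  # per-window channel-wise z-scoring

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def full_fidelity(cls, **kw) -> "TrainingConfig":
        return cls(epochs=1000, **kw)


def build_lstm_rnn(n_layers: int, input_shape=(16, 125)) -> ArchitectureSpec:
    if n_layers not in (1, 2, 3):
        raise ValueError(f"n_layers must be 1, 2 or 3, got {n_layers}")
    widths = [50, 40, 40][:n_layers]
    return ArchitectureSpec(
        family=f"lstm{n_layers}",
        input_shape=tuple(input_shape),
        hyper={
            "lstm_widths": widths,
            "dense": [(20, "sigmoid"), (10, "relu")],
            "dropout": 0.5,
        },
    )


def build_deep_convnet(input_shape=(16, 125)) -> ArchitectureSpec:
    spec = ArchitectureSpec(
        family="deep_convnet",
        input_shape=tuple(input_shape),
        hyper={
            "filters": [25, 50, 100, 200],
            "temporal_kernel": 5,
            "pool": 2,
        },
    )
    _conv_cascade_width(spec)  # validates the window length
    return spec


def build_shallow_convnet(input_shape=(16, 125)) -> ArchitectureSpec:
    spec = ArchitectureSpec(
        family="shallow_convnet",
        input_shape=tuple(input_shape),
        hyper={
            "filters": 25,
            "temporal_kernel": 13,
            "max_pool": 2,
            "avg_pool": 8,
        },
    )
    _conv_cascade_width(spec)
    return spec


def build_eegnet(input_shape=(16, 125)) -> ArchitectureSpec:
    spec = ArchitectureSpec(
        family="eegnet",
        input_shape=tuple(input_shape),
        hyper={
            "temporal_filters": 8,
            "temporal_kernel": 64,
            "depth_multiplier": 2,
            "separable_filters": 16,
            "separable_kernel": 16,
            "pools": (4, 8),
            "dropout": 0.5,
        },
    )
    _conv_cascade_width(spec)
    return spec


def build_lstm_fcn(input_shape=(16, 125)) -> ArchitectureSpec:
    return ArchitectureSpec(
        family="lstm_fcn",
        input_shape=tuple(input_shape),
        hyper={
            "lstm_units": 8,
            "lstm_dropout": 0.8,
            "conv_filters": [128, 256, 128],
            "conv_kernels": [8, 5, 3],
        },
    )


def build_architecture(family: str, input_shape=(16, 125)) -> ArchitectureSpec:
    builders = {
        "lstm1": lambda s: build_lstm_rnn(1, s),
        "lstm2": lambda s: build_lstm_rnn(2, s),
        "lstm3": lambda s: build_lstm_rnn(3, s),
        "deep_convnet": build_deep_convnet,
        "shallow_convnet": build_shallow_convnet,
        "eegnet": build_eegnet,
        "lstm_fcn": build_lstm_fcn,
    }
    if family not in builders:
        raise ValueError(f"unknown family {family!r}")
    return builders[family](input_shape)


def _cascade_width(family: str, hyper: dict, t: int) -> int | None:
    """Final temporal width after a family's conv/pool cascade, or ``None``
    if a ``t``-sample window cannot traverse it."""
    w = t
    if family == "deep_convnet":
        for _ in hyper["filters"]:
            w = (w - (hyper["temporal_kernel"] - 1)) // hyper["pool"]
            if w < 1:
                return None
    elif family == "shallow_convnet":
        w = ((w - (hyper["temporal_kernel"] - 1)) // hyper["max_pool"])
        w = w // hyper["avg_pool"] if w >= 1 else 0
        if w < 1:
            return None
    elif family == "eegnet":
        # temporal and separable convolutions are 'same'-padded
        w = (w // hyper["pools"][0]) // hyper["pools"][1]
        if w < 1:
            return None
    else:
        raise AssertionError(family)
    return w


def _conv_cascade_width(spec: ArchitectureSpec) -> int:
    """Width after the cascade; raises with the minimum usable length if the
    window is too short."""
    t = spec.input_shape[1]
    w = _cascade_width(spec.family, spec.hyper, t)
    if w is None:
        minimum = next(
            n for n in range(1, 4096)
            if _cascade_width(spec.family, spec.hyper, n) is not None
        )
        raise ValueError(
            f"{spec.family}: window of {t} samples is too short for the "
            f"pooling cascade; minimum length is {minimum} samples"
        )
    return w


def instantiate(spec: ArchitectureSpec, seed: int = 0) -> Network:
    """Materialize a spec into an initialized :class:`~stressbci.nn.Network`."""
    rng = np.random.default_rng([seed, 0xDEE9])
    n_ch, t = spec.input_shape
    h = spec.hyper

    if spec.family in ("lstm1", "lstm2", "lstm3"):
        widths = h["lstm_widths"]
        layers = [Transpose((0, 2, 1))]
        d = n_ch
        for li, w in enumerate(widths):
            layers.append(
                LSTM(d, w, rng=rng, return_sequences=li < len(widths) - 1)
            )
            d = w
        layers.append(Dropout(h["dropout"], rng=rng))
        layers += [Dense(d, 20, rng=rng), Sigmoid(), Dropout(h["dropout"], rng=rng)]
        layers += [Dense(20, 10, rng=rng), ReLU(), Dense(10, spec.n_classes, rng=rng)]
        return Network(Sequential(layers), spec.n_classes)

    if spec.family == "deep_convnet":
        f = h["filters"]
        k, pool = h["temporal_kernel"], h["pool"]
        layers = [
            AsConvInput(maps=False),
            Conv2D(1, f[0], 1, k, rng=rng),
            Conv2D(f[0], f[0], n_ch, 1, rng=rng),
            ELU(),
            MaxPool2D(1, pool),
        ]
        for c_in, c_out in zip(f, f[1:]):
            layers += [Conv2D(c_in, c_out, 1, k, rng=rng), ELU(), MaxPool2D(1, pool)]
        w = _conv_cascade_width(spec)
        layers += [Flatten(), Dense(f[-1] * w, spec.n_classes, rng=rng)]
        return Network(Sequential(layers), spec.n_classes)

    if spec.family == "shallow_convnet":
        f, k = h["filters"], h["temporal_kernel"]
        w = _conv_cascade_width(spec)
        layers = [
            AsConvInput(maps=False),
            Conv2D(1, f, 1, k, rng=rng),
            Conv2D(f, f, n_ch, 1, rng=rng),
            MaxPool2D(1, h["max_pool"]),
            Square(),
            AvgPool2D(1, h["avg_pool"]),
            SafeLog(),
            Flatten(),
            Dense(f * w, spec.n_classes, rng=rng),
        ]
        return Network(Sequential(layers), spec.n_classes)

    if spec.family == "eegnet":
        f1, kt = h["temporal_filters"], h["temporal_kernel"]
        dmult, f2, ks = h["depth_multiplier"], h["separable_filters"], h["separable_kernel"]
        p1, p2 = h["pools"]
        fd = f1 * dmult
        w = _conv_cascade_width(spec)
        layers = [
            AsConvInput(maps=False),
            Conv2D(1, f1, 1, kt, rng=rng, bias=False, padding="same"),
            BatchNorm(f1),
            DepthwiseConv2D(f1, dmult, n_ch, 1, rng=rng),
            BatchNorm(fd),
            ELU(),
            AvgPool2D(1, p1),
            Dropout(h["dropout"], rng=rng),
            DepthwiseConv2D(fd, 1, 1, ks, rng=rng, padding="same"),
            Conv2D(fd, f2, 1, 1, rng=rng, bias=False),
            BatchNorm(f2),
            ELU(),
            AvgPool2D(1, p2),
            Dropout(h["dropout"], rng=rng),
            Flatten(),
            Dense(f2 * w, spec.n_classes, rng=rng),
        ]
        return Network(Sequential(layers), spec.n_classes)

    if spec.family == "lstm_fcn":
        units = h["lstm_units"]
        lstm_branch = Sequential([
            Transpose((0, 2, 1)),
            LSTM(n_ch, units, rng=rng),
            Dropout(h["lstm_dropout"], rng=rng),
        ])
        conv_layers = [AsConvInput(maps=True)]
        c_in = n_ch
        for f, k in zip(h["conv_filters"], h["conv_kernels"]):
            conv_layers += [
                Conv2D(c_in, f, 1, k, rng=rng, bias=False, padding="same"),
                BatchNorm(f),
                ReLU(),
            ]
            c_in = f
        conv_layers.append(GlobalAvgPool2D())
        root = Sequential([
            Parallel([lstm_branch, Sequential(conv_layers)]),
            Dense(units + h["conv_filters"][-1], spec.n_classes, rng=rng),
        ])
        return Network(root, spec.n_classes)

    raise AssertionError(spec.family)


@dataclass
class TrainedModel:
    """A fitted network, its spec, config and per-epoch training history."""

    spec: ArchitectureSpec
    network: Network
    config: TrainingConfig
    history: dict


def _prepare(ws: WindowSet, config: TrainingConfig) -> np.ndarray:
    x = ws.standardized().windows if config.standardize else ws.windows
    return x


def train_model(
    spec: ArchitectureSpec, config: TrainingConfig, train_ws: WindowSet
) -> TrainedModel:
    """Seeded training of one architecture on a labeled window set."""
    counts = np.bincount(train_ws.labels, minlength=spec.n_classes)
    if (counts == 0).any():
        missing = [train_ws.label_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"training set lacks windows for: {', '.join(missing)}")
    net = instantiate(spec, seed=config.seed)
    x = _prepare(train_ws, config)
    if x.shape[1:] != spec.input_shape:
        raise ValueError(
            f"windows of shape {x.shape[1:]} do not match spec input "
            f"{spec.input_shape}"
        )
    history = fit(
        net, x, train_ws.labels,
        epochs=config.epochs, batch_size=config.batch_size,
        lr=config.learning_rate, seed=config.seed,
    )
    return TrainedModel(spec=spec, network=net, config=config, history=history)


def predict(model: TrainedModel, ws: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-window class scores (rows sum to 1) and argmax labels."""
    x = _prepare(ws, model.config)
    if x.shape[1:] != model.spec.input_shape:
        raise ValueError(
            f"windows of shape {x.shape[1:]} do not match model input "
            f"{model.spec.input_shape}"
        )
    scores = model.network.predict_proba(x)
    return scores, np.argmax(scores, axis=1)


def evaluate(model: TrainedModel, ws: WindowSet) -> float:
    """Holdout accuracy of a trained model on a labeled window set."""
    _, pred = predict(model, ws)
    return float(np.mean(pred == ws.labels))
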