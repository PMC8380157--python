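"""3D convolutional feature extractor.

Six-convolution backbone for single-channel brain volumes: Conv1 (1x1x1)
and Conv2 (3x3x3) widen the features at full resolution, a 2x2x2 max-pool
halves each axis, then three [Conv 3x3x3 -> channel attention -> pool]
blocks deepen the representation, and Conv6 (3x3x3, no padding) followed by
global average pooling yields the embedding vector fed to the SVM head.
Every convolution is followed by normalization (instance by default, batch
as an ablation) and ReLU.  A temporary dropout + fully connected head with
two units is attached only for supervised pretraining.

Training uses plain SGD on label-smoothed cross-entropy with gradients
accumulated over several mini-batches and applied as their average — the
small-batch regime 3D volumes force.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import yaml

from . import nn
from .volumes_io import Dataset, Volume

FULL_INPUT = (80, 100, 76)
N_CONV = 6
MIN_AXIS = 16  # four 2x halvings must stay >= 1


class ConfigurationError(ValueError):
    """Architecture cannot be instantiated for the requested input shape."""


@dataclass
class BackboneConfig:
    conv_channels: tuple = (32, 64, 128, 256, 512, 512)
    conv_kernels: tuple = ((1, 1, 1), (3, 3, 3), (3, 3, 3), (3, 3, 3), (3, 3, 3), (3, 3, 3))
    input_shape: tuple = FULL_INPUT
    attention_enabled: bool = True
    attention_ratio: int = 16
    norm_kind: str = "instance"
    dropout_rate: float = 0.5
    label_smoothing: float = 0.1
    num_pretrain_classes: int = 2
    conv6_padding: str = "valid"

    def __post_init__(self) -> None:
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        self.conv_kernels = tuple(tuple(int(k) for k in ks) for ks in self.conv_kernels)
        self.input_shape = tuple(int(s) for s in self.input_shape)
        if len(self.conv_channels) != N_CONV or len(self.conv_kernels) != N_CONV:
            raise ConfigurationError("need exactly 6 conv channel counts and kernels")
        if self.norm_kind not in ("instance", "batch"):
            raise ConfigurationError(f"norm_kind must be instance|batch, got {self.norm_kind!r}")
        if self.conv6_padding not in ("valid", "same"):
            raise ConfigurationError("conv6_padding must be valid|same")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ConfigurationError("label_smoothing must be in [0, 1)")
        if self.attention_enabled:
            for ch in self.conv_channels[2:5]:
                if ch // self.attention_ratio < 1:
                    raise ConfigurationError(
                        f"attention_ratio {self.attention_ratio} reduces {ch} channels below 1")

    @property
    def embedding_dim(self) -> int:
        return self.conv_channels[-1]


def desk_config(**overrides) -> BackboneConfig:
    """Reduced-width preset for CPU-scale experiments on (32, 40, 30) grids.

    Narrow channels, a same-padded Conv6 (the desk grid leaves (2, 2, 1)
    after the four poolings, too small for a 3x3x3 valid convolution), and
    no dropout — a 0.5 rate on a 32-d embedding starves the pretraining
    head, where on the 512-d full model it is ordinary regularization.
    """
    base = dict(conv_channels=(4, 8, 16, 32, 32, 32), input_shape=(32, 40, 30),
                attention_ratio=4, conv6_padding="same", dropout_rate=0.0)
    base.update(overrides)
    return BackboneConfig(**base)


# positions: pool after conv2..conv5; attention after conv3..conv5
_POOL_AFTER = (1, 2, 3, 4)
_ATTENTION_AFTER = (2, 3, 4)


def forward_shapes(cfg: BackboneConfig, input_shape: tuple | None = None) -> list:
    """Symbolic per-layer output shapes, mirroring the architecture table.

    ``input_shape`` is (1, d, h, w).  Returns [(layer_name, (C, d, h, w)), ...]
    from the input row through GAP, Flatten and the pretraining FC head.
    Raises ConfigurationError where the stack cannot be instantiated.
    """
    if input_shape is None:
        input_shape = (1, *cfg.input_shape)
    c, *spatial = input_shape
    if c != 1:
        raise ConfigurationError("backbone expects single-channel input")
    spatial = tuple(int(s) for s in spatial)
    if any(s < MIN_AXIS for s in spatial):
        raise ConfigurationError(
            f"input axes {spatial} below {MIN_AXIS}: four 2x poolings impossible")
    rows = [("Input", (1, *spatial))]
    for i in range(N_CONV):
        pad = cfg.conv6_padding if i == N_CONV - 1 else "same"
        k = cfg.conv_kernels[i]
        if pad == "valid":
            new = tuple(s - kk + 1 for s, kk in zip(spatial, k))
            if any(s < 1 for s in new):
                raise ConfigurationError(
                    f"Conv{i + 1} (valid, kernel {k}) infeasible on spatial {spatial}")
            spatial = new
        rows.append((f"Conv{i + 1}", (cfg.conv_channels[i], *spatial)))
        if cfg.attention_enabled and i in _ATTENTION_AFTER:
            rows.append(("Attention", (cfg.conv_channels[i], *spatial)))
        if i in _POOL_AFTER:
            spatial = tuple(s // 2 for s in spatial)
            if any(s < 1 for s in spatial):
                raise ConfigurationError(f"pooling after Conv{i + 1} empties an axis")
            rows.append(("MaxPool3D", (cfg.conv_channels[i], *spatial)))
    rows.append(("GAP", (cfg.conv_channels[-1], 1, 1, 1)))
    rows.append(("Flatten", (cfg.conv_channels[-1],)))
    rows.append(("FC", (cfg.num_pretrain_classes,)))
    return rows


class Backbone3D:
    """Concrete feature extractor with an optional pretraining FC head."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0) -> None:
        forward_shapes(cfg)  # surfaces configuration errors at build time
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        norm_cls = nn.InstanceNorm3d if cfg.norm_kind == "instance" else nn.BatchNorm3d
        layers: list[nn.Layer] = []
        in_ch = 1
        for i in range(N_CONV):
            pad = cfg.conv6_padding if i == N_CONV - 1 else "same"
            layers.append(nn.Conv3d(in_ch, cfg.conv_channels[i], cfg.conv_kernels[i], pad, rng))
            layers.append(norm_cls(cfg.conv_channels[i]))
            layers.append(nn.ReLU())
            if cfg.attention_enabled and i in _ATTENTION_AFTER:
                layers.append(nn.ChannelAttention(cfg.conv_channels[i], cfg.attention_ratio, rng))
            if i in _POOL_AFTER:
                layers.append(nn.MaxPool3d())
            in_ch = cfg.conv_channels[i]
        layers.append(nn.GlobalAvgPool())
        self.feature_layers = layers
        self.dropout = nn.Dropout(cfg.dropout_rate, self._dropout_rng)
        self.fc = nn.Linear(cfg.embedding_dim, cfg.num_pretrain_classes, rng)

    # -- forward / backward ------------------------------------------------
    @property
    def dtype(self):
        return self.feature_layers[0].params["w"].dtype

    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, 1, d, h, w) -> (N, embedding_dim)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        for layer in self.feature_layers:
            x = layer.forward(x, training)
        return x

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        emb = self.features(x, training)
        return self.fc.forward(self.dropout.forward(emb, training), training)

    def backward_from_embedding(self, g_emb: np.ndarray) -> None:
        g = np.ascontiguousarray(g_emb, dtype=self.dtype)
        for layer in reversed(self.feature_layers):
            g = layer.backward(g)

    def backward_from_logits(self, g_logits: np.ndarray) -> None:
        g = self.dropout.backward(self.fc.backward(g_logits))
        self.backward_from_embedding(g)

    # -- parameter plumbing ------------------------------------------------
    def feature_parameter_layers(self) -> list[nn.Layer]:
        return [l for l in self.feature_layers if l.params]

    def all_parameter_layers(self) -> list[nn.Layer]:
        return self.feature_parameter_layers() + [self.fc]

    def n_conv_layers(self) -> int:
        return sum(isinstance(l, nn.Conv3d) for l in self.feature_layers)

    def has_attention_params(self) -> bool:
        return any(isinstance(l, nn.ChannelAttention) for l in self.feature_layers)

    def parameter_bytes(self) -> bytes:
        """Canonical serialization of all feature parameters (checksum basis)."""
        buf = io.BytesIO()
        for i, layer in enumerate(self.feature_layers):
            for k in sorted(layer.params):
                buf.write(layer.params[k].tobytes())
        return buf.getvalue()


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> Backbone3D:
    """Instantiate the feature extractor; configuration errors surface here."""
    return Backbone3D(cfg, seed)


def _stack(samples) -> np.ndarray:
    return np.stack([s.volume.data for s in samples])[:, None, :, :, :]


def extract_embedding(model: Backbone3D, v: Volume) -> np.ndarray:
    """Evaluation-mode embedding of a single volume (length embedding_dim)."""
    if tuple(v.shape) != tuple(model.cfg.input_shape):
        raise ValueError(f"volume shape {v.shape} != model input {model.cfg.input_shape}")
    return model.features(v.data[None, None], training=False)[0]


def extract_embeddings(model: Backbone3D, data, batch_size: int = 8) -> np.ndarray:
    """Evaluation-mode embeddings for an iterable of samples, (n, dim)."""
    samples = list(data)
    out = []
    for i in range(0, len(samples), batch_size):
        out.append(model.features(_stack(samples[i:i + batch_size]), training=False))
    return np.concatenate(out, axis=0)


@dataclass
class TrainOptions:
    """Optimizer settings for supervised (pre)training.

    ``lr_decay`` multiplies the learning rate after every epoch (1.0 keeps
    it constant).  Two optional "until converged" rules with ``epochs`` as
    the cap and ``min_epochs`` as the floor: ``converge_tol`` > 0 stops once
    an epoch improves the mean loss by less than that relative fraction;
    ``stop_acc`` stops after two consecutive epochs whose training accuracy
    reaches that level (two, so a single lucky epoch mid-oscillation does
    not end training).
    """

    epochs: int = 10
    lr: float = 1e-3
    momentum: float = 0.0
    batch_size: int = 4
    accum_batches: int = 4  # parameter update every `accum_batches` mini-batches
    lr_decay: float = 1.0
    converge_tol: float = 0.0  # early stop when relative epoch-loss improvement falls below
    min_epochs: int = 1
    stop_acc: float | None = None  # early stop after 2 consecutive epochs at/above this accuracy


def _binary_targets(data: Dataset, pos_label: str | None = None):
    labels = sorted({s.label for s in data})
    if len(labels) != 2:
        raise ValueError(f"binary training needs exactly 2 classes, got {labels}")
    if pos_label is None:
        pos_label = labels[-1]
    if pos_label not in labels:
        raise ValueError(f"positive label {pos_label!r} not present in data")
    y = np.array([1 if s.label == pos_label else 0 for s in data], dtype=int)
    return y, pos_label


def pretrain(model: Backbone3D, train_set: Dataset, opts: TrainOptions,
             seed: int, pos_label: str | None = None) -> list[float]:
    """Train backbone + FC head with label-smoothed cross-entropy.

    Gradients are accumulated over ``accum_batches`` mini-batches of
    ``batch_size`` samples and applied as their average.  Returns the
    per-epoch mean training loss.  Fully deterministic given ``seed``.
    """
    y, _ = _binary_targets(train_set, pos_label)
    samples = list(train_set)
    rng = np.random.default_rng(seed)
    opt = nn.SGD(model.all_parameter_layers(), lr=opts.lr, momentum=opts.momentum)
    history: list[float] = []
    acc_streak = 0
    for epoch in range(opts.epochs):
        opt.lr = opts.lr * opts.lr_decay ** epoch
        order = rng.permutation(len(samples))
        losses: list[float] = []
        correct = 0
        opt.zero_grad()
        pending = 0
        for start in range(0, len(order), opts.batch_size):
            idx = order[start:start + opts.batch_size]
            xb = _stack([samples[i] for i in idx])
            logits = model.logits(xb, training=True)
            correct += int(((logits[:, 1] > logits[:, 0]) == (y[idx] == 1)).sum())
            loss, g = nn.softmax_cross_entropy(logits, y[idx], model.cfg.label_smoothing)
            model.backward_from_logits(g)
            losses.append(loss)
            pending += 1
            if pending == opts.accum_batches:
                opt.step(scale=1.0 / pending)
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step(scale=1.0 / pending)
            opt.zero_grad()
        history.append(float(np.mean(losses)))
        acc_streak = acc_streak + 1 \
            if opts.stop_acc and correct / len(samples) >= opts.stop_acc else 0
        if epoch + 1 >= opts.min_epochs:
            if acc_streak >= 2:
                break
            if (opts.converge_tol > 0 and len(history) > 1
                    and history[-2] - history[-1] <= opts.converge_tol * abs(history[-2])):
                break
    return history


# -- checkpoints -----------------------------------------------------------

def save_backbone(model: Backbone3D, path) -> None:
    """Serialize config + parameters (+ batch-norm running stats) to .npz."""
    arrays = {}
    for i, layer in enumerate(model.feature_layers):
        for k, v in layer.params.items():
            arrays[f"feat{i}:{k}"] = v
        if isinstance(layer, nn.BatchNorm3d):
            arrays[f"feat{i}:running_mean"] = layer.running_mean
            arrays[f"feat{i}:running_var"] = layer.running_var
    for k, v in model.fc.params.items():
        arrays[f"fc:{k}"] = v
    def plain(v):
        return [plain(x) for x in v] if isinstance(v, tuple) else v

    cfg_yaml = yaml.safe_dump({**{k: plain(v) for k, v in model.cfg.__dict__.items()},
                               "seed": model.seed})
    np.savez(path, __config__=np.frombuffer(cfg_yaml.encode(), dtype=np.uint8), **arrays)


def load_backbone(path) -> Backbone3D:
    with np.load(path) as z:
        doc = yaml.safe_load(bytes(z["__config__"]).decode())
        seed = doc.pop("seed", 0)
        cfg = BackboneConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in doc.items()})
        model = Backbone3D(cfg, seed)
        for i, layer in enumerate(model.feature_layers):
            for k in layer.params:
                layer.params[k][...] = z[f"feat{i}:{k}"]
            if isinstance(layer, nn.BatchNorm3d):
                layer.running_mean[...] = z[f"feat{i}:running_mean"]
                layer.running_var[...] = z[f"feat{i}:running_var"]
        for k in model.fc.params:
            model.fc.params[k][...] = z[f"fc:{k}"]
    return model
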