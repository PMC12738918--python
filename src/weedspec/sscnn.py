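"""The spectral-spatial CNN (SS-CNN), its ablation variants, training and inference.

The full model consumes a ``(w, w, B, 1)`` patch of the band-reduced cube and
chains three 3-D convolutions (kernels (3,3,7), (3,3,5), (3,3,3); 8/16/32
filters) that learn joint spectral-spatial features, reshapes the remaining
spectral positions into channels, then four 3x3 2-D convolutions (32/64/128/256
filters) for spatial abstraction, a squeeze-and-excitation (SE) channel gate,
and a two-layer dense head with dropout feeding an n-class softmax.

Ablation variants:

========  ===========  =========  ====================
variant   3-D + 2-D    SE gate    superpixel smoothing
========  ===========  =========  ====================
SS        both         yes        yes
SD        both         no         yes
SE        both         yes        no
CNN3D     3-D only     no         no
CNN2D     2-D only     no         no
========  ===========  =========  ====================

``build_model`` computes the full layer chain, output shapes and parameter
counts from first principles (valid convolutions, channels-last); any
inconsistent chain raises rather than silently passing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .errors import ConstructionError, EmptySelectionError, ParameterError, ShapeMismatchError
from .patch_dataset import PatchSet, SplitSpec, extract_patches, split_train_test
from .superpixel import ReducedCube, SuperpixelMap, superpixel_smooth

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "LayerInfo",
    "ModelSpec",
    "softsign",
    "build_model",
    "build_network",
    "TrainedModel",
    "train",
    "predict_map",
    "ablation_suite",
]

VARIANTS = ("SS", "SD", "SE", "CNN3D", "CNN2D")

softsign = nn.softsign


@dataclass(frozen=True)
class ModelConfig:
    """Declarative hyperparameters of an SS-CNN variant.

    Defaults mirror the full-scale architecture (25x25 window, 25 reduced
    bands, 36-way head for the 35-weed-species + rice catalogue, Adam at
    lr 1e-4, 50 epochs, mini-batches of 32, dropout 0.4).
    """

    variant: str = "SS"
    window: int = 25
    bands: int = 25
    n_classes: int = 36
    conv3d_filters: tuple[int, ...] = (8, 16, 32)
    conv3d_kernels: tuple[tuple[int, int, int], ...] = ((3, 3, 7), (3, 3, 5), (3, 3, 3))
    conv2d_filters: tuple[int, ...] = (32, 64, 128, 256)
    conv2d_kernel: tuple[int, int] = (3, 3)
    dense_units: tuple[int, ...] = (256, 128)
    dropout: float = 0.4
    activation: str = "relu"
    se_reduction: int = 16
    use_bn: bool = True
    lr: float = 1e-4
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"variant must be one of {VARIANTS}")
        if self.window % 2 == 0 or self.window < 1:
            raise ParameterError("window must be odd and positive")
        if len(self.conv3d_filters) != len(self.conv3d_kernels):
            raise ParameterError("conv3d filters/kernels length mismatch")
        if self.activation not in ("relu", "softsign"):
            raise ParameterError("activation must be relu or softsign")

    @property
    def has_3d(self) -> bool:
        return self.variant in ("SS", "SD", "SE", "CNN3D")

    @property
    def has_2d(self) -> bool:
        return self.variant in ("SS", "SD", "SE", "CNN2D")

    @property
    def has_se(self) -> bool:
        return self.variant in ("SS", "SE")

    @property
    def smooths_superpixels(self) -> bool:
        return self.variant in ("SS", "SD")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, default=list)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        def tup(v):
            return tuple(tuple(x) if isinstance(x, list) else x for x in v) if isinstance(v, list) else v
        return cls(**{k: tup(v) for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class LayerInfo:
    name: str
    kind: str
    kernel: tuple | None
    output_shape: tuple
    activation: str | None
    params: int


@dataclass
class ModelSpec:
    """Ordered layer summary with shapes and first-principles parameter counts."""

    config: ModelConfig
    layers: list[LayerInfo] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(li.params for li in self.layers)

    def layer(self, name: str) -> LayerInfo:
        for li in self.layers:
            if li.name == name:
                return li
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": li.name,
                    "kind": li.kind,
                    "kernel": li.kernel,
                    "output_shape": li.output_shape,
                    "activation": li.activation,
                    "params": li.params,
                }
                for li in self.layers
            ]
        )


def build_model(cfg: ModelConfig) -> ModelSpec:
    """Compute the layer chain of a variant; inconsistent chains raise."""
    spec = ModelSpec(config=cfg)
    act = cfg.activation
    w, b = cfg.window, cfg.bands

    def add(name, kind, kernel, shape, activation, params):
        if any(s < 1 for s in shape):
            raise ConstructionError(f"layer {name} output shape {shape} is degenerate")
        spec.layers.append(LayerInfo(name, kind, kernel, tuple(shape), activation, params))
        return tuple(shape)

    if cfg.has_3d:
        shape = add("input", "input", None, (w, w, b, 1), None, 0)
        for i, (f, k) in enumerate(zip(cfg.conv3d_filters, cfg.conv3d_kernels), 1):
            kh, kw, kd = k
            in_ch = shape[3]
            out = (shape[0] - kh + 1, shape[1] - kw + 1, shape[2] - kd + 1, f)
            shape = add(f"conv3d_{i}", "conv3d", k, out,
                        act, f * (kh * kw * kd * in_ch) + f)
        channels = shape[2] * shape[3]
        shape = add("reshape", "reshape", None, (shape[0], shape[1], channels), None, 0)
        if cfg.use_bn:
            shape = add("bn_1", "batchnorm", None, shape, None, 2 * channels)
            shape = add("bn_2", "batchnorm", None, shape, None, 2 * channels)
    else:
        shape = add("input", "input", None, (w, w, b), None, 0)

    if cfg.has_2d:
        kh, kw = cfg.conv2d_kernel
        for i, f in enumerate(cfg.conv2d_filters, 1):
            in_ch = shape[2]
            out = (shape[0] - kh + 1, shape[1] - kw + 1, f)
            shape = add(f"conv2d_{i}", "conv2d", (kh, kw), out,
                        act, f * (kh * kw * in_ch) + f)

    if cfg.has_se:
        c = shape[-1]
        if c % cfg.se_reduction != 0:
            raise ConstructionError("SE reduction must divide the channel count")
        hidden = c // cfg.se_reduction
        shape = add("se", "se", None, shape, "sigmoid",
                    c * hidden + hidden + hidden * c + c)

    flat = int(np.prod(shape))
    shape = add("flatten", "flatten", None, (flat,), None, 0)
    for i, units in enumerate(cfg.dense_units, 1):
        shape = add(f"dense_{i}", "dense", None, (units,), act,
                    shape[0] * units + units)
        shape = add(f"dropout_{i}", "dropout", None, shape, None, 0)
    add("head", "dense", None, (cfg.n_classes,), "softmax",
        shape[0] * cfg.n_classes + cfg.n_classes)
    return spec


def build_network(cfg: ModelConfig) -> nn.Network:
    """Instantiate trainable layers matching :func:`build_model` exactly."""
    spec = build_model(cfg)
    rng = np.random.default_rng(cfg.seed)
    layers: list[nn.Layer] = []
    prev: tuple = ()
    for li in spec.layers:
        if li.kind == "input":
            prev = li.output_shape
        elif li.kind == "conv3d":
            layers.append(nn.Conv3D(prev[3], li.output_shape[3], li.kernel, rng))
            layers.append(nn.Activation(cfg.activation))
            prev = li.output_shape
        elif li.kind == "reshape":
            layers.append(nn.Reshape(li.output_shape))
            prev = li.output_shape
        elif li.kind == "batchnorm":
            layers.append(nn.BatchNorm(prev[-1]))
        elif li.kind == "conv2d":
            layers.append(nn.Conv2D(prev[2], li.output_shape[2], li.kernel, rng))
            layers.append(nn.Activation(cfg.activation))
            prev = li.output_shape
        elif li.kind == "se":
            layers.append(nn.SEBlock(prev[-1], cfg.se_reduction, rng))
        elif li.kind == "flatten":
            layers.append(nn.Flatten())
            prev = li.output_shape
        elif li.kind == "dropout":
            layers.append(nn.Dropout(cfg.dropout, rng))
        elif li.kind == "dense":
            layers.append(nn.Dense(prev[0], li.output_shape[0], rng))
            if li.name != "head":
                layers.append(nn.Activation(cfg.activation))
            prev = li.output_shape
        else:  # pragma: no cover
            raise ConstructionError(f"unknown layer kind {li.kind}")
    net = nn.Network(layers)
    built = sum(ly.n_params for ly in net.layers)
    if built != spec.total_params:
        raise ConstructionError(
            f"built network has {built} parameters, spec says {spec.total_params}"
        )
    return net


@dataclass
class TrainedModel:
    network: nn.Network
    config: ModelConfig
    history: pd.DataFrame

    def _prepare(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=float)
        if self.config.has_3d:
            x = x[..., None]
        return x

    def predict_proba(self, windows: np.ndarray, batch: int = 256) -> np.ndarray:
        x = self._prepare(windows)
        out = []
        for start in range(0, len(x), batch):
            logits = self.network.forward(x[start : start + batch], training=False)
            out.append(nn.softmax(logits))
        return np.concatenate(out, axis=0)

    def predict_labels(self, windows: np.ndarray, batch: int = 256) -> np.ndarray:
        # argmax takes the first maximum -> ties resolve to the lowest class index
        return np.argmax(self.predict_proba(windows, batch), axis=1) + 1

    def save(self, path) -> None:
        state = self.network.get_state()
        np.savez(path, __config__=np.array(self.config.to_json()), **state)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            cfg = ModelConfig.from_dict(json.loads(str(z["__config__"])))
            state = {k: z[k] for k in z.files if k != "__config__"}
        net = build_network(cfg)
        net.set_state(state)
        return cls(network=net, config=cfg, history=pd.DataFrame())


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels - 1] = 1.0
    return out


def train(
    cfg: ModelConfig, train_set: PatchSet, val_set: PatchSet | None = None
) -> TrainedModel:
    """Mini-batch Adam training with softmax cross-entropy; seeded end to end."""
    if len(train_set) == 0:
        raise EmptySelectionError("training set is empty")
    if train_set.labels.max() > cfg.n_classes:
        raise ParameterError("training labels exceed n_classes")
    net = build_network(cfg)
    model = TrainedModel(network=net, config=cfg, history=pd.DataFrame())
    x = model._prepare(train_set.windows)
    y = _onehot(train_set.labels, cfg.n_classes)
    opt = nn.Adam(net, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(x[idx], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((np.argmax(logits, axis=1) + 1 == train_set.labels[idx]).sum())
        row = {
            "epoch": epoch,
            "loss": float(np.sum(losses) / len(x)),
            "train_oa": correct / len(x),
        }
        if val_set is not None and len(val_set):
            pred = model.predict_labels(val_set.windows)
            row["val_oa"] = float(np.mean(pred == val_set.labels))
        rows.append(row)
    model.history = pd.DataFrame(rows)
    return model


def predict_map(
    model: TrainedModel, rc: ReducedCube, w: int | None = None, chunk: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every pixel of a reduced cube.

    Returns the predicted label map (argmax + 1) and the per-pixel softmax
    probability field ``(M, N, n_classes)``.
    """
    cfg = model.config
    if w is None:
        w = cfg.window
    if w != cfg.window:
        raise ParameterError("prediction window must equal the model window")
    if rc.B != cfg.bands:
        raise ShapeMismatchError(
            f"cube has {rc.B} bands but the model expects {cfg.bands}"
        )
    m, n, b = rc.values.shape
    half = w // 2
    padded = np.pad(rc.values, ((half, half), (half, half), (0, 0)), mode="edge")
    view = sliding_window_view(padded, (w, w), axis=(0, 1))  # (M, N, B, w, w)
    flat_view = view.reshape(m * n, b, w, w)
    probs = np.empty((m * n, cfg.n_classes))
    for start in range(0, m * n, chunk):
        windows = flat_view[start : start + chunk].transpose(0, 2, 3, 1)
        probs[start : start + chunk] = model.predict_proba(
            np.ascontiguousarray(windows), batch=chunk
        )
    labels = (np.argmax(probs, axis=1) + 1).reshape(m, n)
    return labels, probs.reshape(m, n, cfg.n_classes)


def ablation_suite(
    rc: ReducedCube,
    seg: SuperpixelMap,
    labels: np.ndarray,
    base_cfg: ModelConfig,
    variants: tuple[str, ...] = VARIANTS,
    tr_list: tuple[float, ...] = (0.7, 0.05),
    seeds: tuple[int, ...] = (0,),
    superpixel_smoothing: bool = True,
) -> pd.DataFrame:
    """Train/evaluate every (variant, Tr, seed) cell and tabulate the metrics.

    Superpixel smoothing is applied to the input cube for the SS and SD
    variants (when enabled); the SE/CNN3D/CNN2D variants see the raw reduced
    cube, realizing the removal of the superpixelwise-division module.
    """
    from .evaluation import confusion, kappa, overall_accuracy, average_accuracy, producer_user_accuracy

    for v in variants:
        if v not in VARIANTS:
            raise ParameterError(f"unknown variant {v!r}")
    smoothed = superpixel_smooth(rc, seg) if superpixel_smoothing else rc
    rows = []
    for variant in variants:
        cfg = replace(base_cfg, variant=variant)
        data = smoothed if (cfg.smooths_superpixels and superpixel_smoothing) else rc
        ps = extract_patches(data, labels, cfg.window)
        ps.n_classes = cfg.n_classes
        for tr in tr_list:
            for seed in seeds:
                cfg_run = replace(cfg, seed=seed)
                train_ps, test_ps = split_train_test(ps, SplitSpec(tr=tr, seed=seed))
                model = train(cfg_run, train_ps)
                pred = model.predict_labels(test_ps.windows)
                cm = confusion(test_ps.labels, pred, cfg.n_classes)
                pa, ua = producer_user_accuracy(cm)
                rows.append(
                    {
                        "variant": variant,
                        "tr": tr,
                        "seed": seed,
                        "n_train": len(train_ps),
                        "n_test": len(test_ps),
                        "oa": overall_accuracy(cm),
                        "aa": average_accuracy(cm, on_empty_row="drop"),
                        "kappa": kappa(cm),
                        "pa": json.dumps(np.round(pa, 6).tolist()),
                        "ua": json.dumps(np.round(ua, 6).tolist()),
                    }
                )
    return pd.DataFrame(rows)
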