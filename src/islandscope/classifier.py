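"""Transfer-learning binary image classifier for genomic-island neighborhoods.

The classifier follows the standard transfer-learning recipe: a convolutional
backbone acts as a feature extractor and a freshly initialized binary head
(global average pooling -> dense(1, sigmoid)) is trained on the island
dataset with binary cross-entropy and Adam.  With ``freeze_backbone`` (the
default) only the head receives gradients; with it off, the whole network is
fine-tuned end to end.

Two backbones are available:

* ``tiny_cnn`` — a compact three-block convolutional network implemented in
  numpy (conv 5x5/stride 4, conv 3x3, conv 3x3, each ReLU + pooling).  Its
  filters are seeded and reproducible, so the frozen-backbone path needs no
  external weights and the full train->predict path is deterministic on one
  machine.
* ``inception_v3_pretrained`` — a pluggable-weights slot for an externally
  exported pretrained feature extractor; the weights file is an input, never
  bundled.

All tensors are float32; images enter as (H, W, 3) uint8 and are scaled to
[0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, ValidationError
from .io import GenomeAnnotation
from .neighborhood import NeighborhoodConfig, build_neighborhood
from .rendering import RenderConfig, RenderedImage, render
from .vocab import KeywordVocabulary

BACKBONES = ("tiny_cnn", "inception_v3_pretrained")


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "tiny_cnn"
    freeze_backbone: bool = True
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    seed: int = 0
    weights_path: str | None = None  # for pretrained backbones

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValidationError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")
        if not (0 < self.validation_fraction < 1):
            raise ValidationError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass(frozen=True)
class LabeledExample:
    image: RenderedImage
    label: str  # "GI" or "not-GI"
    source_id: str

    def __post_init__(self) -> None:
        if self.label not in ("GI", "not-GI"):
            raise ValidationError(f"label must be 'GI' or 'not-GI', got {self.label!r}")


@dataclass
class TrainReport:
    epoch_loss: list[float]
    epoch_val_accuracy: list[float]
    final_val_accuracy: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "epoch_loss": self.epoch_loss,
                "epoch_val_accuracy": self.epoch_val_accuracy,
                "final_val_accuracy": self.final_val_accuracy,
            }
        )


# ---------------------------------------------------------------------------
# numpy network primitives
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int):
    """Valid cross-correlation. x: (N,H,W,C); W: (kh,kw,Cin,Cout)."""
    kh, kw = W.shape[:2]
    patches = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    # patches: (N, Ho, Wo, Cin, kh, kw)
    out = np.tensordot(patches, W, axes=([4, 5, 3], [0, 1, 2])) + b
    return out.astype(np.float32), patches


def _conv_backward_params(patches: np.ndarray, grad: np.ndarray):
    dW = np.tensordot(patches, grad, axes=([0, 1, 2], [0, 1, 2]))
    # dW axes: (Cin, kh, kw, Cout) -> (kh, kw, Cin, Cout)
    dW = np.transpose(dW, (1, 2, 0, 3))
    db = grad.sum(axis=(0, 1, 2))
    return dW.astype(np.float32), db.astype(np.float32)


def _conv_backward_input(grad: np.ndarray, W: np.ndarray, in_shape):
    """Input gradient for a stride-1 valid conv: full correlation with the
    spatially flipped, channel-transposed kernel."""
    kh, kw = W.shape[:2]
    padded = np.pad(grad, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0)))
    W_rot = np.transpose(W[::-1, ::-1], (0, 1, 3, 2))  # (kh,kw,Cout,Cin)
    patches = sliding_window_view(padded, (kh, kw), axis=(1, 2))
    dx = np.tensordot(patches, W_rot, axes=([4, 5, 3], [0, 1, 2]))
    return dx[:, : in_shape[1], : in_shape[2]].astype(np.float32)


def _maxpool_forward(x: np.ndarray):
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    view = x[:, : h2 * 2, : w2 * 2].reshape(n, h2, 2, w2, 2, c)
    out = view.max(axis=(2, 4))
    return out.astype(np.float32), view

def _maxpool_backward(grad: np.ndarray, view: np.ndarray, in_shape):
    n, h2, _, w2, _, c = view.shape
    out = view.max(axis=(2, 4), keepdims=True)
    mask = (view == out).astype(np.float32)
    # split ties evenly so the gradient check stays exact
    mask /= mask.sum(axis=(2, 4), keepdims=True)
    dview = mask * grad.reshape(n, h2, 1, w2, 1, c)
    dx = np.zeros(in_shape, dtype=np.float32)
    dx[:, : h2 * 2, : w2 * 2] = dview.reshape(n, h2 * 2, w2 * 2, c)
    return dx


_LAYOUT = (
    ("W1", "b1", 5, 4, 3, 8),
    ("W2", "b2", 3, 1, 8, 16),
    ("W3", "b3", 3, 1, 16, 32),
)
_FEATURE_DIM = 32


def _init_backbone(rng: np.random.Generator) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    for wname, bname, k, _stride, cin, cout in _LAYOUT:
        fan_in = k * k * cin
        params[wname] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (k, k, cin, cout)).astype(
            np.float32
        )
        params[bname] = np.zeros(cout, dtype=np.float32)
    return params


def _backbone_param_count() -> int:
    return sum(k * k * cin * cout + cout for _, _, k, _s, cin, cout in _LAYOUT)


def _head_param_count() -> int:
    return _FEATURE_DIM + 1


@dataclass
class ModelHandle:
    """Opaque handle: backbone name, parameter arrays, training metadata."""

    backbone: str
    input_shape: tuple[int, int, int]
    params: dict[str, np.ndarray]
    freeze_backbone: bool = True
    metadata: dict = field(default_factory=dict)

    @property
    def trainable_parameter_count(self) -> int:
        n = _head_param_count()
        if not self.freeze_backbone:
            n += _backbone_param_count()
        return n

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "backbone": self.backbone,
            "input_shape": list(self.input_shape),
            "freeze_backbone": self.freeze_backbone,
            "metadata": self.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelHandle":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(
            backbone=meta["backbone"],
            input_shape=tuple(meta["input_shape"]),
            params=params,
            freeze_backbone=meta["freeze_backbone"],
            metadata=meta["metadata"],
        )


def build_model(
    config: TrainConfig, input_shape: tuple[int, int, int] = (299, 299, 3)
) -> ModelHandle:
    """Assemble backbone + fresh binary head.

    ``tiny_cnn`` seeds its own filters from ``config.seed``.  The pretrained
    backbone requires ``config.weights_path`` (an .npz exporting W1/b1, W2/b2,
    W3/b3 in the documented layout); it is never downloaded.
    """
    if min(input_shape[0], input_shape[1]) < 65 or input_shape[2] != 3:
        raise ValidationError(
            f"input shape {input_shape} unsupported: the three conv blocks need "
            "at least 65x65 RGB pixels"
        )
    rng = np.random.default_rng(config.seed)
    if config.backbone == "tiny_cnn":
        params = _init_backbone(rng)
    else:
        if config.weights_path is None or not Path(config.weights_path).exists():
            raise ConfigurationError(
                "backbone 'inception_v3_pretrained' needs pretrained weights: set "
                "TrainConfig.weights_path to an .npz file exporting arrays "
                "W1,b1,W2,b2,W3,b3 (see the model checkpoint format); pretrained "
                "weights are an input to this package, not bundled with it"
            )
        with np.load(config.weights_path) as npz:
            params = {k: np.asarray(npz[k], dtype=np.float32) for k in npz.files}
        for wname, bname, *_ in _LAYOUT:
            if wname not in params or bname not in params:
                raise ConfigurationError(f"weights file lacks array {wname!r}/{bname!r}")
    # fresh head, zero-initialised: training starts from chance probability 0.5
    params["Wh"] = np.zeros((_FEATURE_DIM, 1), dtype=np.float32)
    params["bh"] = np.zeros(1, dtype=np.float32)
    return ModelHandle(
        backbone=config.backbone,
        input_shape=input_shape,
        params=params,
        freeze_backbone=config.freeze_backbone,
        metadata={"seed": config.seed},
    )


def _forward_backbone(params: dict, x: np.ndarray, keep_cache: bool = False):
    cache: dict = {"x": x}
    h, cache["p1"] = _conv_forward(x, params["W1"], params["b1"], stride=4)
    cache["z1"] = h
    h = np.maximum(h, 0.0)
    h, cache["v1"] = _maxpool_forward(h)
    cache["a1_shape"] = cache["z1"].shape
    h2, cache["p2"] = _conv_forward(h, params["W2"], params["b2"], stride=1)
    cache["in2_shape"] = h.shape
    cache["z2"] = h2
    h2 = np.maximum(h2, 0.0)
    h2, cache["v2"] = _maxpool_forward(h2)
    h3, cache["p3"] = _conv_forward(h2, params["W3"], params["b3"], stride=1)
    cache["in3_shape"] = h2.shape
    cache["z3"] = h3
    h3 = np.maximum(h3, 0.0)
    cache["a3"] = h3
    feats = h3.mean(axis=(1, 2))  # global average pooling
    return feats.astype(np.float32), (cache if keep_cache else None)


def _normalize_feats(params: dict, feats: np.ndarray) -> np.ndarray:
    # frozen standardization layer fit on the training split; identity before fit
    mu = params.get("feat_mu")
    if mu is None:
        return feats
    return (feats - mu) / params["feat_sd"]


def _forward_head(params: dict, feats: np.ndarray) -> np.ndarray:
    logits = _normalize_feats(params, feats) @ params["Wh"] + params["bh"]
    return logits[:, 0]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _images_to_array(images: list[RenderedImage], input_shape) -> np.ndarray:
    arrs = []
    for im in images:
        if im.pixels.shape != tuple(input_shape):
            raise ValidationError(
                f"image {im.neighborhood_id!r} has shape {im.pixels.shape}, "
                f"model expects {tuple(input_shape)}"
            )
        arrs.append(im.pixels)
    return np.stack(arrs).astype(np.float32) / 255.0


class _Adam:
    def __init__(self, keys: list[str], lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_grads(params: dict, xb: np.ndarray, yb: np.ndarray, frozen: bool):
    """Mean BCE loss and gradients for one minibatch."""
    feats, cache = _forward_backbone(params, xb, keep_cache=not frozen)
    logits = _forward_head(params, feats)
    p = _sigmoid(logits)
    eps = 1e-7
    loss = float(-np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)))
    dlogit = (p - yb) / len(yb)  # (N,)
    zn = _normalize_feats(params, feats)
    grads = {
        "Wh": zn.T @ dlogit[:, None],
        "bh": np.array([dlogit.sum()], dtype=np.float32),
    }
    if not frozen:
        dfeats = dlogit[:, None] @ params["Wh"].T  # (N, F)
        if "feat_sd" in params:
            dfeats = dfeats / params["feat_sd"]
        n, hh, ww, _ = cache["a3"].shape
        da3 = np.broadcast_to(dfeats[:, None, None, :], cache["a3"].shape) / (hh * ww)
        dz3 = (da3 * (cache["z3"] > 0)).astype(np.float32)
        grads["W3"], grads["b3"] = _conv_backward_params(cache["p3"], dz3)
        dh2 = _conv_backward_input(dz3, params["W3"], cache["in3_shape"])
        dz2in = _maxpool_backward(dh2, cache["v2"], cache["z2"].shape)
        dz2 = (dz2in * (cache["z2"] > 0)).astype(np.float32)
        grads["W2"], grads["b2"] = _conv_backward_params(cache["p2"], dz2)
        dh1 = _conv_backward_input(dz2, params["W2"], cache["in2_shape"])
        dz1in = _maxpool_backward(dh1, cache["v1"], cache["a1_shape"])
        dz1 = (dz1in * (cache["z1"] > 0)).astype(np.float32)
        grads["W1"], grads["b1"] = _conv_backward_params(cache["p1"], dz1)
    return loss, grads


def train(
    model: ModelHandle, data: list[LabeledExample], config: TrainConfig
) -> tuple[ModelHandle, TrainReport]:
    """Train the head (and optionally the backbone) on labeled examples.

    The train/validation split is a seeded shuffle; with the same seed on the
    same machine the full path is reproducible.
    """
    labels = np.array([1.0 if ex.label == "GI" else 0.0 for ex in data], dtype=np.float32)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"need >=2 examples per class, got GI={n_pos}, not-GI={n_neg}"
        )
    x = _images_to_array([ex.image for ex in data], model.input_shape)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(data))
    n_val = max(1, int(round(config.validation_fraction * len(data))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValidationError("validation fraction leaves no training data")

    params = {k: v.copy() for k, v in model.params.items()}
    frozen = model.freeze_backbone
    feat_cache = None
    if frozen:
        # backbone fixed: extract features once, in batches to bound memory
        feat_cache = np.concatenate(
            [
                _forward_backbone(params, x[lo : lo + config.batch_size])[0]
                for lo in range(0, len(x), config.batch_size)
            ]
        )

    # fit the frozen feature-standardization layer on the training split
    if frozen:
        train_feats = feat_cache[train_idx]
    else:
        train_feats = np.concatenate(
            [
                _forward_backbone(params, x[train_idx[lo : lo + config.batch_size]])[0]
                for lo in range(0, len(train_idx), config.batch_size)
            ]
        )
    params["feat_mu"] = train_feats.mean(axis=0).astype(np.float32)
    params["feat_sd"] = (train_feats.std(axis=0) + 1e-6).astype(np.float32)

    opt_keys = ["Wh", "bh"] + ([] if frozen else ["W1", "b1", "W2", "b2", "W3", "b3"])
    opt = _Adam(opt_keys, config.learning_rate)

    def val_accuracy() -> float:
        if frozen:
            feats = feat_cache[val_idx]
        else:
            feats = _forward_backbone(params, x[val_idx])[0]
        p = _sigmoid(_forward_head(params, feats))
        return float(np.mean((p >= 0.5) == (labels[val_idx] == 1.0)))

    epoch_loss, epoch_val = [], []
    for _epoch in range(config.epochs):
        perm = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for lo in range(0, len(perm), config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            yb = labels[idx]
            if frozen:
                feats = feat_cache[idx]
                zn = _normalize_feats(params, feats)
                logits = _forward_head(params, feats)
                p = _sigmoid(logits)
                eps = 1e-7
                loss = float(
                    -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
                )
                dlogit = (p - yb) / len(yb)
                grads = {
                    "Wh": zn.T @ dlogit[:, None],
                    "bh": np.array([dlogit.sum()], dtype=np.float32),
                }
            else:
                loss, grads = _batch_grads(params, x[idx], yb, frozen=False)
            opt.step(params, grads)
            losses.append(loss)
        epoch_loss.append(float(np.mean(losses)))
        epoch_val.append(val_accuracy())

    report = TrainReport(
        epoch_loss=epoch_loss,
        epoch_val_accuracy=epoch_val,
        final_val_accuracy=epoch_val[-1],
    )
    trained = ModelHandle(
        backbone=model.backbone,
        input_shape=model.input_shape,
        params=params,
        freeze_backbone=model.freeze_backbone,
        metadata={
            **model.metadata,
            "seed": config.seed,
            "epochs": config.epochs,
            "final_val_accuracy": report.final_val_accuracy,
            "trained": True,
        },
    )
    return trained, report


def predict(
    model: ModelHandle, images: list[RenderedImage], batch_size: int = 32
) -> list[float]:
    """GI probability per image, order preserved; pure given a trained model."""
    if not images:
        return []
    x = _images_to_array(images, model.input_shape)
    probs: list[float] = []
    for lo in range(0, len(x), batch_size):
        feats, _ = _forward_backbone(model.params, x[lo : lo + batch_size])
        probs.extend(float(p) for p in _sigmoid(_forward_head(model.params, feats)))
    return probs


def classify_genes(
    model: ModelHandle,
    genome: GenomeAnnotation,
    reference_genomes: list[tuple[GenomeAnnotation, float]],
    vocab: KeywordVocabulary,
    neighborhood_config: NeighborhoodConfig = NeighborhoodConfig(),
    render_config: RenderConfig | None = None,
    threshold: float = 0.5,
    batch_size: int = 32,
):
    """One GI prediction per gene of the genome, in genome order.

    The per-gene probability comes from rendering the gene's compare-region
    image and running it through the model; ``call`` is GI iff probability is
    at or above ``threshold``.
    """
    from .calling import GenePrediction

    if render_config is None:
        h, w, _ = model.input_shape
        render_config = RenderConfig(width=w, height=h)
    images = []
    for g in genome.genes:
        nb = build_neighborhood(g.gene_id, genome, reference_genomes, neighborhood_config)
        images.append(render(nb, render_config, vocab))
    probs = predict(model, images, batch_size=batch_size)
    return [
        GenePrediction(
            gene_id=g.gene_id,
            contig_id=g.contig_id,
            start=g.start,
            end=g.end,
            probability=p,
            call="GI" if p >= threshold else "not-GI",
        )
        for g, p in zip(genome.genes, probs)
    ]
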