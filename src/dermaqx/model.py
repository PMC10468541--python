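"""The image-quality network: a convolutional feature extractor feeding an
explanation head whose sigmoid outputs are concatenated into the quality head.

Two linear blocks (linear layer, batch normalisation, dropout) parse the
backbone features. Block A predicts the five poor-quality explanations
through sigmoids; block B's output is concatenated with those five
explanation probabilities before the four-way softmax quality prediction, so
the quality verdict is explicitly conditioned on the predicted defects and
the whole network trains end to end.

The composite objective is

    L = lambda_D * L_D + lambda_C * L_C

where ``L_D`` is class-weighted categorical cross-entropy on the quality
label (each sample's term multiplied by the weight of its true class,
averaged over the batch) and ``L_C`` is binary cross-entropy averaged over
the five explanation bits and the batch, unweighted. Images whose reference
class is not poor quality use all-zero explanation targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn
from .annotations import ClassWeights
from .taxonomy import CLASS_INDEX, EXPLANATIONS, QUALITY_CLASSES

__all__ = [
    "ModelConfig",
    "QXOutput",
    "LossTerms",
    "QualityExplainerNet",
    "UnsupportedBackboneError",
    "build_model",
    "qx_loss",
    "loss_gradients",
    "predict",
    "Prediction",
    "preprocess_images",
    "save_checkpoint",
    "load_checkpoint",
]


class UnsupportedBackboneError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and loss hyperparameters.

    ``lambda_d`` and ``lambda_c`` weight the quality and explanation loss
    terms (defaults 1.0 and 5.0). ``linear_block_width`` is the width of both
    linear blocks (default 64); dropout defaults to 0.2. ``tiny_cnn`` is a
    four-stage stride-2 convolutional backbone whose final feature map is
    flattened (position-preserving, so off-centre framing stays detectable);
    ``efficientnet_b0`` requires ImageNet-pretrained weights and a GPU-class
    framework and is not available in this distribution.
    """

    backbone: str = "tiny_cnn"
    input_size: int = 64
    linear_block_width: int = 64
    dropout: float = 0.2
    n_classes: int = 4
    n_explanations: int = 5
    lambda_d: float = 1.0
    lambda_c: float = 5.0
    pretrained: bool = False
    concat_explanations: bool = True
    channels: tuple[int, ...] = (16, 32, 64, 64)

    def __post_init__(self):
        if self.linear_block_width <= 0:
            raise ValueError("linear_block_width must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.lambda_d < 0 or self.lambda_c < 0:
            raise ValueError("loss weights must be non-negative")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d) -> "ModelConfig":
        d = dict(d)
        d["channels"] = tuple(d.get("channels", (16, 32, 64, 64)))
        return cls(**d)


@dataclass
class QXOutput:
    """Network outputs for a batch: probabilities and raw pre-activation scores."""

    quality_probs: np.ndarray      # (N, 4), rows sum to 1
    explanation_probs: np.ndarray  # (N, 5), each in [0, 1]
    quality_logits: np.ndarray
    explanation_logits: np.ndarray


@dataclass
class LossTerms:
    """Composite loss: total = lambda_d * l_d + lambda_c * l_c."""

    l_d: float
    l_c: float
    total: float


@dataclass
class Prediction:
    image_id: str
    quality_class: str
    explanations: np.ndarray  # (5,) int8


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class QualityExplainerNet:
    """Backbone + explanation head + explanation-conditioned quality head.

    ``forward`` caches everything needed for a manual backward pass;
    ``backward`` accepts gradient seeds on the two pre-activation score
    vectors, which serves both training (loss gradients) and saliency
    mapping (one-hot score gradients with activation gradients captured at
    every convolutional stage).
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed & 0x7FFFFFFF)
        self._dropout_rng = np.random.default_rng((seed & 0x7FFFFFFF) + 1)

        cin = 3
        self.stages: list[nn.Sequential] = []
        self.stage_names: list[str] = []
        for i, cout in enumerate(cfg.channels):
            stage = nn.Sequential(
                nn.Conv2d(cin, cout, k=3, stride=2, pad=1, rng=rng,
                          name=f"stage{i + 1}.conv"),
                nn.BatchNorm2d(cout, name=f"stage{i + 1}.bn"),
                nn.ReLU(),
            )
            self.stages.append(stage)
            self.stage_names.append(f"stage{i + 1}")
            cin = cout
        side = cfg.input_size // (2 ** len(cfg.channels))
        if side < 1:
            raise ValueError("input_size too small for the backbone depth")
        feat_dim = cfg.channels[-1] * side * side

        w = cfg.linear_block_width
        self.block_a = nn.Sequential(
            nn.Linear(feat_dim, w, rng=rng, name="block_a.linear"),
            nn.BatchNorm1d(w, name="block_a.bn"),
            nn.Dropout(cfg.dropout, rng=self._dropout_rng),
        )
        self.block_b = nn.Sequential(
            nn.Linear(feat_dim, w, rng=rng, name="block_b.linear"),
            nn.BatchNorm1d(w, name="block_b.bn"),
            nn.Dropout(cfg.dropout, rng=self._dropout_rng),
        )
        self.head_e = nn.Linear(w, cfg.n_explanations, rng=rng, name="head_e")
        q_in = w + (cfg.n_explanations if cfg.concat_explanations else 0)
        self.head_q = nn.Linear(q_in, cfg.n_classes, rng=rng, name="head_q")

        self._cache: dict = {}
        self.stage_activations: list[np.ndarray] | None = None
        self.stage_gradients: list[np.ndarray] | None = None

    # -- parameter plumbing -------------------------------------------------

    def _modules(self):
        return [*self.stages, self.block_a, self.block_b, self.head_e, self.head_q]

    def parameters(self) -> list[nn.Parameter]:
        return [p for m in self._modules() for p in m.parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {p.name: p.value for p in self.parameters()}
        for m in self._modules():
            out.update(m.state())
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for m in self._modules():
            for k, buf in m.state().items():
                buf[...] = state[k]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> QXOutput:
        """``x``: (N, 3, H, W) float32, already normalised."""
        acts = []
        h = x
        for stage in self.stages:
            h = stage.forward(h, train=train)
            acts.append(h)
        n = h.shape[0]
        feats = h.reshape(n, -1)

        a = self.block_a.forward(feats, train=train)
        e_logits = self.head_e.forward(a, train=train)
        e_probs = _sigmoid(e_logits)
        b = self.block_b.forward(feats, train=train)
        if self.cfg.concat_explanations:
            c = np.concatenate([b, e_probs], axis=1)
        else:
            c = b
        q_logits = self.head_q.forward(c, train=train)
        q_probs = _softmax(q_logits)

        self.stage_activations = acts
        self._cache = {"feat_shape": h.shape, "e_probs": e_probs}
        return QXOutput(q_probs, e_probs, q_logits, e_logits)

    def backward(self, d_q_logits: np.ndarray, d_e_logits: np.ndarray,
                 capture_stage_grads: bool = False) -> np.ndarray:
        """Backpropagate score-space gradient seeds; returns the input
        gradient. The chain through the explanation-probability concatenation
        is handled here, so seeds are expressed purely on the two logit
        vectors."""
        e_probs = self._cache["e_probs"]
        dc = self.head_q.backward(d_q_logits)
        w = self.cfg.linear_block_width
        if self.cfg.concat_explanations:
            db, d_e_probs = dc[:, :w], dc[:, w:]
            d_e_total = d_e_logits + d_e_probs * e_probs * (1.0 - e_probs)
        else:
            db, d_e_total = dc, d_e_logits
        da = self.head_e.backward(d_e_total.astype(np.float32))
        dfeat = self.block_a.backward(da) + self.block_b.backward(db)
        dh = dfeat.reshape(self._cache["feat_shape"]).astype(np.float32)

        grads = []
        for stage in reversed(self.stages):
            if capture_stage_grads:
                grads.append(dh)
            dh = stage.backward(dh)
        if capture_stage_grads:
            self.stage_gradients = grads[::-1]
        return dh


def build_model(cfg: ModelConfig, seed: int = 0) -> QualityExplainerNet:
    """Construct the network; only the ``tiny_cnn`` backbone is supported."""
    if cfg.backbone == "tiny_cnn":
        if cfg.pretrained:
            raise UnsupportedBackboneError("tiny_cnn has no pretrained weights")
        return QualityExplainerNet(cfg, seed=seed)
    if cfg.backbone == "efficientnet_b0":
        raise UnsupportedBackboneError(
            "the efficientnet_b0 backbone requires ImageNet-pretrained "
            "weights and a deep-learning framework; this distribution "
            "provides the self-contained tiny_cnn backbone"
        )
    raise UnsupportedBackboneError(f"unknown backbone {cfg.backbone!r}")


# --------------------------------------------------------------------------
# Loss


def _class_weight_array(weights: ClassWeights | np.ndarray | None) -> np.ndarray:
    if weights is None:
        return np.ones(len(QUALITY_CLASSES))
    if isinstance(weights, ClassWeights):
        return weights.as_array(QUALITY_CLASSES)
    return np.asarray(weights, dtype=np.float64)


def qx_loss(
    q_logits: np.ndarray,
    e_logits: np.ndarray,
    class_targets: np.ndarray,
    explanation_targets: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    lambda_d: float = 1.0,
    lambda_c: float = 5.0,
) -> LossTerms:
    """Composite loss on pre-activation scores.

    ``class_targets``: (N,) integer class indices in the canonical order;
    ``explanation_targets``: (N, 5) bits, all-zero for non-poor images.
    """
    q_logits = np.asarray(q_logits, dtype=np.float64)
    e_logits = np.asarray(e_logits, dtype=np.float64)
    if not (np.isfinite(q_logits).all() and np.isfinite(e_logits).all()):
        raise FloatingPointError("non-finite logits passed to qx_loss")
    y = np.asarray(class_targets, dtype=np.intp)
    t = np.asarray(explanation_targets, dtype=np.float64)
    n = q_logits.shape[0]
    w = _class_weight_array(weights)[y]

    zmax = q_logits.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(q_logits - zmax).sum(axis=1))
    ce = lse - q_logits[np.arange(n), y]
    l_d = float(np.mean(w * ce))

    # numerically stable BCE with logits: max(z,0) - z*t + log1p(exp(-|z|))
    z = e_logits
    bce = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    l_c = float(np.mean(bce))

    return LossTerms(l_d=l_d, l_c=l_c, total=lambda_d * l_d + lambda_c * l_c)


def loss_gradients(
    output: QXOutput,
    class_targets: np.ndarray,
    explanation_targets: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    lambda_d: float = 1.0,
    lambda_c: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of the composite loss w.r.t. the two logit vectors."""
    y = np.asarray(class_targets, dtype=np.intp)
    t = np.asarray(explanation_targets, dtype=np.float64)
    n = output.quality_logits.shape[0]
    w = _class_weight_array(weights)[y]
    d_q = output.quality_probs.astype(np.float64).copy()
    d_q[np.arange(n), y] -= 1.0
    d_q *= lambda_d * w[:, None] / n
    d_e = lambda_c * (output.explanation_probs - t) / (n * t.shape[1])
    return d_q.astype(np.float32), d_e.astype(np.float32)


# --------------------------------------------------------------------------
# Prediction


def preprocess_images(images, input_size: int) -> np.ndarray:
    """uint8 (N, H, W, 3) or a list of HxWx3 arrays -> normalised
    (N, 3, S, S) float32 in [-1, 1], resizing when needed."""
    arrs = []
    for img in images:
        a = np.asarray(img)
        if a.dtype == np.uint8:
            a = a.astype(np.float32) / 255.0
        if a.shape[0] != input_size or a.shape[1] != input_size:
            a = resize(a, (input_size, input_size, 3), order=1, mode="edge",
                       anti_aliasing=True).astype(np.float32)
        arrs.append((a - 0.5) / 0.5)
    x = np.stack(arrs).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(x, dtype=np.float32)


def predict(
    model: QualityExplainerNet,
    images,
    explanation_threshold: float = 0.5,
    image_ids: list[str] | None = None,
    batch_size: int = 64,
) -> tuple[list[Prediction], QXOutput]:
    """Evaluation-mode inference: argmax quality class, thresholded
    explanation bits, raw probabilities retained for threshold tuning."""
    imgs = list(images)
    if not imgs:
        raise ValueError("predict requires a non-empty batch")
    if image_ids is None:
        image_ids = [f"image{i}" for i in range(len(imgs))]
    qp, ep, ql, el = [], [], [], []
    for start in range(0, len(imgs), batch_size):
        x = preprocess_images(imgs[start : start + batch_size], model.cfg.input_size)
        out = model.forward(x, train=False)
        qp.append(out.quality_probs)
        ep.append(out.explanation_probs)
        ql.append(out.quality_logits)
        el.append(out.explanation_logits)
    out = QXOutput(*(np.concatenate(a) for a in (qp, ep, ql, el)))
    preds = []
    for i, image_id in enumerate(image_ids):
        cls = QUALITY_CLASSES[int(np.argmax(out.quality_probs[i]))]
        bits = (out.explanation_probs[i] >= explanation_threshold).astype(np.int8)
        preds.append(Prediction(image_id, cls, bits))
    return preds, out


def targets_from_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    """Fused labels -> (class indices, explanation-bit matrix); bits are
    zeroed for non-poor classes so the BCE targets match the training rule."""
    y = np.array([CLASS_INDEX[l.quality_class] for l in labels], dtype=np.intp)
    t = np.stack([np.asarray(l.explanations, dtype=np.float64) for l in labels])
    t[y != CLASS_INDEX["poor_quality"]] = 0.0
    return y, t


# --------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(model: QualityExplainerNet, path: str | Path) -> float:
    """Save weights (.npz) plus a JSON sidecar with the config; returns the
    artifact size in MB (informational)."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    side = npz.with_suffix(".json")
    side.write_text(json.dumps(model.cfg.to_dict(), indent=2))
    return npz.stat().st_size / 1e6


def load_checkpoint(path: str | Path, seed: int = 0) -> QualityExplainerNet:
    npz = Path(path)
    if npz.suffix != ".npz":
        npz = npz.with_suffix(npz.suffix + ".npz")
    cfg = ModelConfig.from_dict(json.loads(npz.with_suffix(".json").read_text()))
    model = build_model(cfg, seed=seed)
    with np.load(npz) as data:
        model.load_state_dict(dict(data))
    return model
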