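"""Feature extraction and the trainable embedding head.

The recognition model is a two-part extractor.  A *backbone* maps a face crop
to a fixed-dimension global feature (a ViT-style backbone emits the 768-dim
CLS token; any callable satisfying :class:`BackboneContract` can be plugged
in).  An *embedding head* then projects that feature into the metric space
used for gallery matching:

    768 -> Linear -> 512 -> BatchNorm -> ReLU -> Dropout
        -> Linear -> 64  -> BatchNorm

The head (plus the sub-center bank and class centers of the dual loss) is
trained with :func:`train_embedder`; at inference the head is a deterministic
pure function of its weights and the running batch-norm statistics, and its
outputs are L2-normalized before matching.

A :class:`TinyConvBackbone` with fixed, seeded random filters is provided so
the whole pipeline runs on a laptop CPU with no downloads: random
convolutional features are a classical frozen-extractor baseline, and the
trained metric head on top of them is what the tests exercise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .autograd import Tensor
from .exceptions import ShapeError, StateError, ValidationError
from .losses import (ClassCenters, DualLossConfig, LossBatch, SubCenterBank,
                     arcface_graph, center_graph)

__all__ = [
    "PatchGridSpec",
    "patch_grid",
    "l2_normalize",
    "EmbeddingHeadConfig",
    "EmbeddingHead",
    "BackboneContract",
    "TinyConvBackbone",
    "TrainedEmbedder",
    "TrainConfig",
    "train_embedder",
]


# --------------------------------------------------------------------------
# patch-grid arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchGridSpec:
    """Square input image tiled into square non-overlapping patches."""

    image_size: int
    patch_size: int
    channels: int = 3


def patch_grid(spec: PatchGridSpec) -> tuple[int, int]:
    """Number of patches and flattened per-patch dimension.

    A 224x224x3 image with 16x16 patches gives (196, 768): 196 tokens of
    dimension 16*16*3 feeding a ViT-style patch embedding.
    """
    if spec.image_size < 1 or spec.patch_size < 1 or spec.channels < 1:
        raise ValidationError("image_size, patch_size and channels must be >= 1")
    if spec.image_size % spec.patch_size != 0:
        raise ValidationError(
            f"image_size {spec.image_size} not divisible by patch_size {spec.patch_size}")
    side = spec.image_size // spec.patch_size
    return side * side, spec.patch_size * spec.patch_size * spec.channels


def l2_normalize(vectors: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unit-normalize along ``axis``; zero vectors are rejected."""
    v = np.asarray(vectors, dtype=np.float64)
    norms = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValidationError("cannot normalize a zero vector")
    return v / norms


# --------------------------------------------------------------------------
# embedding head
# --------------------------------------------------------------------------

@dataclass
class EmbeddingHeadConfig:
    in_dim: int = 768
    hidden_dim: int = 512
    out_dim: int = 64
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if min(self.in_dim, self.hidden_dim, self.out_dim) < 1:
            raise ValidationError("all head dimensions must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")


class _BatchNorm:
    """1-D batch normalization with trainable affine and running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def forward_train(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=0, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        n = x.shape[0]
        # running stats track the unbiased variance, torch-style
        self.running_mean = ((1 - self.momentum) * self.running_mean
                             + self.momentum * mu.data.ravel())
        unbiased = var.data.ravel() * n / max(n - 1, 1)
        self.running_var = ((1 - self.momentum) * self.running_var
                            + self.momentum * unbiased)
        return xhat * self.gamma + self.beta

    def forward_eval(self, x: np.ndarray) -> np.ndarray:
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma.data + self.beta.data


class EmbeddingHead:
    """The 768 -> 512 -> 64 projection head (dims configurable)."""

    def __init__(self, config: EmbeddingHeadConfig | None = None,
                 rng: np.random.Generator | int | None = None):
        self.config = config or EmbeddingHeadConfig()
        rng = np.random.default_rng(rng)
        c = self.config
        # He-style fan-in scaling
        self.w1 = Tensor(rng.standard_normal((c.in_dim, c.hidden_dim))
                         * np.sqrt(2.0 / c.in_dim), requires_grad=True)
        self.b1 = Tensor(np.zeros(c.hidden_dim), requires_grad=True)
        self.bn1 = _BatchNorm(c.hidden_dim)
        self.w2 = Tensor(rng.standard_normal((c.hidden_dim, c.out_dim))
                         * np.sqrt(2.0 / c.hidden_dim), requires_grad=True)
        self.b2 = Tensor(np.zeros(c.out_dim), requires_grad=True)
        self.bn2 = _BatchNorm(c.out_dim)

    def params(self) -> list[Tensor]:
        return ([self.w1, self.b1, self.w2, self.b2]
                + self.bn1.params() + self.bn2.params())

    def forward_train(self, features: np.ndarray,
                      rng: np.random.Generator) -> Tensor:
        """Training-mode forward: batch statistics + dropout; batch >= 2."""
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != self.config.in_dim:
            raise ShapeError(f"expected (batch, {self.config.in_dim}) features")
        if features.shape[0] < 2:
            raise ValidationError(
                "training mode needs batch >= 2: batch normalization statistics "
                "are undefined for a single sample")
        h = Tensor(features) @ self.w1 + self.b1
        h = self.bn1.forward_train(h).relu()
        p = self.config.dropout_rate
        if p > 0:
            mask = (rng.random(h.shape) >= p) / (1.0 - p)
            h = h * mask
        out = h @ self.w2 + self.b2
        return self.bn2.forward_train(out)

    def forward_eval(self, features: np.ndarray) -> np.ndarray:
        """Inference-mode forward: running statistics, no dropout, deterministic."""
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != self.config.in_dim:
            raise ShapeError(f"expected (batch, {self.config.in_dim}) features")
        h = features @ self.w1.data + self.b1.data
        h = np.maximum(self.bn1.forward_eval(h), 0.0)
        out = h @ self.w2.data + self.b2.data
        return self.bn2.forward_eval(out)

    # -- persistence --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            "w1": self.w1.data, "b1": self.b1.data,
            "w2": self.w2.data, "b2": self.b2.data,
            "bn1_gamma": self.bn1.gamma.data, "bn1_beta": self.bn1.beta.data,
            "bn1_mean": self.bn1.running_mean, "bn1_var": self.bn1.running_var,
            "bn2_gamma": self.bn2.gamma.data, "bn2_beta": self.bn2.beta.data,
            "bn2_mean": self.bn2.running_mean, "bn2_var": self.bn2.running_var,
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.w1.data = np.asarray(state["w1"], dtype=np.float64)
        self.b1.data = np.asarray(state["b1"], dtype=np.float64)
        self.w2.data = np.asarray(state["w2"], dtype=np.float64)
        self.b2.data = np.asarray(state["b2"], dtype=np.float64)
        self.bn1.gamma.data = np.asarray(state["bn1_gamma"], dtype=np.float64)
        self.bn1.beta.data = np.asarray(state["bn1_beta"], dtype=np.float64)
        self.bn1.running_mean = np.asarray(state["bn1_mean"], dtype=np.float64)
        self.bn1.running_var = np.asarray(state["bn1_var"], dtype=np.float64)
        self.bn2.gamma.data = np.asarray(state["bn2_gamma"], dtype=np.float64)
        self.bn2.beta.data = np.asarray(state["bn2_beta"], dtype=np.float64)
        self.bn2.running_mean = np.asarray(state["bn2_mean"], dtype=np.float64)
        self.bn2.running_var = np.asarray(state["bn2_var"], dtype=np.float64)


# --------------------------------------------------------------------------
# backbones
# --------------------------------------------------------------------------

@runtime_checkable
class BackboneContract(Protocol):
    """Anything that maps a batch of images to (batch, feature_dim) features."""

    feature_dim: int

    def extract(self, images: np.ndarray) -> np.ndarray: ...


class TinyConvBackbone:
    """Fixed random convolutional feature extractor.

    Three 3x3 conv + ReLU + 2x2 max-pool blocks followed by a seeded random
    projection to ``feature_dim``.  The filters are drawn once from a seeded
    generator and never updated, so inference is deterministic; only the
    metric head downstream is trained.
    """

    def __init__(self, image_size: int = 48, channels: int = 3,
                 feature_dim: int = 768, seed: int = 0):
        if image_size % 8 != 0:
            raise ValidationError("image_size must be divisible by 8 (three 2x2 pools)")
        self.image_size = image_size
        self.channels = channels
        self.feature_dim = feature_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [channels, 12, 24, 48]
        self.filters = [
            rng.standard_normal((widths[i + 1], widths[i], 3, 3))
            * np.sqrt(2.0 / (widths[i] * 9))
            for i in range(3)
        ]
        flat = (image_size // 8) ** 2 * widths[-1]
        self.proj = rng.standard_normal((flat, feature_dim)) / np.sqrt(flat)

    @staticmethod
    def _conv_relu_pool(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
        # x: (B, C, H, W), filt: (O, C, 3, 3); "same" padding then 2x2 max-pool
        b, c, h, w = x.shape
        o = filt.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # im2col
        cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = cols.reshape(b, c, h, w, 9).transpose(0, 2, 3, 1, 4).reshape(b, h * w, c * 9)
        out = cols @ filt.reshape(o, c * 9).T            # (B, H*W, O)
        out = np.maximum(out, 0.0).reshape(b, h, w, o).transpose(0, 3, 1, 2)
        return out.reshape(b, o, h // 2, 2, w // 2, 2).max(axis=(3, 5))

    def extract(self, images: np.ndarray) -> np.ndarray:
        """Images (B, H, W, C) in [0, 1] -> (B, feature_dim) features."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[1] != self.image_size \
                or images.shape[3] != self.channels:
            raise ShapeError(
                f"expected (batch, {self.image_size}, {self.image_size}, "
                f"{self.channels}) images")
        x = images.transpose(0, 3, 1, 2)
        for filt in self.filters:
            x = self._conv_relu_pool(x, filt)
        flat = x.reshape(x.shape[0], -1)
        return np.tanh(flat @ self.proj)


class PrecomputedBackbone:
    """Backbone stand-in used when features are already extracted."""

    def __init__(self, feature_dim: int):
        self.feature_dim = feature_dim

    def extract(self, images: np.ndarray) -> np.ndarray:
        feats = np.asarray(images, dtype=np.float64)
        if feats.ndim != 2 or feats.shape[1] != self.feature_dim:
            raise ShapeError(f"expected (batch, {self.feature_dim}) features")
        return feats


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimization settings for the head + loss parameters.

    The published reference setting is Adam at 1e-5 with step decay, 200
    epochs, batch 128; desk-scale runs use fewer epochs and a larger rate.
    """

    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-5
    lr_decay_every: int = 0          # 0 disables step decay
    lr_decay_factor: float = 0.5
    seed: int = 0


class _Adam:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainedEmbedder:
    """A trained extractor: backbone -> standardization -> head -> L2 norm."""

    backbone: BackboneContract
    head: EmbeddingHead
    feat_mean: np.ndarray
    feat_std: np.ndarray
    history: list[dict] = field(default_factory=list)

    def embed(self, images_or_features: np.ndarray) -> np.ndarray:
        """Deterministic inference embeddings, unit-norm rows."""
        feats = self.backbone.extract(images_or_features)
        feats = (feats - self.feat_mean) / self.feat_std
        return l2_normalize(self.head.forward_eval(feats))

    # -- checkpointing -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """npz weight container with an embedded JSON config manifest."""
        path = Path(path)
        manifest = {
            "head_config": vars(self.head.config),
            "feature_dim": self.backbone.feature_dim,
            "backbone": type(self.backbone).__name__,
            "backbone_seed": getattr(self.backbone, "seed", None),
            "backbone_image_size": getattr(self.backbone, "image_size", None),
            "backbone_channels": getattr(self.backbone, "channels", None),
        }
        arrays = {f"head_{k}": v for k, v in self.head.state_dict().items()}
        arrays["feat_mean"] = self.feat_mean
        arrays["feat_std"] = self.feat_std
        np.savez(path, manifest=json.dumps(manifest), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEmbedder":
        with np.load(Path(path), allow_pickle=False) as data:
            manifest = json.loads(str(data["manifest"]))
            head = EmbeddingHead(EmbeddingHeadConfig(**manifest["head_config"]))
            head.load_state_dict(
                {k[5:]: data[k] for k in data.files if k.startswith("head_")})
            if manifest["backbone"] == "TinyConvBackbone":
                backbone: BackboneContract = TinyConvBackbone(
                    image_size=manifest["backbone_image_size"],
                    channels=manifest["backbone_channels"],
                    feature_dim=manifest["feature_dim"],
                    seed=manifest["backbone_seed"])
            else:
                backbone = PrecomputedBackbone(manifest["feature_dim"])
            return cls(backbone=backbone, head=head,
                       feat_mean=data["feat_mean"], feat_std=data["feat_std"])


def train_embedder(train_items: np.ndarray, labels: np.ndarray,
                   backbone: BackboneContract | None = None,
                   head_config: EmbeddingHeadConfig | None = None,
                   loss_config: DualLossConfig | None = None,
                   train_config: TrainConfig | None = None) -> TrainedEmbedder:
    """Train the embedding head with the dual loss.

    ``train_items`` is either a batch of images (with a backbone) or a matrix
    of precomputed features.  The backbone is frozen; its features are
    extracted once, standardized, and the head + sub-center bank + class
    centers are optimized jointly with Adam.  Per-epoch mean losses are
    recorded in ``history``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError(
            "training needs >= 2 classes: the angular-margin loss is degenerate "
            "with a single class")
    if not np.array_equal(classes, np.arange(classes.size)):
        raise ValidationError("labels must be contiguous integers starting at 0")

    head_config = head_config or EmbeddingHeadConfig()
    loss_config = loss_config or DualLossConfig()
    train_config = train_config or TrainConfig()
    rng = np.random.default_rng(train_config.seed)

    if backbone is None:
        backbone = PrecomputedBackbone(feature_dim=np.asarray(train_items).shape[1])
    feats = backbone.extract(np.asarray(train_items))
    feat_mean = feats.mean(axis=0)
    feat_std = feats.std(axis=0) + 1e-8
    feats = (feats - feat_mean) / feat_std

    head = EmbeddingHead(head_config, rng=rng)
    bank = SubCenterBank.random(classes.size, loss_config.num_subcenters,
                                head_config.out_dim, rng=rng)
    w_bank = Tensor(bank.weights, requires_grad=True)
    centers = Tensor(np.zeros((classes.size, head_config.out_dim)),
                     requires_grad=True)

    params = head.params() + [w_bank, centers]
    opt = _Adam(params, train_config.learning_rate)
    n = feats.shape[0]
    history: list[dict] = []
    for epoch in range(train_config.epochs):
        if (train_config.lr_decay_every
                and epoch and epoch % train_config.lr_decay_every == 0):
            opt.lr *= train_config.lr_decay_factor
        order = rng.permutation(n)
        sums = np.zeros(3)
        steps = 0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            if idx.size < 2:
                continue  # batch-norm needs >= 2 samples
            emb = head.forward_train(feats[idx], rng)
            sal = arcface_graph(emb, w_bank, labels[idx], loss_config)
            cen = center_graph(emb, centers, labels[idx],
                               loss_config.center_reduction)
            total = sal * loss_config.lambda_arcface + cen * loss_config.lambda_center
            opt.zero_grad()
            total.backward()
            opt.step()
            # keep sub-centers on the unit sphere after each update
            w_bank.data /= np.linalg.norm(w_bank.data, axis=-1, keepdims=True)
            sums += (total.item(), sal.item(), cen.item())
            steps += 1
        if steps == 0:
            raise StateError("no trainable batch of size >= 2 could be formed")
        history.append({"epoch": epoch, "total": sums[0] / steps,
                        "arcface": sums[1] / steps, "center": sums[2] / steps})

    return TrainedEmbedder(backbone=backbone, head=head, feat_mean=feat_mean,
                           feat_std=feat_std, history=history)
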