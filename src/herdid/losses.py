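"""Dual metric-learning objective: sub-center ArcFace plus center loss.

The embedding network is trained with a weighted sum of two complementary
losses.  The *sub-center ArcFace* loss is an additive angular-margin softmax
in which every class ``j`` owns ``K`` unit-norm sub-center weight vectors
``W_j^k``; the class cosine for a sample is the **maximum** cosine over the
class's sub-centers, which lets a multimodal class (pose, lighting, growth
stage) occupy several modes without paying an intra-class penalty:

    theta_ij = arccos( max_k  W_j^k . x_i / |x_i| )
    L_SAL    = mean_i  -log  e^{s cos(theta_iy + m)}
                       / ( e^{s cos(theta_iy + m)} + sum_{j != y} e^{s cos(theta_ij)} )

with angular margin ``m`` (given in degrees, applied in radians) and logit
scale ``s``.  The *center loss* pulls each embedding toward its class center
``c_y`` and controls intra-class spread:

    L_center = sum_i |x_i - c_{y_i}|^2      (a batch-mean variant is available)

The total objective is ``lambda1 * L_SAL + lambda2 * L_center`` with defaults
``m = 28.6 deg, s = 64, K = 3, lambda1 = 1, lambda2 = 0.5``.

All losses are differentiable with respect to the embeddings, the sub-center
bank, and the class centers; pass ``return_grads=True`` to obtain analytic
gradients (used by the trainer and checked against finite differences in the
test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .exceptions import ShapeError, ValidationError

__all__ = [
    "LossBatch",
    "SubCenterBank",
    "ClassCenters",
    "DualLossConfig",
    "DualLossValue",
    "angular_logits",
    "subcenter_arcface_loss",
    "center_loss",
    "dual_loss",
]

#: cosines are clamped to [-1 + COS_EPS, 1 - COS_EPS] before arccos
COS_EPS = 1e-7


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class LossBatch:
    """A mini-batch of embeddings ``x_i`` with integer identity labels ``y_i``."""

    embeddings: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.embeddings.ndim != 2:
            raise ShapeError("embeddings must be a 2-D (batch, dim) array")
        if self.labels.ndim != 1 or self.labels.shape[0] != self.embeddings.shape[0]:
            raise ShapeError("labels must be 1-D with one entry per embedding")
        if self.embeddings.shape[0] < 1:
            raise ValidationError("batch must contain at least one sample")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValidationError("embeddings contain non-finite values")
        if np.any(self.labels < 0):
            raise ValidationError("labels must be non-negative class indices")

    @property
    def batch_size(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]


@dataclass
class SubCenterBank:
    """Per-class sub-center weight vectors, shape (C, K, D), each unit-norm."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ShapeError("weights must have shape (classes, subcenters, dim)")
        if self.weights.shape[0] < 1 or self.weights.shape[1] < 1:
            raise ValidationError("need at least one class and one sub-center")
        norms = np.linalg.norm(self.weights, axis=-1)
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("sub-center weights contain non-finite values")
        if np.any(norms < 1e-12):
            raise ValidationError("sub-center vectors must be non-zero")
        # store unit-normalized
        self.weights = self.weights / norms[..., None]

    @property
    def num_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def num_subcenters(self) -> int:
        return self.weights.shape[1]

    @property
    def dim(self) -> int:
        return self.weights.shape[2]

    @classmethod
    def random(cls, num_classes: int, num_subcenters: int, dim: int,
               rng: np.random.Generator | int | None = None) -> "SubCenterBank":
        """Isotropic Gaussian draws, unit-normalized; seedable."""
        rng = np.random.default_rng(rng)
        w = rng.standard_normal((num_classes, num_subcenters, dim))
        return cls(w)


@dataclass
class ClassCenters:
    """Class centers ``c_y`` for the center loss, shape (C, D)."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.centers.ndim != 2:
            raise ShapeError("centers must have shape (classes, dim)")
        if not np.all(np.isfinite(self.centers)):
            raise ValidationError("centers contain non-finite values")

    @property
    def num_classes(self) -> int:
        return self.centers.shape[0]

    @classmethod
    def zeros(cls, num_classes: int, dim: int) -> "ClassCenters":
        return cls(np.zeros((num_classes, dim)))


@dataclass
class DualLossConfig:
    """Hyperparameters of the combined objective.

    ``margin_deg`` is accepted in degrees and converted to radians
    internally (28.6 deg = 0.4991 rad, the canonical ArcFace margin).
    """

    margin_deg: float = 28.6
    scale: float = 64.0
    num_subcenters: int = 3
    lambda_arcface: float = 1.0
    lambda_center: float = 0.5
    center_reduction: str = "sum"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("scale must be positive")
        if self.margin_deg < 0:
            raise ValidationError("margin must be non-negative")
        if self.lambda_arcface < 0 or self.lambda_center < 0:
            raise ValidationError("loss weights must be non-negative")
        if self.num_subcenters < 1:
            raise ValidationError("need at least one sub-center")
        if self.center_reduction not in ("sum", "mean"):
            raise ValidationError("center_reduction must be 'sum' or 'mean'")

    @property
    def margin_rad(self) -> float:
        return float(np.deg2rad(self.margin_deg))


@dataclass
class DualLossValue:
    """Total loss with its two components."""

    total: float
    arcface: float
    center: float
    grads: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# graph builders (shared by the public API and the trainer)
# --------------------------------------------------------------------------

def _l2norm_rows(t: Tensor) -> Tensor:
    """Unit-normalize along the last axis inside the autodiff graph."""
    sq = (t * t).sum(axis=-1, keepdims=True)
    return t / (sq + 1e-24).sqrt()


def arcface_graph(x: Tensor, weights: Tensor, labels: np.ndarray,
                  config: DualLossConfig) -> Tensor:
    """Sub-center ArcFace loss as an autodiff graph node (batch mean).

    ``weights`` has shape (C, K, D); embeddings need not be pre-normalized.
    The margin term uses cos(t + m) = cos t cos m - sin t sin m, which keeps
    the graph free of arccos.
    """
    n, d = x.shape
    c, k, d2 = weights.shape
    if d != d2:
        raise ShapeError(f"embedding dim {d} != sub-center dim {d2}")
    xn = _l2norm_rows(x)
    wn = _l2norm_rows(weights)
    # (N, D) @ (D, C*K) -> (N, C, K) -> max over sub-centers
    cos_all = (xn @ wn.reshape(c * k, d).T).reshape(n, c, k)
    cos_cls = cos_all.max(axis=2).clip(-1.0 + COS_EPS, 1.0 - COS_EPS)  # (N, C)

    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0

    cos_y = (cos_cls * onehot).sum(axis=1)                      # (N,)
    sin_y = (1.0 - cos_y * cos_y).clip(0.0, 1.0).sqrt()
    m = config.margin_rad
    cos_y_m = cos_y * np.cos(m) - sin_y * np.sin(m)             # cos(theta_y + m)

    logits = cos_cls * (1.0 - onehot) + cos_y_m.reshape(n, 1) * onehot
    logits = logits * config.scale

    # numerically stable log-sum-exp; the row max is a constant w.r.t. grads
    row_max = logits.data.max(axis=1, keepdims=True)
    lse = (logits - row_max).exp().sum(axis=1, keepdims=True).log() + row_max
    target = (logits * onehot).sum(axis=1, keepdims=True)
    return (lse - target).mean()


def center_graph(x: Tensor, centers: Tensor, labels: np.ndarray,
                 reduction: str = "sum") -> Tensor:
    """Center loss as an autodiff graph node."""
    diff = x - centers[labels]
    total = (diff * diff).sum()
    if reduction == "mean":
        return total * (1.0 / x.shape[0])
    return total


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def _check_labels(batch: LossBatch, num_classes: int) -> None:
    if num_classes < 1:
        raise ValidationError("need at least one class")
    if np.any(batch.labels >= num_classes):
        raise ValidationError(
            f"label {int(batch.labels.max())} out of range for {num_classes} classes")


def angular_logits(batch: LossBatch, bank: SubCenterBank) -> np.ndarray:
    """Per-sample, per-class angles theta_ij in radians, shape (N, C).

    theta_ij = arccos of the clamped maximum cosine between the (internally
    normalized) embedding x_i and the K sub-centers of class j.
    """
    if batch.dim != bank.dim:
        raise ShapeError(f"embedding dim {batch.dim} != sub-center dim {bank.dim}")
    xn = batch.embeddings / np.linalg.norm(batch.embeddings, axis=1, keepdims=True)
    cos = np.einsum("nd,ckd->nck", xn, bank.weights).max(axis=2)
    cos = np.clip(cos, -1.0 + COS_EPS, 1.0 - COS_EPS)
    return np.arccos(cos)


def subcenter_arcface_loss(batch: LossBatch, bank: SubCenterBank,
                           config: DualLossConfig | None = None,
                           return_grads: bool = False):
    """Mean sub-center ArcFace loss over the batch.

    With ``return_grads=True`` returns ``(loss, grads)`` where ``grads`` maps
    ``"embeddings"`` and ``"weights"`` to analytic gradients.
    """
    config = config or DualLossConfig()
    _check_labels(batch, bank.num_classes)
    x = Tensor(batch.embeddings, requires_grad=True)
    w = Tensor(bank.weights, requires_grad=True)
    loss = arcface_graph(x, w, batch.labels, config)
    if not return_grads:
        return loss.item()
    loss.backward()
    return loss.item(), {"embeddings": x.grad, "weights": w.grad}


def center_loss(batch: LossBatch, centers: ClassCenters,
                reduction: str = "sum", return_grads: bool = False):
    """Center loss: sum (or batch mean) of squared distances |x_i - c_{y_i}|^2."""
    if reduction not in ("sum", "mean"):
        raise ValidationError("reduction must be 'sum' or 'mean'")
    if centers.centers.shape[1] != batch.dim:
        raise ShapeError("center dim does not match embedding dim")
    _check_labels(batch, centers.num_classes)
    x = Tensor(batch.embeddings, requires_grad=True)
    c = Tensor(centers.centers, requires_grad=True)
    loss = center_graph(x, c, batch.labels, reduction)
    if not return_grads:
        return loss.item()
    loss.backward()
    return loss.item(), {"embeddings": x.grad, "centers": c.grad}


def dual_loss(batch: LossBatch, bank: SubCenterBank, centers: ClassCenters,
              config: DualLossConfig | None = None,
              return_grads: bool = False) -> DualLossValue:
    """Weighted total:  lambda1 * L_SAL + lambda2 * L_center."""
    config = config or DualLossConfig()
    _check_labels(batch, bank.num_classes)
    _check_labels(batch, centers.num_classes)
    x = Tensor(batch.embeddings, requires_grad=True)
    w = Tensor(bank.weights, requires_grad=True)
    c = Tensor(centers.centers, requires_grad=True)
    sal = arcface_graph(x, w, batch.labels, config)
    cen = center_graph(x, c, batch.labels, config.center_reduction)
    total = sal * config.lambda_arcface + cen * config.lambda_center
    value = DualLossValue(total=total.item(), arcface=sal.item(), center=cen.item())
    if return_grads:
        total.backward()
        value.grads = {"embeddings": x.grad, "weights": w.grad, "centers": c.grad}
    return value
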