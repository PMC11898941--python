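"""Synthetic identities for exercising the full pipeline without real data.

Two fidelity levels are generated, both seeded:

* **Embedding level** — each identity is a von Mises-Fisher cluster on the
  unit hypersphere: a mean direction plus samples with concentration kappa.
  High kappa means tight identity clusters (strong identity signal); kappa
  near zero degenerates to uniform draws (no signal).  This level exercises
  the gallery and evaluation modules in milliseconds.

* **Image level** — each identity is a procedural pattern (seeded blob and
  stripe parameters on a small canvas); images of one identity share the
  pattern and differ only by nuisance draws (brightness, translation,
  occlusion, pixel noise).  This level exercises the backbone + trained
  embedding head.

Either level is arranged into the five-way open-set protocol: a known-identity
training split, a per-identity gallery-registration split, a known-identity
test split, an unknown-identity registration split and an unknown-identity
test split.  Protocol defaults mirror the study scale (56 known and 9 unknown
identities, 30 gallery images each); the test-suite preset is 8/3/10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import vonmises_fisher

from .exceptions import ValidationError

__all__ = [
    "ClusterSpec",
    "ImageSpec",
    "ProtocolCounts",
    "SyntheticProtocol",
    "sample_cluster_embeddings",
    "render_identity_images",
    "make_embedding_protocol",
    "make_image_protocol",
]


# --------------------------------------------------------------------------
# embedding-level simulation
# --------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    """Von Mises-Fisher identity clusters on the unit sphere in R^dim."""

    num_identities: int
    samples_per_identity: int
    dim: int = 64
    kappa: float = 50.0
    min_angle_deg: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValidationError("dim must be >= 2")
        if self.kappa < 0:
            raise ValidationError("kappa must be non-negative")
        if self.num_identities < 1 or self.samples_per_identity < 1:
            raise ValidationError("counts must be >= 1")


def _sample_means(spec: ClusterSpec, rng: np.random.Generator) -> np.ndarray:
    """Mean directions with pairwise angle >= min_angle_deg (rejection)."""
    min_cos = np.cos(np.deg2rad(spec.min_angle_deg))
    means: list[np.ndarray] = []
    for _ in range(spec.num_identities):
        for _attempt in range(2000):
            v = rng.standard_normal(spec.dim)
            v /= np.linalg.norm(v)
            if all(v @ m < min_cos for m in means):
                means.append(v)
                break
        else:
            raise ValidationError(
                f"could not place {spec.num_identities} identity means with "
                f"pairwise angle >= {spec.min_angle_deg} deg in dimension "
                f"{spec.dim}; lower min_angle_deg or num_identities")
    return np.stack(means)


def sample_cluster_embeddings(
        spec: ClusterSpec,
        means: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labeled unit vectors: (embeddings, labels, means).

    ``kappa = 0`` draws uniformly on the sphere (no identity structure);
    otherwise each identity's samples are vMF around its mean direction.
    Passing ``means`` reuses previously drawn identity directions so that
    several splits share the same identities.
    """
    rng = np.random.default_rng(spec.seed)
    if means is None:
        means = _sample_means(spec, rng)
    n = spec.num_identities * spec.samples_per_identity
    labels = np.repeat(np.arange(spec.num_identities), spec.samples_per_identity)
    if spec.kappa < 1e-9:
        x = rng.standard_normal((n, spec.dim))
        emb = x / np.linalg.norm(x, axis=1, keepdims=True)
    else:
        parts = []
        for i in range(spec.num_identities):
            dist = vonmises_fisher(means[i], spec.kappa)
            parts.append(dist.rvs(spec.samples_per_identity, random_state=rng))
        emb = np.concatenate(parts, axis=0)
    return emb, labels, means


# --------------------------------------------------------------------------
# image-level simulation
# --------------------------------------------------------------------------

@dataclass
class ImageSpec:
    """Procedural identity images on a small square canvas."""

    canvas: int = 48
    num_blobs: int = 4
    brightness_range: tuple[float, float] = (0.7, 1.3)
    max_shift: int = 3
    occlusion_fraction: float = 0.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas < 32:
            raise ValidationError("canvas must be >= 32 px")
        if not (0.0 <= self.occlusion_fraction < 1.0):
            raise ValidationError("occlusion_fraction must be in [0, 1)")


def _identity_pattern(spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    """One identity's base pattern: colored Gaussian blobs over striped texture."""
    c = spec.canvas
    yy, xx = np.mgrid[0:c, 0:c].astype(np.float64)
    img = np.zeros((c, c, 3))
    # per-identity sinusoidal texture
    freq = rng.uniform(0.1, 0.5, size=2)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    base = 0.25 + 0.15 * np.sin(freq[0] * xx + phase[0]) * np.sin(freq[1] * yy + phase[1])
    img += base[..., None] * rng.uniform(0.4, 1.0, size=3)
    # per-identity blob constellation (the "facial landmarks")
    for _ in range(spec.num_blobs):
        cy, cx = rng.uniform(0.15 * c, 0.85 * c, size=2)
        sig = rng.uniform(0.04 * c, 0.12 * c)
        color = rng.uniform(0.3, 1.0, size=3)
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2))
        img += blob[..., None] * color
    return np.clip(img, 0.0, 1.0)


def _apply_nuisance(pattern: np.ndarray, spec: ImageSpec,
                    rng: np.random.Generator) -> np.ndarray:
    img = pattern.copy()
    if spec.max_shift > 0:
        dy, dx = rng.integers(-spec.max_shift, spec.max_shift + 1, size=2)
        img = np.roll(img, (dy, dx), axis=(0, 1))
    lo, hi = spec.brightness_range
    if hi > lo:
        img = img * rng.uniform(lo, hi)
    if spec.occlusion_fraction > 0:
        c = spec.canvas
        side = int(round(np.sqrt(spec.occlusion_fraction) * c))
        if side > 0:
            y0 = rng.integers(0, c - side + 1)
            x0 = rng.integers(0, c - side + 1)
            img[y0:y0 + side, x0:x0 + side] = rng.uniform(0, 1, size=3)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_identity_images(spec: ImageSpec, num_identities: int,
                           images_per_identity: int,
                           out_dir: str | Path | None = None
                           ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Images (N, canvas, canvas, 3) in [0, 1], labels, and a manifest.

    Same-identity images share the seeded pattern and differ only by nuisance
    draws.  If ``out_dir`` is given, PNGs and a ``manifest.csv`` (columns:
    path, identity_id) are written there.
    """
    rng = np.random.default_rng(spec.seed)
    patterns = [_identity_pattern(spec, rng) for _ in range(num_identities)]
    images, labels, rows = [], [], []
    for ident in range(num_identities):
        for j in range(images_per_identity):
            images.append(_apply_nuisance(patterns[ident], spec, rng))
            labels.append(ident)
            rows.append({"path": f"id{ident:03d}_img{j:03d}.png",
                         "identity_id": ident})
    images_arr = np.stack(images)
    labels_arr = np.asarray(labels, dtype=np.int64)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import imageio.v3 as iio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images_arr, rows):
            iio.imwrite(out / row["path"], (img * 255).astype(np.uint8))
        manifest.to_csv(out / "manifest.csv", index=False)
    return images_arr, labels_arr, manifest


# --------------------------------------------------------------------------
# the five-way protocol
# --------------------------------------------------------------------------

@dataclass
class ProtocolCounts:
    """Split sizes; defaults mirror the study design (56/9/30)."""

    known_identities: int = 56
    unknown_identities: int = 9
    gallery_per_identity: int = 30
    train_per_identity: int = 30
    test_per_identity: int = 10

    @classmethod
    def desk_scale(cls) -> "ProtocolCounts":
        """The scaled-down preset used by the fast test-suite."""
        return cls(known_identities=8, unknown_identities=3,
                   gallery_per_identity=10, train_per_identity=30,
                   test_per_identity=10)


@dataclass
class SyntheticProtocol:
    """Items + identity labels for the five protocol roles.

    Known identities are labeled ``known_<i>``, unknown ones ``unk_<i>``;
    unknown identities never occur in the ``known_*`` splits and every item
    belongs to exactly one split.
    """

    known_train: tuple[np.ndarray, np.ndarray]
    known_gallery: tuple[np.ndarray, np.ndarray]
    known_test: tuple[np.ndarray, np.ndarray]
    unknown_register: tuple[np.ndarray, np.ndarray]
    unknown_test: tuple[np.ndarray, np.ndarray]
    counts: ProtocolCounts = field(default_factory=ProtocolCounts)

    def split_labels(self, split: str) -> np.ndarray:
        return getattr(self, split)[1]

    def describe(self) -> dict:
        return {name: {"items": int(getattr(self, name)[0].shape[0]),
                       "identities": int(len(set(getattr(self, name)[1])))}
                for name in ("known_train", "known_gallery", "known_test",
                             "unknown_register", "unknown_test")}


def _tag(labels: np.ndarray, prefix: str) -> np.ndarray:
    return np.array([f"{prefix}_{int(v)}" for v in labels], dtype=object)


def _split_rows(items: np.ndarray, labels: np.ndarray,
                sizes: list[int]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition each identity's items into consecutive chunks of ``sizes``."""
    outs: list[list] = [[[], []] for _ in sizes]
    for ident in np.unique(labels):
        rows = np.flatnonzero(labels == ident)
        need = sum(sizes)
        if rows.size < need:
            raise ValidationError(
                f"identity {ident} has {rows.size} items, protocol needs {need}")
        start = 0
        for slot, size in enumerate(sizes):
            take = rows[start:start + size]
            outs[slot][0].append(items[take])
            outs[slot][1].append(labels[take])
            start += size
    return [(np.concatenate(a), np.concatenate(b)) for a, b in outs]


def make_embedding_protocol(counts: ProtocolCounts | None = None,
                            dim: int = 64, kappa: float = 50.0,
                            min_angle_deg: float = 25.0,
                            seed: int = 0) -> SyntheticProtocol:
    """Five-way protocol at embedding fidelity (vMF clusters).

    Known and unknown identities draw their mean directions from the same
    seeded stream (with the packing constraint applied across all of them),
    then each split samples fresh vectors around the identity means.
    """
    counts = counts or ProtocolCounts()
    rng = np.random.default_rng(seed)
    total = counts.known_identities + counts.unknown_identities
    per_known = (counts.train_per_identity + counts.gallery_per_identity
                 + counts.test_per_identity)
    per_unknown = counts.gallery_per_identity + counts.test_per_identity
    per_id = max(per_known, per_unknown)
    spec = ClusterSpec(num_identities=total, samples_per_identity=per_id,
                       dim=dim, kappa=kappa, min_angle_deg=min_angle_deg,
                       seed=int(rng.integers(2 ** 31)))
    emb, labels, _ = sample_cluster_embeddings(spec)

    known_ids = np.arange(counts.known_identities)
    unk_ids = np.arange(counts.known_identities, total)
    kmask = np.isin(labels, known_ids)

    ktrain, kgal, ktest = _split_rows(
        emb[kmask], labels[kmask],
        [counts.train_per_identity, counts.gallery_per_identity,
         counts.test_per_identity])
    ureg, utest = _split_rows(
        emb[~kmask], labels[~kmask],
        [counts.gallery_per_identity, counts.test_per_identity])

    return SyntheticProtocol(
        known_train=(ktrain[0], _tag(ktrain[1], "known")),
        known_gallery=(kgal[0], _tag(kgal[1], "known")),
        known_test=(ktest[0], _tag(ktest[1], "known")),
        unknown_register=(ureg[0], _tag(ureg[1] - counts.known_identities, "unk")),
        unknown_test=(utest[0], _tag(utest[1] - counts.known_identities, "unk")),
        counts=counts)


def make_image_protocol(counts: ProtocolCounts | None = None,
                        image_spec: ImageSpec | None = None,
                        seed: int = 0) -> SyntheticProtocol:
    """Five-way protocol at image fidelity (procedural identity patterns)."""
    counts = counts or ProtocolCounts.desk_scale()
    base = image_spec or ImageSpec()
    rng = np.random.default_rng(seed)
    spec = ImageSpec(canvas=base.canvas, num_blobs=base.num_blobs,
                     brightness_range=base.brightness_range,
                     max_shift=base.max_shift,
                     occlusion_fraction=base.occlusion_fraction,
                     noise_sigma=base.noise_sigma,
                     seed=int(rng.integers(2 ** 31)))
    total = counts.known_identities + counts.unknown_identities
    per_known = (counts.train_per_identity + counts.gallery_per_identity
                 + counts.test_per_identity)
    per_unknown = counts.gallery_per_identity + counts.test_per_identity
    per_id = max(per_known, per_unknown)
    images, labels, _ = render_identity_images(spec, total, per_id)

    known_ids = np.arange(counts.known_identities)
    kmask = np.isin(labels, known_ids)
    ktrain, kgal, ktest = _split_rows(
        images[kmask], labels[kmask],
        [counts.train_per_identity, counts.gallery_per_identity,
         counts.test_per_identity])
    ureg, utest = _split_rows(
        images[~kmask], labels[~kmask],
        [counts.gallery_per_identity, counts.test_per_identity])
    return SyntheticProtocol(
        known_train=(ktrain[0], _tag(ktrain[1], "known")),
        known_gallery=(kgal[0], _tag(kgal[1], "known")),
        known_test=(ktest[0], _tag(ktest[1], "known")),
        unknown_register=(ureg[0], _tag(ureg[1] - counts.known_identities, "unk")),
        unknown_test=(utest[0], _tag(utest[1] - counts.known_identities, "unk")),
        counts=counts)
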