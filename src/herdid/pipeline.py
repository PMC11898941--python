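"""End-to-end glue: protocol -> gallery -> score table -> metrics.

These helpers chain the individual modules the way the deployed system runs:
embed the gallery-registration split, enroll each known identity, embed the
known and unknown test splits, match them 1:N, and hand the score table to
the evaluation suite.  They work identically for embedding-level protocols
(items already are vectors; ``embed_fn=None``) and image-level protocols
(``embed_fn`` is a trained extractor's ``embed``).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .embedder import (DualLossConfig, EmbeddingHeadConfig, TinyConvBackbone,
                       TrainConfig, TrainedEmbedder, train_embedder)
from .gallery import FeatureGallery, OpenSetPolicy, dynamic_register
from .openset_eval import (OpenSetScoreTable, ThresholdSweepResult,
                           full_report, score_queries, threshold_sweep)
from .synthetic import SyntheticProtocol

__all__ = [
    "build_gallery",
    "score_protocol",
    "evaluate_protocol",
    "train_on_protocol",
    "register_unknowns",
]

EmbedFn = Callable[[np.ndarray], np.ndarray]


def _maybe_embed(items: np.ndarray, embed_fn: EmbedFn | None) -> np.ndarray:
    return np.asarray(items, dtype=np.float64) if embed_fn is None else embed_fn(items)


def build_gallery(items: np.ndarray, labels: np.ndarray,
                  embed_fn: EmbedFn | None = None,
                  n_img: int | None = None, strict: bool = True) -> FeatureGallery:
    """Enroll every identity present in ``labels`` with its embeddings."""
    emb = _maybe_embed(items, embed_fn)
    labels = np.asarray(labels, dtype=object)
    identities = sorted(set(labels), key=str)
    counts = [int(np.sum(labels == i)) for i in identities]
    if n_img is None:
        n_img = counts[0]
    gallery = FeatureGallery(dim=emb.shape[1], n_img=n_img, strict=strict)
    for identity in identities:
        gallery.register_identity(identity, emb[labels == identity])
    return gallery


def score_protocol(protocol: SyntheticProtocol,
                   embed_fn: EmbedFn | None = None) -> OpenSetScoreTable:
    """Gallery from the registration split; score known + unknown test queries.

    Unknown-identity queries enter the table with the UNKNOWN ground truth
    label regardless of their generator-side identity tag.
    """
    from .gallery import UNKNOWN

    gallery = build_gallery(*protocol.known_gallery, embed_fn=embed_fn,
                            n_img=protocol.counts.gallery_per_identity)
    k_items, k_labels = protocol.known_test
    u_items, _ = protocol.unknown_test
    queries = np.concatenate([_maybe_embed(k_items, embed_fn),
                              _maybe_embed(u_items, embed_fn)])
    truth = np.concatenate([k_labels,
                            np.full(u_items.shape[0], UNKNOWN, dtype=object)])
    return score_queries(gallery, queries, truth)


def evaluate_protocol(protocol: SyntheticProtocol,
                      embed_fn: EmbedFn | None = None,
                      theta: float | None = None
                      ) -> tuple[OpenSetScoreTable, ThresholdSweepResult, dict]:
    """Score table, threshold sweep and the full metric report."""
    table = score_protocol(protocol, embed_fn)
    sweep = threshold_sweep(table)
    report = full_report(table, theta)
    return table, sweep, report


def train_on_protocol(protocol: SyntheticProtocol,
                      backbone: TinyConvBackbone | None = None,
                      head_config: EmbeddingHeadConfig | None = None,
                      loss_config: DualLossConfig | None = None,
                      train_config: TrainConfig | None = None) -> TrainedEmbedder:
    """Train the embedding head on the protocol's known training split.

    The generator tags known identities ``known_<i>``; they are mapped to
    contiguous class indices for the loss.
    """
    items, labels = protocol.known_train
    classes = {c: i for i, c in enumerate(sorted(set(labels), key=str))}
    y = np.array([classes[v] for v in labels], dtype=np.int64)
    if backbone is None and np.asarray(items).ndim == 4:
        backbone = TinyConvBackbone(image_size=items.shape[1],
                                    channels=items.shape[3])
    return train_embedder(items, y, backbone=backbone, head_config=head_config,
                          loss_config=loss_config, train_config=train_config)


def register_unknowns(gallery: FeatureGallery, protocol: SyntheticProtocol,
                      policy: OpenSetPolicy,
                      embed_fn: EmbedFn | None = None):
    """Feed the unknown-registration split through dynamic registration.

    Each unknown identity forms one stream group; its registration embeddings
    double as the queries (first sighting).  Returns (gallery, log).
    """
    items, labels = protocol.unknown_register
    emb = _maybe_embed(items, embed_fn)
    stream = []
    for identity in sorted(set(labels), key=str):
        rows = emb[np.asarray(labels, dtype=object) == identity]
        stream.append((identity, rows, rows))
    return dynamic_register(gallery, stream, policy)
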