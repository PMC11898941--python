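"""Dynamic feature gallery: 1:N cosine matching and open-set enrollment.

The gallery is the reference database of the recognition system: for each
enrolled identity it stores ``n_img`` unit-norm embeddings (conceptually an
(N_class, N_img, D) array).  A query embedding is compared against every
stored vector by cosine similarity; the identity holding the highest score is
the 1:N match.  If that best score falls below the acceptance threshold the
query is declared UNKNOWN, and — when a registration set for the new
individual is supplied — the gallery grows by one identity without any
retraining (dynamic registration).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .embedder import l2_normalize
from .exceptions import (ConflictError, ShapeError, StateError,
                         ValidationError)

__all__ = [
    "UNKNOWN",
    "FeatureGallery",
    "MatchResult",
    "OpenSetPolicy",
    "cosine_similarity",
    "open_set_decide",
    "dynamic_register",
]

#: sentinel label for queries rejected as not belonging to any enrolled identity
UNKNOWN = "UNKNOWN"


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (|a||b|), in [-1, 1]; symmetric, scale-invariant."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ShapeError("vectors must share dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValidationError("cosine similarity undefined for zero vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class MatchResult:
    """Outcome of one 1:N lookup: best identity, best score, top-k ranking."""

    best_identity: str
    best_score: float
    topk: list[tuple[str, float]]
    query_id: str | None = None


@dataclass
class OpenSetPolicy:
    """Accept/reject rule for open-set decisions.

    A best score >= ``threshold`` is accepted as the matched known identity;
    strictly below it the query is declared UNKNOWN.  ``aggregation`` chooses
    how per-identity scores are pooled for the ranking: the max over that
    identity's stored vectors (the decision rule) or their mean.
    """

    threshold: float
    aggregation: str = "max"

    def __post_init__(self) -> None:
        if not (-1.0 <= self.threshold <= 1.0):
            raise ValidationError("threshold must lie in [-1, 1]")
        if self.aggregation not in ("max", "mean"):
            raise ValidationError("aggregation must be 'max' or 'mean'")


class FeatureGallery:
    """Identity-indexed store of unit-norm reference embeddings.

    In strict mode every identity must hold exactly ``n_img`` embeddings
    (the (N_class, N_img, D) layout); lenient mode permits ragged counts.
    """

    def __init__(self, dim: int, n_img: int = 30, strict: bool = True):
        if dim < 1 or n_img < 1:
            raise ValidationError("dim and n_img must be >= 1")
        self.dim = dim
        self.n_img = n_img
        self.strict = strict
        self._store: dict[str, np.ndarray] = {}   # insertion-ordered

    # -- views ---------------------------------------------------------------

    @property
    def identity_ids(self) -> list[str]:
        return list(self._store.keys())

    @property
    def num_identities(self) -> int:
        return len(self._store)

    def __contains__(self, identity: str) -> bool:
        return str(identity) in self._store

    def embeddings_of(self, identity: str) -> np.ndarray:
        return self._store[str(identity)]

    def as_array(self) -> np.ndarray:
        """The (N_class, N_img, D) stack; strict mode only."""
        if not self.strict:
            raise StateError("ragged lenient gallery has no rectangular view")
        if not self._store:
            return np.zeros((0, self.n_img, self.dim))
        return np.stack(list(self._store.values()))

    # -- registration --------------------------------------------------------

    def register_identity(self, identity: str, embeddings: np.ndarray) -> None:
        """Enroll a new identity with its reference embeddings (unit-normalized)."""
        identity = str(identity)
        if identity in self._store:
            raise ConflictError(f"identity {identity!r} already registered")
        emb = np.asarray(embeddings, dtype=np.float64)
        if emb.ndim != 2 or emb.shape[1] != self.dim:
            raise ShapeError(f"expected (n_img, {self.dim}) embeddings")
        if self.strict and emb.shape[0] != self.n_img:
            raise ValidationError(
                f"strict gallery requires exactly {self.n_img} embeddings per "
                f"identity, got {emb.shape[0]}")
        self._store[identity] = l2_normalize(emb)

    # -- matching ------------------------------------------------------------

    def match(self, query: np.ndarray, k: int = 5,
              aggregation: str = "max") -> MatchResult:
        """1:N lookup of a query embedding.

        ``best_score`` is the maximum cosine over all stored vectors of all
        identities; ``topk`` ranks identities by their pooled score (one entry
        per identity, truncated to the number of enrolled identities).
        """
        if not self._store:
            raise StateError("cannot match against an empty gallery")
        q = np.asarray(query, dtype=np.float64).ravel()
        if q.shape[0] != self.dim:
            raise ShapeError(f"query dimension {q.shape[0]} != gallery dim {self.dim}")
        nq = np.linalg.norm(q)
        if nq < 1e-12:
            raise ValidationError("query must be non-zero")
        q = q / nq
        scores = {}
        for identity, emb in self._store.items():
            sims = emb @ q
            scores[identity] = float(sims.max() if aggregation == "max"
                                     else sims.mean())
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best_identity, best_score = ranked[0]
        return MatchResult(best_identity=best_identity,
                           best_score=float(np.clip(best_score, -1.0, 1.0)),
                           topk=[(i, float(np.clip(s, -1.0, 1.0)))
                                 for i, s in ranked[:k]])

    def match_batch(self, queries: np.ndarray, k: int = 5,
                    aggregation: str = "max") -> list[MatchResult]:
        return [self.match(q, k=k, aggregation=aggregation) for q in np.atleast_2d(queries)]

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """npz array container + JSON manifest (identity order, n_img, dim)."""
        path = Path(path)
        manifest = {
            "identity_ids": self.identity_ids,
            "dim": self.dim,
            "n_img": self.n_img,
            "strict": self.strict,
            "counts": {i: int(e.shape[0]) for i, e in self._store.items()},
        }
        arrays = {f"emb_{idx}": emb
                  for idx, emb in enumerate(self._store.values())}
        np.savez(path, manifest=json.dumps(manifest), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureGallery":
        with np.load(Path(path), allow_pickle=False) as data:
            try:
                manifest = json.loads(str(data["manifest"]))
            except (KeyError, json.JSONDecodeError) as exc:
                raise ValidationError(f"corrupt gallery manifest: {exc}") from exc
            gal = cls(dim=manifest["dim"], n_img=manifest["n_img"],
                      strict=manifest["strict"])
            for idx, identity in enumerate(manifest["identity_ids"]):
                gal._store[str(identity)] = np.asarray(data[f"emb_{idx}"],
                                                       dtype=np.float64)
        return gal


def open_set_decide(result: MatchResult, policy: OpenSetPolicy) -> str:
    """Threshold-gated decision: the matched identity, or UNKNOWN.

    A best score exactly equal to the threshold is accepted as known (the
    rejection rule fires only when the score falls strictly below it).
    """
    if result.best_score >= policy.threshold:
        return result.best_identity
    return UNKNOWN


@dataclass
class AssignmentRecord:
    """One row of the dynamic-registration log."""

    group: str
    best_identity: str
    best_score: float
    decision: str
    threshold: float
    registered_as: str | None = None


def _next_novel_id(gallery: FeatureGallery) -> str:
    """Monotone integer IDs beyond the maximum existing numeric suffix."""
    mx = -1
    for ident in gallery.identity_ids:
        tail = ident.rsplit("_", 1)[-1]
        if tail.isdigit():
            mx = max(mx, int(tail))
        elif ident.isdigit():
            mx = max(mx, int(ident))
    return f"novel_{mx + 1}"


def dynamic_register(
    gallery: FeatureGallery,
    stream: Iterable[tuple[str, np.ndarray, np.ndarray | None]],
    policy: OpenSetPolicy,
) -> tuple[FeatureGallery, list[AssignmentRecord]]:
    """Process grouped query batches, enrolling unrecognized individuals.

    ``stream`` yields ``(group_id, query_embeddings, registration_embeddings)``
    triples, one per putative individual (the grouping is given by the input;
    no clustering of unknowns is attempted).  The group's best score is the
    maximum best-match score over its queries.  If it clears the threshold the
    group maps to the existing matched identity and the gallery is unchanged
    (idempotence for enrolled individuals); otherwise a fresh ``novel_<n>`` ID
    is created and the registration embeddings are stored.

    Returns the (mutated) gallery and the per-group decision log.
    """
    log: list[AssignmentRecord] = []
    for group_id, queries, reg_embeddings in stream:
        queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        results = [gallery.match(q, k=1) for q in queries]
        best = max(results, key=lambda r: r.best_score)
        decision = open_set_decide(best, policy)
        record = AssignmentRecord(group=str(group_id),
                                  best_identity=best.best_identity,
                                  best_score=best.best_score,
                                  decision=decision,
                                  threshold=policy.threshold)
        if decision == UNKNOWN:
            if reg_embeddings is None:
                raise ValidationError(
                    f"group {group_id!r} was declared unknown but supplied no "
                    "registration embeddings")
            reg = np.atleast_2d(np.asarray(reg_embeddings, dtype=np.float64))
            if gallery.strict and reg.shape[0] != gallery.n_img:
                raise ValidationError(
                    f"registration set for {group_id!r} has {reg.shape[0]} "
                    f"embeddings; strict gallery requires {gallery.n_img}")
            new_id = _next_novel_id(gallery)
            gallery.register_identity(new_id, reg)
            record.decision = UNKNOWN
            record.registered_as = new_id
        log.append(record)
    return gallery, log


def assignment_log_frame(log: Sequence[AssignmentRecord]) -> pd.DataFrame:
    """Decision log as a DataFrame (CSV-exportable)."""
    return pd.DataFrame([vars(r) for r in log])
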