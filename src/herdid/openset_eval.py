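"""Closed- and open-set evaluation of gallery-based identification.

Every metric here consumes an :class:`OpenSetScoreTable`: one row per query
holding the ground-truth label (a known identity or the UNKNOWN sentinel),
the predicted identity (the 1:N argmax match) and the best cosine score.

Closed-set metrics (CSA, macro precision/recall/F1, AMI, NMI, confusion
matrix, retrieval precision@1 / R-precision / MAP@R) ignore the acceptance
threshold.  Open-set metrics apply threshold-gated rejection:

* CCR(theta) — fraction of known queries that are both correctly matched and
  accepted (score >= theta).
* FAR(theta) — fraction of unknown queries whose best score clears theta.
* OSCR — area under the CCR-vs-FAR curve swept over all thresholds.
* AUROC / AUPR — separability of known vs unknown by best score.
* F1-Open(theta) — F1 with rejection in effect: a rejected known query is a
  false negative for its class, an accepted unknown a false positive for the
  predicted class; macro-averaged over known classes by default.

:func:`threshold_sweep` evaluates F1-Open/CCR/FAR at every observed score and
selects the F1-Open-maximizing threshold (ties -> smallest threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (adjusted_mutual_info_score, average_precision_score,
                             confusion_matrix, normalized_mutual_info_score,
                             precision_recall_fscore_support, roc_auc_score)

from .exceptions import ValidationError
from .gallery import UNKNOWN, FeatureGallery

__all__ = [
    "OpenSetScoreTable",
    "ThresholdSweepResult",
    "csa",
    "ccr_far_at",
    "oscr",
    "auroc",
    "aupr",
    "f1_open",
    "threshold_sweep",
    "closed_set_report",
    "retrieval_report",
    "full_report",
    "score_queries",
]


# --------------------------------------------------------------------------
# the score table
# --------------------------------------------------------------------------

@dataclass
class OpenSetScoreTable:
    """Per-query ground truth, argmax prediction and best similarity score."""

    true_labels: np.ndarray
    predicted: np.ndarray
    scores: np.ndarray
    query_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=object)
        self.predicted = np.asarray(self.predicted, dtype=object)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n = self.scores.shape[0]
        if self.true_labels.shape != (n,) or self.predicted.shape != (n,):
            raise ValidationError("table columns must share length")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("scores must be finite")
        if self.query_ids is None:
            self.query_ids = np.array([f"q{i}" for i in range(n)], dtype=object)

    @property
    def known_mask(self) -> np.ndarray:
        return self.true_labels != UNKNOWN

    def __len__(self) -> int:
        return self.scores.shape[0]

    # -- persistence ---------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "query_id": self.query_ids,
            "true_label": self.true_labels,
            "predicted_label": self.predicted,
            "best_score": self.scores,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OpenSetScoreTable":
        df = pd.read_csv(path)
        return cls(true_labels=df["true_label"].astype(str).to_numpy(),
                   predicted=df["predicted_label"].astype(str).to_numpy(),
                   scores=df["best_score"].to_numpy(),
                   query_ids=df["query_id"].astype(str).to_numpy())


def score_queries(gallery: FeatureGallery, queries: np.ndarray,
                  true_labels, k: int = 5) -> OpenSetScoreTable:
    """Match every query against the gallery and assemble the score table."""
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    true_labels = np.asarray(true_labels, dtype=object)
    results = [gallery.match(q, k=k) for q in queries]
    return OpenSetScoreTable(
        true_labels=true_labels,
        predicted=np.array([r.best_identity for r in results], dtype=object),
        scores=np.array([r.best_score for r in results]))


def _require_both(table: OpenSetScoreTable) -> None:
    known = table.known_mask
    if not known.any():
        raise ValidationError("table contains no known queries")
    if known.all():
        raise ValidationError("table contains no unknown queries")


# --------------------------------------------------------------------------
# open-set metrics
# --------------------------------------------------------------------------

def csa(table: OpenSetScoreTable) -> float:
    """Closed-set accuracy: argmax correctness on known queries, no rejection."""
    known = table.known_mask
    if not known.any():
        raise ValidationError("CSA needs at least one known query")
    return float(np.mean(table.predicted[known] == table.true_labels[known]))


def ccr_far_at(table: OpenSetScoreTable, theta: float) -> tuple[float, float]:
    """(CCR, FAR) at an acceptance threshold ``theta`` (score >= theta accepts)."""
    _require_both(table)
    known = table.known_mask
    accepted = table.scores >= theta
    correct = table.predicted == table.true_labels
    ccr = float(np.mean(accepted[known] & correct[known]))
    far = float(np.mean(accepted[~known]))
    return ccr, far


def _sweep_points(table: OpenSetScoreTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thresholds (ascending, with sentinels) and aligned CCR/FAR arrays."""
    thresholds = np.unique(np.concatenate(
        [[-1.0], np.unique(table.scores), [np.nextafter(table.scores.max(), 2.0)]]))
    pairs = np.array([ccr_far_at(table, t) for t in thresholds])
    return thresholds, pairs[:, 0], pairs[:, 1]


def oscr(table: OpenSetScoreTable) -> float:
    """Area under the CCR-vs-FAR curve (trapezoidal, FAR swept over [0, 1])."""
    _, ccr_arr, far_arr = _sweep_points(table)
    # traverse in descending-threshold order: FAR and CCR both non-decreasing,
    # so ties in FAR keep the attainable (highest-CCR) operating point
    return float(np.trapezoid(ccr_arr[::-1], far_arr[::-1]))


def auroc(table: OpenSetScoreTable) -> float:
    """Known-vs-unknown separability of best scores (rank / Mann-Whitney AUC)."""
    _require_both(table)
    return float(roc_auc_score(table.known_mask.astype(int), table.scores))


def aupr(table: OpenSetScoreTable) -> float:
    """Area under the precision-recall curve, known = positive, step-wise."""
    _require_both(table)
    return float(average_precision_score(table.known_mask.astype(int), table.scores))


def f1_open(table: OpenSetScoreTable, theta: float,
            average: str = "macro") -> float:
    """F1 with open-set rejection at ``theta``.

    Per known class ``c``: TP = accepted, predicted ``c``, truly ``c``;
    FP = accepted, predicted ``c``, truly something else (unknowns included);
    FN = truly ``c`` but rejected or mispredicted.  ``average`` is "macro"
    (mean of per-class F1, the reported convention) or "micro".
    """
    if average not in ("macro", "micro"):
        raise ValidationError("average must be 'macro' or 'micro'")
    known = table.known_mask
    if not known.any():
        raise ValidationError("F1-Open needs at least one known query")
    accepted = table.scores >= theta
    classes = np.unique(table.true_labels[known].astype(str))
    tps, fps, fns = [], [], []
    for c in classes:
        pred_c = accepted & (table.predicted.astype(str) == c)
        true_c = table.true_labels.astype(str) == c
        tps.append(np.sum(pred_c & true_c))
        fps.append(np.sum(pred_c & ~true_c))
        fns.append(np.sum(true_c & ~pred_c))
    tps, fps, fns = np.array(tps), np.array(fps), np.array(fns)
    if average == "micro":
        denom = 2 * tps.sum() + fps.sum() + fns.sum()
        return float(2 * tps.sum() / denom) if denom else 0.0
    denom = 2 * tps + fps + fns
    per_class = np.where(denom > 0, 2 * tps / np.maximum(denom, 1), 0.0)
    return float(per_class.mean())


@dataclass
class ThresholdSweepResult:
    """F1-Open/CCR/FAR evaluated at every observed score threshold."""

    thresholds: np.ndarray
    f1_open: np.ndarray
    ccr: np.ndarray
    far: np.ndarray
    best_threshold: float
    best_f1_open: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "f1_open": self.f1_open,
                             "ccr": self.ccr, "far": self.far})


def threshold_sweep(table: OpenSetScoreTable,
                    average: str = "macro") -> ThresholdSweepResult:
    """Evaluate the operating curve and select the F1-Open-optimal threshold.

    Thresholds are the unique observed scores (ascending).  Ties in F1-Open
    break toward the smallest threshold.  FAR and CCR are non-increasing in
    the threshold by construction.
    """
    thresholds = np.unique(table.scores)
    f1s = np.array([f1_open(table, t, average=average) for t in thresholds])
    pairs = np.array([ccr_far_at(table, t) for t in thresholds])
    best_idx = int(np.argmax(f1s))        # argmax returns the first maximum
    return ThresholdSweepResult(
        thresholds=thresholds, f1_open=f1s,
        ccr=pairs[:, 0], far=pairs[:, 1],
        best_threshold=float(thresholds[best_idx]),
        best_f1_open=float(f1s[best_idx]))


# --------------------------------------------------------------------------
# closed-set metrics
# --------------------------------------------------------------------------

def closed_set_report(table: OpenSetScoreTable) -> dict:
    """Macro precision/recall/F1, AMI, NMI and the confusion matrix.

    Computed on known queries only, with no rejection (pure argmax
    identification).  AMI/NMI compare the true and predicted partitions of
    the query set; AMI is chance-adjusted.
    """
    known = table.known_mask
    if not known.any():
        raise ValidationError("closed-set report needs known queries")
    y_true = table.true_labels[known].astype(str)
    y_pred = table.predicted[known].astype(str)
    labels = sorted(set(y_true) | set(y_pred))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=sorted(set(y_true)), average="macro",
        zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return {
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "ami": float(adjusted_mutual_info_score(y_true, y_pred)),
        "nmi": float(normalized_mutual_info_score(y_true, y_pred)),
        "confusion": pd.DataFrame(cm, index=labels, columns=labels),
    }


def retrieval_report(gallery_embeddings: np.ndarray, gallery_labels,
                     queries: np.ndarray | None = None,
                     query_labels=None) -> dict:
    """Precision@1, R-precision and MAP@R over cosine rankings.

    With ``queries=None`` the gallery retrieves against itself and each item
    is excluded from its own ranking; otherwise each query ranks the full
    gallery.  R is the per-query count of gallery items sharing its identity.
    Metrics are macro-averaged over queries.
    """
    gal = np.asarray(gallery_embeddings, dtype=np.float64)
    gal_labels = np.asarray(gallery_labels, dtype=object)
    self_mode = queries is None
    if self_mode:
        queries, query_labels = gal, gal_labels
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    query_labels = np.asarray(query_labels, dtype=object)

    gn = gal / np.linalg.norm(gal, axis=1, keepdims=True)
    qn = queries / np.linalg.norm(queries, axis=1, keepdims=True)
    sims = qn @ gn.T

    p1s, rps, maps = [], [], []
    for i in range(queries.shape[0]):
        s = sims[i].copy()
        mask = np.ones(gal.shape[0], dtype=bool)
        if self_mode:
            mask[i] = False
        rel_all = (gal_labels == query_labels[i]) & mask
        r = int(rel_all.sum())
        if r == 0:
            continue  # no retrievable positives for this query
        order = np.argsort(-s[mask], kind="stable")
        rel = rel_all[mask][order]
        p1s.append(float(rel[0]))
        rps.append(float(rel[:r].mean()))
        prec_at = np.cumsum(rel[:r]) / np.arange(1, r + 1)
        maps.append(float(np.sum(prec_at * rel[:r]) / r))
    if not p1s:
        raise ValidationError("no query had a same-identity gallery item")
    return {"precision_at_1": float(np.mean(p1s)),
            "r_precision": float(np.mean(rps)),
            "map_at_r": float(np.mean(maps))}


# --------------------------------------------------------------------------
# aggregate report and plots
# --------------------------------------------------------------------------

def full_report(table: OpenSetScoreTable, theta: float | None = None) -> dict:
    """All open-set metrics (plus closed-set block) in one dictionary.

    If ``theta`` is omitted the F1-Open-optimal swept threshold is used.
    """
    sweep = threshold_sweep(table)
    if theta is None:
        theta = sweep.best_threshold
    ccr, far = ccr_far_at(table, theta)
    closed = closed_set_report(table)
    confusion = closed.pop("confusion")
    return {
        "threshold": float(theta),
        "csa": csa(table),
        "auroc": auroc(table),
        "aupr": aupr(table),
        "oscr": oscr(table),
        "f1_open": f1_open(table, theta),
        "ccr": ccr,
        "far": far,
        "best_threshold": sweep.best_threshold,
        "best_f1_open": sweep.best_f1_open,
        "closed_set": closed,
        "confusion": confusion,
    }


def plot_threshold_sweep(sweep: ThresholdSweepResult, path: str | Path) -> None:
    """F1-Open / CCR / FAR against the threshold, one panel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep.thresholds, sweep.f1_open, label="F1-Open")
    ax.plot(sweep.thresholds, sweep.ccr, label="CCR")
    ax.plot(sweep.thresholds, sweep.far, label="FAR")
    ax.axvline(sweep.best_threshold, ls="--", c="gray",
               label=f"best = {sweep.best_threshold:.4f}")
    ax.set_xlabel("similarity threshold")
    ax.set_ylabel("rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_confusion(confusion: pd.DataFrame, path: str | Path) -> None:
    """Confusion-matrix heatmap for the closed-set report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(confusion.to_numpy(), cmap="viridis")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
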