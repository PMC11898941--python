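"""Open-set and closed-set metric oracles."""

from math import factorial, log

import numpy as np
import pytest

from herdid.exceptions import ValidationError
from herdid.gallery import UNKNOWN
from herdid.openset_eval import (OpenSetScoreTable, aupr, auroc, ccr_far_at,
                                 closed_set_report, csa, f1_open, full_report,
                                 oscr, retrieval_report, score_queries,
                                 threshold_sweep)


def make_table(true, pred, score):
    return OpenSetScoreTable(np.array(true, dtype=object),
                             np.array(pred, dtype=object),
                             np.array(score, dtype=float))


# --------------------------------------------------------------------------
# CSA / CCR / FAR
# --------------------------------------------------------------------------

class TestCsa:
    def test_all_correct(self):
        t = make_table(["a", "b"], ["a", "b"], [0.9, 0.8])
        assert csa(t) == 1.0

    def test_none_correct(self):
        t = make_table(["a", "b"], ["b", "a"], [0.9, 0.8])
        assert csa(t) == 0.0

    def test_hand_counted_fraction(self):
        true = list("aaabbbcccc")
        pred = list("aabbbbccdd")   # 7 of 10 correct
        t = make_table(true, pred, np.linspace(0.1, 0.9, 10))
        assert csa(t) == pytest.approx(0.7)

    def test_unknowns_are_excluded(self, toy_table):
        assert csa(toy_table) == pytest.approx(5 / 6)

    def test_no_knowns_rejected(self):
        t = make_table([UNKNOWN], ["a"], [0.5])
        with pytest.raises(ValidationError):
            csa(t)


class TestCcrFar:
    def test_threshold_below_all_scores(self, toy_table):
        ccr, far = ccr_far_at(toy_table, -1.0)
        assert far == 1.0
        assert ccr == pytest.approx(csa(toy_table))

    def test_threshold_above_all_scores(self, toy_table):
        assert ccr_far_at(toy_table, 0.99) == (0.0, 0.0)

    def test_hand_enumerated_toy(self, toy_table):
        # theta = 0.65: accepted knowns = scores {0.9,0.8,0.7,0.85}, all correct
        # -> ccr = 4/6; accepted unknowns = {0.75} -> far = 1/4
        ccr, far = ccr_far_at(toy_table, 0.65)
        assert ccr == pytest.approx(4 / 6)
        assert far == pytest.approx(1 / 4)

    def test_misclassified_accepted_known_does_not_count(self, toy_table):
        # theta = 0.55 additionally accepts the b->c error (0.6): ccr unchanged
        ccr, far = ccr_far_at(toy_table, 0.55)
        assert ccr == pytest.approx(4 / 6)
        assert far == pytest.approx(1 / 4)


# --------------------------------------------------------------------------
# OSCR
# --------------------------------------------------------------------------

def oscr_grid_oracle(table, grid=20001):
    """Dense-threshold numerical integration of the CCR-vs-FAR curve."""
    thetas = np.linspace(-1.001, 1.001, grid)
    pts = sorted({ccr_far_at(table, t)[::-1] for t in thetas})
    far = np.array([p[0] for p in pts])
    ccr = np.array([p[1] for p in pts])
    return float(np.trapezoid(ccr, far))


class TestOscr:
    def test_perfect_separation_gives_one(self):
        t = make_table(["a", "b", UNKNOWN, UNKNOWN], ["a", "b", "a", "b"],
                       [0.9, 0.8, 0.2, 0.1])
        assert oscr(t) == pytest.approx(1.0)

    def test_knowns_never_correct_gives_zero(self):
        t = make_table(["a", "b", UNKNOWN], ["b", "a", "a"], [0.9, 0.8, 0.5])
        assert oscr(t) == pytest.approx(0.0)

    def test_matches_fine_grid_integration(self, toy_table):
        assert oscr(toy_table) == pytest.approx(oscr_grid_oracle(toy_table),
                                                abs=1e-6)

    def test_in_unit_interval_on_random_tables(self, rng):
        for _ in range(10):
            n = 20
            true = np.where(rng.random(n) < 0.5, "a", UNKNOWN).astype(object)
            if (true == UNKNOWN).all() or (true != UNKNOWN).all():
                continue
            t = OpenSetScoreTable(true,
                                  np.full(n, "a", dtype=object),
                                  rng.random(n))
            v = oscr(t)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(oscr_grid_oracle(t), abs=1e-6)


# --------------------------------------------------------------------------
# AUROC / AUPR
# --------------------------------------------------------------------------

def auroc_pair_oracle(table):
    """Mann-Whitney: P(known score > unknown score) + 0.5 P(tie)."""
    known = table.scores[table.known_mask]
    unknown = table.scores[~table.known_mask]
    wins = sum((k > u) + 0.5 * (k == u) for k in known for u in unknown)
    return wins / (len(known) * len(unknown))


class TestAurocAupr:
    def test_disjoint_ranges_give_one(self):
        t = make_table(["a", "a", UNKNOWN, UNKNOWN], ["a"] * 4,
                       [0.9, 0.8, 0.3, 0.1])
        assert auroc(t) == pytest.approx(1.0)
        assert aupr(t) == pytest.approx(1.0)

    def test_identical_score_multisets_give_half(self):
        t = make_table(["a", "a", UNKNOWN, UNKNOWN], ["a"] * 4,
                       [0.5, 0.7, 0.5, 0.7])
        assert auroc(t) == pytest.approx(0.5)

    def test_matches_pair_count_oracle(self, toy_table, rng):
        assert auroc(toy_table) == pytest.approx(auroc_pair_oracle(toy_table),
                                                 abs=1e-12)
        for _ in range(5):
            n = 30
            true = np.array([("a" if v < 0.6 else UNKNOWN)
                             for v in rng.random(n)], dtype=object)
            scores = rng.integers(0, 10, n) / 10.0  # force ties
            if (true == UNKNOWN).all() or (true != UNKNOWN).all():
                continue
            t = OpenSetScoreTable(true, np.full(n, "a", dtype=object), scores)
            assert auroc(t) == pytest.approx(auroc_pair_oracle(t), abs=1e-12)

    def test_both_populations_required(self):
        with pytest.raises(ValidationError):
            auroc(make_table(["a", "b"], ["a", "b"], [0.5, 0.6]))


# --------------------------------------------------------------------------
# F1-Open
# --------------------------------------------------------------------------

def f1_open_confusion_oracle(table, theta):
    """Per-class confusion counting, written independently of the package."""
    accepted = table.scores >= theta
    classes = sorted({v for v in table.true_labels if v != UNKNOWN})
    f1s = []
    for c in classes:
        tp = fp = fn = 0
        for t, p, a in zip(table.true_labels, table.predicted, accepted):
            pred_c = a and p == c
            if pred_c and t == c:
                tp += 1
            elif pred_c:
                fp += 1
            if t == c and not pred_c:
                fn += 1
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    return float(np.mean(f1s))


class TestF1Open:
    def test_perfect_acceptance_and_rejection(self):
        t = make_table(["a", "b", UNKNOWN], ["a", "b", "a"], [0.9, 0.8, 0.1])
        assert f1_open(t, 0.5) == pytest.approx(1.0)

    def test_everything_rejected_gives_zero(self, toy_table):
        assert f1_open(toy_table, 0.99) == 0.0

    def test_matches_confusion_oracle(self, toy_table):
        for theta in (-1.0, 0.3, 0.55, 0.65, 0.82, 0.99):
            assert f1_open(toy_table, theta) == pytest.approx(
                f1_open_confusion_oracle(toy_table, theta), abs=1e-12)

    def test_micro_variant_counts_globally(self, toy_table):
        # micro at theta=0.65: TP=4, FP=1 (unknown at .75), FN=2 rejected knowns
        assert f1_open(toy_table, 0.65, average="micro") == pytest.approx(
            2 * 4 / (2 * 4 + 1 + 2))


# --------------------------------------------------------------------------
# sweep
# --------------------------------------------------------------------------

class TestThresholdSweep:
    def test_single_unique_score(self):
        t = make_table(["a", UNKNOWN], ["a", "a"], [0.5, 0.5])
        res = threshold_sweep(t)
        assert res.thresholds.tolist() == [0.5]
        assert res.best_threshold == 0.5

    def test_far_and_ccr_non_increasing(self, toy_table):
        res = threshold_sweep(toy_table)
        assert np.all(np.diff(res.far) <= 1e-12)
        assert np.all(np.diff(res.ccr) <= 1e-12)

    def test_best_threshold_separates_well_separated_table(self):
        t = make_table(["a", "a", "b", UNKNOWN, UNKNOWN],
                       ["a", "a", "b", "a", "b"],
                       [0.9, 0.85, 0.8, 0.3, 0.2])
        res = threshold_sweep(t)
        assert 0.3 < res.best_threshold <= 0.8
        assert res.best_f1_open == pytest.approx(1.0)
        assert res.best_f1_open == res.f1_open.max()

    def test_ties_break_to_smallest_threshold(self):
        t = make_table(["a", UNKNOWN], ["a", "b"], [0.9, 0.1])
        res = threshold_sweep(t)
        # both 0.1 and 0.9 rejectionless/f1=... compute: at 0.1 unknown accepted
        # as b (fp for absent class b is not a known class) -> still f1=1 at 0.9
        assert res.best_threshold == min(
            th for th, f1 in zip(res.thresholds, res.f1_open)
            if f1 == res.best_f1_open)


# --------------------------------------------------------------------------
# closed-set report
# --------------------------------------------------------------------------

def nmi_ami_formula_oracle(y_true, y_pred):
    """Contingency-table MI/NMI/AMI with arithmetic-mean normalization."""
    n = len(y_true)
    cls_t, cls_p = sorted(set(y_true)), sorted(set(y_pred))
    cont = np.zeros((len(cls_t), len(cls_p)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cont[cls_t.index(t), cls_p.index(p)] += 1
    a, b = cont.sum(1), cont.sum(0)
    mi = sum(cont[i, j] / n * log(n * cont[i, j] / (a[i] * b[j]))
             for i in range(len(cls_t)) for j in range(len(cls_p))
             if cont[i, j] > 0)
    ht = -sum(ai / n * log(ai / n) for ai in a if ai)
    hp = -sum(bj / n * log(bj / n) for bj in b if bj)
    mean_h = (ht + hp) / 2
    nmi = mi / mean_h if mean_h > 0 else (1.0 if mi == 0 else 0.0)
    # expected MI under the permutation model (hypergeometric)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo, hi = max(1, ai + bj - n), min(ai, bj)
            for nij in range(lo, hi + 1):
                prob = (factorial(ai) * factorial(bj) * factorial(n - ai)
                        * factorial(n - bj)) / (
                    factorial(n) * factorial(nij) * factorial(ai - nij)
                    * factorial(bj - nij) * factorial(n - ai - bj + nij))
                emi += prob * (nij / n) * log(n * nij / (ai * bj))
    denom = mean_h - emi
    ami = (mi - emi) / denom if abs(denom) > 1e-15 else 0.0
    return nmi, ami


class TestClosedSetReport:
    def test_perfect_predictions(self):
        t = make_table(["a", "b", "c"], ["a", "b", "c"], [0.9, 0.8, 0.7])
        rep = closed_set_report(t)
        for key in ("precision", "recall", "f1", "ami", "nmi"):
            assert rep[key] == pytest.approx(1.0)

    def test_single_cluster_prediction_has_zero_nmi(self):
        t = make_table(["a", "b", "c"], ["a", "a", "a"], [0.9, 0.8, 0.7])
        rep = closed_set_report(t)
        assert rep["nmi"] == pytest.approx(0.0)

    def test_ami_nmi_match_contingency_formula(self):
        true = ["a", "a", "b", "b", "c", "c"]
        pred = ["a", "b", "b", "b", "c", "a"]
        t = make_table(true, pred, np.linspace(0.2, 0.9, 6))
        rep = closed_set_report(t)
        nmi, ami = nmi_ami_formula_oracle(true, pred)
        assert rep["nmi"] == pytest.approx(nmi, abs=1e-10)
        assert rep["ami"] == pytest.approx(ami, abs=1e-10)

    def test_confusion_rows_sum_to_class_counts(self, toy_table):
        rep = closed_set_report(toy_table)
        cm = rep["confusion"]
        for cls in ("a", "b", "c"):
            assert cm.loc[cls].sum() == int(np.sum(
                toy_table.true_labels[toy_table.known_mask] == cls))


# --------------------------------------------------------------------------
# retrieval metrics
# --------------------------------------------------------------------------

def retrieval_loop_oracle(gal, labels, self_mode=True):
    gal = np.asarray(gal, dtype=float)
    gn = gal / np.linalg.norm(gal, axis=1, keepdims=True)
    p1s, rps, maps = [], [], []
    for i in range(len(labels)):
        sims = [(float(gn[i] @ gn[j]), labels[j]) for j in range(len(labels))
                if not (self_mode and j == i)]
        sims.sort(key=lambda kv: -kv[0])
        rel = [lab == labels[i] for _, lab in sims]
        r = sum(rel)
        if r == 0:
            continue
        p1s.append(float(rel[0]))
        rps.append(sum(rel[:r]) / r)
        ap = sum((sum(rel[:k + 1]) / (k + 1)) * rel[k] for k in range(r)) / r
        maps.append(ap)
    return np.mean(p1s), np.mean(rps), np.mean(maps)


class TestRetrieval:
    def test_duplicate_query_has_perfect_precision_at_1(self):
        gal = np.array([[1, 0], [0.9, 0.1], [0, 1], [0.1, 0.9]], dtype=float)
        labels = ["a", "a", "b", "b"]
        rep = retrieval_report(gal, labels, queries=np.array([[1.0, 0.0]]),
                               query_labels=["a"])
        assert rep["precision_at_1"] == 1.0

    def test_adversarial_gallery_gives_zero_precision(self):
        gal = np.array([[1, 0], [0, 1]], dtype=float)
        rep = retrieval_report(gal, ["a", "b"],
                               queries=np.array([[0.0, 1.0], [1.0, 0.0]]),
                               query_labels=["a", "b"])
        assert rep["precision_at_1"] == 0.0

    def test_matches_exhaustive_ranking_oracle(self, rng):
        means = rng.standard_normal((3, 5)) * 2
        gal = np.vstack([m + 0.5 * rng.standard_normal((4, 5)) for m in means])
        labels = [f"id{i}" for i in range(3) for _ in range(4)]
        rep = retrieval_report(gal, labels)
        p1, rp, mar = retrieval_loop_oracle(gal, labels)
        assert rep["precision_at_1"] == pytest.approx(p1, abs=1e-12)
        assert rep["r_precision"] == pytest.approx(rp, abs=1e-12)
        assert rep["map_at_r"] == pytest.approx(mar, abs=1e-12)


# --------------------------------------------------------------------------
# table plumbing
# --------------------------------------------------------------------------

class TestTablePlumbing:
    def test_csv_round_trip_reproduces_report(self, toy_table, tmp_path):
        path = tmp_path / "scores.csv"
        toy_table.to_csv(path)
        back = OpenSetScoreTable.from_csv(path)
        a = full_report(toy_table, 0.65)
        b = full_report(back, 0.65)
        for key in ("csa", "auroc", "aupr", "oscr", "f1_open", "ccr", "far"):
            assert a[key] == b[key]

    def test_score_queries_builds_consistent_table(self, rng):
        from herdid.gallery import FeatureGallery
        gal = FeatureGallery(dim=4, n_img=2)
        for i in range(3):
            gal.register_identity(f"id{i}", rng.standard_normal((2, 4)))
        queries = rng.standard_normal((5, 4))
        truth = ["id0", "id1", "id2", UNKNOWN, UNKNOWN]
        table = score_queries(gal, queries, truth)
        assert len(table) == 5
        for q, pred, score in zip(queries, table.predicted, table.scores):
            res = gal.match(q)
            assert res.best_identity == pred
            assert res.best_score == pytest.approx(score)
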