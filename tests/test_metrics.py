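"""Metric ledger, ROC/PR curves, overlays, observer consensus."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glandcell import refdata
from glandcell.cmg import BiopsyContainer, PatchRecord
from glandcell.metrics import (
    ConfusionCounts,
    ObserverRanking,
    OverlayScheme,
    confusion,
    consensus_select,
    f1_from,
    overlay_color_counts,
    pr_points,
    render_overlay,
    report,
    roc_points,
)


def _labels(n_gland, n_stroma):
    return ["gland"] * n_gland + ["stroma"] * n_stroma


class TestConfusion:
    def test_perfect_agreement(self):
        t = _labels(3, 4)
        c = confusion(t, t)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 0, 4, 0)

    def test_total_miss(self):
        c = confusion(_labels(5, 0), _labels(0, 5))
        assert (c.tp, c.fn) == (0, 5)

    def test_matches_per_item_tally(self, rng):
        t = rng.choice(["gland", "stroma"], size=200)
        p = rng.choice(["gland", "stroma"], size=200)
        c = confusion(t, p)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for ti, pi in zip(t, p):
            key = ("t" if ti == pi else "f") + ("p" if pi == "gland" else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tally["tp"], tally["fp"], tally["tn"], tally["fn"])
        assert c.total == 200

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError):
            confusion(_labels(2, 2), _labels(2, 1))
        with pytest.raises(ValueError):
            confusion(["gland", "weird"], ["gland", "gland"])


class TestReport:
    def test_published_best_biopsy_f1(self):
        # SN and PPV of the best-ranked test biopsy reproduce its printed F1
        row = refdata.BEST3_TABLE[1]
        assert f1_from(row["sensitivity"], row["ppv"]) == pytest.approx(row["f1"], abs=0.05)

    def test_published_tables_f1_consistency(self):
        # every printed per-biopsy row of the development study's metric
        # tables is internally consistent: F1 recomputed from (SN, PPV)
        # matches the printed F1 within one printed decimal unit (the
        # inputs are themselves rounded to one decimal); the "Average"
        # rows are unweighted means of the per-biopsy rows
        for table in (refdata.PATCH128_TABLE, refdata.BEST3_TABLE, refdata.WORST3_TABLE):
            for key, row in table.items():
                if key == "avg":
                    continue
                recomputed = f1_from(row["sensitivity"], row["ppv"])
                assert recomputed == pytest.approx(row["f1"], abs=0.1)
            for stat in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1"):
                mean = np.mean([table[i][stat] for i in (1, 2, 3)])
                assert mean == pytest.approx(table["avg"][stat], abs=0.1)

    def test_perfection(self):
        rep = report(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        for field in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1"):
            assert getattr(rep, field) == 100.0
        assert rep.fnr == 0.0 and rep.fpr == 0.0

    def test_undefined_statistics_are_none_not_zero(self):
        rep = report(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))  # no positives anywhere
        assert rep.sensitivity is None and rep.fnr is None
        assert rep.ppv is None and rep.f1 is None
        assert rep.specificity == 100.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            report(ConfusionCounts(0, 0, 0, 0))

    def test_matches_independent_formulas_on_random_tables(self, rng):
        # dual implementation via scikit-learn on reconstructed label arrays
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            precision_score,
            recall_score,
        )

        for _ in range(300):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            truth = _labels(tp + fn, fp + tn)
            preds = (
                ["gland"] * tp + ["stroma"] * fn + ["gland"] * fp + ["stroma"] * tn
            )
            rep = report(confusion(truth, preds))
            y_true = [1] * (tp + fn) + [0] * (fp + tn)
            y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            assert rep.accuracy == pytest.approx(100 * accuracy_score(y_true, y_pred), abs=1e-9)
            assert rep.sensitivity == pytest.approx(100 * recall_score(y_true, y_pred), abs=1e-9)
            assert rep.ppv == pytest.approx(100 * precision_score(y_true, y_pred), abs=1e-9)
            assert rep.f1 == pytest.approx(100 * f1_score(y_true, y_pred), abs=1e-9)

    @settings(deadline=None, max_examples=200)
    @given(counts=st.tuples(*[st.integers(0, 1000)] * 4))
    def test_identity_invariants(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        rep = report(ConfusionCounts(tp, fp, tn, fn))
        if rep.sensitivity is not None:
            assert rep.fnr == pytest.approx(100 - rep.sensitivity, abs=1e-9)
        if rep.specificity is not None:
            assert rep.fpr == pytest.approx(100 - rep.specificity, abs=1e-9)
        if rep.f1 is not None and rep.sensitivity + rep.ppv > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity), abs=1e-9
            )
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "fnr", "fpr", "f1"):
            v = getattr(rep, name)
            assert v is None or 0.0 <= v <= 100.0


def _concordance_auc(scores, truth):
    """O(n^2) Mann-Whitney pairwise concordance, ties counted one half."""
    pos = [s for s, t in zip(scores, truth) if t == "gland"]
    neg = [s for s, t in zip(scores, truth) if t == "stroma"]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _step_sum_ap(scores, truth):
    """Exhaustive AP oracle: walk descending distinct scores, sum P * dR."""
    n_pos = sum(t == "gland" for t in truth)
    pairs = sorted(zip(scores, truth), key=lambda x: -x[0])
    ap, prev_recall = 0.0, 0.0
    i = 0
    tp = taken = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            tp += pairs[j][1] == "gland"
            taken += 1
            j += 1
        recall, precision = tp / n_pos, tp / taken
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestROC:
    def test_perfect_separation(self):
        truth = _labels(3, 3)
        _, _, auc = roc_points([0.9, 0.8, 0.7, 0.3, 0.2, 0.1], truth)
        assert auc == pytest.approx(1.0)

    def test_uninformative_scores_near_half(self, rng):
        n = 4000
        truth = list(rng.choice(["gland", "stroma"], size=n))
        scores = rng.uniform(size=n)
        _, _, auc = roc_points(scores, truth)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_hand_made_scores_match_concordance_oracle(self):
        scores = [0.9, 0.8, 0.8, 0.7, 0.6, 0.5, 0.5, 0.5, 0.4, 0.3, 0.2, 0.1]
        truth = ["gland", "gland", "stroma", "gland", "stroma", "gland",
                 "stroma", "gland", "stroma", "stroma", "gland", "stroma"]
        _, _, auc = roc_points(scores, truth)
        assert auc == pytest.approx(_concordance_auc(scores, truth), abs=1e-12)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 200))
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            truth = list(rng.choice(["gland", "stroma"], size=n))
            if len(set(truth)) < 2:
                continue
            _, _, auc = roc_points(scores, truth)
            assert auc == pytest.approx(_concordance_auc(scores, truth), abs=1e-9)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        n = 300
        truth = list(rng.choice(["gland", "stroma"], size=n))
        scores = np.round(rng.uniform(size=n), 2)
        _, _, auc = roc_points(scores, truth)
        y = [1 if t == "gland" else 0 for t in truth]
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([0.1, 0.9], ["gland", "gland"])


class TestPR:
    def test_perfect_ranking(self):
        _, _, ap = pr_points([0.9, 0.8, 0.2, 0.1], _labels(2, 2))
        assert ap == pytest.approx(1.0)

    def test_all_tied_scores_give_prevalence(self):
        truth = _labels(3, 9)
        _, _, ap = pr_points([0.5] * 12, truth)
        assert ap == pytest.approx(3 / 12)

    def test_hand_made_scores_match_step_sum_oracle(self):
        scores = [0.9, 0.8, 0.8, 0.7, 0.6, 0.5, 0.5, 0.5, 0.4, 0.3, 0.2, 0.1]
        truth = ["gland", "stroma", "gland", "gland", "stroma", "gland",
                 "stroma", "stroma", "gland", "stroma", "gland", "stroma"]
        _, _, ap = pr_points(scores, truth)
        assert ap == pytest.approx(_step_sum_ap(scores, truth), abs=1e-12)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 150))
            scores = np.round(rng.uniform(size=n), 2)
            truth = list(rng.choice(["gland", "stroma"], size=n))
            if "gland" not in truth:
                continue
            _, _, ap = pr_points(scores, truth)
            assert ap == pytest.approx(_step_sum_ap(scores, truth), abs=1e-9)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_points([0.5, 0.6], ["stroma", "stroma"])


def _overlay_container():
    size = 16
    records = []
    for i, offset in enumerate([(4, 4), (4, 44), (44, 4), (44, 44)]):
        pixels = np.full((size, size), 200, dtype=np.uint8)
        boundary = np.array([[4.0, 4.0], [4.0, 12.0], [12.0, 12.0], [12.0, 4.0]])
        records.append(PatchRecord(i, pixels, boundary, offset))
    return BiopsyContainer("b", (64, 64), size, records=records)


class TestOverlay:
    def test_all_correct_shows_only_red_and_blue(self):
        cont = _overlay_container()
        truth = ["gland", "gland", "stroma", "stroma"]
        overlay = render_overlay(cont, truth, truth)
        counts = overlay_color_counts(overlay)
        assert counts == {"tp": 2, "tn": 2, "fn": 0, "fp": 0}

    def test_flipping_one_prediction_recolors_one_nucleus(self):
        cont = _overlay_container()
        truth = ["gland", "gland", "stroma", "stroma"]
        preds = ["stroma", "gland", "stroma", "stroma"]  # one missed gland
        counts = overlay_color_counts(render_overlay(cont, truth, preds))
        assert counts == {"tp": 1, "tn": 2, "fn": 1, "fp": 0}

    def test_color_counts_sum_to_evaluated_nuclei(self, rng):
        cont = _overlay_container()
        truth = list(rng.choice(["gland", "stroma"], size=4))
        preds = list(rng.choice(["gland", "stroma"], size=4))
        counts = overlay_color_counts(render_overlay(cont, truth, preds))
        assert sum(counts.values()) == len(cont.records)
        c = confusion(truth, preds)
        assert counts == {"tp": c.tp, "tn": c.tn, "fn": c.fn, "fp": c.fp}

    def test_distinct_colors_required(self):
        with pytest.raises(ValueError):
            OverlayScheme(tp_color=(1, 1, 1), tn_color=(1, 1, 1))


class TestConsensus:
    def test_common_core_of_three(self):
        core = ("b1", "b2", "b3")
        rankings = [
            ObserverRanking("o1", core + ("b4", "b5"), ("w1", "w2", "w3", "w4", "w5")),
            ObserverRanking("o2", core + ("b6", "b7"), ("w1", "w2", "w8", "w9", "w4")),
            ObserverRanking("o3", ("b4",) + core + ("b8",), ("w2", "w1", "w6", "w7", "w5")),
        ]
        best, worst, agreement = consensus_select(rankings, k=5)
        assert best == set(core)
        assert worst == {"w1", "w2"}
        assert agreement["b1"] == 3

    def test_identical_rankings_intersect_to_themselves(self):
        r = ObserverRanking("o", ("a", "b"), ("c", "d"))
        best, worst, _ = consensus_select([r, r, r], k=2)
        assert best == {"a", "b"} and worst == {"c", "d"}

    def test_disjoint_rankings_warn_and_return_empty(self):
        rankings = [
            ObserverRanking("o1", ("a",), ("b",)),
            ObserverRanking("o2", ("c",), ("d",)),
        ]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            best, worst, _ = consensus_select(rankings, k=1)
        assert best == set() and worst == set()
        assert any("no common" in str(w.message) for w in caught)

    def test_fewer_than_two_observers_rejected(self):
        with pytest.raises(ValueError):
            consensus_select([ObserverRanking("o", ("a",), ("b",))], k=1)

    def test_unknown_biopsy_ids_rejected(self):
        rankings = [
            ObserverRanking("o1", ("a",), ("b",)),
            ObserverRanking("o2", ("zzz",), ("b",)),
        ]
        with pytest.raises(ValueError, match="zzz"):
            consensus_select(rankings, k=1, biopsy_ids={"a", "b"})
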