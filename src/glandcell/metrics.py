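"""Evaluation suite: eight-statistic ledger, ROC/PR curves, overlays, consensus.

The positive class is the glandular cell EVERYWHERE in this package;
specificity is therefore automatically the stroma recognition rate.
Statistics with zero denominators are reported as ``None`` (undefined),
never silently as 0, so cohort averages are not inflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cmg import BiopsyContainer, reconstruct_image

POSITIVE_LABEL = "gland"
NEGATIVE_LABEL = "stroma"


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally with gland as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """The eight-statistic ledger, as percentages; curve areas as fractions.

    Identities: FNR = 100 - SN, FPR = 100 - SP, and F1 is the harmonic
    mean of PPV and SN.  ``None`` marks a statistic whose denominator
    was zero.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    fnr: float | None
    fpr: float | None
    f1: float | None
    auc: float | None = None
    ap: float | None = None
    counts: ConfusionCounts | None = field(default=None, repr=False)

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        out = {}
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "fnr", "fpr", "f1"):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, ndigits)
        for k in ("auc", "ap"):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, 3)
        return out


def _check_labels(seq, name: str) -> np.ndarray:
    arr = np.asarray(seq)
    bad = set(np.unique(arr)) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ValueError(f"{name} contains labels outside gland/stroma: {sorted(bad)}")
    return arr


def confusion(truth, preds) -> ConfusionCounts:
    """Tally a pair of aligned gland/stroma label sequences."""
    t = _check_labels(truth, "truth")
    p = _check_labels(preds, "preds")
    if t.shape != p.shape:
        raise ValueError(f"truth has {t.shape} labels but preds has {p.shape}")
    tpos = t == POSITIVE_LABEL
    ppos = p == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def f1_from(sensitivity: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and PPV (both and the result in %)."""
    if sensitivity + ppv == 0:
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def report(c: ConfusionCounts, auc: float | None = None, ap: float | None = None) -> MetricReport:
    """The eight statistics of a confusion table, as percentages.

    acc=(TP+TN)/total, SN=TP/(TP+FN), SP=TN/(TN+FP), PPV=TP/(TP+FP),
    NPV=TN/(TN+FN), FNR=FN/(TP+FN), FPR=FP/(TN+FP),
    F1=2*PPV*SN/(PPV+SN).
    """
    if c.total == 0:
        raise ValueError("cannot report on an all-zero confusion table")

    def frac(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    sn = frac(c.tp, c.tp + c.fn)
    sp = frac(c.tn, c.tn + c.fp)
    ppv = frac(c.tp, c.tp + c.fp)
    npv = frac(c.tn, c.tn + c.fn)
    if sn is None or ppv is None:
        f1 = None
    elif sn + ppv == 0:
        f1 = 0.0
    else:
        f1 = f1_from(sn, ppv)
    return MetricReport(
        accuracy=frac(c.tp + c.tn, c.total),
        sensitivity=sn,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        fnr=None if sn is None else 100.0 - sn,
        fpr=None if sp is None else 100.0 - sp,
        f1=f1,
        auc=auc,
        ap=ap,
        counts=c,
    )


def evaluate(truth, preds, scores=None) -> MetricReport:
    """Convenience: confusion + report, with curves when scores are given."""
    c = confusion(truth, preds)
    auc = ap = None
    if scores is not None:
        t = _check_labels(truth, "truth")
        if len(set(t)) == 2:
            _, _, auc = roc_points(scores, truth)
            _, _, ap = pr_points(scores, truth)
    return report(c, auc=auc, ap=ap)


def _scores_and_truth(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=np.float64)
    t = _check_labels(truth, "truth")
    if s.shape != t.shape:
        raise ValueError("scores and truth must be aligned")
    return s, (t == POSITIVE_LABEL)


def roc_points(scores, truth) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR arrays) and trapezoid AUC.

    Thresholds sweep the unique scores in descending order; tied scores
    move as one block, which makes the trapezoid AUC equal to pairwise
    concordance with ties counted one half (midrank convention).
    """
    s, pos = _scores_and_truth(scores, truth)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present in truth")
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    # indices where a new (lower) threshold block ends
    distinct = np.nonzero(np.diff(s_sorted))[0]
    block_ends = np.r_[distinct, len(s_sorted) - 1]
    tp_cum = np.cumsum(pos_sorted)[block_ends]
    fp_cum = np.cumsum(~pos_sorted)[block_ends]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def pr_points(scores, truth) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and step-summed average precision.

    ``AP = sum_i (R_i - R_{i-1}) * P_i`` over the descending-score
    sweep, tied scores moving as one block.  With all scores tied the
    curve is a single operating point and AP equals the positive
    prevalence.
    """
    s, pos = _scores_and_truth(scores, truth)
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("average precision needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    block_ends = np.r_[distinct, len(s_sorted) - 1]
    tp_cum = np.cumsum(pos_sorted)[block_ends]
    n_cum = block_ends + 1.0
    precision = tp_cum / n_cum
    recall = tp_cum / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    ap = float(np.sum(d_recall * precision))
    return recall, precision, ap


@dataclass(frozen=True)
class OverlayScheme:
    """Four-color nucleus overlay: outcomes of the gland/stroma decision."""

    tp_color: tuple[int, int, int] = (220, 30, 30)     # red: correct gland
    tn_color: tuple[int, int, int] = (40, 70, 220)     # blue: correct stroma
    fn_color: tuple[int, int, int] = (30, 170, 60)     # green: missed gland
    fp_color: tuple[int, int, int] = (220, 40, 220)    # magenta: stroma called gland

    def __post_init__(self):
        if len({self.tp_color, self.tn_color, self.fn_color, self.fp_color}) != 4:
            raise ValueError("overlay colors must be four distinct colors")

    def color_of(self, true_label: str, pred_label: str) -> tuple[int, int, int]:
        if true_label == POSITIVE_LABEL:
            return self.tp_color if pred_label == POSITIVE_LABEL else self.fn_color
        return self.fp_color if pred_label == POSITIVE_LABEL else self.tn_color


def render_overlay(
    container: BiopsyContainer,
    truth,
    preds,
    scheme: OverlayScheme = OverlayScheme(),
) -> np.ndarray:
    """Reconstructed biopsy with nuclei filled by decision outcome.

    ``truth``/``preds`` are gland/stroma sequences aligned with the
    container's records.  Returns an RGB uint8 canvas.
    """
    from skimage.draw import polygon as draw_polygon

    t = _check_labels(truth, "truth")
    p = _check_labels(preds, "preds")
    if not (len(t) == len(p) == len(container.records)):
        raise ValueError("truth/preds must align with container records")
    base = reconstruct_image(container, draw_boundaries=False, fill=230)
    if base.ndim == 2:
        rgb = np.stack([base] * 3, axis=-1)
    else:
        rgb = base.copy()
    if rgb.dtype != np.uint8:
        rgb = np.clip(rgb * 255.0, 0, 255).astype(np.uint8)
    h, w = container.slide_shape
    for rec, tl, pl in zip(container.records, t, p):
        verts = rec.boundary_slide_frame()
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=(h, w))
        rgb[rr, cc] = scheme.color_of(str(tl), str(pl))
    return rgb


def overlay_color_counts(overlay: np.ndarray, scheme: OverlayScheme = OverlayScheme()) -> dict[str, int]:
    """Count connected nucleus components per overlay color (for audits)."""
    from skimage.measure import label as cc_label

    out = {}
    for name, color in (
        ("tp", scheme.tp_color),
        ("tn", scheme.tn_color),
        ("fn", scheme.fn_color),
        ("fp", scheme.fp_color),
    ):
        mask = np.all(overlay == np.asarray(color, dtype=overlay.dtype), axis=-1)
        out[name] = int(cc_label(mask).max())
    return out


@dataclass(frozen=True)
class ObserverRanking:
    """One observer's best-k and worst-k biopsy lists (ordered, disjoint)."""

    observer_id: str
    best: tuple[str, ...]
    worst: tuple[str, ...]

    def __post_init__(self):
        if set(self.best) & set(self.worst):
            raise ValueError(f"observer {self.observer_id}: best/worst lists overlap")


def consensus_select(
    rankings: list[ObserverRanking], k: int, biopsy_ids: set[str] | None = None
) -> tuple[set[str], set[str], dict[str, int]]:
    """Best/worst consensus: biopsies on EVERY observer's best-k (worst-k) list.

    Returns ``(best_set, worst_set, agreement_counts)`` where the counts
    give, for each mentioned biopsy, how many observers listed it
    (best-list mentions count positively, worst-list mentions count too).
    """
    if len(rankings) < 2:
        raise ValueError("consensus needs at least two observer rankings")
    if biopsy_ids is not None:
        for r in rankings:
            stray = (set(r.best) | set(r.worst)) - set(biopsy_ids)
            if stray:
                raise ValueError(
                    f"observer {r.observer_id} ranked unknown biopsies: {sorted(stray)}"
                )
    best_lists = [set(r.best[:k]) for r in rankings]
    worst_lists = [set(r.worst[:k]) for r in rankings]
    best = set.intersection(*best_lists)
    worst = set.intersection(*worst_lists)
    agreement: dict[str, int] = {}
    for group in (best_lists, worst_lists):
        for lst in group:
            for bid in lst:
                agreement[bid] = agreement.get(bid, 0) + 1
    if not best and not worst:
        warnings.warn("observer rankings share no common best or worst biopsies")
    return best, worst, agreement
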