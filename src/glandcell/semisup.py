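"""Two-round false-positive-relabeling semi-supervised training.

The procedure compensates for one-sided annotation misses (true gland
nuclei labeled stroma by the annotator): round 1 trains on the human
labels; nuclei of the validation cohort that the round-1 model calls
gland while their annotation says stroma (the "false positives") are
harvested and appended to the training set as positives; round 2
retrains from scratch on the augmented set.  Every change is ledgered —
original human labels are retained immutably alongside the pseudo-labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np

from .classifier import (
    GlandNet,
    ModelSpec,
    TrainConfig,
    build_model,
    predict_proba,
    stack_container_data,
    train,
)
from .cmg import BiopsyContainer
from .metrics import MetricReport, evaluate

PROVENANCE_HUMAN = "human"


def _pseudo_provenance(round_index: int) -> str:
    return f"round-{round_index}-pseudo"


@dataclass
class RoundLedger:
    """Bookkeeping for one training round.

    ``provenance`` maps every (biopsy_id, nucleus_id) in the round's
    training set to ``"human"`` or ``"round-k-pseudo"``;
    ``human_labels`` preserves the original annotation of relabeled
    nuclei so no information is silently deleted.
    """

    round_index: int
    train_positive_count: int
    train_negative_count: int
    harvested_fp_ids: frozenset[tuple[Hashable, Hashable]] = frozenset()
    validation_report: MetricReport | None = None
    provenance: dict[tuple[Hashable, Hashable], str] = field(default_factory=dict)
    human_labels: dict[tuple[Hashable, Hashable], str] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "round_index": self.round_index,
            "train_positive_count": self.train_positive_count,
            "train_negative_count": self.train_negative_count,
            "harvested_fp_ids": sorted(map(list, self.harvested_fp_ids)),
            "validation_report": (
                self.validation_report.rounded() if self.validation_report else None
            ),
            "n_pseudo": sum(1 for v in self.provenance.values() if v != PROVENANCE_HUMAN),
        }


@dataclass
class TwoRoundResult:
    """Final-round model, per-round ledgers, first/last-round val probabilities."""

    model: GlandNet
    round1_model: GlandNet
    ledgers: tuple[RoundLedger, ...]
    val_probs_round1: dict[tuple[str, int], float]
    val_probs_round2: dict[tuple[str, int], float]


def harvest_false_positives(labels: dict, preds: dict) -> frozenset:
    """Ids whose annotation is stroma but whose prediction is gland.

    ``labels`` and ``preds`` must be dicts over exactly the same keys.
    """
    if set(labels) != set(preds):
        missing = set(labels) ^ set(preds)
        raise ValueError(f"labels and predictions are misaligned on ids {sorted(missing)[:5]}")
    return frozenset(
        k for k in labels if labels[k] == "stroma" and preds[k] == "gland"
    )


def relabel_training(
    train_labels: dict,
    harvested: frozenset,
    mode: str = "add-val-fps-to-train",
    round_index: int = 1,
) -> tuple[dict, RoundLedger]:
    """Fold harvested false positives into the training label set.

    Default mode (the reference procedure) appends harvested VALIDATION
    nuclei to the training set as gland; a harvested id colliding with an
    existing training nucleus is an error.  ``relabel-in-place`` instead
    flips existing training nuclei from stroma to gland.  Either way the
    relabeling is strictly one-sided (stroma -> gland) and the ledger
    records provenance plus the retrievable original labels.
    """
    if mode not in ("add-val-fps-to-train", "relabel-in-place"):
        raise ValueError(f"unknown relabel mode {mode!r}")
    out = dict(train_labels)
    provenance = {k: PROVENANCE_HUMAN for k in train_labels}
    human_labels: dict = {}
    pseudo = _pseudo_provenance(round_index)
    for key in sorted(harvested):
        if mode == "add-val-fps-to-train":
            if key in out:
                raise ValueError(
                    f"harvested id {key} collides with an existing training nucleus"
                )
            out[key] = "gland"
            human_labels[key] = "stroma"  # the annotation that was overridden
        else:
            if key not in out:
                raise ValueError(f"cannot relabel unknown training nucleus {key}")
            if out[key] == "gland":
                raise ValueError(f"harvested id {key} is already positive in training")
            human_labels[key] = out[key]
            out[key] = "gland"
        provenance[key] = pseudo
    pos = sum(1 for v in out.values() if v == "gland")
    neg = sum(1 for v in out.values() if v == "stroma")
    ledger = RoundLedger(
        round_index=round_index + 1,
        train_positive_count=pos,
        train_negative_count=neg,
        harvested_fp_ids=frozenset(harvested),
        provenance=provenance,
        human_labels=human_labels,
    )
    return out, ledger


def _validation_snapshot(
    model: GlandNet, val_containers: list[BiopsyContainer], threshold: float
) -> tuple[dict[tuple[str, int], float], MetricReport | None]:
    probs: dict[tuple[str, int], float] = {}
    labels, preds, scores = [], [], []
    for cont in val_containers:
        p = predict_proba(model, cont)
        for rec, pi in zip(cont.records, p):
            probs[(cont.biopsy_id, rec.nucleus_id)] = float(pi)
            if rec.label != "unknown":
                labels.append(rec.label)
                preds.append("gland" if pi > threshold else "stroma")
                scores.append(pi)
    rep = None
    if labels and len(set(labels)) > 0:
        try:
            rep = evaluate(labels, preds, scores)
        except ValueError:
            rep = None
    return probs, rep


def run_two_rounds(
    train_containers: list[BiopsyContainer],
    val_containers: list[BiopsyContainer],
    model_spec: ModelSpec,
    train_config: TrainConfig,
    harvest_threshold: float | None = None,
    warm_start: bool = False,
    rounds: int = 2,
    pseudo_label_mode: str = "hard",
) -> TwoRoundResult:
    """Execute the two-round strategy on disjoint train/validation cohorts.

    Round 1 trains on the human annotations only; false positives are
    harvested from the validation predictions at ``harvest_threshold``
    (defaults to the classification threshold); round 2 retrains —
    from scratch with the same seeded init unless ``warm_start`` — on
    the training set plus the harvested nuclei as pseudo-positives
    (``hard``: weight 1; ``soft``: weight = predicted probability).
    An empty harvest is logged as a warning and the next round still
    runs.  ``rounds`` generalizes the loop beyond the default 2.
    """
    import warnings

    if rounds < 2:
        raise ValueError("rounds must be >= 2")
    if pseudo_label_mode not in ("hard", "soft"):
        raise ValueError("pseudo_label_mode must be 'hard' or 'soft'")
    train_ids = {c.biopsy_id for c in train_containers}
    val_ids = {c.biopsy_id for c in val_containers}
    if train_ids & val_ids:
        raise ValueError(
            f"cohorts must be disjoint at the biopsy level; shared: {sorted(train_ids & val_ids)}"
        )
    tau = harvest_threshold if harvest_threshold is not None else train_config.decision_threshold

    x_tr, y_tr, ids_tr = stack_container_data(train_containers)
    val_labels = {
        (c.biopsy_id, r.nucleus_id): r.label
        for c in val_containers
        for r in c.records
        if r.label != "unknown"
    }
    val_pixels = {
        (c.biopsy_id, r.nucleus_id): (
            r.pixels if r.pixels.ndim == 3 else r.pixels[..., None]
        ).astype(np.float32)
        for c in val_containers
        for r in c.records
    }

    x_cur, y_cur = x_tr, y_tr
    weights_cur = None  # per-sample weights; only used in soft mode
    harvested_all: set[tuple] = set()
    models, ledgers, probs_per_round = [], [], []

    for round_index in range(1, rounds + 1):
        model = build_model(model_spec, seed=train_config.seed)
        if warm_start and models:
            model.net.load_state_arrays(models[-1].net.state_arrays())
        train(model, (x_cur, y_cur), train_config, sample_weights=weights_cur)
        probs, report_ = _validation_snapshot(model, val_containers, tau)
        models.append(model)
        probs_per_round.append(probs)

        if round_index == 1:
            ledgers.append(
                RoundLedger(
                    round_index=1,
                    train_positive_count=int((y_tr == 1).sum()),
                    train_negative_count=int((y_tr == 0).sum()),
                    validation_report=report_,
                    provenance={k: PROVENANCE_HUMAN for k in ids_tr},
                )
            )
        else:
            ledgers[-1].validation_report = report_

        if round_index == rounds:
            break

        # harvest this round's validation false positives (new ids only)
        val_preds = {k: ("gland" if probs[k] > tau else "stroma") for k in val_labels}
        harvested = frozenset(
            harvest_false_positives(val_labels, val_preds) - harvested_all
        )
        if not harvested:
            warnings.warn(
                f"round-{round_index} harvest is empty; "
                "the next round degenerates to retraining"
            )
        ledgers[round_index - 1].harvested_fp_ids = harvested
        harvested_all |= harvested

        train_labels = {
            k: ("gland" if yi == 1 else "stroma") for k, yi in zip(ids_tr, y_tr)
        }
        earlier_pseudo = harvested_all - harvested
        for k in sorted(earlier_pseudo):
            train_labels[k] = "gland"  # pseudo-positives from earlier rounds
        _, next_ledger = relabel_training(train_labels, harvested, round_index=round_index)
        for k in earlier_pseudo:  # keep their true provenance
            next_ledger.provenance[k] = ledgers[-1].provenance[k]
            next_ledger.human_labels[k] = "stroma"
        ledgers.append(next_ledger)

        # keep container/record order for the appended patches (determinism)
        keys = [
            (c.biopsy_id, r.nucleus_id)
            for c in val_containers
            for r in c.records
            if (c.biopsy_id, r.nucleus_id) in harvested
        ]
        extra = [val_pixels[k] for k in keys]
        if extra:
            x_cur = np.concatenate([x_cur, np.stack(extra)])
            y_cur = np.concatenate([y_cur, np.ones(len(extra), dtype=np.int64)])
            if pseudo_label_mode == "soft":
                if weights_cur is None:
                    weights_cur = np.ones(len(y_cur) - len(extra), dtype=np.float64)
                weights_cur = np.concatenate(
                    [weights_cur, np.array([probs[k] for k in keys], dtype=np.float64)]
                )
            elif weights_cur is not None:
                weights_cur = np.concatenate([weights_cur, np.ones(len(extra))])

    return TwoRoundResult(
        model=models[-1],
        round1_model=models[0],
        ledgers=tuple(ledgers),
        val_probs_round1=probs_per_round[0],
        val_probs_round2=probs_per_round[-1],
    )
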