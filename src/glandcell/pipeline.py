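"""End-to-end orchestration: demo, prepare, train, predict, evaluate.

A run lives in a workdir with a fixed layout::

    workdir/
      manifest.json            run provenance (config, seeds, version)
      scenes/                  rendered images + nuclei/gland annotation files
      containers/              one CMG container per biopsy
      truth/labels.json        hidden truth, corrupted annotation, flipped ids
      model/                   checkpoint, topology JSON, training history CSV
      ledgers/                 per-round semi-supervised ledgers + audit table
      reports/                 metric reports, ROC/PR curves (CSV)
      overlays/                four-color prediction overlays (PNG)
      rankings/                simulated observer rankings + consensus

Stages are composable: ``predict`` consumes any checkpoint, ``evaluate``
consumes any container set with predictions plus a truth file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (
    GlandNet,
    ModelSpec,
    TrainConfig,
    build_model,
    classify,
    predict_proba,
    train,
)
from .cmg import read_container, write_container
from .experiments import DESK_PATCH_SIZE
from .io import save_image, write_gland_annotation, write_nuclei_csv, write_nucleus_boundaries
from .metrics import ObserverRanking, consensus_select, evaluate, render_overlay, roc_points, pr_points
from .patching import build_biopsy_container, split_by_biopsy
from .semisup import run_two_rounds
from .synthetic import (
    AnnotationNoiseSpec,
    SceneSpec,
    inject_annotation_misses,
    render_scene,
    small_gland_preset,
)

log = logging.getLogger("glandcell")

STAGES = ("prepare", "train", "predict", "evaluate")


@dataclass
class RunConfig:
    """Configuration of one demo/pipeline run (YAML-serializable)."""

    workdir: str = "scratch/demo"
    seed: int = 0
    n_biopsies: int = 6
    small_gland_every: int = 3  # every k-th synthetic biopsy uses the small-gland preset
    split_fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    miss_fraction: float = 0.2
    patch_size: int = DESK_PATCH_SIZE
    width_scale: float = 1 / 8
    noise_sigma: float = 0.1
    epochs: int = 10
    learning_rate: float = 4e-4
    batch_size: int = 32
    two_rounds: bool = True
    consensus_k: int = 1
    verbosity: str = "info"

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            width_scale=self.width_scale,
            input_size=self.patch_size,
            allow_any_input_size=True,
            noise_sigma=self.noise_sigma,
        )

    def train_config(self) -> TrainConfig:
        cfg = TrainConfig.desk_scale(seed=self.seed, epochs=self.epochs)
        cfg.learning_rate = self.learning_rate
        cfg.batch_size = self.batch_size
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(d["split_fractions"])
        Path(path).write_text(yaml.safe_dump(d))
        return Path(path)


def _workdir(config: RunConfig) -> Path:
    wd = Path(config.workdir)
    for sub in ("scenes", "containers", "truth", "model", "ledgers", "reports", "overlays", "rankings"):
        (wd / sub).mkdir(parents=True, exist_ok=True)
    return wd


def _write_manifest(config: RunConfig, wd: Path) -> None:
    cfg = dataclasses.asdict(config)
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
    }
    (wd / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact {path} — run `{hint}` first")
    return path


def _biopsy_ids(config: RunConfig) -> list[str]:
    return [f"synthetic-{i:02d}" for i in range(config.n_biopsies)]


def stage_prepare(config: RunConfig) -> Path:
    """Render synthetic biopsies, write scene files and CMG containers."""
    wd = _workdir(config)
    _write_manifest(config, wd)
    ids = _biopsy_ids(config)
    split = split_by_biopsy(ids, config.split_fractions, seed=config.seed)
    truth_payload: dict = {"cohorts": {}, "truth": {}, "annotation": {}, "flipped": {}}
    for i, bid in enumerate(ids):
        use_small = config.small_gland_every > 0 and (i % config.small_gland_every == config.small_gland_every - 1)
        scene_seed = config.seed * 1000 + i
        spec = small_gland_preset(seed=scene_seed) if use_small else SceneSpec(seed=scene_seed)
        scene = render_scene(spec)
        corrupted, flipped = inject_annotation_misses(
            scene.labels, AnnotationNoiseSpec(config.miss_fraction, seed=scene_seed + 1)
        )
        save_image(scene.image, wd / "scenes" / f"{bid}.tif")
        write_nuclei_csv(wd / "scenes" / f"{bid}.nuclei.csv", scene.nuclei, labels=corrupted)
        write_gland_annotation(wd / "scenes" / f"{bid}.glands.json", scene.glands)
        write_nucleus_boundaries(wd / "scenes" / f"{bid}.boundaries.json", scene.nuclei)
        cont = build_biopsy_container(
            scene.image, scene.nuclei, scene.glands, config.patch_size, biopsy_id=bid,
            pixel_spacing_um=spec.pixel_spacing_um,
        )
        for rec in cont.records:  # containers carry the (corrupted) annotation labels
            rec.label = corrupted[rec.nucleus_id]
        write_container(cont, wd / "containers" / f"{bid}.cmg")
        truth_payload["cohorts"][bid] = split.cohort_of(bid)
        truth_payload["truth"][bid] = {str(k): v for k, v in scene.labels.items()}
        truth_payload["annotation"][bid] = {str(k): v for k, v in corrupted.items()}
        truth_payload["flipped"][bid] = sorted(int(x) for x in flipped)
        log.info("prepare: %s (%s cohort, %d nuclei)", bid, split.cohort_of(bid), len(cont))
    (wd / "truth" / "labels.json").write_text(json.dumps(truth_payload))
    return wd


def _load_cohort_containers(config: RunConfig, wd: Path) -> dict[str, list]:
    truth = json.loads(_require(wd / "truth" / "labels.json", "glandcell prepare").read_text())
    out: dict[str, list] = {"train": [], "val": [], "test": []}
    for bid, cohort in truth["cohorts"].items():
        cont = read_container(_require(wd / "containers" / f"{bid}.cmg", "glandcell prepare"))
        out[cohort].append(cont)
    return out


def stage_train(config: RunConfig) -> Path:
    """Train (one or two rounds) on the prepared cohorts; persist artifacts."""
    wd = _workdir(config)
    cohorts = _load_cohort_containers(config, wd)
    spec, tcfg = config.model_spec(), config.train_config()
    if config.two_rounds:
        result = run_two_rounds(cohorts["train"], cohorts["val"], spec, tcfg)
        model = result.model
        for ledger in result.ledgers:
            (wd / "ledgers" / f"round{ledger.round_index}.json").write_text(
                json.dumps(ledger.to_jsonable(), indent=1)
            )
        audit_rows = [
            {
                "biopsy_id": bid,
                "nucleus_id": nid,
                "provenance": prov,
                "human_label": result.ledgers[1].human_labels.get((bid, nid), ""),
            }
            for (bid, nid), prov in result.ledgers[1].provenance.items()
        ]
        pd.DataFrame(audit_rows).to_csv(wd / "ledgers" / "audit.csv", index=False)
    else:
        model = build_model(spec, seed=tcfg.seed)
        train(model, cohorts["train"], tcfg, val_data=cohorts["val"] or None)
    model.save(wd / "model" / "checkpoint.npz")
    pd.DataFrame(model.history).to_csv(wd / "model" / "history.csv", index=False)
    log.info("train: checkpoint at %s", wd / "model" / "checkpoint.npz")
    return wd


def stage_predict(config: RunConfig) -> Path:
    """Predict every container with the checkpointed model; store in records."""
    wd = _workdir(config)
    model = GlandNet.load(_require(wd / "model" / "checkpoint.npz", "glandcell train"))
    for path in sorted((wd / "containers").glob("*.cmg")):
        cont = read_container(path)
        if cont.patch_size != model.spec.input_size:
            raise ValueError(
                f"{path.name}: container patch size {cont.patch_size} does not match "
                f"model input size {model.spec.input_size}"
            )
        probs = predict_proba(model, cont)
        write_container(cont, path)
        pd.DataFrame(
            {"nucleus_id": [r.nucleus_id for r in cont.records], "p_gland": probs}
        ).to_csv(wd / "reports" / f"predictions_{cont.biopsy_id}.csv", index=False)
    log.info("predict: wrote probabilities into %s", wd / "containers")
    return wd


def stage_evaluate(config: RunConfig) -> Path:
    """Score test-cohort predictions against hidden truth; emit reports/overlays."""
    wd = _workdir(config)
    truth = json.loads(_require(wd / "truth" / "labels.json", "glandcell prepare").read_text())
    reports: dict[str, dict] = {}
    per_biopsy_acc: dict[str, float] = {}
    for bid, cohort in truth["cohorts"].items():
        if cohort != "test":
            continue
        cont = read_container(_require(wd / "containers" / f"{bid}.cmg", "glandcell prepare"))
        if any(r.prediction is None for r in cont.records):
            raise FileNotFoundError(
                f"container {bid} has no predictions — run `glandcell predict` first"
            )
        t = [truth["truth"][bid][str(r.nucleus_id)] for r in cont.records]
        scores = np.array([r.prediction for r in cont.records])
        preds = classify(scores, config.train_config().decision_threshold)
        rep = evaluate(t, preds, scores)
        reports[bid] = rep.rounded()
        per_biopsy_acc[bid] = rep.accuracy
        fpr, tpr, _ = roc_points(scores, t)
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(wd / "reports" / f"roc_{bid}.csv", index=False)
        rec, prec, _ = pr_points(scores, t)
        pd.DataFrame({"recall": rec, "precision": prec}).to_csv(
            wd / "reports" / f"pr_{bid}.csv", index=False
        )
        overlay = render_overlay(cont, t, preds)
        save_image(overlay, wd / "overlays" / f"{bid}.png")
    if not reports:
        raise FileNotFoundError("no test-cohort containers found to evaluate")
    (wd / "reports" / "test_reports.json").write_text(json.dumps(reports, indent=1))
    pd.DataFrame(reports).T.to_csv(wd / "reports" / "summary.csv")

    # simulated observer consensus over per-biopsy quality
    rng = np.random.default_rng(config.seed + 7)
    bids = sorted(per_biopsy_acc)
    k = min(config.consensus_k, len(bids) // 2)  # best/worst lists must not overlap
    if k >= 1:
        rankings = []
        for obs in range(3):
            noisy = {b: per_biopsy_acc[b] + rng.normal(0, 0.5) for b in bids}
            ordered = sorted(bids, key=lambda b: -noisy[b])
            rankings.append(
                ObserverRanking(f"observer-{obs}", tuple(ordered[:k]), tuple(ordered[-k:]))
            )
        best, worst, agreement = consensus_select(rankings, k, biopsy_ids=set(bids))
        payload = {
            "rankings": [dataclasses.asdict(r) for r in rankings],
            "consensus_best": sorted(best),
            "consensus_worst": sorted(worst),
            "agreement": agreement,
        }
    else:
        best = worst = set()
        payload = {
            "rankings": [],
            "note": "test cohort too small for disjoint best/worst ranking lists",
        }
    (wd / "rankings" / "observers.json").write_text(json.dumps(payload, indent=1))
    log.info("evaluate: %d test biopsies, consensus best=%s worst=%s", len(reports), sorted(best), sorted(worst))
    return wd


def run_stage(stage: str, config: RunConfig) -> Path:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    return {
        "prepare": stage_prepare,
        "train": stage_train,
        "predict": stage_predict,
        "evaluate": stage_evaluate,
    }[stage](config)


def run_demo(config: RunConfig | None = None) -> Path:
    """The full synthetic demonstration: prepare -> train -> predict -> evaluate."""
    config = config or RunConfig()
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    wd = stage_prepare(config)
    stage_train(config)
    stage_predict(config)
    stage_evaluate(config)
    return wd


def compare_patch_sizes(
    config: RunConfig, sizes: tuple[int, int] = (32, 64)
) -> pd.DataFrame:
    """Train/evaluate the same cohorts at two patch sizes, side by side.

    Mirrors the original patch-size comparison harness (their 128 vs 256)
    at desk scale; returns and persists a two-row metric table.
    """
    rows = {}
    base_wd = Path(config.workdir)
    for size in sizes:
        sub = dataclasses.replace(
            config, patch_size=size, workdir=str(base_wd / f"patch{size}"), two_rounds=False
        )
        stage_prepare(sub)
        stage_train(sub)
        stage_predict(sub)
        stage_evaluate(sub)
        reports = json.loads((Path(sub.workdir) / "reports" / "test_reports.json").read_text())
        df = pd.DataFrame(reports).T
        rows[f"patch-{size}"] = df.mean(numeric_only=True)
    table = pd.DataFrame(rows).T
    base_wd.mkdir(parents=True, exist_ok=True)
    table.to_csv(base_wd / "patch_size_comparison.csv")
    return table
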