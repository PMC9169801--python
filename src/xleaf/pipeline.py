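"""End-to-end orchestration of the explanation-guided improvement framework.

The four-step loop: (1) train a baseline classifier with cross-entropy,
(2) explain it with Grad-CAM, (3) encode expertise as annotation matrices
(generated automatically by the simulator), (4) retrain from a fresh,
identically seeded initialization with the balanced right-reasons loss, and
assess both models on the identical test split.  ``kfold_cv`` repeats the
comparison under stratified k-fold resampling.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gradcam, leafsim, nets, xmetrics
from .leafsim import LabeledDataset, SceneConfig, build_dataset
from .nets import NetworkSpec, TrainConfig, build_network, train
from .rrr import LossSpec
from .xmetrics import AssessmentReport, assess_model

__all__ = ["ExperimentConfig", "ComparisonReport", "CVReport",
           "run_framework", "kfold_cv", "DEFAULT_EPOCHS", "DEFAULT_LAMBDA"]

log = logging.getLogger("xleaf")

# task-specific defaults: training epochs and right-reasons weight
DEFAULT_EPOCHS = {"fake_vs_real": 90, "diseased_vs_healthy": 60, "species": 90}
DEFAULT_LAMBDA = {"fake_vs_real": 1.5, "diseased_vs_healthy": 2.0, "species": 2.0}


@dataclass
class ExperimentConfig:
    task: str = "fake_vs_real"
    scene: SceneConfig = field(default_factory=SceneConfig)
    n_samples: int = 500
    split_fracs: tuple[float, float, float] = (0.6, 0.2, 0.2)
    variant: str = "tiny"
    epochs: int | None = None           # None -> task default
    batch_size: int = 16
    learning_rate: float = 3e-3
    lambda_weight: float | None = None  # None -> task default
    rloss_variant: str = "squared"
    percents: tuple[float, ...] = (1.0, 5.0, 10.0)
    seed: int = 0
    out_dir: str | None = None

    def resolved_epochs(self) -> int:
        return self.epochs if self.epochs is not None \
            else DEFAULT_EPOCHS[self.task]

    def resolved_lambda(self) -> float:
        return self.lambda_weight if self.lambda_weight is not None \
            else DEFAULT_LAMBDA[self.task]

    def network_spec(self) -> NetworkSpec:
        n_classes = 3 if self.task == "species" else 2
        U, V = self.scene.image_size
        return NetworkSpec(variant=self.variant, n_classes=n_classes,
                           input_size=(U, V, 3))

    def validate(self) -> None:
        self.scene.validate()
        self.network_spec().validate()
        if self.resolved_lambda() < 0:
            raise ValueError("lambda_weight must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        if "scene" in d:
            d["scene"] = SceneConfig.from_json(json.dumps(d["scene"]))
        for k in ("split_fracs", "percents"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ComparisonReport:
    """Baseline vs RRR assessment on the identical test split."""

    baseline: AssessmentReport
    rrr: AssessmentReport
    config: ExperimentConfig | None = None

    def deltas(self) -> dict:
        d = {"accuracy_pct": self.rrr.accuracy_pct - self.baseline.accuracy_pct,
             "rmse": self.rrr.mean_rmse - self.baseline.mean_rmse,
             "cosines": self.rrr.mean_cosine - self.baseline.mean_cosine}
        for p in self.baseline.percents:
            d[f"pip_{p:g}"] = self.rrr.mean_pip[p] - self.baseline.mean_pip[p]
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.baseline.to_row(), self.rrr.to_row()])


def _stage(name: str):
    log.info("stage: %s", name)


def _train_pair(ds: LabeledDataset, cfg: ExperimentConfig):
    """Train baseline (cross-entropy) and RRR models from the same init seed."""
    spec = cfg.network_spec()
    tc = TrainConfig(epochs=cfg.resolved_epochs(), batch_size=cfg.batch_size,
                     learning_rate=cfg.learning_rate, seed=cfg.seed)

    _stage("train baseline (cross-entropy)")
    base = build_network(spec, seed=cfg.seed)
    base, hist_base = train(base, ds, LossSpec(lambda_weight=0.0), tc)

    _stage("retrain with right-reasons loss (fresh identically-seeded init)")
    guided = build_network(spec, seed=cfg.seed)
    guided, hist_rrr = train(
        guided, ds,
        LossSpec(lambda_weight=cfg.resolved_lambda(),
                 rloss_variant=cfg.rloss_variant), tc)
    return base, hist_base, guided, hist_rrr


def _assess_pair(base, guided, ds, cfg, split="test") -> ComparisonReport:
    _stage("assess explanations (Grad-CAM + metrics)")
    rep_base = assess_model(base, ds, split=split, percents=cfg.percents,
                            model_id="baseline")
    rep_rrr = assess_model(guided, ds, split=split, percents=cfg.percents,
                           model_id="rrr")
    return ComparisonReport(baseline=rep_base, rrr=rep_rrr, config=cfg)


def run_framework(cfg: ExperimentConfig,
                  dataset: LabeledDataset | None = None) -> ComparisonReport:
    """Execute the full four-step framework and return the comparison.

    When ``cfg.out_dir`` is set, artifacts (manifest, histories, checkpoints,
    a few explanation previews, report.csv) are written there.
    """
    cfg.validate()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(cfg.to_json())

    if dataset is None:
        _stage("build dataset")
        dataset = build_dataset(cfg.task, cfg.scene, cfg.n_samples,
                                cfg.split_fracs, seed=cfg.seed)
    if out:
        leafsim.save_dataset(dataset, out / "dataset")

    base, hist_base, guided, hist_rrr = _train_pair(dataset, cfg)

    if out:
        pd.DataFrame(hist_base).to_csv(out / "history_baseline.csv", index=False)
        pd.DataFrame(hist_rrr).to_csv(out / "history_rrr.csv", index=False)
        nets.save_model(base, out / "baseline.npz")
        nets.save_model(guided, out / "rrr.npz")

    report = _assess_pair(base, guided, dataset, cfg)

    if out:
        report.to_frame().to_csv(out / "report.csv", index=False)
        # a few baseline-explanation previews for visual inspection
        test_idx = dataset.splits["test"][:4]
        for j, i in enumerate(test_idx):
            s = dataset.samples[i]
            for name, model in (("baseline", base), ("rrr", guided)):
                e = gradcam.gradcam_explain(model, s.image, s.label,
                                            model_id=name)
                gradcam.save_explanation(e, out / f"explanation_{name}_{j}")
                gradcam.render_preview(e, out / f"explanation_{name}_{j}.png")
    return report


@dataclass
class CVReport:
    """Per-fold accuracy and RMSE for both models, plus avg/max/min aggregates."""

    folds: pd.DataFrame  # columns: fold, acc_baseline, acc_rrr, rmse_baseline, rmse_rrr

    def aggregates(self) -> pd.DataFrame:
        rows = []
        for model in ("baseline", "rrr"):
            acc = self.folds[f"acc_{model}"]
            rm = self.folds[f"rmse_{model}"]
            rows.append({"model": model,
                         "average_acc_pct": acc.mean(), "max_acc_pct": acc.max(),
                         "min_acc_pct": acc.min(),
                         "average_rmse": rm.mean(), "max_rmse": rm.max(),
                         "min_rmse": rm.min()})
        return pd.DataFrame(rows)


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 31])
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < k:
            raise ValueError(f"class {cls} has {len(idx)} samples; cannot form "
                             f"{k} folds")
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


def kfold_cv(cfg: ExperimentConfig, k: int = 5) -> CVReport:
    """Stratified k-fold comparison; no validation split inside folds."""
    cfg.validate()
    if k < 2:
        raise ValueError("k must be >= 2")
    _stage("build dataset for cross-validation")
    full = build_dataset(cfg.task, cfg.scene, cfg.n_samples,
                         (1.0, 0.0, 0.0), seed=cfg.seed)
    labels = np.array([s.label for s in full.samples])
    folds = _stratified_folds(labels, k, cfg.seed)
    all_idx = np.arange(len(full.samples))

    rows = []
    for f, test_idx in enumerate(folds):
        _stage(f"fold {f + 1}/{k}")
        train_idx = np.setdiff1d(all_idx, test_idx)
        ds = LabeledDataset(samples=full.samples,
                            splits={"train": train_idx,
                                    "validation": np.array([], dtype=np.int64),
                                    "test": test_idx},
                            class_names=full.class_names, task=full.task)
        base, _, guided, _ = _train_pair(ds, cfg)
        rep = _assess_pair(base, guided, ds, cfg)
        rows.append({"fold": f,
                     "acc_baseline": rep.baseline.accuracy_pct,
                     "acc_rrr": rep.rrr.accuracy_pct,
                     "rmse_baseline": rep.baseline.mean_rmse,
                     "rmse_rrr": rep.rrr.mean_rmse})
    report = CVReport(folds=pd.DataFrame(rows))
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.folds.to_csv(out / "cv_folds.csv", index=False)
        report.aggregates().to_csv(out / "cv_report.csv", index=False)
    return report
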