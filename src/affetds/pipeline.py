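"""End-to-end experiment: corpus -> split -> adversarial training -> ensemble.

One seeded run generates a synthetic corpus, splits it 70/15/15 stratified,
trains the CNN (clean warm-up, then continued training on an adversarially
augmented training set), extracts fused HOG+deep features for the RBF-SVM,
combines both members by AUC-weighted soft voting, and evaluates everything
on the held-out test split. ``run_experiment`` repeats this over seeds and
compares the ensemble against each base model with Wilcoxon signed-rank
tests on the per-seed AUC and F1 series.

All randomness derives from the single root seed through a fixed per-stage
hash, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._exceptions import StageError
from .attacks import AttackConfig, adversarial_augment
from .backbone import BackboneConfig, RandomConvBackbone
from .classifiers import TrainReport, train_cnn, train_svm
from .config import RunConfig
from .data import DatasetManifest, ImageSample
from .ensemble import EnsembleWeights, compute_weights, ensemble_predict
from .evaluation import EvaluationReport, evaluate_scores, holm_adjust, wilcoxon_signed_rank
from .features import fused_feature_matrix
from .nn import CnnConfig, SmallCnn
from .preprocessing import PreprocessConfig, preprocess
from .synthetic import CorpusParams, PhantomParams, build_default_corpus, stratified_split

logger = logging.getLogger("affetds")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s affetds %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

_STAGES = ("corpus", "split", "cnn", "attack", "backbone", "svm")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the root seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(root_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class SeedRunResult:
    """Artifacts of one seeded end-to-end run."""

    seed: int
    reports: dict[str, EvaluationReport]
    weights: EnsembleWeights
    train_reports: dict[str, TrainReport]
    svm_model: object = None
    cnn_model: Optional[SmallCnn] = None
    backbone: Optional[RandomConvBackbone] = None
    manifest: Optional[DatasetManifest] = None


@dataclass
class ExperimentResult:
    """Per-seed reports plus the cross-seed model comparison table."""

    runs: list[SeedRunResult]
    comparison: pd.DataFrame
    metrics_table: pd.DataFrame

    def mean_metric(self, model: str, metric: str) -> float:
        rows = self.metrics_table[self.metrics_table["model"] == model]
        return float(rows[metric].mean())


def _split_arrays(manifest: DatasetManifest, pp: PreprocessConfig):
    """Preprocessed image stacks and 0/1 labels per split."""
    out = {}
    for split in ("train", "val", "test"):
        subset = manifest.subset(split)
        samples = [subset.samples[r.id] for r in subset.records]
        X = np.stack([preprocess(s.pixels, pp) for s in samples])
        y = np.array([1 if s.label == "manipulated" else 0 for s in samples], dtype=np.int64)
        out[split] = (samples, X, y)
    return out


def _timed(stage: str, root_seed: int, fn, *args, **kwargs):
    start = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # attach the stage name for diagnosability
        raise StageError(stage, exc) from exc
    logger.info("stage=%s seed=%d duration=%.1fs", stage, root_seed, time.perf_counter() - start)
    return result


def run_one(config: RunConfig, seed: int, keep_models: bool = False) -> SeedRunResult:
    """Execute the full pipeline for one root seed."""
    corpus_params = CorpusParams(
        n_total=config.corpus.n_total,
        real_fraction=config.corpus.real_fraction,
        insert_fraction=config.corpus.insert_fraction,
        image_size=config.corpus.image_size,
        phantom=PhantomParams(
            size=config.corpus.image_size,
            texture_amplitude=config.corpus.texture_amplitude,
        ),
    )
    pp = PreprocessConfig(size=config.preprocess.size, sigma=config.preprocess.sigma,
                          interp=config.preprocess.interp)

    corpus = _timed("corpus", seed, build_default_corpus, stage_seed(seed, "corpus"), params=corpus_params)
    manifest = _timed("split", seed, stratified_split, corpus, seed=stage_seed(seed, "split"))
    arrays = _split_arrays(manifest, pp)
    train_samples, X_train, y_train = arrays["train"]
    _, X_val, y_val = arrays["val"]
    _, X_test, y_test = arrays["test"]

    cnn_seed = stage_seed(seed, "cnn")
    base_cfg = dict(
        input_size=config.preprocess.size,
        conv_widths=config.train.conv_widths,
        fc_width=config.train.fc_width,
        head_pool=config.train.head_pool,
        head_downsample=config.train.head_downsample,
        weight_decay=config.train.weight_decay,
        learning_rate=config.train.learning_rate,
        batch_size=config.train.batch_size,
        seed=cnn_seed,
    )

    def _train_cnn_stage():
        # Phase 1: full clean training (early-stopped) so the attacks are
        # crafted against a competent gradient source.
        clean_cfg = CnnConfig(**base_cfg, patience=config.train.patience,
                              max_epochs=config.train.max_epochs)
        model, _ = train_cnn(X_train, y_train, X_val, y_val, config=clean_cfg)

        attack_cfg = AttackConfig(
            epsilon=config.attack.eps,
            alpha=config.attack.alpha,
            iterations=config.attack.iterations,
            seed=stage_seed(seed, "attack"),
        )
        # Attack images are the *preprocessed* training inputs.
        pp_samples = [
            ImageSample(
                s.id,
                X_train[i],
                s.label,
                s.mask if s.mask is not None and s.mask.shape == X_train[i].shape else None,
                s.provenance,
            )
            for i, s in enumerate(train_samples)
        ]
        augmented = adversarial_augment(
            model, pp_samples, attack_cfg,
            methods=config.attack.methods, fraction=config.attack.fraction,
        )
        X_aug = np.stack([s.pixels for s in augmented])
        y_aug = np.array([1 if s.label == "manipulated" else 0 for s in augmented], dtype=np.int64)

        # Phase 2: fine-tune on the adversarially augmented set; early
        # stopping treats the incoming clean weights as the baseline.
        finetune_cfg = CnnConfig(**base_cfg, patience=config.train.patience,
                                 max_epochs=max(1, config.train.finetune_epochs))
        model, report = train_cnn(X_aug, y_aug, X_val, y_val, config=finetune_cfg,
                                  initial_model=model)
        return model, report, X_aug, y_aug

    cnn_model, cnn_report, X_aug, y_aug = _timed("cnn", seed, _train_cnn_stage)

    backbone = RandomConvBackbone(
        BackboneConfig(input_size=config.preprocess.size, seed=stage_seed(seed, "backbone"))
    )

    def _train_svm_stage():
        F_train = fused_feature_matrix(X_aug, backbone)
        F_val = fused_feature_matrix(X_val, backbone)
        F_test = fused_feature_matrix(X_test, backbone)
        model, report = train_svm(
            F_train, y_aug, F_val, y_val,
            c_grid=config.train.c_grid, gamma_grid=config.train.gamma_grid,
            seed=stage_seed(seed, "svm"),
        )
        return model, report, F_test

    svm_model, svm_report, F_test = _timed("svm", seed, _train_svm_stage)

    weights = compute_weights(svm_report.val_auc, cnn_report.val_auc)
    p_svm = svm_model.predict_proba(F_test)
    p_cnn = cnn_model.predict_proba(X_test)
    p_final, _ = ensemble_predict(p_svm, p_cnn, weights, threshold=config.ensemble.threshold)

    threshold = config.ensemble.threshold
    reports = {
        "ensemble": evaluate_scores(y_test, p_final, model="ensemble", threshold=threshold, seed=seed),
        "svm": evaluate_scores(y_test, p_svm, model="svm", threshold=threshold, seed=seed),
        "cnn": evaluate_scores(y_test, p_cnn, model="cnn", threshold=threshold, seed=seed),
    }
    return SeedRunResult(
        seed=seed,
        reports=reports,
        weights=weights,
        train_reports={"svm": svm_report, "cnn": cnn_report},
        svm_model=svm_model if keep_models else None,
        cnn_model=cnn_model if keep_models else None,
        backbone=backbone if keep_models else None,
        manifest=manifest if keep_models else None,
    )


def compare_models(metrics_table: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank comparisons of the ensemble vs each base model.

    One row per (metric, baseline); Holm adjustment is applied across the
    two baselines within each metric.
    """
    rows = []
    for metric in ("auc", "f1"):
        p_values = []
        entries = []
        ens = metrics_table[metrics_table["model"] == "ensemble"].sort_values("seed")[metric].to_numpy(dtype=float)
        for baseline in ("svm", "cnn"):
            base = metrics_table[metrics_table["model"] == baseline].sort_values("seed")[metric].to_numpy(dtype=float)
            keep = np.isfinite(ens) & np.isfinite(base)  # drop seeds with undefined metrics
            w, p = wilcoxon_signed_rank(ens[keep], base[keep])
            entries.append({
                "metric": metric,
                "comparison": f"ensemble_vs_{baseline}",
                "mean_ensemble": float(np.nanmean(ens)) if np.isfinite(ens).any() else float("nan"),
                "mean_baseline": float(np.nanmean(base)) if np.isfinite(base).any() else float("nan"),
                "W": w,
                "p_value": p,
            })
            p_values.append(p)
        adjusted = holm_adjust(p_values)
        for entry, p_adj in zip(entries, adjusted):
            entry["p_holm"] = p_adj
            rows.append(entry)
    return pd.DataFrame(rows)


def run_experiment(
    config: RunConfig,
    seeds: Sequence[int],
    out_dir: Optional[str | Path] = None,
) -> ExperimentResult:
    """Run the pipeline per seed and compare models across seeds."""
    if len(seeds) == 0:
        raise StageError("experiment", ValueError("at least one seed is required"))
    runs = [run_one(config, int(s)) for s in seeds]

    rows = []
    for run in runs:
        for model, report in run.reports.items():
            def _num(value):
                return float("nan") if value is None else float(value)

            rows.append({
                "seed": run.seed,
                "model": model,
                "accuracy": _num(report.metrics["accuracy"]),
                "f1": _num(report.metrics["f1"]),
                "auc": _num(report.auc),
                "average_precision": _num(report.average_precision),
            })
    metrics_table = pd.DataFrame(rows)
    comparison = compare_models(metrics_table)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_table.to_csv(out / "metrics.csv", index=False)
        comparison.to_csv(out / "comparison.csv", index=False)
        for run in runs:
            for model, report in run.reports.items():
                report.to_json(out / f"report_seed{run.seed}_{model}.json")
            (out / f"weights_seed{run.seed}.json").write_text(
                json.dumps({"w_svm": run.weights.w_svm, "w_cnn": run.weights.w_cnn}, indent=2)
            )
    return ExperimentResult(runs=runs, comparison=comparison, metrics_table=metrics_table)
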