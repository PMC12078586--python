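"""End-to-end pipeline: synthesize/ingest images -> preprocess ->
rebalance -> extract texture features -> bGGO feature selection ->
classify -> report.

A pipeline run is a pure function of (config, seed): the global seed
fans out to every stage through fixed offsets, so each stage can be
rerun in isolation and the whole report regenerates bit-identically.
The report carries a before/after-selection metric pair so the effect
of wrapper selection on held-out performance is visible directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import TABLE_METRIC_NAMES, MetricReport, confusion, metric_report, train_predict
from .ggo import GGOConfig
from .preprocess import (
    DatasetManifest,
    ImageSample,
    extract_texture_features,
    preprocess_pipeline,
    rebalance_splits,
)
from .select import FeatureTable, FitnessSpec, select_features
from .synthetic import gen_dataset

logger = logging.getLogger("greylag")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]

# fixed per-stage seed offsets (stages are rerunnable in isolation)
_SYNTH_OFFSET = 0
_SELECT_OFFSET = 1009
_CLASSIFY_OFFSET = 2003


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults give a small imbalanced
    two-class study that exercises every stage."""

    seed: int = 0
    image_counts: dict = field(default_factory=lambda: {
        ("train", "normal"): 60, ("train", "osteoarthritis"): 100,
        ("validation", "normal"): 20, ("validation", "osteoarthritis"): 32,
        ("test", "normal"): 50, ("test", "osteoarthritis"): 50,
    })
    image_side: int = 64
    highpass_cutoff: float = 0.05
    sharpen_amount: float = 1.0
    texture_grid: int = 4
    do_preprocess: bool = True
    do_rebalance: bool = True
    do_select: bool = True
    alpha: float = 0.99
    select_population: int = 12
    select_iterations: int = 30
    classifier_kind: str = "nn1"
    positive_class: str = "osteoarthritis"
    input_dir: str | None = None  # ingest instead of synthesizing
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "image_counts" in raw:
            raw["image_counts"] = {
                (r["split"], r["class"]): int(r["count"]) for r in raw["image_counts"]
            }
        return cls(**raw)


@dataclass
class RunReport:
    """All pipeline outputs; every number is recomputable from the
    stored intermediates."""

    manifest_before: DatasetManifest
    manifest_after: DatasetManifest
    metrics_before: MetricReport
    metrics_after: MetricReport
    mask_bits: np.ndarray
    feature_names: list[str]
    selection_fitness: float | None
    selection_error: float | None
    fitness_trace: np.ndarray | None
    seed: int
    timings: dict[str, float] = field(default_factory=dict)
    environment: dict[str, str] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {"Stage": "Before Feature Selection", **self.metrics_before.to_dict()},
            {"Stage": "After Feature Selection", **self.metrics_after.to_dict()},
        ]
        return pd.DataFrame(rows, columns=["Stage", *TABLE_METRIC_NAMES])


def _feature_table(images: list[ImageSample], split: str, grid: int) -> FeatureTable:
    subset = [img for img in images if img.split == split]
    names = [f"b{i}_{stat}" for stat in ("mean", "sd", "grad") for i in range(grid**2)]
    if not subset:
        return FeatureTable(np.zeros((0, 3 * grid**2)), np.array([]), names)
    vecs = np.array([extract_texture_features(img, grid) for img in subset])
    labels = np.array([img.class_label for img in subset])
    return FeatureTable(vecs, labels, names)


def _fingerprint() -> dict[str, str]:
    import sklearn, scipy, skimage

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "skimage": skimage.__version__,
    }


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order and return the report."""
    timings: dict[str, float] = {}
    current = {"stage": "init"}
    _t0 = {"t": 0.0}

    def stage(name):
        logger.info("stage=%s seed=%d", name, cfg.seed)
        current["stage"] = name
        _t0["t"] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - _t0["t"]

    try:
        stage("ingest")
        if cfg.input_dir:
            from .preprocess import load_image_dir

            images = load_image_dir(cfg.input_dir)
        else:
            images, _ = gen_dataset(cfg.image_counts, seed=cfg.seed + _SYNTH_OFFSET,
                                    side=cfg.image_side)
        manifest_before = DatasetManifest.from_images(images)
        done("ingest")

        stage("preprocess")
        if cfg.do_preprocess:
            images = [preprocess_pipeline(img, side=cfg.image_side,
                                          cutoff=cfg.highpass_cutoff,
                                          sharpen_amount=cfg.sharpen_amount)
                      for img in images]
        done("preprocess")

        stage("rebalance")
        if cfg.do_rebalance:
            manifest_after, images = rebalance_splits(images)
        else:
            manifest_after = DatasetManifest.from_images(images)
        done("rebalance")

        stage("extract")
        train = _feature_table(images, "train", cfg.texture_grid)
        val = _feature_table(images, "validation", cfg.texture_grid)
        test = _feature_table(images, "test", cfg.texture_grid)
        done("extract")

        stage("classify_before")
        clf_seed = (cfg.seed + _CLASSIFY_OFFSET) % (2**31)
        pred = train_predict(cfg.classifier_kind, {"seed": clf_seed}, train, test)
        metrics_before = metric_report(confusion(pred, test.labels, cfg.positive_class))
        done("classify_before")

        stage("select")
        if cfg.do_select:
            # wrapper validation = the pipeline's own validation split,
            # standardized by the training-split statistics
            mu = train.values.mean(axis=0)
            sd = train.values.std(axis=0)
            sd[sd == 0.0] = 1.0
            wrapper_split = (
                FeatureTable((train.values - mu) / sd, train.labels, train.column_names),
                FeatureTable((val.values - mu) / sd, val.labels, val.column_names),
            ) if val.n_samples else None
            sel = select_features(
                train,
                FitnessSpec(alpha=cfg.alpha),
                GGOConfig(population_size=cfg.select_population,
                          max_iterations=cfg.select_iterations,
                          seed=(cfg.seed + _SELECT_OFFSET) % (2**31)),
                split=wrapper_split,
            )
            bits = sel.best_mask.bits
            cols = sel.best_mask.selected_indices
            sel_fitness, sel_error, trace = sel.best_fitness, sel.error_at_best, sel.fitness_trace
        else:
            bits = np.ones(train.n_features, dtype=np.int8)
            cols = np.arange(train.n_features)
            sel_fitness = sel_error = None
            trace = None
        done("select")

        stage("classify_after")
        train_sel = FeatureTable(train.values[:, cols], train.labels,
                                 [train.column_names[i] for i in cols])
        test_sel = FeatureTable(test.values[:, cols], test.labels,
                                [test.column_names[i] for i in cols])
        pred = train_predict(cfg.classifier_kind, {"seed": clf_seed}, train_sel, test_sel)
        metrics_after = metric_report(confusion(pred, test_sel.labels, cfg.positive_class))
        done("classify_after")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {exc}") from exc

    report = RunReport(
        manifest_before=manifest_before,
        manifest_after=manifest_after,
        metrics_before=metrics_before,
        metrics_after=metrics_after,
        mask_bits=bits,
        feature_names=train.column_names,
        selection_fitness=sel_fitness,
        selection_error=sel_error,
        fitness_trace=trace,
        seed=cfg.seed,
        timings=timings,
        environment=_fingerprint(),
    )
    if cfg.output_dir:
        write_report(report, cfg.output_dir)
    return report


def write_report(report: RunReport, path) -> None:
    """Write the report: deterministic data CSVs plus a separate
    run-metadata file (timings, library versions)."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    report.manifest_before.to_csv(out / "manifest_before.csv")
    report.manifest_after.to_csv(out / "manifest_after.csv")
    report.metrics_frame().to_csv(out / "metrics.csv", index=False)
    pd.DataFrame({"column_name": report.feature_names,
                  "bit": report.mask_bits}).to_csv(out / "mask.csv", index=False)
    if report.fitness_trace is not None:
        pd.DataFrame({"iteration": np.arange(len(report.fitness_trace)),
                      "best_fitness": report.fitness_trace}
                     ).to_csv(out / "selection_trace.csv", index=False)
    summary = {
        "seed": report.seed,
        "selected_features": int(report.mask_bits.sum()),
        "total_features": int(len(report.mask_bits)),
        "selection_fitness": report.selection_fitness,
        "selection_error": report.selection_error,
        "accuracy_before": report.metrics_before.accuracy,
        "accuracy_after": report.metrics_after.accuracy,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    meta = {"timings_s": report.timings, "environment": report.environment}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
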