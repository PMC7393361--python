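"""End-to-end orchestration: preprocess -> split -> reduce -> classify -> report.

The pipeline trains all nine reduction x classifier combinations
(PCA/SPA/GA x LDA/QDA/SVM) on the Kennard-Stone training set, tunes
hyperparameters (PC count, SVM box constraint) on the validation set, and
evaluates figures of merit and ROC/AUC on the held-out test set.  Test rows
never reach any fitting or tuning routine; the provenance record logs the
index sets so this can be audited.

A single global seed is fanned out to per-stage seeds through a fixed
derivation (``stage_seeds``), so any stochastic stage (generator, GA) can be
rerun in isolation and reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import performance as perf
from .preprocessing import PreprocessConfig, preprocess
from .reduction import (
    GAParams,
    ReductionModel,
    choose_pca_components,
    ga_select,
    spa_select,
)
from .spectra import SpectralDataset, average_replicates, read_spectra
from .splitting import SplitResult, split_dataset
from .synthetic import GeneratorConfig, generate

logger = logging.getLogger(__name__)

REDUCTIONS = ("PCA", "SPA", "GA")
CLASSIFIERS = ("LDA", "QDA", "SVM")
MODEL_NAMES = tuple(f"{r}-{c}" for r in REDUCTIONS for c in CLASSIFIERS)

METRIC_COLUMNS = ("AC", "SENS", "SPEC", "YOU", "PPV", "NPV", "F_score", "G_score", "AUC")


def stage_seeds(seed: int) -> dict:
    """Deterministic fan-out of one global seed into per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2)
    return {
        "generator": int(children[0].generate_state(1)[0] % 2**31),
        "ga": int(children[1].generate_state(1)[0] % 2**31),
    }


@dataclass
class RunConfig:
    """Everything a full run needs; exactly one input source.

    ``input_path`` reads a replicate-level wide CSV; otherwise ``generator``
    produces a synthetic cohort.  ``seed`` is mandatory when the generator or
    the GA is used.
    """

    seed: int = 0
    input_path: Optional[str] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    f_train: float = 0.70
    f_val: float = 0.15
    f_test: float = 0.15
    pca_max_components: int = 20
    spa_max_vars: int = 30
    ga: GAParams = field(default_factory=GAParams)
    svm_gamma: float = 1.0
    svm_C_grid: tuple = clf.DEFAULT_C_GRID
    models: tuple = MODEL_NAMES

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "generator" in kwargs and isinstance(kwargs["generator"], dict):
            kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
        if "preprocess" in kwargs and isinstance(kwargs["preprocess"], dict):
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "ga" in kwargs and isinstance(kwargs["ga"], dict):
            kwargs["ga"] = GAParams(**kwargs["ga"])
        for tup in ("svm_C_grid", "models"):
            if tup in kwargs and isinstance(kwargs[tup], list):
                kwargs[tup] = tuple(kwargs[tup])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ModelResult:
    """One reduction x classifier combination, evaluated on the test set."""

    name: str
    reduction: ReductionModel
    report: perf.PerformanceReport
    confusion: perf.ConfusionMatrix
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    scores: np.ndarray  # per-test-sample ROC score
    classifier: object  # DiscriminantModel | SvmModel


def load_input(cfg: RunConfig):
    """Obtain the replicate-level dataset (file or generator) and ground truth."""
    if cfg.input_path is not None:
        return read_spectra(cfg.input_path), None
    gen_cfg = dataclasses.replace(cfg.generator, seed=stage_seeds(cfg.seed)["generator"])
    return generate(gen_cfg)


def fit_reductions(
    X: np.ndarray,
    y: np.ndarray,
    split: SplitResult,
    cfg: RunConfig,
    which=REDUCTIONS,
) -> dict:
    """Fit the requested reduction models on train, scored on validation."""
    tr, va = split.train_idx, split.val_idx
    out = {}
    if "PCA" in which:
        out["PCA"] = choose_pca_components(
            X[tr], y[tr], X[va], y[va], cfg.pca_max_components
        )
    if "SPA" in which:
        out["SPA"] = spa_select(X[tr], y[tr], X[va], y[va], cfg.spa_max_vars)
    if "GA" in which:
        ga_params = dataclasses.replace(cfg.ga, seed=stage_seeds(cfg.seed)["ga"])
        out["GA"] = ga_select(X[tr], y[tr], X[va], y[va], ga_params)
    return out


def _evaluate_combo(
    name: str,
    reduction: ReductionModel,
    X: np.ndarray,
    y: np.ndarray,
    split: SplitResult,
    cfg: RunConfig,
) -> ModelResult:
    classifier_kind = name.split("-")[1]
    tr, va, te = split.train_idx, split.val_idx, split.test_idx
    Xt, Xv, Xe = (reduction.transform(X[idx]) for idx in (tr, va, te))
    if classifier_kind in ("LDA", "QDA"):
        model = clf.fit_discriminant(Xt, y[tr], classifier_kind.lower())
        y_pred, margins, _ = clf.classify_discriminant(model, Xe)
        scores = margins
    else:
        model = clf.fit_svm(
            Xt, y[tr], gamma=cfg.svm_gamma, C_grid=cfg.svm_C_grid,
            X_val=Xv, y_val=y[va],
        )
        dec = clf.svm_decision(model, Xe)
        pm, _ = clf.svm_classify(model, Xe)
        y_pred = (pm == 1).astype(int)
        scores = dec
    cm = perf.confusion(y[te], y_pred)
    fpr, tpr, _, auc = perf.roc(scores, y[te])
    report = perf.figures_of_merit(cm, auc=auc)
    return ModelResult(name=name, reduction=reduction, report=report,
                       confusion=cm, roc_fpr=fpr, roc_tpr=tpr,
                       scores=scores, classifier=model)


def run_models(ds_raw: SpectralDataset, cfg: RunConfig):
    """Library entry point: full pipeline on a replicate-level dataset.

    Returns ``(results, context)`` where ``results`` maps model names to
    :class:`ModelResult` (failed combinations are absent, logged) and
    ``context`` carries the preprocessed dataset, the split and provenance.
    """
    ds_avg = average_replicates(ds_raw)
    ds_p, prep_prov = preprocess(ds_avg, cfg.preprocess)
    split = split_dataset(ds_p, cfg.f_train, cfg.f_val, cfg.f_test)
    X, y = ds_p.absorbance, ds_p.labels
    if y is None:
        raise ValueError("pipeline requires labelled data")
    wanted_reductions = sorted({m.split("-")[0] for m in cfg.models},
                               key=REDUCTIONS.index)
    reductions = fit_reductions(X, y, split, cfg, wanted_reductions)
    results = {}
    for name in cfg.models:
        red = reductions.get(name.split("-")[0])
        if red is None:
            continue
        try:
            results[name] = _evaluate_combo(name, red, X, y, split, cfg)
        except Exception:
            logger.exception("model %s failed; continuing with the rest", name)
    context = {
        "dataset": ds_p,
        "split": split,
        "reductions": reductions,
        "preprocess_provenance": prep_prov,
        "provenance": {
            "seed": cfg.seed,
            "stage_seeds": stage_seeds(cfg.seed),
            "n_samples": ds_p.n_rows,
            "split_sizes": [int(split.train_idx.size), int(split.val_idx.size),
                            int(split.test_idx.size)],
            "train_idx": split.train_idx.tolist(),
            "val_idx": split.val_idx.tolist(),
            "test_idx": split.test_idx.tolist(),
            "preprocess": prep_prov,
        },
    }
    return results, context


def metrics_frame(results: dict) -> pd.DataFrame:
    """Metric table, one row per model (display-rounded percentages)."""
    rows = []
    for name in MODEL_NAMES:
        if name not in results:
            continue
        rows.append({"Model": name, **results[name].report.rounded()})
    return pd.DataFrame(rows, columns=["Model", *METRIC_COLUMNS])


def selected_wavenumbers(results: dict, wavenumbers: np.ndarray) -> dict:
    """Wavenumbers (cm^-1) chosen by each selection-based reduction."""
    out = {}
    for name, res in results.items():
        if res.reduction.kind in ("spa", "ga"):
            out[name] = [float(wavenumbers[i]) for i in res.reduction.selected]
        else:
            out[name] = {"n_components": int(res.reduction.components.shape[0])}
    return out


def run_all(cfg: RunConfig, output_dir) -> dict:
    """Run everything and write report files into ``output_dir``.

    Writes ``metrics.csv`` / ``metrics.json`` (one row per model),
    ``roc_<model>.csv``, ``selected_wavenumbers.json`` and
    ``provenance.json``.  Returns the in-memory results dict.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds_raw, truth = load_input(cfg)
    results, context = run_models(ds_raw, cfg)

    table = metrics_frame(results)
    table.to_csv(outdir / "metrics.csv", index=False)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump({name: res.report.rounded() for name, res in results.items()},
                  fh, indent=2)
    wn = context["dataset"].wavenumbers
    with open(outdir / "selected_wavenumbers.json", "w") as fh:
        json.dump(selected_wavenumbers(results, wn), fh, indent=2)
    for name, res in results.items():
        pd.DataFrame({"fpr": res.roc_fpr, "tpr": res.roc_tpr}).to_csv(
            outdir / f"roc_{name}.csv", index=False
        )
    prov = dict(context["provenance"])
    if truth is not None:
        prov["synthetic"] = {
            "marker_wavenumbers": truth.marker_wavenumbers.tolist(),
            "n_positive": int(truth.labels.sum()),
        }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2)
    logger.info("wrote reports for %d model(s) to %s", len(results), outdir)
    return results
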