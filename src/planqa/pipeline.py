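"""Config-driven orchestration of the whole QA-prediction study.

One call runs the complete chain — cohort (synthetic or ingested),
features, 8:2 split, six tuned models, evaluation, feature importance,
univariate screens, learning curves — and writes a reproducible report
directory.  Everything stochastic derives from the single study seed,
so two runs with the same config produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from planqa import evaluation, models, synthetic
from planqa.evaluation import (
    DEFAULT_PASS_THRESHOLD, classify_labels, frame_to_records, records_to_frame,
    regression_metrics, roc_curve, auc, sens_spec, univariate_analysis,
)
from planqa.features import FEATURE_NAMES, features_frame
from planqa.mlc_io import read_fields
from planqa.models import ModelConfig, feature_importance, learning_curve, predict, split_dataset, tune_and_train

logger = logging.getLogger(__name__)

MODEL_LABELS = {("ann", "regression"): "ANN-RM", ("svm", "regression"): "SVM-RM",
                ("rf", "regression"): "RF-RM", ("ann", "classification"): "ANN-CM",
                ("svm", "classification"): "SVM-CM", ("rf", "classification"): "RF-CM"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Study parameters.

    Exactly one input source: either ``fields_path`` + ``gpr_csv``
    (measured cohort) or ``n_synthetic`` (simulated cohort).
    """

    seed: int
    n_synthetic: int | None = None
    fields_path: str | None = None
    gpr_csv: str | None = None
    test_fraction: float = 0.2
    pass_threshold: float = DEFAULT_PASS_THRESHOLD
    grids: dict = dc_field(default_factory=dict)  # per-algorithm overrides
    cv_folds: int = 10
    learning_curve_fractions: tuple = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))
    learning_curve_replicates: int = 3
    learning_curve_algorithms: tuple = ("rf",)
    run_learning_curves: bool = True
    out_dir: str = "planqa_study"

    def __post_init__(self) -> None:
        synth = self.n_synthetic is not None
        measured = self.fields_path is not None
        if synth == measured:
            raise ValueError("exactly one input source: n_synthetic or fields_path+gpr_csv")
        if measured and self.gpr_csv is None:
            raise ValueError("measured input needs gpr_csv with per-field GPR values")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}; known keys: {sorted(known)}")
        if "learning_curve_fractions" in raw:
            raw["learning_curve_fractions"] = tuple(raw["learning_curve_fractions"])
        if "learning_curve_algorithms" in raw:
            raw["learning_curve_algorithms"] = tuple(raw["learning_curve_algorithms"])
        return cls(**raw)


def _load_records(config: StudyConfig):
    if config.n_synthetic is not None:
        logger.info("stage=simulate n=%d seed=%d", config.n_synthetic, config.seed)
        return synthetic.generate_dataset(config.n_synthetic, master_seed=config.seed,
                                          pass_threshold=config.pass_threshold)
    logger.info("stage=ingest fields=%s gpr=%s", config.fields_path, config.gpr_csv)
    fields = read_fields(config.fields_path)
    feats = features_frame(fields)
    gpr = pd.read_csv(config.gpr_csv).set_index("field_id")["gpr_percent"]
    missing = [i for i in feats.index if i not in gpr.index]
    if missing:
        raise PipelineError("ingest", f"GPR values missing for fields {missing[:5]}...")
    df = feats.copy()
    df["gpr_percent"] = gpr.reindex(feats.index)
    df["label"] = classify_labels(df["gpr_percent"], config.pass_threshold)
    return frame_to_records(df)


def run_study(config: StudyConfig) -> dict:
    """Run the full study; writes records.csv, model summaries and report.json
    under ``config.out_dir`` and returns the report dictionary."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        records = _load_records(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cohort", str(exc)) from exc
    records_to_frame(records).to_csv(out / "records.csv")

    train, test = split_dataset(records, config.test_fraction, config.seed)
    logger.info("stage=split n=%d train=%d test=%d seed=%d",
                len(records), len(train), len(test), config.seed)

    report: dict = {
        "seed": config.seed,
        "n_records": len(records),
        "n_train": len(train),
        "n_test": len(test),
        "pass_threshold": config.pass_threshold,
        "pass_fraction": float(np.mean([r.label == 0 for r in records])),
        "models": {},
    }

    rf_models = {}
    for task in models.TASKS:
        for algo in models.ALGORITHMS:
            label = MODEL_LABELS[(algo, task)]
            cfg = ModelConfig(algorithm=algo, task=task,
                              tuning_grid=config.grids.get(algo, {}),
                              cv_folds=config.cv_folds, seed=config.seed)
            logger.info("stage=train model=%s grid=%s seed=%d", label, cfg.grid, config.seed)
            try:
                model = tune_and_train(cfg, train)
            except Exception as exc:
                raise PipelineError(f"train:{label}", str(exc)) from exc
            if algo == "rf":
                rf_models[task] = model
            scores = predict(model, test)
            block: dict = {"chosen_hyperparameters": model.chosen_hyperparameters,
                           "n_grid_points": len(model.tuning_trace)}
            if task == "regression":
                y_true = np.array([r.gpr for r in test])
                block["regression"] = regression_metrics(y_true, scores)
            else:
                y_true = np.array([r.label for r in test])
                sens, spec = sens_spec((scores >= 0.5).astype(int), y_true)
                block["classification"] = {
                    "auc": auc(scores, y_true),
                    "sensitivity": sens,
                    "specificity": spec,
                    "roc": [[float(a), float(b)] for a, b in roc_curve(scores, y_true)],
                }
            report["models"][label] = block
            logger.info("stage=evaluate model=%s chosen=%s elapsed=%.1fs",
                        label, model.chosen_hyperparameters, time.time() - t0)

    report["importance"] = {
        task: [[name, float(v)] for name, v in feature_importance(m)]
        for task, m in rf_models.items()
    }
    report["univariate"] = {
        name: univariate_analysis(records, name, config.pass_threshold)
        for name in FEATURE_NAMES
    }

    if config.run_learning_curves:
        report["learning_curves"] = {}
        for task in models.TASKS:
            for algo in config.learning_curve_algorithms:
                label = MODEL_LABELS[(algo, task)]
                cfg = ModelConfig(algorithm=algo, task=task,
                                  tuning_grid=config.grids.get(algo, {}),
                                  cv_folds=config.cv_folds, seed=config.seed)
                hp = report["models"][label]["chosen_hyperparameters"]
                logger.info("stage=learning_curve model=%s", label)
                curve = learning_curve(records, cfg,
                                       fractions=config.learning_curve_fractions,
                                       replicates=config.learning_curve_replicates,
                                       seed=config.seed,
                                       test_fraction=config.test_fraction,
                                       fixed_hyperparameters=hp)
                report["learning_curves"][label] = curve.to_dict(orient="records")

    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
    reg_table, cls_table = make_report_tables(report)
    reg_table.to_csv(out / "regression_table.csv")
    cls_table.to_csv(out / "classification_table.csv")
    logger.info("stage=done elapsed=%.1fs out=%s", time.time() - t0, out)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def make_report_tables(report: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summary tables: regression rows {RMSE(%), MAE(%), CC} × {ANN-RM,
    SVM-RM, RF-RM}; classification rows {AUC, specificity, sensitivity} ×
    {ANN-CM, SVM-CM, RF-CM}; cells formatted to two decimals."""
    missing = [lbl for lbl in MODEL_LABELS.values() if lbl not in report.get("models", {})]
    if missing:
        raise ValueError(f"report is missing model blocks: {missing}")
    reg_cols, cls_cols = ["ANN-RM", "SVM-RM", "RF-RM"], ["ANN-CM", "SVM-CM", "RF-CM"]
    reg = pd.DataFrame(
        {c: {
            "RMSE(%)": f"{report['models'][c]['regression']['rmse']:.2f}",
            "MAE(%)": f"{report['models'][c]['regression']['mae']:.2f}",
            "CC": f"{report['models'][c]['regression']['cc']:.2f}",
        } for c in reg_cols}
    ).loc[["RMSE(%)", "MAE(%)", "CC"]]
    cls = pd.DataFrame(
        {c: {
            "AUC": f"{report['models'][c]['classification']['auc']:.2f}",
            "specificity": f"{report['models'][c]['classification']['specificity']:.2f}",
            "sensitivity": f"{report['models'][c]['classification']['sensitivity']:.2f}",
        } for c in cls_cols}
    ).loc[["AUC", "specificity", "sensitivity"]]
    reg.index.name = "Evaluation indicators"
    cls.index.name = "Evaluation indicators"
    return reg, cls
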