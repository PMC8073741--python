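"""End-to-end convenience: synthetic study -> features -> classifier -> metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ethoclass, evalmetrics, featex, traceio
from .core import DEPLOYMENTS
from .synthio import StudyConfig, generate_study

__all__ = ["PipelineResult", "study_feature_table", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one train/evaluate pass produces."""

    deployment: str
    ethogram: int
    algorithm: str
    feature_table: pd.DataFrame
    train: pd.DataFrame
    test: pd.DataFrame
    ranking: pd.DataFrame
    model: ethoclass.TrainedClassifier
    predictions: np.ndarray
    cm: evalmetrics.ConfusionMatrix
    report: evalmetrics.MetricsReport

    @property
    def test_accuracy(self) -> float:
        return self.report.overall_accuracy


def study_feature_table(
    config: StudyConfig,
    deployment: str,
    min_event_s: float = 10.0,
) -> pd.DataFrame:
    """Generate a study in memory and extract its pooled feature table for
    one deployment, applying the >= ``min_event_s`` annotation rule and the
    observation-window trim exactly as the CSV path would."""
    if deployment not in DEPLOYMENTS:
        raise ValueError(f"unknown deployment {deployment!r}")
    epochs: list[featex.Epoch] = []
    start, end = config.observation_window
    for _, days in generate_study(config).items():
        for log, traces in days:
            log = traceio.filter_short_events(log, min_event_s)
            trace = traceio.trim_to_window(traces[deployment], start, end)
            lt = traceio.label_trace(trace, log)
            epochs.extend(featex.segment_epochs(lt, config.epoch_s))
    return featex.build_feature_table(epochs)


def run_pipeline(
    feature_table: pd.DataFrame,
    ethogram: int,
    algorithm: str = "RF",
    seed: int = 0,
    train_fraction: float = 0.70,
    cv_folds: int = 10,
    deployment: str = "",
) -> PipelineResult:
    """Split, rank, select, train and evaluate on one feature table."""
    mapped = ethoclass.apply_ethogram(feature_table, ethogram)
    train, test = ethoclass.stratified_split(mapped, train_fraction, seed=seed)
    ranking = ethoclass.rank_features_gini(train, seed=seed)
    features = ethoclass.select_features(ranking, algorithm)
    spec = ethoclass.ModelSpec(
        algorithm=algorithm, features=features, cv_folds=cv_folds, seed=seed
    )
    model = ethoclass.train_model(train, spec)
    predictions = ethoclass.predict(model, test)
    classes = sorted(mapped["label"].unique())
    cm = evalmetrics.confusion_matrix(predictions, test["label"].to_numpy(), classes)
    report = evalmetrics.metrics_report(cm)
    return PipelineResult(
        deployment=deployment,
        ethogram=ethogram,
        algorithm=algorithm,
        feature_table=feature_table,
        train=train,
        test=test,
        ranking=ranking,
        model=model,
        predictions=predictions,
        cm=cm,
        report=report,
    )
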