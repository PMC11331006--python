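"""Stacking of branch features and the boosted random-forest classifier.

The four hidden representations are column-concatenated in the fixed order
``F_PSN + F_Clin + F_Expr + F_CNV`` and passed to an adaptive-boosting
ensemble whose base learner is a small random forest (discrete boosting:
sample weights are re-weighted each round by the base forest's weighted
error). Prediction scores are the boosting-weight-weighted fraction of base
forests voting for the long-term class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier

from .datatypes import SOURCE_ORDER, FeatureBlock, LabelVector, StackedFeatures


@dataclass
class EnsembleConfig:
    n_boost_rounds: int = 50
    base_forest_trees: int = 10
    base_tree_depth: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_boost_rounds, self.base_forest_trees, self.base_tree_depth) < 1:
            raise ValueError("ensemble sizes must be >= 1")


@dataclass
class TrainedEnsemble:
    booster: AdaBoostClassifier
    config: EnsembleConfig
    n_features: int


def stack_features(blocks: list[FeatureBlock]) -> StackedFeatures:
    """Concatenate the four branch blocks in canonical source order."""
    sources = [b.source for b in blocks]
    if len(set(sources)) != len(sources):
        raise ValueError("duplicate feature-block source")
    if set(sources) != set(SOURCE_ORDER):
        raise ValueError(f"expected exactly the sources {SOURCE_ORDER}, got {sources}")
    by_source = {b.source: b for b in blocks}
    ids = by_source[SOURCE_ORDER[0]].patient_ids
    for b in blocks:
        if not np.array_equal(b.patient_ids, ids):
            raise ValueError("feature blocks must share patient order")
    boundaries: dict[str, tuple[int, int]] = {}
    pieces, offset = [], 0
    for source in SOURCE_ORDER:
        values = by_source[source].values
        boundaries[source] = (offset, offset + values.shape[1])
        offset += values.shape[1]
        pieces.append(values)
    return StackedFeatures(
        values=np.concatenate(pieces, axis=1),
        patient_ids=ids,
        block_boundaries=boundaries,
    )


def train_adaboost_rf(
    stacked: StackedFeatures, labels: LabelVector, config: EnsembleConfig = EnsembleConfig()
) -> TrainedEnsemble:
    """Fit AdaBoost over small random-forest base learners."""
    if not np.array_equal(stacked.patient_ids, labels.patient_ids):
        raise ValueError("stacked features and labels must be aligned")
    y = labels.label
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    base = RandomForestClassifier(
        n_estimators=config.base_forest_trees,
        max_depth=config.base_tree_depth,
        random_state=config.seed,
    )
    booster = AdaBoostClassifier(
        estimator=base,
        n_estimators=config.n_boost_rounds,
        random_state=config.seed,
    )
    booster.fit(stacked.values, y)
    return TrainedEnsemble(
        booster=booster, config=config, n_features=stacked.values.shape[1]
    )


def predict(
    model: TrainedEnsemble, stacked: StackedFeatures, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Scores (weighted vote fraction for class 1) and thresholded labels."""
    if stacked.values.shape[1] != model.n_features:
        raise ValueError("feature width does not match the trained model")
    booster = model.booster
    weights = np.asarray(booster.estimator_weights_[: len(booster.estimators_)])
    if weights.sum() <= 0:
        weights = np.ones(len(booster.estimators_))
    # each base forest's class-1 vote fraction, combined by boosting weight
    votes = np.stack(
        [est.predict_proba(stacked.values)[:, 1] for est in booster.estimators_], axis=1
    )
    scores = votes @ (weights / weights.sum())
    labels = (scores >= threshold).astype(int)
    return scores, labels


def predictions_to_frame(
    stacked: StackedFeatures, scores: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    return pd.DataFrame(
        {"patient_id": stacked.patient_ids, "score": scores, "label": labels}
    )
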