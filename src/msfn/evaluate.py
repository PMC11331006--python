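"""Evaluation: classification metrics, cross-validation, survival checks.

The six reported metrics are AUC (probability a positive's score exceeds a
negative's, ties counted half), accuracy, precision, recall, F1 and
Matthews correlation, all computed from per-fold confusion counts and then
averaged across folds — never pooled. Kaplan-Meier curves with a two-sample
log-rank test and a 2-D stochastic-neighbour embedding of the stacked
features provide the survival-analysis view of a classifier's output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .datatypes import LabelVector, OmicsBlock, StackedFeatures

METRIC_NAMES = ("accuracy", "auc", "precision", "recall", "f1", "mcc")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    per_fold: pd.DataFrame
    mean: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        out = self.per_fold.copy()
        out.loc["mean"] = {k: self.mean.get(k, np.nan) for k in out.columns}
        return out


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise-comparison AUC; tied positive/negative scores count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_confusion_metrics(cc: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and MCC from confusion counts."""
    tp, fp, tn, fn = cc.tp, cc.fp, cc.tn, cc.fn
    accuracy = _safe_div(tp + tn, cc.total, "accuracy")
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * recall * precision, recall + precision, "f1")
    mcc = _safe_div(
        tp * tn - fp * fn,
        float(np.sqrt(float(tp + fn) * (tp + fp) * (tn + fn) * (tn + fp))),
        "mcc",
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics_row(y_true: np.ndarray, scores: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """All six metrics plus raw confusion counts for one evaluated set."""
    cc = confusion_counts(y_true, y_pred)
    row = compute_confusion_metrics(cc)
    row["auc"] = compute_auc(scores, y_true)
    row.update({"tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn})
    return row


# ---------------------------------------------------------------------------
# cross-validation

def stratified_folds(
    labels: np.ndarray, k: int = 10, seed: int = 0, stratified: bool = True
) -> np.ndarray:
    """Deterministic fold assignment: a partition with fold sizes differing
    by at most one and, when stratified, class counts balanced per fold."""
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if k < 2 or k > n:
        raise ValueError("k must be in [2, n]")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    counter = 0
    groups = (
        [np.flatnonzero(labels == c) for c in sorted(np.unique(labels))]
        if stratified
        else [np.arange(n)]
    )
    for members in groups:
        members = rng.permutation(members)
        for idx in members:
            assignment[idx] = counter % k
            counter += 1
    return assignment


FitPredict = Callable[[Mapping[str, OmicsBlock], LabelVector, np.ndarray, int], tuple[np.ndarray, np.ndarray]]


def run_cross_validation(
    views: Mapping[str, OmicsBlock],
    labels: LabelVector,
    fit_predict: FitPredict | None = None,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> MetricsReport:
    """k-fold cross-validation of a fit/predict routine.

    ``fit_predict(views, labels, train_mask, fold_seed)`` must fit on the
    masked patients only and return (scores, predicted_labels) for every
    patient; metrics are computed on each test fold and averaged across
    folds. The default routine is the full stacked-fusion pipeline.
    """
    if fit_predict is None:
        from .pipeline import make_fit_predict

        fit_predict = make_fit_predict()
    y = labels.label
    folds = stratified_folds(y, k=k, seed=seed, stratified=stratified)
    rows = []
    for fold in range(k):
        test = folds == fold
        if len(np.unique(y[test])) < 2:
            raise ValueError(f"fold {fold} is missing a class; use stratified folds")
        train = ~test
        scores, preds = fit_predict(views, labels, train, seed * 1000 + fold)
        rows.append(metrics_row(y[test], scores[test], preds[test]))
    per_fold = pd.DataFrame(rows, index=[f"fold{f}" for f in range(k)])
    mean = {m: float(per_fold[m].mean()) for m in METRIC_NAMES}
    return MetricsReport(per_fold=per_fold, mean=mean)


def ablation_harness(
    views: Mapping[str, OmicsBlock],
    labels: LabelVector,
    variants: tuple[str, ...] = ("full", "-ResGCN", "-CNNs", "-RF"),
    k: int = 10,
    seed: int = 0,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Cross-validate the pipeline with single components removed.

    ``-ResGCN`` drops the patient-similarity feature block, ``-CNNs`` drops
    the three per-view blocks, ``-RF`` swaps the boosted forest for a
    one-hidden-layer perceptron head.
    """
    from .pipeline import make_fit_predict

    rows = []
    for variant in variants:
        fp = make_fit_predict(variant=variant, **pipeline_kwargs)
        report = run_cross_validation(views, labels, fp, k=k, seed=seed)
        rows.append({"variant": variant, **report.mean})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival analysis

def km_logrank(
    times: np.ndarray,
    events: np.ndarray,
    predicted_labels: np.ndarray,
) -> tuple[dict[int, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per predicted group plus a two-sample log-rank test.

    Returns ({group: survival curve}, chi-square statistic, p-value); the
    p-value comes from the 1-df chi-square distribution.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(predicted_labels, dtype=int)
    curves: dict[int, pd.DataFrame] = {}
    for g in (0, 1):
        mask = groups == g
        if not mask.any():
            raise ValueError(f"predicted group {g} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=f"group{g}")
        curves[g] = kmf.survival_function_
    res = logrank_test(
        times[groups == 0], times[groups == 1],
        event_observed_A=events[groups == 0], event_observed_B=events[groups == 1],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def plot_km(curves: dict[int, pd.DataFrame], path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, curve in curves.items():
        ax.step(curve.index, curve.iloc[:, 0], where="post", label=f"predicted {g}")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embed_2d(
    stacked: StackedFeatures,
    labels: np.ndarray,
    seed: int = 0,
    path: str | None = None,
) -> np.ndarray:
    """2-D t-distributed stochastic-neighbour embedding of stacked features."""
    from sklearn.manifold import TSNE

    n = len(stacked.values)
    if n < 10:
        raise ValueError("embedding needs at least 10 patients")
    perplexity = min(30.0, (n - 1) / 3.0)
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(stacked.values)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        labels = np.asarray(labels, dtype=int)
        for g, color in ((0, "tab:red"), (1, "tab:blue")):
            mask = labels == g
            ax.scatter(coords[mask, 0], coords[mask, 1], s=12, c=color, label=f"class {g}")
        ax.set_xlabel("dimension 1")
        ax.set_ylabel("dimension 2")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return coords
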