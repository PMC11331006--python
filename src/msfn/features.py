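"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

Greedy mutual-information selection: the first feature maximizes MI with
the class label; each subsequent feature maximizes relevance minus the mean
MI with the already-selected set (the MID, "difference", criterion; MIQ,
"quotient", is available as an option). Continuous features are discretized
into equal-frequency bins before any MI computation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import LabelVector, OmicsBlock


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI (nats) between two integer-coded variables via their contingency
    table: ``sum_ij p_ij log(p_ij / (p_i p_j))``."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    nx, ny = x.max() + 1, y.max() + 1
    joint = np.bincount(x * ny + y, minlength=nx * ny).reshape(nx, ny) / len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum())


@dataclass
class FeatureRanking:
    """Features in selection order with their criterion score at selection."""

    feature_names: list[str]
    scores: list[float]

    def top(self, n: int) -> list[str]:
        return self.feature_names[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names, "score": self.scores})


def discretize_columns(values: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning of every column (columns with few distinct
    values are left on their own codes)."""
    out = np.empty_like(values, dtype=int)
    for j in range(values.shape[1]):
        col = values[:, j]
        uniq = np.unique(col)
        if len(uniq) <= n_bins:
            out[:, j] = np.searchsorted(uniq, col)
        else:
            binned = pd.qcut(col, n_bins, labels=False, duplicates="drop")
            out[:, j] = np.asarray(binned, dtype=int)
    return out


def mrmr_rank(
    block: OmicsBlock,
    labels: LabelVector,
    n_top: int,
    criterion: str = "MID",
    n_bins: int = 3,
) -> FeatureRanking:
    """Greedy mRMR ranking of ``block``'s features against the labels.

    Deterministic: score ties are broken toward the lexicographically
    smaller feature name.
    """
    if criterion not in ("MID", "MIQ"):
        raise ValueError("criterion must be MID or MIQ")
    if n_top > block.n_features:
        raise ValueError("n_top exceeds the number of features")
    if not np.array_equal(block.patient_ids, labels.patient_ids):
        raise ValueError("block and labels must be aligned")
    y = labels.label
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; mutual information is undefined")

    binned = discretize_columns(block.values, n_bins)
    names = [str(n) for n in block.feature_names]
    f = block.n_features
    relevance = np.array([mutual_information(binned[:, j], y) for j in range(f)])

    # candidate order = lexicographic by name, so argmax ties resolve to the
    # smaller name
    order = sorted(range(f), key=lambda j: names[j])
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(f)
    pair_mi: dict[tuple[int, int], float] = {}

    for _ in range(n_top):
        best_j, best_score = -1, -np.inf
        for j in order:
            if j in selected:
                continue
            if not selected:
                score = relevance[j]
            else:
                red = redundancy_sum[j] / len(selected)
                if criterion == "MID":
                    score = relevance[j] - red
                else:
                    score = relevance[j] / max(red, 1e-12)
            if score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)
        scores.append(float(best_score))
        for j in order:
            if j not in selected:
                key = (min(j, best_j), max(j, best_j))
                if key not in pair_mi:
                    pair_mi[key] = mutual_information(binned[:, j], binned[:, best_j])
                redundancy_sum[j] += pair_mi[key]

    return FeatureRanking(
        feature_names=[names[j] for j in selected], scores=scores
    )


def incremental_search(
    cv_runner: Callable[[Mapping[str, int]], Mapping[str, float]],
    grid: Mapping[str, Sequence[int]],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Grid search over per-view feature counts.

    ``cv_runner`` receives a map view-name -> number of top-ranked features
    and returns the cross-validated metrics for that configuration (views
    absent from the map use all their features). Returns one metric row per
    combination and the accuracy-argmax combination.
    """
    view_names = sorted(grid)
    if not view_names or any(len(grid[v]) == 0 for v in view_names):
        raise ValueError("empty search grid")
    rows = []
    for combo in itertools.product(*(grid[v] for v in view_names)):
        counts = dict(zip(view_names, combo))
        metrics = dict(cv_runner(counts))
        rows.append({**{f"n_{v}": c for v, c in counts.items()}, **metrics})
    table = pd.DataFrame(rows)
    best_idx = int(table["accuracy"].idxmax())
    best = {v: int(table.loc[best_idx, f"n_{v}"]) for v in view_names}
    return table, best
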