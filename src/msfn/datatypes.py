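"""Shared data containers used across the pipeline.

All containers keep patients on rows, ordered consistently across views;
alignment is always by patient identifier, never by position alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VIEW_KINDS = ("clinical", "expression", "cnv")

#: Fixed order in which branch feature blocks are stacked.
SOURCE_ORDER = ("PSN", "Clin", "Expr", "CNV")


@dataclass
class OmicsBlock:
    """One view's patients x features matrix plus metadata.

    Missing entries are encoded as NaN; blocks are expected to be free of
    missing values after imputation.
    """

    values: np.ndarray
    patient_ids: np.ndarray
    feature_names: np.ndarray
    view_kind: str
    feature_kinds: np.ndarray | None = None  # 'discrete'/'continuous', clinical only

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.feature_names = np.asarray(self.feature_names, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, f = self.values.shape
        if len(self.patient_ids) != n:
            raise ValueError(f"{len(self.patient_ids)} patient ids for {n} rows")
        if len(self.feature_names) != f:
            raise ValueError(f"{len(self.feature_names)} feature names for {f} columns")
        if self.view_kind not in VIEW_KINDS:
            raise ValueError(f"view_kind must be one of {VIEW_KINDS}, got {self.view_kind!r}")
        if self.feature_kinds is not None:
            self.feature_kinds = np.asarray(self.feature_kinds, dtype=object)
            if len(self.feature_kinds) != f:
                raise ValueError("feature_kinds length must match feature count")
            bad = set(self.feature_kinds) - {"discrete", "continuous"}
            if bad:
                raise ValueError(f"unknown feature kinds: {bad}")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def continuous_mask(self) -> np.ndarray:
        """Boolean column mask of continuous features (all, if kinds absent)."""
        if self.feature_kinds is None:
            return np.ones(self.n_features, dtype=bool)
        return self.feature_kinds == "continuous"

    def with_values(self, values: np.ndarray) -> "OmicsBlock":
        return replace(self, values=np.asarray(values, dtype=float))

    def subset_features(self, names: Sequence[str]) -> "OmicsBlock":
        index = {name: i for i, name in enumerate(self.feature_names)}
        cols = np.array([index[n] for n in names], dtype=int)
        kinds = None if self.feature_kinds is None else self.feature_kinds[cols]
        return OmicsBlock(
            values=self.values[:, cols],
            patient_ids=self.patient_ids,
            feature_names=self.feature_names[cols],
            view_kind=self.view_kind,
            feature_kinds=kinds,
        )

    def subset_patients(self, ids: Sequence[str]) -> "OmicsBlock":
        index = {pid: i for i, pid in enumerate(self.patient_ids)}
        rows = np.array([index[p] for p in ids], dtype=int)
        return replace(self, values=self.values[rows], patient_ids=self.patient_ids[rows])


@dataclass
class SurvivalTable:
    """Per-patient follow-up time (months) and event indicator (1 = death)."""

    patient_ids: np.ndarray
    time_months: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.time_months = np.asarray(self.time_months, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.patient_ids) == len(self.time_months) == len(self.event)):
            raise ValueError("survival table columns must share length")
        if len(self.patient_ids) == 0:
            raise ValueError("survival table is empty")
        if (self.time_months <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    def __len__(self) -> int:
        return len(self.patient_ids)


@dataclass
class LabelVector:
    """Binary survival labels: 1 = long-term survivor (past the threshold)."""

    patient_ids: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.label = np.asarray(self.label, dtype=int)
        if len(self.patient_ids) != len(self.label):
            raise ValueError("ids and labels must share length")
        if not np.isin(self.label, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.patient_ids)


@dataclass
class FeatureBlock:
    """Hidden-layer representation exported by one trained branch."""

    values: np.ndarray
    source: str  # one of SOURCE_ORDER
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        if self.source not in SOURCE_ORDER:
            raise ValueError(f"source must be one of {SOURCE_ORDER}")
        if self.values.ndim != 2 or self.values.shape[0] != len(self.patient_ids):
            raise ValueError("values must be n_patients x d")
        if not np.isfinite(self.values).all():
            raise ValueError("feature block contains non-finite values")


@dataclass
class StackedFeatures:
    """Column-concatenation of branch feature blocks in fixed source order."""

    values: np.ndarray
    patient_ids: np.ndarray
    block_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)

    @property
    def width(self) -> int:
        return self.values.shape[1]
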