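"""Loading, cleaning, imputation, normalization and label derivation.

The cleaning protocol: drop features then samples whose missing fraction
exceeds 20%; impute continuous features by k-nearest-neighbour means and
discrete features by the per-feature mode; min-max scale continuous
features to [0, 1]. Copy-number values arrive already discretized and pass
through untouched. Binary labels come from a 5-year survival threshold:
patients alive at 5 years are long-term survivors (1), patients who died
earlier are short-term survivors (0), and patients censored before 5 years
carry no determinable 5-year outcome and are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .datatypes import LabelVector, OmicsBlock, SurvivalTable

MONTHS_PER_YEAR = 12.0


# ---------------------------------------------------------------------------
# readers / writers

def read_omics_tsv(
    path: str,
    view_kind: str,
    delimiter: str = "\t",
    feature_kinds: dict[str, str] | None = None,
) -> OmicsBlock:
    """Read a patients x features table (first column = patient id).

    Empty cells and ``NA`` are treated as missing. ``feature_kinds`` maps
    feature name -> 'discrete'/'continuous' for clinical views; unlisted
    features default to continuous.
    """
    df = pd.read_csv(path, sep=delimiter, na_values=["NA"], dtype={0: str})
    ids = df.iloc[:, 0].to_numpy(dtype=object)
    df = df.iloc[:, 1:]
    kinds = None
    if feature_kinds is not None:
        kinds = np.array(
            [feature_kinds.get(c, "continuous") for c in df.columns], dtype=object
        )
    return OmicsBlock(
        values=df.to_numpy(dtype=float),
        patient_ids=ids,
        feature_names=np.array(df.columns, dtype=object),
        view_kind=view_kind,
        feature_kinds=kinds,
    )


def read_survival_tsv(path: str, delimiter: str = "\t") -> SurvivalTable:
    """Read a (patient_id, time_months, event) table."""
    df = pd.read_csv(path, sep=delimiter, dtype={0: str})
    return SurvivalTable(
        patient_ids=df.iloc[:, 0].to_numpy(dtype=object),
        time_months=df.iloc[:, 1].to_numpy(dtype=float),
        event=df.iloc[:, 2].to_numpy(dtype=int),
    )


def one_hot_encode(df: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode string columns, categories ordered lexicographically.

    Numeric columns pass through unchanged. Utility for clinical tables that
    arrive with raw categorical strings rather than label-coded integers.
    """
    pieces = []
    for col in df.columns:
        if df[col].dtype == object:
            cats = sorted(x for x in df[col].dropna().unique())
            for cat in cats:
                pieces.append((f"{col}={cat}", (df[col] == cat).astype(float)))
        else:
            pieces.append((col, df[col].astype(float)))
    return pd.DataFrame(dict(pieces), index=df.index)


# ---------------------------------------------------------------------------
# label derivation

def derive_labels(surv: SurvivalTable, threshold_years: float = 5.0) -> LabelVector:
    """Binary 5-year survival labels; censored-before-threshold excluded."""
    if len(surv) == 0:
        raise ValueError("empty survival table")
    thr = threshold_years * MONTHS_PER_YEAR
    long_term = surv.time_months >= thr
    short_term = (surv.time_months < thr) & (surv.event == 1)
    keep = long_term | short_term
    return LabelVector(
        patient_ids=surv.patient_ids[keep],
        label=long_term[keep].astype(int),
    )


# ---------------------------------------------------------------------------
# cleaning / imputation / scaling

def filter_missing(block: OmicsBlock, max_frac: float = 0.20) -> OmicsBlock:
    """Drop features, then samples, whose missing fraction exceeds ``max_frac``."""
    if not 0.0 <= max_frac < 1.0:
        raise ValueError("max_frac must be in [0, 1)")
    miss = np.isnan(block.values)
    keep_cols = miss.mean(axis=0) <= max_frac
    miss = miss[:, keep_cols]
    keep_rows = (
        miss.mean(axis=1) <= max_frac
        if keep_cols.any()
        else np.zeros(block.n_patients, dtype=bool)
    )
    if not keep_rows.any():
        raise ValueError("missing-value filter removed every sample")
    kinds = None if block.feature_kinds is None else block.feature_kinds[keep_cols]
    return OmicsBlock(
        values=block.values[np.ix_(keep_rows, keep_cols)],
        patient_ids=block.patient_ids[keep_rows],
        feature_names=block.feature_names[keep_cols],
        view_kind=block.view_kind,
        feature_kinds=kinds,
    )


def impute_knn_continuous(block: OmicsBlock, k: int = 5) -> OmicsBlock:
    """Fill missing continuous cells with the mean of the k nearest patients.

    Distances are Euclidean over mutually observed continuous features
    (missing-aware), and only neighbours observing the target feature donate.
    """
    cont = block.continuous_mask()
    values = block.values.copy()
    sub = values[:, cont]
    if sub.size == 0 or not np.isnan(sub).any():
        return block.with_values(values)
    if np.isnan(sub).all(axis=0).any():
        raise ValueError("a continuous feature is entirely missing")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    values[:, cont] = imputer.fit_transform(sub)
    return block.with_values(values)


def impute_mode_discrete(block: OmicsBlock) -> OmicsBlock:
    """Fill missing discrete cells with the per-feature mode (ties -> smallest)."""
    if block.feature_kinds is None:
        return block
    values = block.values.copy()
    for j in np.flatnonzero(block.feature_kinds == "discrete"):
        col = values[:, j]
        nan = np.isnan(col)
        if not nan.any():
            continue
        observed = col[~nan]
        if observed.size == 0:
            raise ValueError(f"feature {block.feature_names[j]} entirely missing")
        uniq, counts = np.unique(observed, return_counts=True)
        mode = uniq[counts == counts.max()].min()  # smallest value wins ties
        col[nan] = mode
    return block.with_values(values)


def minmax_normalize(block: OmicsBlock) -> OmicsBlock:
    """Scale each continuous feature to [0, 1]; constant features map to 0."""
    if block.has_missing():
        raise ValueError("impute before normalizing")
    values = block.values.copy()
    cont = block.continuous_mask()
    sub = values[:, cont]
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    span = hi - lo
    constant = span == 0
    span[constant] = 1.0
    sub = (sub - lo) / span
    sub[:, constant] = 0.0
    values[:, cont] = sub
    return block.with_values(values)


def preprocess_view(block: OmicsBlock, max_missing: float = 0.20, knn_k: int = 5) -> OmicsBlock:
    """Filter -> impute -> normalize, per view kind.

    Clinical: KNN imputation for continuous covariates, mode for discrete,
    then min-max on continuous columns. Expression: min-max. CNV: the
    discretized values pass through unchanged.
    """
    block = filter_missing(block, max_missing)
    if block.view_kind == "clinical":
        block = impute_knn_continuous(block, knn_k)
        block = impute_mode_discrete(block)
        return minmax_normalize(block)
    if block.view_kind == "expression":
        block = impute_knn_continuous(block, knn_k)
        return minmax_normalize(block)
    # cnv: discretized raw values are used directly
    if block.has_missing():
        block = impute_mode_discrete(
            OmicsBlock(
                values=block.values,
                patient_ids=block.patient_ids,
                feature_names=block.feature_names,
                view_kind=block.view_kind,
                feature_kinds=np.array(["discrete"] * block.n_features, dtype=object),
            )
        )
        block = OmicsBlock(
            values=block.values,
            patient_ids=block.patient_ids,
            feature_names=block.feature_names,
            view_kind="cnv",
        )
    return block


def align_patients(
    views: dict[str, OmicsBlock], labels: LabelVector
) -> tuple[dict[str, OmicsBlock], LabelVector]:
    """Restrict all views and labels to their common patients, sorted by id."""
    common = set(labels.patient_ids)
    for block in views.values():
        common &= set(block.patient_ids)
    if not common:
        raise ValueError("no patients shared across views and labels")
    order = sorted(common)
    lab_index = {p: i for i, p in enumerate(labels.patient_ids)}
    rows = [lab_index[p] for p in order]
    aligned_labels = LabelVector(
        patient_ids=labels.patient_ids[rows], label=labels.label[rows]
    )
    aligned_views = {v: b.subset_patients(order) for v, b in views.items()}
    return aligned_views, aligned_labels
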